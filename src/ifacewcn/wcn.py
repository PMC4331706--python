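"""Weighted contact number (WCN) and its normalizations.

The WCN of residue i is sum over every other residue j of the same
subunit of 1/r_ij^2, with r_ij the distance between residue
representative points (Cα by default). High WCN means dense local
packing, which tracks rigidity; the reciprocal of WCN approximates the
crystallographic B-factor profile. Partner subunits never contribute, so
the measure describes the subunit as if unbound.

Because WCN grows with subunit size, comparisons use z-scores. Two
normalizations exist: per subunit (mean/SD over that subunit's surface
residues -> ``z``) and global (one mean/SD over the pooled surface
residues of a whole dataset -> ``zwcn``). Population SD throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import Subunit


def compute_wcn(subunit: Subunit, representative: str = "CA") -> np.ndarray:
    """Per-residue WCN (Å⁻²) over all residues of one subunit.

    ``representative`` is 'CA' or 'centroid' (heavy-atom centroid used for
    every residue; residues missing Cα raise under the default rule).
    """
    n = len(subunit.residues)
    if n < 2:
        raise ValueError("WCN needs at least 2 residues")
    points = np.array(
        [r.representative_point(representative) for r in subunit.residues]
    )
    d = squareform(pdist(points))
    zero = np.argwhere((d == 0.0) & ~np.eye(n, dtype=bool))
    if len(zero):
        i, j = zero[0]
        ri, rj = subunit.residues[i], subunit.residues[j]
        raise ValueError(
            f"coincident representative points: {ri.chain_id}/{ri.seq_id} "
            f"and {rj.chain_id}/{rj.seq_id}"
        )
    np.fill_diagonal(d, np.inf)
    return (1.0 / d**2).sum(axis=1)


def zscore_per_subunit(w: np.ndarray, surface_mask: np.ndarray) -> np.ndarray:
    """Standardize WCN over one subunit's surface residues.

    Mean and population SD are taken over surface residues only; the
    returned array carries z for surface residues and NaN elsewhere
    (buried residues have no z by definition).
    """
    w = np.asarray(w, dtype=float)
    surface_mask = np.asarray(surface_mask, dtype=bool)
    n_surf = int(surface_mask.sum())
    if n_surf < 2:
        raise ValueError(f"need >=2 surface residues, got {n_surf}")
    ws = w[surface_mask]
    sd = ws.std()  # population SD (ddof=0)
    if sd == 0.0:
        raise ValueError("zero WCN variance over surface residues (degenerate subunit)")
    z = np.full(w.shape, np.nan)
    z[surface_mask] = (ws - ws.mean()) / sd
    return z


def zscore_global(
    w_by_subunit: list[np.ndarray], surface_masks: list[np.ndarray]
) -> list[np.ndarray]:
    """Standardize WCN over the pooled surface residues of a dataset.

    One mean/SD is computed from all surface residues of all subunits;
    each subunit gets back an array with zWCN on surface positions and
    NaN elsewhere.
    """
    if len(w_by_subunit) != len(surface_masks):
        raise ValueError("w_by_subunit and surface_masks differ in length")
    pool = np.concatenate(
        [np.asarray(w)[np.asarray(m, dtype=bool)] for w, m in zip(w_by_subunit, surface_masks)]
    )
    if pool.size < 2:
        raise ValueError("need >=2 pooled surface residues")
    mean, sd = pool.mean(), pool.std()
    if sd == 0.0:
        raise ValueError("zero pooled WCN variance")
    out = []
    for w, m in zip(w_by_subunit, surface_masks):
        w = np.asarray(w, dtype=float)
        m = np.asarray(m, dtype=bool)
        zw = np.full(w.shape, np.nan)
        zw[m] = (w[m] - mean) / sd
        out.append(zw)
    return out
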