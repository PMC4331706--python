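"""Partition a subunit's residues into surface subregions.

Every residue of an unbound subunit receives exactly one label:

* NON_SURFACE — zero accessible area in the unbound subunit;
* NON_INTERFACE — on the surface, no partner contact;
* PERIPHERAL — interface residue still partly exposed in the complex;
* CENTRAL — interface residue essentially buried on complex formation
  (bound-state relative accessibility <= 5%).

An interface residue is a surface residue with any heavy atom within
5 Å (inclusive) of any partner-subunit heavy atom.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Subunit


class RegionLabel(str, Enum):
    NON_SURFACE = "non_surface"
    NON_INTERFACE = "non_interface"
    PERIPHERAL = "peripheral"
    CENTRAL = "central"

    def __str__(self) -> str:  # keep TSV exports compact
        return self.value


def surface_residues(unbound_sasa: np.ndarray) -> np.ndarray:
    """Mask of residues with strictly positive unbound accessible area."""
    return np.asarray(unbound_sasa, dtype=float) > 0.0


def interface_residues(
    subunit: Subunit,
    partner_atoms: np.ndarray,
    surface_mask: np.ndarray,
    cutoff: float = 5.0,
) -> np.ndarray:
    """Mask of surface residues with a heavy atom within ``cutoff`` of a partner.

    ``partner_atoms`` are the heavy-atom coordinates of all other subunits
    of the complex (protein atoms only, never ligands or waters). The
    cutoff is inclusive. A grid (k-d tree) search is used but the result
    equals the brute-force all-pairs answer.
    """
    partner_atoms = np.asarray(partner_atoms, dtype=float)
    if partner_atoms.size == 0:
        raise ValueError("empty partner atom set: not a complex")
    surface_mask = np.asarray(surface_mask, dtype=bool)
    if len(surface_mask) != len(subunit.residues):
        raise ValueError("surface mask length mismatch")
    tree = cKDTree(partner_atoms)
    mask = np.zeros(len(subunit.residues), dtype=bool)
    for i, res in enumerate(subunit.residues):
        if not surface_mask[i]:
            continue
        d, _ = tree.query(res.coords(), k=1)
        mask[i] = bool(np.min(d) <= cutoff)
    return mask


def partition_interface(
    surface_mask: np.ndarray,
    interface_mask: np.ndarray,
    bound_rsasa: np.ndarray,
    threshold: float = 0.05,
) -> list[RegionLabel]:
    """Assign one :class:`RegionLabel` per residue.

    Interface residues split on bound-state relative accessibility:
    <= ``threshold`` (inclusive) is CENTRAL, the rest PERIPHERAL. The
    threshold is never applied outside the interface.
    """
    surface_mask = np.asarray(surface_mask, dtype=bool)
    interface_mask = np.asarray(interface_mask, dtype=bool)
    bound_rsasa = np.asarray(bound_rsasa, dtype=float)
    if np.any(interface_mask & ~surface_mask):
        raise ValueError("interface mask contains non-surface residues")
    labels = []
    for i in range(len(surface_mask)):
        if interface_mask[i]:
            if not np.isfinite(bound_rsasa[i]):
                raise ValueError(f"bound rSASA missing for interface residue {i}")
            labels.append(
                RegionLabel.CENTRAL if bound_rsasa[i] <= threshold else RegionLabel.PERIPHERAL
            )
        elif surface_mask[i]:
            labels.append(RegionLabel.NON_INTERFACE)
        else:
            labels.append(RegionLabel.NON_SURFACE)
    return labels
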