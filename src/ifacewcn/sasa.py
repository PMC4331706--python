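"""Solvent-accessible surface area by the Shrake-Rupley method.

Each heavy atom is inflated by the probe radius (water, 1.4 Å by default)
and covered with a fixed, deterministic set of quasi-uniform test points
(golden-spiral lattice). A test point is buried when it falls inside any
other atom's inflated sphere; the accessible area is the exposed fraction
of the inflated sphere. Downstream analysis consumes areas only through
thresholds (surface: area > 0; interface core: relative area <= 5%), so
the contract here is classification stability, not parity with any
particular reference program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ComplexStructure, Residue

#: Van-der-Waals radii (Å) for the elements found in protein heavy atoms.
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90}

#: Maximal per-residue accessibility (Å²), Rost & Sander (1994) Gly-X-Gly
#: tripeptide convention. Used to turn areas into relative accessibility.
MAX_ASA_ROST_SANDER = {
    "ALA": 106.0, "ARG": 248.0, "ASN": 157.0, "ASP": 163.0, "CYS": 135.0,
    "GLN": 198.0, "GLU": 194.0, "GLY": 84.0, "HIS": 184.0, "ILE": 169.0,
    "LEU": 164.0, "LYS": 205.0, "MET": 188.0, "PHE": 197.0, "PRO": 136.0,
    "SER": 130.0, "THR": 142.0, "TRP": 227.0, "TYR": 222.0, "VAL": 142.0,
}

#: Theoretical maxima of Tien et al. (2013), selectable via configuration.
MAX_ASA_TIEN_THEORETICAL = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

MAX_ASA_TABLES = {
    "rost_sander": MAX_ASA_ROST_SANDER,
    "tien_theoretical": MAX_ASA_TIEN_THEORETICAL,
}


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible areas (Å²) for one computation."""

    per_atom: np.ndarray
    per_residue: np.ndarray
    probe_radius: float
    n_points: int


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit vectors."""
    k = np.arange(n, dtype=float)
    # offset 0.5 avoids degenerate poles; golden angle spaces the azimuths
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _atom_table(residues: list[Residue], vdw_radii: dict[str, float]):
    coords, radii, owner = [], [], []
    for ri, res in enumerate(residues):
        for atom in res.atoms:
            el = atom.element.upper()
            if el not in vdw_radii:
                raise KeyError(
                    f"no van-der-Waals radius configured for element {el!r} "
                    f"(atom {atom.name} in {res.chain_id}/{res.seq_id})"
                )
            coords.append(atom.coord)
            radii.append(vdw_radii[el])
            owner.append(ri)
    return (
        np.asarray(coords, dtype=float),
        np.asarray(radii, dtype=float),
        np.asarray(owner, dtype=int),
    )


def shrake_rupley(
    residues: list[Residue],
    probe: float = 1.4,
    n_points: int = 960,
    vdw_radii: dict[str, float] | None = None,
) -> SasaResult:
    """Accessible surface area of a heavy-atom collection.

    Parameters
    ----------
    residues
        Atom collection grouped by residue; per-residue areas follow this
        ordering.
    probe
        Solvent probe radius in Å.
    n_points
        Test points per atom. The point set is a fixed golden-spiral
        lattice, so results are bit-stable across runs.
    vdw_radii
        Element → radius (Å) overrides; defaults cover C/N/O/S/Se.
    """
    if n_points < 32:
        raise ValueError(f"n_points={n_points} too small for a stable estimate")
    radii_table = dict(DEFAULT_VDW_RADII)
    if vdw_radii:
        radii_table.update({k.upper(): v for k, v in vdw_radii.items()})
    coords, radii, owner = _atom_table(residues, radii_table)
    if len(coords) == 0:
        raise ValueError("no heavy atoms")

    inflated = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_inflated = inflated.max()

    per_atom = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * unit
        # any atom able to bury a test point of i lies within this radius
        neigh = tree.query_ball_point(coords[i], inflated[i] + max_inflated)
        neigh = [j for j in neigh if j != i]
        exposed = np.ones(n_points, dtype=bool)
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :], axis=2)
            exposed = ~np.any(d < inflated[neigh][None, :], axis=1)
        per_atom[i] = exposed.mean() * 4.0 * np.pi * inflated[i] ** 2

    per_residue = np.zeros(len(residues))
    np.add.at(per_residue, owner, per_atom)
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        probe_radius=probe,
        n_points=n_points,
    )


def relative_sasa(area: float, res_name: str, table: dict[str, float] | None = None) -> float:
    """Area divided by the residue type's maximal accessibility.

    Not clamped to 1: slightly over-exposed termini are fine because only
    the <=5% burial threshold is consumed downstream.
    """
    if table is None:
        table = MAX_ASA_ROST_SANDER
    if res_name not in table:
        raise KeyError(f"no maximal accessibility for residue type {res_name!r}")
    return float(area) / table[res_name]


def bound_and_unbound_sasa(
    structure: ComplexStructure,
    groups: list[frozenset[str]],
    probe: float = 1.4,
    n_points: int = 960,
    vdw_radii: dict[str, float] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-residue (unbound Å², bound Å²) for every chain group.

    The unbound value is computed on each subunit's atoms alone; the bound
    value comes from a single computation over all atoms of the complex.
    Because every atom keeps the same test-point set in both computations,
    unbound >= bound holds exactly residue by residue.
    """
    all_residues = structure.residues()
    bound = shrake_rupley(all_residues, probe=probe, n_points=n_points, vdw_radii=vdw_radii)

    res_index = {id(r): i for i, r in enumerate(all_residues)}
    out = []
    for group in groups:
        sub_res = [r for cid in structure.chains if cid in group for r in structure.chains[cid]]
        unbound = shrake_rupley(sub_res, probe=probe, n_points=n_points, vdw_radii=vdw_radii)
        bound_for_group = np.array(
            [bound.per_residue[res_index[id(r)]] for r in sub_res]
        )
        out.append((unbound.per_residue, bound_for_group))
    return out
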