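"""Synthetic complexes with known ground-truth surface subregions.

The workhorse is the *slab dimer*: two mirrored rectangular lattices of
single-atom pseudo-residues (glycine-like, one Cα-sized carbon each)
facing one another across a gap. The geometry designs in exactly the
features the analysis must detect:

* the contact-face interior is caged laterally by the face's edge ring
  (the "collar") and frontally by the partner slab, so its bound-state
  accessible area vanishes — ground-truth CENTRAL;
* the collar itself stays partly exposed in the complex — ground-truth
  PERIPHERAL;
* slab-interior residues have zero unbound accessibility (NON_SURFACE),
  the remaining hull is NON_INTERFACE;
* face-interior residues keep more same-subunit neighbors than the edge
  ring, so the central region is denser packed than the rim — the
  core-rigid / rim-flexible packing gradient.

Ground truth is fixed geometrically at generation time and never
consults the classifiers under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .interface import RegionLabel
from .structure_io import Atom, ComplexStructure, Residue, Subunit, write_pdb

__all__ = [
    "SlabDimerSpec",
    "make_slab_dimer",
    "make_lattice_subunit",
    "make_helix_pair",
    "make_fixture_set",
    "write_pdb",
]


@dataclass
class SlabDimerSpec:
    """Geometry of one synthetic slab dimer.

    ``core_radius`` (lattice units, Chebyshev distance from the contact
    face's center) sets the designed buried patch; the face extents must
    be ``2*core_radius + 3`` so that the patch is ringed by exactly one
    collar of edge residues. ``gap`` <= 5 Å guarantees a designed
    contact. The default ``spacing`` of 3.4 Å keeps slab-interior
    pseudo-atoms solvent-inaccessible: a cubic cage of carbon atoms
    (vdW 1.7 Å) buries its center against a 1.4 Å probe only for
    spacings below 2(1.7+1.4)/√3 ≈ 3.58 Å. ``jitter`` is Gaussian
    positional noise (Å), mirrored between the two subunits so the dimer
    stays exactly symmetric.
    """

    nx: int = 7
    ny: int = 7
    nz: int = 3
    spacing: float = 3.4
    gap: float = 4.0
    core_radius: int = 2
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("lattice extents must be >= 3 in each direction")
        want = 2 * self.core_radius + 3
        if self.nx != want or self.ny != want:
            raise ValueError(
                f"face extents must equal 2*core_radius+3={want} so the core "
                f"patch is ringed by one collar (got nx={self.nx}, ny={self.ny})"
            )
        if self.spacing <= 0 or self.gap <= 0:
            raise ValueError("spacing and gap must be positive")


def _gly(chain_id: str, number: int, coord: np.ndarray) -> Residue:
    atom = Atom(name="CA", element="C", coord=coord)
    return Residue(chain_id=chain_id, seq_id=str(number), res_name="GLY", atoms=[atom])


def make_lattice_subunit(
    n_per_side: int, spacing: float = 3.4, chain_id: str = "A"
) -> Subunit:
    """Cubic lattice of single-atom residues; hull membership is analytic.

    Residues are ordered x-fastest; residue index ``i*(n²)+j*n+k`` sits at
    lattice coordinate (i, j, k). Interior residues (all indices strictly
    between 0 and n-1) are solvent-inaccessible below the ≈3.58 Å burial
    threshold (see :class:`SlabDimerSpec`).
    """
    if n_per_side < 2:
        raise ValueError("n_per_side must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    residues = []
    num = 1
    for i in range(n_per_side):
        for j in range(n_per_side):
            for k in range(n_per_side):
                coord = spacing * np.array([i, j, k], dtype=float)
                residues.append(_gly(chain_id, num, coord))
                num += 1
    return Subunit(chain_ids=frozenset({chain_id}), residues=residues)


def make_slab_dimer(
    spec: SlabDimerSpec,
) -> tuple[ComplexStructure, list[RegionLabel]]:
    """Build one slab dimer and its ground-truth region labels.

    Returns the two-chain structure (chains A and B, mirror images across
    the mid-plane) and one label per residue in structure order. Labels
    derive from geometry alone: a contact-face residue is interface
    ground truth when its atom lies within 5 Å of a partner atom;
    interface residues in the face interior are CENTRAL, on the face
    boundary PERIPHERAL; slab-interior residues are NON_SURFACE and the
    rest of the hull NON_INTERFACE.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing
    half_gap = spec.gap / 2.0

    grid = []
    for i in range(spec.nx):
        for j in range(spec.ny):
            for k in range(spec.nz):
                grid.append((i, j, k))

    noise = rng.normal(0.0, spec.jitter, size=(len(grid), 3)) if spec.jitter > 0 else np.zeros((len(grid), 3))

    coords_a = np.empty((len(grid), 3))
    for idx, (i, j, k) in enumerate(grid):
        coords_a[idx] = (
            (i - (spec.nx - 1) / 2.0) * s,
            (j - (spec.ny - 1) / 2.0) * s,
            -half_gap - k * s,
        )
    coords_a += noise
    # chain B is the exact mirror image (z -> -z), noise included, so the
    # two subunits are congruent and produce identical per-residue values
    coords_b = coords_a * np.array([1.0, 1.0, -1.0])

    all_coords = np.vstack([coords_a, coords_b])
    if pdist(all_coords).min() <= 1e-6:
        raise ValueError("jitter produced coincident atoms; reduce jitter or respace")

    chains = {"A": [], "B": []}
    for idx in range(len(grid)):
        chains["A"].append(_gly("A", idx + 1, coords_a[idx]))
    for idx in range(len(grid)):
        chains["B"].append(_gly("B", idx + 1, coords_b[idx]))
    structure = ComplexStructure(pdb_id="SYNT", model_index=0, chains=chains)

    # ground truth from geometry: contact distances use the actual
    # (jittered) coordinates, region membership the lattice indices
    d_ab = cdist(coords_a, coords_b).min(axis=1)
    d_ba = cdist(coords_b, coords_a).min(axis=1)

    def _labels(dists: np.ndarray) -> list[RegionLabel]:
        labels = []
        for idx, (i, j, k) in enumerate(grid):
            interior_xy = 0 < i < spec.nx - 1 and 0 < j < spec.ny - 1
            if interior_xy and 0 < k < spec.nz - 1:
                labels.append(RegionLabel.NON_SURFACE)
            elif k == 0 and dists[idx] <= 5.0:
                labels.append(RegionLabel.CENTRAL if interior_xy else RegionLabel.PERIPHERAL)
            else:
                labels.append(RegionLabel.NON_INTERFACE)
        return labels

    return structure, _labels(d_ab) + _labels(d_ba)


def make_helix_pair(
    n_res: int = 30, separation: float = 9.0, seed: int = 0, jitter: float = 0.0
) -> ComplexStructure:
    """Two parallel ideal Cα-trace helices — a realistic-geometry smoke test.

    Ideal α-helix Cα parameters: 2.3 Å radius, 1.5 Å rise and 100° turn
    per residue. No ground-truth labels are claimed for this geometry.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_res)
    theta = np.deg2rad(100.0) * t
    base = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t])
    chains = {}
    for cid, xshift in (("A", 0.0), ("B", separation)):
        coords = base + np.array([xshift, 0.0, 0.0])
        if jitter > 0:
            coords = coords + rng.normal(0.0, jitter, size=coords.shape)
        chains[cid] = [_gly(cid, i + 1, c) for i, c in enumerate(coords)]
    return ComplexStructure(pdb_id="HLX2", model_index=0, chains=chains)


def make_fixture_set(
    n_dimers: int, seed: int, out_dir: str | Path
) -> Path:
    """Write ``n_dimers`` slab-dimer PDB files plus a manifest TSV.

    Dimer geometry cycles through a few core sizes and slab thicknesses
    so the set is not one structure repeated; per-dimer seeds derive from
    ``seed``. Returns the manifest path. Re-running with the same
    arguments reproduces the files byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    core_cycle = (1, 2, 3)
    nz_cycle = (3, 4)
    rows = []
    for i in range(n_dimers):
        core = core_cycle[i % len(core_cycle)]
        face = 2 * core + 3
        spec = SlabDimerSpec(
            nx=face,
            ny=face,
            nz=nz_cycle[i % len(nz_cycle)],
            core_radius=core,
            seed=seed + i,
        )
        structure, _ = make_slab_dimer(spec)
        pdb_id = f"S{i:03d}"
        structure.pdb_id = pdb_id
        (out_dir / f"{pdb_id}.pdb").write_text(write_pdb(structure))
        rows.append(f"{pdb_id}\tA\tB\thomodimer")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
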