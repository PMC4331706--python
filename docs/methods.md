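# Methods

## Model and procedure

The pipeline treats each biological subunit of a complex as an
*unbound* protein: every quantity is computed either on the subunit's
atoms alone (packing density, surface definition) or on the full
complex (bound-state burial), never mixing partners into the subunit's
internal statistics.

1. **Weighted contact number.** For residue *i*, `w_i = Σ_{j≠i} 1/r_ij²`
   over all residues *j* of the same subunit, with `r_ij` the distance
   between residue representative points. The representative point is
   the Cα atom; a heavy-atom-centroid rule is available for coarse or
   incomplete models. Distances are in Å, so `w` carries units Å⁻²;
   scaling coordinates by *s* scales `w` by `1/s²` (tested). Neighbors
   from partner subunits are never counted — `w` estimates the thermal
   fluctuation the residue would have in the free subunit. Multi-chain
   subunits (as declared by the manifest's chain groups) pool all their
   chains' residues; chains are never merged unless the manifest says
   so.
2. **Accessible surface.** Shrake–Rupley with probe radius 1.4 Å and a
   deterministic golden-spiral point set (default 960 points/atom; no
   RNG, so areas are bit-stable). Van-der-Waals radii: C 1.70, N 1.55,
   O 1.52, S 1.80, Se 1.90 Å, overridable. Unbound areas come from the
   subunit's atoms alone, bound areas from one computation over the
   whole complex; with the shared point set, bound ≤ unbound holds
   exactly per residue.
3. **Region partition.** Surface = unbound area strictly > 0.
   Interface = surface residue with any heavy atom within 5.0 Å
   (inclusive) of any partner heavy atom (k-d-tree search, equal to the
   all-pairs answer). Central = interface residue whose bound-state
   relative accessibility is ≤ 5% (inclusive); peripheral = the rest of
   the interface. Relative accessibility divides by the residue type's
   maximal accessibility and is deliberately not clamped at 1 — only
   the 5% threshold is consumed. Both thresholds are inclusive: the 5%
   rule is inherently "at or below", and 5.0 Å follows the same reading
   for consistency.
4. **Normalization and statistics.** Per subunit, `z = (w − w̄)/σ_w`
   with mean and *population* SD over that subunit's surface residues
   only (the sample/population choice is immaterial at realistic sizes
   but is fixed for reproducibility); `w` itself is computed over all
   residues, buried included. Dataset-level `zWCN` uses one mean/SD
   over the pooled surface residues of all retained subunits. Region
   comparisons use the classical pooled-variance Student's t-test
   (Welch available as `stats.welch_t`), strict inequalities with ties
   counted as failures, and per-region relative-frequency histograms on
   a shared grid (default bin width 0.25 z-units).

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `contact_cutoff` | 5.0 Å | heavy-atom distance defining interface membership (inclusive) |
| `central_rsasa` | 0.05 | bound-state relative accessibility at/below which an interface residue is central |
| `probe` | 1.4 Å | solvent probe radius (water) |
| `n_points` | 960 | test points per atom; rotation error of areas is ≈0.6% of an atom sphere at 960, ≈0.25% at 4000 |
| `min_central` | 2 | subunits with fewer central residues are excluded from dataset statistics — the region t-tests and means need populated groups; 2 encodes "one or zero central residues removed" |
| `max_asa_table` | `rost_sander` | maximal-accessibility scale; `tien_theoretical` selectable. Classifications within a fraction of a percent of the 5% boundary can differ between scales, so the scale is configuration, not inference |
| `representative` | `CA` | WCN representative point; `centroid` for residues without Cα |

## The synthetic generator

`make_slab_dimer` builds two mirrored lattice slabs of single-atom
glycine-like residues facing across a gap (default 4 Å). It emulates
exactly the features the analysis consumes: a geometrically
identifiable contact patch, a patch core with near-zero bound-state
accessibility, an exposed rim ring, a buried slab interior, and a
packing-density gradient (face-interior residues keep more same-subunit
neighbors than the rim). Ground truth is fixed from lattice indices and
actual interatomic distances at generation time, independent of the
classifiers under test. Jitter (default 0.05 Å) is mirrored between the
subunits so the dimer stays exactly symmetric; at spacing-scale jitter
(~2 Å and up) the designed labels stop being recovered, which the tests
use to show the statistic responds to geometry rather than to the
generator's bookkeeping.

Lattice spacing defaults to 3.4 Å rather than the Cα-virtual-bond
3.8 Å: a cubic cage of carbon pseudo-atoms buries its center against a
1.4 Å probe only below `2(1.7+1.4)/√3 ≈ 3.58 Å`, and the designed
NON_SURFACE ground truth requires genuinely buried interiors. The
default study set is 10 dimers (20 subunits, ~2,600 residues) with face
core radii cycling 1–3 and slab thickness 3–4 — large enough for the
region pools to separate decisively, small enough that the whole
pipeline runs in seconds.

What the generator does **not** emulate: side-chain packing, amino-acid
composition differences between core and rim, concave/convex interface
shapes, crystallographic noise, or realistic maximal-accessibility
denominators (all pseudo-residues are glycine). Passing tests therefore
demonstrate that the machinery measures the designed packing/burial
structure correctly — not that any particular biological dataset shows
the pattern. Real-data runs go through the same `run` entry point on a
user-supplied manifest.

## Numerical choices and degenerate inputs

* SASA test points are a fixed golden-spiral lattice; a point is buried
  when strictly inside a neighbor's inflated sphere. Areas are exact
  for an isolated atom (all points exposed).
* WCN raises on coincident representative points (naming the residue
  pair) rather than returning infinities.
* z-normalization raises on zero variance or fewer than two surface
  residues; at the pipeline level such subunits are recorded as skipped
  with a reason and never silently dropped.
* Region means over empty regions are missing values, not errors; a
  subunit enters an inequality comparison's denominator only when both
  means exist.
* Altloc conformers: highest occupancy wins, first in file order on a
  tie. Hydrogens, waters, HETATM ligands and non-standard residues are
  excluded at parse time (contacts and accessibility are defined on
  protein heavy atoms); insertion codes stay part of residue identity.
* Outputs are byte-deterministic for identical inputs (no RNG anywhere
  in the analysis path; fixed float formatting in exports).

## Known limitations

* The SASA engine is a faithful Shrake–Rupley implementation, not a
  re-creation of any particular legacy accessibility program;
  per-residue areas can differ from DSSP-family tools by a few percent,
  which can flip classifications of residues sitting exactly at the 5%
  burial boundary. Thresholded region labels, not raw areas, are the
  supported contract.
* Only PDB-format input is supported (no mmCIF, no assembly
  reconstruction from symmetry records); manifests are inputs, and no
  dataset curation (redundancy filtering, obligate/transient
  classification) is performed.
* The maximal-accessibility scale behind published relative-SASA
  thresholds is a convention choice; results near the 5% boundary
  should be interpreted with the configured scale in mind.
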