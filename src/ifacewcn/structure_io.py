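"""Read and write protein structures and dataset manifests.

The domain model is deliberately small: a complex is an ordered set of
chains, a chain an ordered list of residues, a residue a list of heavy
atoms. Parsing is delegated to Bio.PDB; what this module adds is the
filtering contract used throughout the analysis (heavy atoms of standard
amino acids only, one conformer per atom, one coordinate model per
structure) and the manifest format that names which chains form each
biological subunit of a complex.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

log = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids; anything else is
#: dropped during parsing (modified residues, ligands, solvent).
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: PDB entries the source datasets reference that have been withdrawn,
#: mapped to their replacement entries.
OBSOLETE_SUBSTITUTIONS = {"2SDH": "3SDH", "2SSI": "3SSI", "3GAP": "1G6N"}

CATEGORIES = frozenset({"homodimer", "heterodimer", "obligate", "transient"})


class PDBParseError(ValueError):
    """Raised when PDB text cannot be turned into a usable structure."""


class ManifestError(ValueError):
    """Raised for malformed dataset manifest rows."""


@dataclass
class Atom:
    """One heavy atom: label, element, position (Å), occupancy, B-factor."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")


@dataclass
class Residue:
    """One amino-acid residue; ``seq_id`` includes any insertion code."""

    chain_id: str
    seq_id: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates, shape (n_atoms, 3)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def representative_point(self, rule: str = "CA") -> np.ndarray:
        """Cα position, or the heavy-atom centroid under rule='centroid'."""
        if rule == "CA":
            ca = self.get_atom("CA")
            if ca is None:
                raise ValueError(
                    f"residue {self.chain_id}/{self.seq_id} has no CA atom; "
                    "use rule='centroid' to fall back to the heavy-atom centroid"
                )
            return ca.coord
        if rule == "centroid":
            return self.coords().mean(axis=0)
        raise ValueError(f"unknown representative rule {rule!r}")


@dataclass
class ComplexStructure:
    """One coordinate model of one complex; chains keep file order."""

    pdb_id: str
    model_index: int
    chains: dict[str, list[Residue]]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self) -> list[Residue]:
        return [r for ch in self.chains.values() for r in ch]

    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains.values())


@dataclass
class Subunit:
    """The residues of one biological unit (one or more chains)."""

    chain_ids: frozenset[str]
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("subunit has no residues")
        bad = {r.chain_id for r in self.residues} - set(self.chain_ids)
        if bad:
            raise ValueError(f"residues from chains {sorted(bad)} outside subunit")

    def heavy_atom_coords(self) -> np.ndarray:
        return np.vstack([r.coords() for r in self.residues])


@dataclass
class ManifestEntry:
    pdb_id: str
    subunit_chain_groups: list[frozenset[str]]
    category: str


def _validate_atom_lines(text: str) -> None:
    """Reject ATOM/HETATM records whose coordinate fields do not parse."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                raw = line[lo:hi].strip()
                try:
                    float(raw)
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate field {raw!r}"
                    ) from None


def _convert_model(model, pdb_id: str) -> ComplexStructure:
    chains: dict[str, list[Residue]] = {}
    dropped: set[str] = set()
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resnum, icode = res.id
            if hetflag != " ":  # water and ligand HETATM groups
                continue
            if res.get_resname() not in STANDARD_AA:
                dropped.add(f"{chain.id}/{res.get_resname()}{resnum}")
                continue
            atoms = []
            # iterating a Bio.PDB residue yields one conformer per atom:
            # for disordered atoms the highest-occupancy altloc (first on tie)
            for a in res:
                if a.element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=a.get_name(),
                        element=a.element or "C",
                        coord=np.asarray(a.get_coord(), dtype=float),
                        occupancy=float(a.get_occupancy() or 1.0),
                        altloc=a.get_altloc().strip(),
                        bfactor=float(a.get_bfactor() or 0.0),
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.id,
                    seq_id=f"{resnum}{icode.strip()}",
                    res_name=res.get_resname(),
                    atoms=atoms,
                )
            )
        if residues:
            chains[chain.id] = residues
    if dropped:
        log.warning("%s: dropped non-standard residues: %s", pdb_id, sorted(dropped))
    return ComplexStructure(pdb_id=pdb_id, model_index=model.id, chains=chains)


def parse_pdb_models(text: str, pdb_id: str = "XXXX") -> list[ComplexStructure]:
    """Parse every coordinate model in ``text`` (see :func:`parse_pdb`)."""
    if not any(line.startswith("ATOM  ") for line in text.splitlines()):
        raise PDBParseError("no ATOM records found")
    _validate_atom_lines(text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(pdb_id, io.StringIO(text))
    models = [_convert_model(m, pdb_id) for m in structure]
    models = [m for m in models if m.chains]
    if not models:
        raise PDBParseError("no standard-amino-acid heavy atoms in any model")
    return models


def parse_pdb(text: str, pdb_id: str = "XXXX") -> ComplexStructure:
    """Parse PDB text into a single-model :class:`ComplexStructure`.

    Hydrogens, waters and HETATM ligands are excluded; among altloc
    duplicates the highest-occupancy conformer is kept (first on tie);
    non-standard residues are dropped with a logged warning. Multi-model
    files (NMR ensembles) contribute only their first model.
    """
    return select_first_model(parse_pdb_models(text, pdb_id=pdb_id))


def select_first_model(
    models: list[ComplexStructure] | ComplexStructure,
) -> ComplexStructure:
    """Return the first coordinate model; a single model passes through."""
    if isinstance(models, ComplexStructure):
        return models
    if not models:
        raise PDBParseError("structure contains no usable coordinate model")
    first = models[0]
    if not first.chains:
        raise PDBParseError("first coordinate model is empty")
    return first


def extract_subunit(structure: ComplexStructure, chain_ids) -> Subunit:
    """Residues of the named chains, in chain-then-sequence order."""
    chain_ids = frozenset(chain_ids)
    missing = chain_ids - set(structure.chains)
    if missing:
        raise KeyError(
            f"chains {sorted(missing)} not in structure "
            f"(available: {sorted(structure.chains)})"
        )
    residues = [r for cid in structure.chains if cid in chain_ids for r in structure.chains[cid]]
    return Subunit(chain_ids=chain_ids, residues=residues)


def load_manifest(text: str) -> list[ManifestEntry]:
    """Parse a dataset manifest.

    Tab- or whitespace-delimited rows: PDB id, two or more chain groups
    (chains within one subunit joined by ':'), and the complex category.
    Example: ``2TSC  A  B  homodimer``. Withdrawn PDB ids are replaced by
    their successors and the substitution logged. Lines starting with '#'
    are comments.
    """
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ManifestError(
                f"line {lineno}: need pdb_id, >=2 chain groups and a category, "
                f"got {len(fields)} fields"
            )
        pdb_id, *group_fields, category = fields
        pdb_id = pdb_id.upper()
        if category not in CATEGORIES:
            raise ManifestError(
                f"line {lineno}: unknown category {category!r} "
                f"(expected one of {sorted(CATEGORIES)})"
            )
        if pdb_id in OBSOLETE_SUBSTITUTIONS:
            new_id = OBSOLETE_SUBSTITUTIONS[pdb_id]
            log.info("manifest: obsolete entry %s substituted with %s", pdb_id, new_id)
            pdb_id = new_id
        groups = [frozenset(g.split(":")) for g in group_fields]
        seen: set[str] = set()
        for g in groups:
            if seen & g:
                raise ManifestError(f"line {lineno}: chain groups overlap")
            seen |= g
        entries.append(
            ManifestEntry(pdb_id=pdb_id, subunit_chain_groups=groups, category=category)
        )
    return entries


def write_pdb(structure: ComplexStructure) -> str:
    """Serialize to PDB ATOM records (one model, TER after each chain)."""
    lines = []
    serial = 1
    for cid, residues in structure.chains.items():
        if len(cid) != 1:
            raise ValueError(f"chain id {cid!r} is not a single character")
        for i, res in enumerate(residues, start=1):
            num_part = res.seq_id
            icode = " "
            if num_part and num_part[-1].isalpha():
                num_part, icode = num_part[:-1], num_part[-1]
            resnum = int(num_part)
            if resnum > 9999:
                raise ValueError(f"residue number {resnum} exceeds PDB field width")
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.res_name:<3s} {cid}"
                    f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
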