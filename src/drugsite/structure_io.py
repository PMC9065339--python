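"""Structure reading, ligand qualification and geometric binding-site labelling.

A residue is a drug-binding site when at least one of its atoms lies within
the contact cutoff (default 6.5 Å) of any atom of a qualified ligand.  A
hetero entity qualifies as a ligand when it is not water, makes at least one
protein contact within the cutoff, and is not covalently bonded to the
protein (no atom pair closer than the covalent cutoff, default 2.0 Å).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Default protein-contact cutoff in Å (inclusive: a pair at exactly the
#: cutoff counts as a contact).
CONTACT_CUTOFF = 6.5
#: Default covalent-bond rejection threshold in Å (exclusive).
COVALENT_CUTOFF = 2.0

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Residue names treated as protein polymer residues.  MSE/SEC/PYL are kept
#: as protein; nucleic-acid residues are neither protein nor ligand.
AMINO_ACIDS_3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE SEC PYL".split()
)
NUCLEIC_RESIDUES = frozenset(
    "DA DC DG DT DU DI A C G U I".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a polymer residue: chain, author number, insertion code, name."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_name", self.residue_name.upper())


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    residue_key: ResidueKey | None
    is_hetero: bool

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")


class Qualification(enum.Enum):
    QUALIFIED = "qualified"
    REJECTED_WATER = "rejected_water"
    REJECTED_NO_CONTACT = "rejected_no_contact"
    REJECTED_COVALENT = "rejected_covalent"
    REJECTED_MW = "rejected_mw"


@dataclass
class LigandCandidate:
    """One hetero entity (a single HETATM residue) and its qualification."""

    entity_id: str
    residue_name: str
    atoms: list[AtomRecord]
    qualification: Qualification | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def molecular_weight(self) -> float:
        return float(sum(gemmi.Element(a.element).weight for a in self.atoms))


@dataclass
class StructureModel:
    """Parsed complex: ordered polymer residues plus hetero entities."""

    structure_id: str
    residues: dict[ResidueKey, list[AtomRecord]]
    hetero_entities: list[LigandCandidate] = field(default_factory=list)

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return list(self.residues)

    def chain_sequence(self, chain_id: str) -> tuple[list[ResidueKey], str]:
        """Ordered residue keys of a chain and its one-letter sequence ('X' for unknowns)."""
        keys = [k for k in self.residues if k.chain_id == chain_id]
        if not keys:
            raise StructureError(f"chain {chain_id!r} not found in {self.structure_id}")
        seq = "".join(THREE_TO_ONE.get(k.residue_name, "X") for k in keys)
        return keys, seq

    def protein_atom_arrays(self) -> tuple[np.ndarray, list[ResidueKey]]:
        """All polymer-atom coordinates and the residue key of each atom."""
        coords, owners = [], []
        for key, atoms in self.residues.items():
            for a in atoms:
                coords.append(a.coord)
                owners.append(key)
        return np.array(coords, dtype=float), owners

    def qualified_ligands(self) -> list[LigandCandidate]:
        return [c for c in self.hetero_entities
                if c.qualification is Qualification.QUALIFIED]


@dataclass
class SiteLabels:
    """Binary binding-site labels: 1 = binding site, 0 = non-binding."""

    structure_id: str
    labels: dict[ResidueKey, int]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, got {sorted(bad)}")

    @property
    def positive_keys(self) -> list[ResidueKey]:
        return [k for k, v in self.labels.items() if v == 1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("structure_id\tchain\tresnum\ticode\tresname\tlabel\n")
            for k, v in self.labels.items():
                fh.write(f"{self.structure_id}\t{k.chain_id}\t{k.residue_number}"
                         f"\t{k.insertion_code}\t{k.residue_name}\t{v}\n")


def _select_altloc(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy wins, ties by altloc letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name, group in by_name.items():
        if len(group) == 1:
            picked.append(group[0])
        else:
            picked.append(min(group, key=lambda a: (-a.occ, a.altloc or "A")))
    return picked


def _validate_pdb_records(path: Path) -> None:
    """Reject PDB coordinate records whose fixed-width fields do not parse.

    The underlying reader is lenient; the binding-site geometry must not be
    built from silently mis-read coordinates.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureError(
                    f"{path}:{lineno}: truncated {line[:6].strip()} record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureError(
                        f"{path}:{lineno}: malformed coordinate field "
                        f"{line[lo:hi]!r} in {line[:6].strip()} record"
                    ) from None


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a protein–ligand complex from a PDB or mmCIF file.

    Polymer (protein) residues are kept ordered by (chain, residue number,
    insertion code); every HETATM residue becomes a :class:`LigandCandidate`
    with qualification unset.  Only the first model is used; alternate
    locations are resolved to the highest-occupancy conformer.  Nucleic-acid
    chains are excluded from both the polymer and the candidate list.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    looks_cif = path.suffix.lower() in (".cif", ".mmcif")
    if format == "pdb" or (format == "auto" and not looks_cif):
        _validate_pdb_records(path)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    residues: dict[ResidueKey, list[AtomRecord]] = {}
    hetero: list[LigandCandidate] = []
    for chain in model:
        for res in chain:
            name = res.name.upper()
            icode = (res.seqid.icode or "").strip()
            atoms = _select_altloc(list(res))
            if name in AMINO_ACIDS_3 and res.het_flag != "H":
                key = ResidueKey(chain.name, res.seqid.num, icode, name)
                recs = [
                    AtomRecord(a.serial, a.name, a.element.name,
                               np.array([a.pos.x, a.pos.y, a.pos.z]), key, False)
                    for a in atoms
                ]
                residues.setdefault(key, []).extend(recs)
            elif name in NUCLEIC_RESIDUES and res.het_flag != "H":
                continue  # nucleic polymer: neither protein nor ligand
            else:
                entity_id = f"{chain.name}:{name}:{res.seqid.num}{icode}"
                recs = [
                    AtomRecord(a.serial, a.name, a.element.name,
                               np.array([a.pos.x, a.pos.y, a.pos.z]), None, True)
                    for a in atoms
                ]
                if recs:
                    hetero.append(LigandCandidate(entity_id, name, recs))

    if not residues:
        raise StructureError(f"{path}: structure contains no polymer protein residues")

    ordered = dict(sorted(residues.items(),
                          key=lambda kv: (kv[0].chain_id, kv[0].residue_number,
                                          kv[0].insertion_code)))
    return StructureModel(path.stem, ordered, hetero)


def qualify_ligands(
    s: StructureModel,
    contact_cutoff: float = CONTACT_CUTOFF,
    covalent_cutoff: float = COVALENT_CUTOFF,
    mw_range: tuple[float, float] | None = None,
) -> StructureModel:
    """Assign a qualification to every hetero entity of ``s`` (in place).

    Order of precedence: water name, molecular-weight window (if requested),
    covalent clash (< ``covalent_cutoff``), no protein contact within
    ``contact_cutoff`` (inclusive); anything else is qualified.
    """
    if contact_cutoff <= 0 or covalent_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    prot_coords, _ = s.protein_atom_arrays()
    tree = cKDTree(prot_coords)
    for cand in s.hetero_entities:
        if cand.residue_name in WATER_NAMES:
            cand.qualification = Qualification.REJECTED_WATER
            continue
        if mw_range is not None:
            mw = cand.molecular_weight()
            if not (mw_range[0] <= mw <= mw_range[1]):
                cand.qualification = Qualification.REJECTED_MW
                continue
        dmin = float(np.min(tree.query(cand.coords())[0]))
        if dmin < covalent_cutoff:
            cand.qualification = Qualification.REJECTED_COVALENT
        elif dmin <= contact_cutoff:
            cand.qualification = Qualification.QUALIFIED
        else:
            cand.qualification = Qualification.REJECTED_NO_CONTACT
    return s


def extract_binding_sites(
    s: StructureModel,
    ligand: LigandCandidate,
    cutoff: float = CONTACT_CUTOFF,
) -> SiteLabels:
    """Label each polymer residue 1 iff any of its atoms is within ``cutoff``
    (inclusive) of any atom of the qualified ``ligand``."""
    if ligand.qualification is not Qualification.QUALIFIED:
        raise ValueError(
            f"ligand {ligand.entity_id} is not qualified "
            f"({ligand.qualification and ligand.qualification.value})"
        )
    lig_tree = cKDTree(ligand.coords())
    labels: dict[ResidueKey, int] = {}
    for key, atoms in s.residues.items():
        coords = np.array([a.coord for a in atoms])
        dmin = float(np.min(lig_tree.query(coords)[0]))
        labels[key] = int(dmin <= cutoff)
    return SiteLabels(s.structure_id, labels)


def merge_site_labels(per_ligand: Iterable[SiteLabels]) -> SiteLabels:
    """Logical OR of per-ligand labels from the same structure."""
    per_ligand = list(per_ligand)
    if not per_ligand:
        raise ValueError("no label sets to merge")
    sid = per_ligand[0].structure_id
    if any(sl.structure_id != sid for sl in per_ligand):
        ids = sorted({sl.structure_id for sl in per_ligand})
        raise ValueError(f"cannot merge labels across structures: {ids}")
    merged = dict(per_ligand[0].labels)
    for sl in per_ligand[1:]:
        if set(sl.labels) != set(merged):
            raise ValueError("label sets cover different residues")
        for k, v in sl.labels.items():
            merged[k] = merged[k] | v
    return SiteLabels(sid, merged)


def label_structure(
    s: StructureModel,
    contact_cutoff: float = CONTACT_CUTOFF,
    covalent_cutoff: float = COVALENT_CUTOFF,
    mw_range: tuple[float, float] | None = None,
) -> SiteLabels:
    """Qualify ligands and merge per-ligand binding-site labels for a structure.

    With no qualified ligand every residue is labelled 0.
    """
    qualify_ligands(s, contact_cutoff, covalent_cutoff, mw_range)
    ligs = s.qualified_ligands()
    if not ligs:
        logger.warning("%s: no qualified ligand; all labels 0", s.structure_id)
        return SiteLabels(s.structure_id, {k: 0 for k in s.residues})
    return merge_site_labels(
        [extract_binding_sites(s, lig, contact_cutoff) for lig in ligs]
    )
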