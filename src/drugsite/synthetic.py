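"""Synthetic complexes, PSSMs and labelled feature tables with known truth.

Everything downstream is testable without any database download: the
complex generator emits a Cα-trace PDB file whose ligand is placed so that
exactly a chosen residue set lies within the binding-site cutoff (with a
clearance margin on the non-contacts), the PSSM generator emits a valid
PSI-BLAST ASCII file, and the classification-set generator plants a known
standardized mean shift in chosen feature columns.

These fixtures are geometric and statistical idealisations: no side-chain
rotamers, no physical energetics, Gaussian feature noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FEATURE_COLUMNS, RIN_FEATURES
from .pssm import PSSM_ALPHABET, PssmMatrix, write_pssm
from .structure_io import CONTACT_CUTOFF, ResidueKey, SiteLabels

AA3 = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER "
       "THR TRP TYR VAL").split()

#: Non-contact residues are kept strictly farther than cutoff + this margin.
CLEARANCE = 0.5


class InfeasibleFixtureError(ValueError):
    """Raised when the requested contact set cannot be realised geometrically."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic protein–ligand complex.

    ``ligand_contacts`` holds 1-based residue indices that must be binding
    sites; ``ligand_offset`` is the slack below the 6.5 Å cutoff at which
    contact atoms are placed (contact distance = cutoff − offset).
    """

    n_residues: int = 50
    geometry: str = "helix"
    ligand_contacts: frozenset[int] = frozenset()
    ligand_offset: float = 1.0
    n_ligand_atoms: int = 0  # 0 → one atom per contact
    seed: int = 0
    with_sidechains: bool = False

    def __post_init__(self) -> None:
        if self.geometry not in ("helix", "extended", "random_coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        object.__setattr__(self, "ligand_contacts",
                           frozenset(int(i) for i in self.ligand_contacts))
        bad = [i for i in self.ligand_contacts
               if not 1 <= i <= self.n_residues]
        if bad:
            raise ValueError(f"ligand_contacts out of range: {sorted(bad)}")
        if not 0 < self.ligand_offset < CONTACT_CUTOFF:
            raise ValueError("ligand_offset must be in (0, cutoff)")


def _backbone(spec: FixtureSpec, rng: np.random.Generator):
    """Cα coordinates and, per residue, an outward unit vector for ligand
    placement (pointing away from the chain body)."""
    n = spec.n_residues
    if spec.geometry == "helix":
        # ideal Cα helix: 1.5 Å rise, 100° twist, 2.3 Å radius
        i = np.arange(n)
        theta = np.deg2rad(100.0) * i
        ca = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        outward = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    elif spec.geometry == "extended":
        i = np.arange(n)
        ca = np.column_stack([3.8 * i, np.zeros(n), np.zeros(n)])
        outward = np.tile([0.0, 1.0, 0.0], (n, 1))
    else:  # random_coil: self-avoiding 3.8 Å random walk
        ca = np.zeros((n, 3))
        for i in range(1, n):
            for _ in range(200):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                cand = ca[i - 1] + step
                if i < 2 or np.min(np.linalg.norm(ca[: i - 1] - cand, axis=1)) > 3.5:
                    ca[i] = cand
                    break
            else:
                raise InfeasibleFixtureError("random coil walk got stuck")
        centroid = ca.mean(axis=0)
        outward = ca - centroid
        norms = np.linalg.norm(outward, axis=1)
        norms[norms < 1e-9] = 1.0
        outward = outward / norms[:, None]
    return ca, outward


def _place_ligand(spec: FixtureSpec, ca: np.ndarray, outward: np.ndarray,
                  cutoff: float) -> np.ndarray:
    contacts = sorted(spec.ligand_contacts)
    d = cutoff - spec.ligand_offset
    atoms = []
    if contacts:
        for i in contacts:
            atoms.append(ca[i - 1] + outward[i - 1] * d)
        anchor, direction = atoms[0], outward[contacts[0] - 1]
        extra = max(0, spec.n_ligand_atoms - len(atoms))
    else:
        # no contacts requested: park the ligand far from everything
        anchor = ca.mean(axis=0) + np.array([cutoff * 20, 0.0, 0.0])
        direction = np.array([1.0, 0.0, 0.0])
        atoms.append(anchor)
        extra = max(0, spec.n_ligand_atoms - 1)
    for k in range(extra):
        atoms.append(anchor + direction * (2.0 + 1.5 * k))
    return np.array(atoms)


def _verify(spec: FixtureSpec, protein: np.ndarray, owner: np.ndarray,
            ligand: np.ndarray, cutoff: float) -> None:
    """Brute-force check that exactly the requested residues are in contact."""
    dmin_per_res = np.full(spec.n_residues, np.inf)
    for coord, res_i in zip(protein, owner):
        dmin_per_res[res_i] = min(
            dmin_per_res[res_i],
            float(np.min(np.linalg.norm(ligand - coord, axis=1))) if len(ligand)
            else np.inf,
        )
    for i in range(spec.n_residues):
        wanted = (i + 1) in spec.ligand_contacts
        if wanted and not dmin_per_res[i] <= cutoff - 1e-6:
            raise InfeasibleFixtureError(
                f"residue {i + 1} requested as contact but min distance "
                f"{dmin_per_res[i]:.2f} Å exceeds the cutoff")
        if not wanted and not dmin_per_res[i] > cutoff + CLEARANCE:
            raise InfeasibleFixtureError(
                f"residue {i + 1} not requested but min distance "
                f"{dmin_per_res[i]:.2f} Å is inside the clearance margin")


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resnum: int, xyz: np.ndarray, element: str) -> str:
    return (f"{record:<6s}{serial:>5d} {name:<4s} {resname:>3s} {chain:1s}"
            f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def make_complex(
    spec: FixtureSpec,
    path: str | Path,
    cutoff: float = CONTACT_CUTOFF,
) -> tuple[Path, SiteLabels]:
    """Write a synthetic complex as a PDB file and return its ground truth.

    The file is deterministic for a given spec (fixed field widths, no
    timestamps).  Ground-truth labels are verified internally against a
    brute-force all-pairs distance scan before writing; an unrealisable
    contact set raises :class:`InfeasibleFixtureError`.
    """
    rng = np.random.default_rng(spec.seed)
    ca, outward = _backbone(spec, rng)
    resnames = [AA3[i] for i in rng.integers(0, 20, size=spec.n_residues)]

    protein_atoms: list[tuple[str, np.ndarray, str]] = []  # (name, xyz, element)
    owner: list[int] = []
    for i in range(spec.n_residues):
        protein_atoms.append(("CA", ca[i], "C"))
        owner.append(i)
        if spec.with_sidechains:
            # dummy side-chain atom pointing inward, away from the ligand
            protein_atoms.append(("CB", ca[i] - outward[i] * 1.5, "C"))
            owner.append(i)

    ligand = _place_ligand(spec, ca, outward, cutoff)
    _verify(spec, np.array([a[1] for a in protein_atoms]), np.array(owner),
            ligand, cutoff)

    sid = Path(path).stem  # ground truth keyed like read_structure's id
    lines = ["HEADER    SYNTHETIC COMPLEX"]  # no id/timestamp: byte-stable
    serial = 0
    for (name, xyz, elem), res_i in zip(protein_atoms, owner):
        serial += 1
        lines.append(_pdb_line("ATOM", serial, f" {name}", resnames[res_i],
                               "A", res_i + 1, xyz, elem))
    for j, xyz in enumerate(ligand):
        serial += 1
        lines.append(_pdb_line("HETATM", serial, f" C{j + 1}", "LIG", "A",
                               spec.n_residues + 100, xyz, "C"))
    lines.append("END")

    path = Path(path)
    path.write_text("\n".join(lines) + "\n")

    labels = {
        ResidueKey("A", i + 1, "", resnames[i]):
            int((i + 1) in spec.ligand_contacts)
        for i in range(spec.n_residues)
    }
    return path, SiteLabels(sid, labels)


def make_pssm(
    length: int,
    seed: int,
    path: str | Path | None = None,
    alphabet_order: str = PSSM_ALPHABET,
    sequence: str | None = None,
) -> PssmMatrix:
    """Random-but-plausible PSSM: integer log-odds in [−10, 12], valid
    PSI-BLAST ASCII dialect when written to ``path``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(alphabet_order[i]
                           for i in rng.integers(0, 20, size=length))
    elif len(sequence) != length:
        raise ValueError("sequence length must equal requested length")
    scores = rng.integers(-10, 13, size=(length, 20))
    m = PssmMatrix(sequence, scores, alphabet_order)
    if path is not None:
        write_pssm(m, path)
    return m


@dataclass(frozen=True)
class ClassSignalSpec:
    """Recipe for a labelled feature table with a planted class signal.

    Negatives are N(0, noise_sd²) in every feature column; positives are
    shifted by ``effect_size × noise_sd`` in ``informative_columns`` only,
    so the standardized between-class shift in those columns equals
    ``effect_size`` by construction.
    """

    n_pos: int = 500
    n_neg: int = 500
    informative_columns: tuple[str, ...] = tuple(RIN_FEATURES)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        unknown = set(self.informative_columns) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown feature columns: {sorted(unknown)}")


def make_classification_set(spec: ClassSignalSpec) -> pd.DataFrame:
    """Labelled 27-column feature table drawn from the planted-signal model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    x = rng.normal(0.0, spec.noise_sd, size=(n, len(FEATURE_COLUMNS)))
    y = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    shift = spec.effect_size * spec.noise_sd
    for col in spec.informative_columns:
        x[: spec.n_pos, FEATURE_COLUMNS.index(col)] += shift
    t = pd.DataFrame(x, columns=FEATURE_COLUMNS)
    t.insert(0, "structure_id", "synthetic")
    t.insert(1, "chain", "A")
    t.insert(2, "resnum", np.arange(1, n + 1))
    t.insert(3, "icode", "")
    t.insert(4, "resname", [AA3[i] for i in rng.integers(0, 20, size=n)])
    t.insert(5, "label", y)
    perm = rng.permutation(n)
    return t.iloc[perm].reset_index(drop=True)
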