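"""PSI-BLAST ASCII PSSM parsing and per-residue evolutionary features.

A PSSM is an L×20 matrix of integer log-odds scores: row i describes how
readily position i of the query tolerates substitution to each of the 20
standard amino acids, as estimated from three PSI-BLAST iterations against
a large sequence database.  Only the log-odds block of the ``-out_ascii_pssm``
file is used; the weighted-percentage block and footer statistics are
ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .structure_io import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

#: Column order of the PSI-BLAST ASCII dialect.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
#: Alphabetical amino-acid order used for feature columns downstream.
AA_ALPHABETICAL = "".join(sorted(PSSM_ALPHABET))

_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(.*)$")


class PssmParseError(ValueError):
    """Raised when a PSSM file does not follow the PSI-BLAST ASCII dialect."""


@dataclass
class PssmMatrix:
    """L×20 log-odds matrix aligned to query positions 1..L."""

    sequence: str
    scores: np.ndarray  # (L, 20) int
    column_order: str = PSSM_ALPHABET

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be L×20")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError("row count must equal sequence length")
        if sorted(self.column_order) != sorted(PSSM_ALPHABET):
            raise ValueError("column_order must be a permutation of the 20 amino acids")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_pssm(path: str | Path) -> PssmMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Data rows carry the position, the query residue, 40 integer columns
    (20 log-odds + 20 weighted percentages) and two trailing statistics;
    the first 20 integers are kept.  A data row with fewer than 40 numeric
    fields is a parse error naming the line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: str | None = None
    seq: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        m = _ROW_RE.match(line)
        if m is None:
            # header / alphabet line / footer
            letters = stripped.split()
            if header_cols is None and len(letters) == 40 and all(
                len(t) == 1 and t.isalpha() for t in letters
            ):
                header_cols = "".join(letters[:20])
            continue
        if rows and stripped.lower().startswith(("k", "lambda")):
            break  # footer statistics
        fields = m.group(3).split()
        numeric: list[float] = []
        for tok in fields:
            try:
                numeric.append(float(tok))
            except ValueError:
                break
        if len(numeric) < 40:
            raise PssmParseError(
                f"{path}:{lineno}: expected 40 numeric fields in PSSM row, "
                f"found {len(numeric)}"
            )
        seq.append(m.group(2))
        rows.append([int(v) for v in numeric[:20]])
    if not rows:
        raise PssmParseError(f"{path}: no PSSM rows found (empty matrix)")
    order = header_cols if header_cols is not None else PSSM_ALPHABET
    return PssmMatrix("".join(seq), np.array(rows, dtype=int), order)


def write_pssm(m: PssmMatrix, path: str | Path) -> None:
    """Write ``m`` back in the PSI-BLAST ASCII dialect (round-trip safe)."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + "  ".join(m.column_order) + "   "
        + "   ".join(m.column_order),
    ]
    for i, (aa, row) in enumerate(zip(m.sequence, m.scores), start=1):
        logodds = "".join(f"{v:4d}" for v in row)
        # percentage block and trailing stats are synthesised placeholders
        pct = "".join(f"{0:4d}" for _ in row)
        lines.append(f"{i:5d} {aa} {logodds} {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.1347     0.3190", ""]
    Path(path).write_text("\n".join(lines))


def encode_pssm(m: PssmMatrix, scaling: str = "raw") -> pd.DataFrame:
    """Per-residue 20-vector feature table, columns in alphabetical aa order.

    ``scaling='raw'`` keeps the log-odds; ``'sigmoid'`` maps each score
    through 1/(1+e^(−P)) into (0, 1).
    """
    if scaling not in ("raw", "sigmoid"):
        raise ValueError(f"unknown scaling {scaling!r}")
    perm = [m.column_order.index(a) for a in AA_ALPHABETICAL]
    vals = m.scores[:, perm].astype(float)
    if scaling == "sigmoid":
        vals = 1.0 / (1.0 + np.exp(-vals))
    df = pd.DataFrame(vals, columns=[f"pssm_{a}" for a in AA_ALPHABETICAL])
    df.insert(0, "position", np.arange(1, m.length + 1))
    df.insert(1, "aa", list(m.sequence))
    return df


def align_pssm_to_structure(
    m: PssmMatrix,
    s: StructureModel,
    chain: str,
    min_identity: float = 0.95,
    min_coverage: float = 0.5,
) -> dict[ResidueKey, int]:
    """Map structure residues of ``chain`` to 0-based PSSM row indices.

    Identical sequences map positionally; otherwise a local alignment of
    the PSSM sequence against the chain's observed sequence is used and
    unmatched residues are left out of the mapping.  An aligned-region
    identity below ``min_identity``, or an alignment covering less than
    ``min_coverage`` of the chain, raises a mismatch error.
    """
    keys, chain_seq = s.chain_sequence(chain)
    if chain_seq == m.sequence:
        return {k: i for i, k in enumerate(keys)}

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(m.sequence, chain_seq)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (p0, p1), (c0, c1) in zip(*aln.aligned):
        for dp in range(p1 - p0):
            pairs.append((p0 + dp, c0 + dp))
            if m.sequence[p0 + dp] == chain_seq[c0 + dp]:
                matches += 1
    ident = matches / len(pairs) if pairs else 0.0
    coverage = len(pairs) / len(keys)
    if not pairs or ident < min_identity or coverage < min_coverage:
        raise ValueError(
            f"PSSM/structure sequence mismatch for chain {chain}: aligned-"
            f"region identity {ident:.2f} (threshold {min_identity:.2f}), "
            f"chain coverage {coverage:.2f} (threshold {min_coverage:.2f})"
        )
    mapping = {keys[ci]: pi for pi, ci in pairs}
    unmatched = len(keys) - len(mapping)
    if unmatched:
        logger.info("chain %s: %d residue(s) without a PSSM row", chain, unmatched)
    return mapping


def pssm_table_for_structure(
    m: PssmMatrix,
    s: StructureModel,
    chain: str,
    scaling: str = "raw",
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Encoded PSSM rows keyed by structure residue (structure_id, chain,
    resnum, icode) for downstream feature assembly."""
    mapping = align_pssm_to_structure(m, s, chain, min_identity)
    enc = encode_pssm(m, scaling)
    feat_cols = [f"pssm_{a}" for a in AA_ALPHABETICAL]
    recs = []
    for key, row_idx in mapping.items():
        rec = {
            "structure_id": s.structure_id,
            "chain": key.chain_id,
            "resnum": key.residue_number,
            "icode": key.insertion_code,
        }
        rec.update(enc.loc[row_idx, feat_cols].to_dict())
        recs.append(rec)
    return pd.DataFrame(recs)
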