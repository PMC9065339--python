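"""Labelled feature-table assembly, complex-level splitting, under-sampling.

The design matrix has one row per residue and 27 feature columns in a
fixed, documented order: the 20 PSSM columns (amino acids alphabetically)
followed by the 7 network-topology columns.  Binding-site residues carry
label 1, all remaining residues label 0; because binding sites are a small
minority, 1:1 random under-sampling of the negatives is applied to the
training table before fitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pssm import AA_ALPHABETICAL
from .rin import TOPOLOGY_COLUMNS
from .structure_io import SiteLabels

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["structure_id", "chain", "resnum", "icode"]
PSSM_FEATURES = [f"pssm_{a}" for a in AA_ALPHABETICAL]
RIN_FEATURES = [f"rin_{c}" for c in TOPOLOGY_COLUMNS]
#: Fixed 27-column feature order: PSSM(20) then RIN(7).
FEATURE_COLUMNS = PSSM_FEATURES + RIN_FEATURES

FEATURE_GROUPS = {
    "pssm": PSSM_FEATURES,
    "rin": RIN_FEATURES,
    "pssm+rin": FEATURE_COLUMNS,
}


class EmptyDatasetError(ValueError):
    """Raised when feature assembly leaves zero rows."""


@dataclass(frozen=True)
class SplitSpec:
    """Complex-level train/test partition, reproducible from its seed."""

    train_structures: tuple[str, ...]
    test_structures: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_structures) & set(self.test_structures):
            raise ValueError("train and test structures overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"train_structures": list(self.train_structures),
             "test_structures": list(self.test_structures),
             "seed": self.seed}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["train_structures"]), tuple(d["test_structures"]),
                   d["seed"])


def _labels_frame(labels: SiteLabels) -> pd.DataFrame:
    recs = [
        {"structure_id": labels.structure_id, "chain": k.chain_id,
         "resnum": k.residue_number, "icode": k.insertion_code,
         "resname": k.residue_name, "label": v}
        for k, v in labels.labels.items()
    ]
    return pd.DataFrame(recs)


def assemble_features(
    labels: Iterable[SiteLabels],
    topo: Iterable[pd.DataFrame],
    pssm_tables: Iterable[pd.DataFrame] | None = None,
    feature_groups: Sequence[str] = ("pssm", "rin"),
) -> pd.DataFrame:
    """Inner-join labels, topology features and encoded PSSM rows per residue.

    Residues missing from any requested source are dropped (count logged).
    ``feature_groups`` selects which feature block(s) the table carries;
    column order is always PSSM first, then RIN.
    """
    for grp in feature_groups:
        if grp not in ("pssm", "rin"):
            raise ValueError(f"unknown feature group {grp!r}")
    table = pd.concat([_labels_frame(sl) for sl in labels], ignore_index=True)
    n_start = len(table)

    if "rin" in feature_groups:
        topo_df = pd.concat(list(topo), ignore_index=True)
        topo_df = topo_df.rename(columns={c: f"rin_{c}" for c in TOPOLOGY_COLUMNS})
        topo_df = topo_df[KEY_COLUMNS + RIN_FEATURES]
        table = table.merge(topo_df, on=KEY_COLUMNS, how="inner")
    if "pssm" in feature_groups:
        if pssm_tables is None:
            raise ValueError("feature group 'pssm' requested but no PSSM tables given")
        pssm_df = pd.concat(list(pssm_tables), ignore_index=True)
        pssm_df = pssm_df[KEY_COLUMNS + PSSM_FEATURES]
        table = table.merge(pssm_df, on=KEY_COLUMNS, how="inner")

    dropped = n_start - len(table)
    if dropped:
        logger.info("assemble_features: dropped %d residue(s) missing a source",
                    dropped)
    if table.empty:
        raise EmptyDatasetError("no residue survived the feature join")

    feat_cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    table = table[["structure_id", "chain", "resnum", "icode", "resname",
                   "label"] + feat_cols]
    table = table.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    if table[feat_cols].isna().any().any():
        raise ValueError("assembled feature table contains missing values")
    return table


def split_complexes(ids: Sequence[str], n_test: int, seed: int) -> SplitSpec:
    """Uniform random complex-level split without replacement.

    Mirrors the protocol of holding out 20 of 120 complexes as the
    independent set; deterministic for a given seed.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("structure ids must be unique")
    if not 0 <= n_test <= len(ids):
        raise ValueError(f"n_test={n_test} out of range for {len(ids)} ids")
    rng = np.random.default_rng(seed)
    test = set(rng.choice(len(ids), size=n_test, replace=False).tolist())
    return SplitSpec(
        tuple(x for i, x in enumerate(ids) if i not in test),
        tuple(x for i, x in enumerate(ids) if i in test),
        seed,
    )


def undersample(t: pd.DataFrame, ratio: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Random under-sampling of the negative class.

    Keeps every positive row and draws round(ratio × n_pos) negatives
    uniformly without replacement; the result is shuffled deterministically
    by ``seed``.  The default 1:1 ratio balances the classes for training.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos = t[t["label"] == 1]
    neg = t[t["label"] == 0]
    n_neg_wanted = int(round(ratio * len(pos)))
    if len(pos) == 0:
        raise ValueError("under-sampling needs at least one positive row")
    if len(neg) < n_neg_wanted:
        raise ValueError(
            f"not enough negatives: need {n_neg_wanted}, have {len(neg)} "
            f"({len(pos)} positives, ratio {ratio})"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(neg), size=n_neg_wanted, replace=False)
    out = pd.concat([pos, neg.iloc[np.sort(take)]], ignore_index=True)
    perm = rng.permutation(len(out))
    return out.iloc[perm].reset_index(drop=True)


def subset_by_structures(t: pd.DataFrame, ids: Sequence[str]) -> pd.DataFrame:
    """Rows of ``t`` belonging to the given structure ids."""
    return t[t["structure_id"].isin(set(ids))].reset_index(drop=True)
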