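"""Distributional analyses of residue features at binding vs non-binding sites.

Covers: pooled min–max normalisation of the topology descriptors with
per-class summaries, rank-based two-sample comparison of the classes,
per-class frequency histograms, HIGH/LOW proportions of amino-acid property
indices (e.g. the eight high-quality AAindex-derived scales: charge,
hydrophobicity, secondary-structure propensities, volume, ...) at binding
sites, and per-ligand-group amino-acid frequency counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import THREE_TO_ONE, SiteLabels

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class NormalizedFeatureSummary:
    """Min–max-normalised feature values with per-class summary statistics.

    Normalisation is fitted on the pooled (both-class) values of each
    feature, so every normalised value lies in [0, 1] and the two classes
    are directly comparable on a common scale.
    """

    normalized: pd.DataFrame  # feature columns + 'label'
    summary: pd.DataFrame     # (feature, label) × {mean, median, q25, q75, min, max}
    columns: list[str]


def normalize_features(t: pd.DataFrame, columns: Sequence[str]) -> NormalizedFeatureSummary:
    """Min–max normalise ``columns`` over the pooled data and summarise per class.

    A constant column cannot be scaled; it is set to all zeros with a warning.
    """
    missing = [c for c in columns if c not in t.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    norm = t[list(columns)].astype(float).copy()
    for c in columns:
        lo, hi = norm[c].min(), norm[c].max()
        if hi == lo:
            warnings.warn(f"feature {c!r} is constant; normalised to all zeros")
            norm[c] = 0.0
        else:
            norm[c] = (norm[c] - lo) / (hi - lo)
    norm["label"] = t["label"].to_numpy(dtype=int)
    summary = (
        norm.groupby("label")[list(columns)]
        .agg(["mean", "median",
              lambda s: s.quantile(0.25), lambda s: s.quantile(0.75),
              "min", "max"])
    )
    summary.columns = summary.columns.set_levels(
        ["mean", "median", "q25", "q75", "min", "max"], level=1)
    return NormalizedFeatureSummary(norm, summary, list(columns))


@dataclass(frozen=True)
class EffectRecord:
    feature: str
    mean_difference: float  # mean(positive class) − mean(negative class)
    statistic: float        # Mann–Whitney U (tie-corrected asymptotics)
    p_value: float


def class_distribution_compare(
    summary: NormalizedFeatureSummary, feature: str
) -> EffectRecord:
    """Compare a feature between binding (1) and non-binding (0) residues.

    Reports the class mean difference and the two-sided Mann–Whitney U
    rank-sum test with tie correction.  With every value tied the statistic
    is its null expectation n1·n2/2 and p = 1.  No multiple-testing
    correction is applied here; apply one externally when scanning many
    features.
    """
    if feature not in summary.columns:
        raise ValueError(f"unknown feature {feature!r}")
    df = summary.normalized
    pos = df.loc[df["label"] == 1, feature].to_numpy(float)
    neg = df.loc[df["label"] == 0, feature].to_numpy(float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    mean_diff = float(pos.mean() - neg.mean())
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        return EffectRecord(feature, mean_diff, len(pos) * len(neg) / 2.0, 1.0)
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic")
    return EffectRecord(feature, mean_diff, float(res.statistic),
                        float(res.pvalue))


def frequency_histogram(
    values: Sequence[float],
    labels: Sequence[int],
    n_bins: int = 10,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-class binned frequencies over equal-width bins of the pooled range.

    Frequencies are normalised so that each class sums to 1 (empty class →
    all-zero row).  Returns a frame with bin edges and one frequency column
    per class.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if value_range is None:
        value_range = (float(v.min()), float(v.max()))
    edges = np.linspace(value_range[0], value_range[1], n_bins + 1)
    out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for cls in (0, 1):
        counts, _ = np.histogram(v[y == cls], bins=edges)
        total = counts.sum()
        out[f"freq_class{cls}"] = counts / total if total else counts.astype(float)
    return pd.DataFrame(out)


class AaIndexTable:
    """Amino-acid property indices: one value per (standard amino acid, index).

    Load from a TSV with an ``aa`` column of one-letter codes and one column
    per index; every index must cover all 20 standard amino acids.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.copy()
        if "aa" in df.columns:
            df = df.set_index("aa")
        df.index = [str(a).upper() for a in df.index]
        missing = sorted(set(STANDARD_AA) - set(df.index))
        if missing:
            raise ValueError(f"index table missing amino acids: {missing}")
        self.values = df.loc[list(STANDARD_AA)].astype(float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AaIndexTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def index_names(self) -> list[str]:
        return list(self.values.columns)

    def mean(self, index_name: str) -> float:
        """Unweighted mean over the 20 standard amino acids (HIGH threshold)."""
        return float(self.values[index_name].mean())


def _to_one_letter(residue_types: Iterable[str]) -> tuple[list[str], int]:
    """One-letter codes from mixed 1-/3-letter input; count of unmapped."""
    out, excluded = [], 0
    for r in residue_types:
        r = str(r).upper()
        one = r if len(r) == 1 else THREE_TO_ONE.get(r, "")
        if one and one in STANDARD_AA:
            out.append(one)
        else:
            excluded += 1
    return out, excluded


def hqi_proportions(
    residue_types: Iterable[str],
    idx: AaIndexTable,
) -> pd.DataFrame:
    """HIGH/LOW percentages of each property index over binding-site residues.

    A residue is HIGH for an index iff its value is ≥ the unweighted mean
    of that index over the 20 standard amino acids (ties count as HIGH, so
    a constant index makes every residue HIGH).  Residue types outside the
    20 standard amino acids are excluded with a logged count.  Returns one
    row per index: high_pct, low_pct, n_used, n_excluded.
    """
    aas, excluded = _to_one_letter(residue_types)
    if excluded:
        logger.info("hqi_proportions: excluded %d non-standard residue(s)", excluded)
    if not aas:
        raise ValueError("no standard-amino-acid residues to analyse")
    rows = []
    for name in idx.index_names:
        thr = idx.mean(name)
        high = sum(1 for a in aas if idx.values.at[a, name] >= thr)
        n = len(aas)
        rows.append({"index": name,
                     "high_pct": 100.0 * high / n,
                     "low_pct": 100.0 * (n - high) / n,
                     "n_used": n, "n_excluded": excluded})
    return pd.DataFrame(rows).set_index("index")


def binding_site_residue_types(labels: SiteLabels) -> list[str]:
    """Residue names (3-letter) of the binding-site (label-1) residues."""
    return [k.residue_name for k in labels.positive_keys]


def ligand_aa_frequency(
    labels: Iterable[SiteLabels],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Amino-acid counts at binding sites, per ligand/structure group.

    ``grouping`` maps structure_id → group id (default: each structure is
    its own group).  Returns groups × residue-type counts; groups with no
    binding site give all-zero rows.
    """
    counts: dict[str, dict[str, int]] = {}
    for sl in labels:
        group = grouping.get(sl.structure_id, sl.structure_id) if grouping \
            else sl.structure_id
        bucket = counts.setdefault(group, {})
        for k in sl.positive_keys:
            bucket[k.residue_name] = bucket.get(k.residue_name, 0) + 1
    out = pd.DataFrame.from_dict(counts, orient="index")
    out = out.reindex(sorted(counts))  # keep groups with no binding site
    return out.fillna(0).astype(int)
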