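"""Feature composition of the constrained genome across CNC deciles.

Each constrained bin is assigned a single genomic feature by walking an
ordered priority hierarchy (coding-first by default), and compositions are
tallied per CNC decile. Fold enrichment between the extreme deciles and
chi-squared tests with Yates' continuity correction quantify the
over/under-representation of individual features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2

from ._intervals import flag_overlaps
from .tracks import read_bed

#: default priority order, highest first (catch-all is implicit lowest)
DEFAULT_PRIORITY = ("coding_exon", "splice_site", "UTR", "promoter",
                    "promoter_flanking", "enhancer", "open_chromatin",
                    "TF_binding", "ncRNA_exon", "intron")


@dataclass
class FeatureHierarchy:
    """Ordered (label, interval set) pairs; lower index = higher priority."""

    levels: tuple[tuple[str, pd.DataFrame], ...]
    catch_all: str = "intergenic"

    def __post_init__(self):
        labels = [lab for lab, _ in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate feature labels")
        if self.catch_all in labels:
            raise ValueError("catch-all label shadows a prioritised feature")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.levels) + (self.catch_all,)

    @classmethod
    def from_yaml(cls, path) -> "FeatureHierarchy":
        """YAML config: ``features: [{label: ..., bed: ...}, ...]`` in priority
        order, with optional ``catch_all``. BED paths are resolved relative to
        the config file."""
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        levels = []
        for item in cfg["features"]:
            bed = Path(item["bed"])
            if not bed.is_absolute():
                bed = path.parent / bed
            levels.append((item["label"], read_bed(bed)))
        return cls(tuple(levels), cfg.get("catch_all", "intergenic"))


@dataclass
class CompositionTable:
    """Bin counts and row-normalised proportions per decile x feature."""

    counts: pd.DataFrame
    proportions: pd.DataFrame


def assign_features(bins: pd.DataFrame, hierarchy: FeatureHierarchy) -> pd.Series:
    """Assign each bin the highest-priority feature overlapping it by >=1 bp;
    the catch-all label if none. Independent of interval file ordering."""
    labels = pd.Series(hierarchy.catch_all, index=bins.index, dtype="object")
    # apply lowest priority first so higher priorities overwrite
    for lab, ivs in reversed(hierarchy.levels):
        hit = flag_overlaps(bins, ivs)
        labels.iloc[np.flatnonzero(hit)] = lab
    return labels


def compose_by_decile(assignments: pd.Series, deciles: pd.Series) -> CompositionTable:
    """Tally features per CNC decile over the constrained bins.

    ``deciles`` may carry NA outside the constrained set; those bins are
    ignored. Constrained bins missing a feature assignment are an error.
    """
    in_decile = deciles.notna()
    missing = in_decile & assignments.isna()
    if missing.any():
        raise ValueError(f"bins missing a feature label: {list(missing[missing].index[:10])}")
    counts = pd.crosstab(deciles[in_decile], assignments[in_decile])
    counts.index.name = "decile"
    counts.columns.name = "feature"
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts, proportions)


@dataclass(frozen=True)
class FoldResult:
    feature: str
    high: str
    low: str
    fold: float            # proportion(high) / proportion(low)
    infinite: bool

    @property
    def depletion_fold(self) -> float:
        """Reciprocal fold, the natural reading when fold < 1 (e.g. a fold of
        1/27 is reported as a 27-fold depletion)."""
        return np.inf if self.fold == 0 else 1.0 / self.fold


def fold_enrichment(table: CompositionTable, feature: str,
                    high: str = "90-100", low: str = "0-10") -> FoldResult:
    """Fold enrichment of a feature's proportion in the high vs low decile."""
    for dec in (high, low):
        if dec not in table.proportions.index:
            raise ValueError(f"decile {dec!r} absent from composition table")
    p_high = float(table.proportions.at[high, feature]) if feature in table.proportions.columns else 0.0
    p_low = float(table.proportions.at[low, feature]) if feature in table.proportions.columns else 0.0
    if p_low == 0.0:
        return FoldResult(feature, high, low, np.inf, True)
    return FoldResult(feature, high, low, p_high / p_low, False)


def chi_squared_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Chi-squared test of a 2x2 table with Yates' continuity correction.

    statistic = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), with the
    corrected deviation floored at 0; p from chi-squared with 1 df.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal total")
    dev = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * dev ** 2 / np.prod([float(m) for m in margins])
    return float(stat), float(chi2.sf(stat, df=1))


def decile_feature_test(table: CompositionTable, feature: str,
                        high: str = "90-100", low: str = "0-10") -> dict:
    """Convenience: fold enrichment plus the Yates chi-squared comparing the
    feature's counts between the two extreme deciles."""
    counts = table.counts
    a = int(counts.at[high, feature]) if feature in counts.columns else 0
    b = int(counts.loc[high].sum()) - a
    c = int(counts.at[low, feature]) if feature in counts.columns else 0
    d = int(counts.loc[low].sum()) - c
    fold = fold_enrichment(table, feature, high, low)
    stat, p = chi_squared_yates(a, b, c, d)
    return {"feature": feature, "fold": fold.fold, "infinite": fold.infinite,
            "chi2": stat, "p": p}
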