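"""CNC scoring and calling of constrained, non-conserved regions (CNCRs).

Every scored bin carries an intra-species constraint score (CDTS-like,
lower = more constrained) and a cross-species conservation score
(phastCons-like). Both are ranked genome-wide so that the highest rank marks
the most constrained / most conserved bin, and the CNC score is

    cnc = log2(rank_constraint / rank_conservation)

A distribution centred at 0 means no fold change between the two ranks; a
CNC of 1 marks a twofold higher ranking in constraint than conservation.
Three annotation categories are derived:

* constrained   — the 12.5% most constrained bins, irrespective of conservation;
* CNCR          — constrained bins with CNC >= 1 (the inclusive threshold);
* non-conserved — bins whose conservation rank falls at or below a rank
  threshold, irrespective of constraint. On GRCh38 with the published input
  tracks that threshold is rank <= 25,623,592 (the rank of the first-quartile
  conservation score at CNC = 1); on other inputs it can be re-derived.

Ties in either score receive midranks (average ranks) so the log ratio is
well defined and reproducible; top-k selection breaks rank ties positionally
by (chromosome order, start) so repeat runs are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._intervals import empty_intervals, merge_adjacent_bins, points_in_intervals
from .tracks import GenomeLayout

#: published non-conserved rank threshold for GRCh38 (10-bp bins)
GRCH38_NONCONSERVED_RANK = 25_623_592

DECILE_LABELS = tuple(f"{10 * i}-{10 * (i + 1)}" for i in range(10))


@dataclass
class AnnotationSet:
    """Merged interval sets for the three annotation categories."""

    cncr: pd.DataFrame
    constrained: pd.DataFrame
    nonconserved: pd.DataFrame
    params: dict = field(default_factory=dict)


def rank_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Add genome-wide midranks: rank_constraint of (-cdts), rank_conservation
    of cons, both ascending so the highest rank is the most constrained /
    conserved bin."""
    if len(bins) == 0:
        raise ValueError("cannot rank an empty bin table")
    out = bins.copy()
    out["rank_constraint"] = rankdata(-out["cdts"].to_numpy(), method="average")
    out["rank_conservation"] = rankdata(out["cons"].to_numpy(), method="average")
    return out


def compute_cnc(rank_constraint, rank_conservation):
    """CNC score: log2 of the constraint rank over the conservation rank."""
    rc = np.asarray(rank_constraint, dtype=float)
    rn = np.asarray(rank_conservation, dtype=float)
    if (rc <= 0).any() or (rn <= 0).any():
        raise ValueError("ranks must be positive")
    out = np.log2(rc / rn)
    return float(out) if out.ndim == 0 else out


def score_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Rank the joined bins and attach the CNC score column."""
    out = rank_bins(bins)
    out["cnc"] = compute_cnc(out["rank_constraint"], out["rank_conservation"])
    return out


def _positional_order(scored: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    rank = layout.order
    chrom_key = scored["chrom"].map(rank)
    if chrom_key.isna().any():
        bad = sorted(scored.loc[chrom_key.isna(), "chrom"].unique())
        raise ValueError(f"bins on chromosomes not in layout: {bad}")
    return chrom_key.to_numpy(), scored["start"].to_numpy()


def call_constrained(scored: pd.DataFrame, layout: GenomeLayout,
                     fraction: float = 0.125) -> tuple[np.ndarray, pd.DataFrame]:
    """Select the ``floor(fraction * N)`` most constrained bins.

    Rank ties straddling the cutoff are broken by (chromosome order, start)
    ascending so exactly k bins are selected deterministically. Returns the
    per-bin flag array and the merged interval set of selected bins.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(scored)
    k = int(np.floor(fraction * n))
    chrom_key, starts = _positional_order(scored, layout)
    order = np.lexsort((starts, chrom_key, -scored["rank_constraint"].to_numpy()))
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    intervals = merge_adjacent_bins(
        scored["chrom"].to_numpy()[flags], scored["start"].to_numpy()[flags],
        scored["end"].to_numpy()[flags], list(layout.chrom_names))
    return flags, intervals


def call_cncr(scored: pd.DataFrame, constrained_flags: np.ndarray,
              layout: GenomeLayout, cnc_threshold: float = 1.0
              ) -> tuple[np.ndarray, pd.DataFrame]:
    """CNCR bins: constrained AND cnc >= threshold (inclusive); merged."""
    flags = constrained_flags & (scored["cnc"].to_numpy() >= cnc_threshold)
    intervals = merge_adjacent_bins(
        scored["chrom"].to_numpy()[flags], scored["start"].to_numpy()[flags],
        scored["end"].to_numpy()[flags], list(layout.chrom_names))
    return flags, intervals


def derive_nonconserved_rank(scored: pd.DataFrame, cnc_threshold: float = 1.0,
                             tol: float = 0.01) -> float:
    """Derive the non-conserved rank threshold from the data: the genome-wide
    conservation midrank of the first-quartile conservation score among bins
    with |cnc - threshold| <= tol."""
    window = scored.loc[(scored["cnc"] - cnc_threshold).abs() <= tol]
    if len(window) == 0:
        raise ValueError(
            f"no bins with |cnc - {cnc_threshold}| <= {tol}; increase tol")
    q1 = float(np.quantile(window["cons"].to_numpy(), 0.25))
    cons = scored["cons"].to_numpy()
    # midrank of the score value q1 within the genome-wide conservation ranking
    below = np.sum(cons < q1)
    equal = np.sum(cons == q1)
    if equal > 0:
        return float(below + (equal + 1) / 2)
    return float(below + 0.5)


def call_nonconserved(scored: pd.DataFrame, layout: GenomeLayout,
                      rank_threshold: float | int | str = "derive",
                      cnc_threshold: float = 1.0, tol: float = 0.01
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Non-conserved bins: conservation rank <= threshold, irrespective of
    constraint. ``rank_threshold`` may be a number (e.g. the published GRCh38
    value) or ``"derive"`` to recompute it from the scored table."""
    if rank_threshold == "derive":
        rank_threshold = derive_nonconserved_rank(scored, cnc_threshold, tol)
    flags = scored["rank_conservation"].to_numpy() <= float(rank_threshold)
    intervals = merge_adjacent_bins(
        scored["chrom"].to_numpy()[flags], scored["start"].to_numpy()[flags],
        scored["end"].to_numpy()[flags], list(layout.chrom_names))
    return flags, intervals


def partition_deciles(scored: pd.DataFrame, constrained_flags: np.ndarray,
                      layout: GenomeLayout) -> pd.Series:
    """Split the constrained bins into 10 equally sized deciles by CNC score.

    Bins are sorted by cnc ascending (ties by chromosome order then start) and
    split into 10 contiguous groups whose sizes differ by at most one; the
    "90-100" decile holds the highest CNC scores. Returns a Series of decile
    labels indexed like ``scored`` (NaN outside the constrained set).
    """
    idx = np.flatnonzero(constrained_flags)
    if len(idx) < 10:
        raise ValueError("need at least 10 constrained bins to form deciles")
    sub = scored.iloc[idx]
    chrom_key, starts = _positional_order(sub, layout)
    order = idx[np.lexsort((starts, chrom_key, sub["cnc"].to_numpy()))]
    labels = pd.Series(pd.NA, index=scored.index, dtype="object")
    for lab, chunk in zip(DECILE_LABELS, np.array_split(order, 10)):
        labels.iloc[chunk] = lab
    return labels


def annotate(scored: pd.DataFrame, layout: GenomeLayout,
             constrained_fraction: float = 0.125, cnc_threshold: float = 1.0,
             nonconserved_rank: float | str = "derive") -> tuple[pd.DataFrame, AnnotationSet]:
    """Run the full calling pipeline on a scored bin table.

    Returns the table with flag columns added and the merged
    :class:`AnnotationSet` for the three categories.
    """
    out = scored.copy()
    cflags, cintervals = call_constrained(out, layout, constrained_fraction)
    rflags, rintervals = call_cncr(out, cflags, layout, cnc_threshold)
    nflags, nintervals = call_nonconserved(out, layout, nonconserved_rank,
                                           cnc_threshold)
    out["constrained"] = cflags
    out["cncr"] = rflags
    out["nonconserved"] = nflags
    params = {"constrained_fraction": constrained_fraction,
              "cnc_threshold": cnc_threshold,
              "nonconserved_rank": nonconserved_rank}
    return out, AnnotationSet(rintervals, cintervals, nintervals, params)


def export_ldsc_annot(annotations: AnnotationSet, snp_table: pd.DataFrame,
                      path=None) -> pd.DataFrame:
    """Thin-annot export: one binary column per annotation category.

    ``snp_table`` has columns chrom, pos (1-based), rsid. A SNP scores 1 iff
    its 0-based position lies inside an interval of the category. SNPs on
    chromosomes absent from every category score 0 with a warning.
    """
    chroms = snp_table["chrom"].to_numpy()
    pos0 = snp_table["pos"].to_numpy() - 1
    cols = {}
    for name, ivs in (("CNCR", annotations.cncr),
                      ("constrained", annotations.constrained),
                      ("nonconserved", annotations.nonconserved)):
        cols[name] = points_in_intervals(chroms, pos0, ivs).astype(int)
    known = set()
    for ivs in (annotations.cncr, annotations.constrained, annotations.nonconserved):
        if len(ivs):
            known.update(ivs["chrom"].unique())
    unknown = sorted(set(chroms) - known) if known else sorted(set(chroms))
    if unknown:
        warnings.warn(f"SNPs on chromosomes without annotation: {unknown}",
                      stacklevel=2)
    out = pd.DataFrame(cols)
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
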