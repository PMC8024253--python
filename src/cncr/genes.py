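"""Per-gene CNCR density and gene-set analyses.

CNCR density is the proportion of a gene's span (transcription start to stop,
introns included) covered by CNCR intervals: d = overlap_bp / span_bp, in
[0, 1]. Gene sets thresholded on density (>0.0, then >=0.1 ... >=0.5) are
nested; biotype composition across the threshold grid is summarised by an
OLS slope per biotype with Benjamini-Hochberg FDR across biotypes, and
density distributions between gene lists are compared with the two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._intervals import overlap_bp
from .tracks import GeneModel

DEFAULT_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def compute_gene_density(genes: list[GeneModel], cncr: pd.DataFrame) -> pd.DataFrame:
    """CNCR density per gene: bp of span/CNCR intersection over span bp.

    ``cncr`` is an interval table (chrom, start, end); it is merged internally
    so overlapping intervals are not double counted. Genes on chromosomes
    with no CNCRs get density 0.
    """
    if not genes:
        return pd.DataFrame(columns=["gene_id", "biotype", "chrom", "span_bp",
                                     "overlap_bp", "density"])
    for g in genes:
        if g.span_bp <= 0:
            raise ValueError(f"{g.gene_id}: zero-length span")
    gdf = pd.DataFrame({"chrom": [g.chrom for g in genes],
                        "start": [g.start for g in genes],
                        "end": [g.end for g in genes],
                        "gene_id": [g.gene_id for g in genes]})
    ov = overlap_bp(gdf, cncr, by="gene_id")
    out = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "biotype": [g.biotype for g in genes],
        "chrom": [g.chrom for g in genes],
        "span_bp": [g.span_bp for g in genes],
        "overlap_bp": ov.loc[[g.gene_id for g in genes]].to_numpy(),
    })
    out["density"] = out["overlap_bp"] / out["span_bp"]
    return out


def gene_sets_by_threshold(densities: pd.DataFrame,
                           grid: tuple[float, ...] = DEFAULT_GRID
                           ) -> dict[float, set[str]]:
    """Nested gene sets across the density grid.

    The first grid point is strict (density > t); the remaining points are
    inclusive (density >= t), matching the conventional "(>0.0 to >=0.5)"
    reading of the grid.
    """
    sets: dict[float, set[str]] = {}
    d = densities["density"].to_numpy()
    ids = densities["gene_id"].to_numpy()
    for i, t in enumerate(grid):
        keep = d > t if i == 0 else d >= t
        sets[t] = set(ids[keep])
    return sets


def biotype_trend(densities: pd.DataFrame,
                  grid: tuple[float, ...] = DEFAULT_GRID) -> pd.DataFrame:
    """OLS slope of each biotype's proportion on the density cutoff.

    For each cutoff, the proportion of each biotype among genes passing the
    cutoff; cutoffs with empty gene sets are dropped (at least 3 non-empty
    cutoffs are required). Slopes are unweighted OLS of proportion on the
    numeric cutoff; p-values are BH-adjusted across biotypes.
    """
    sets = gene_sets_by_threshold(densities, grid)
    by_id = densities.set_index("gene_id")["biotype"]
    rows = {}
    cutoffs = []
    for t, ids in sets.items():
        if not ids:
            continue
        cutoffs.append(t)
        counts = by_id.loc[sorted(ids)].value_counts()
        rows[t] = counts / counts.sum()
    if len(cutoffs) < 3:
        raise ValueError("fewer than 3 cutoffs with non-empty gene sets")
    prop = pd.DataFrame(rows).T.fillna(0.0)  # cutoffs x biotypes
    prop = prop.loc[cutoffs]
    results = []
    for biotype in sorted(prop.columns):
        y = prop[biotype].to_numpy()
        fit = stats.linregress(np.asarray(cutoffs, dtype=float), y)
        results.append({"biotype": biotype, "beta": fit.slope,
                        "p": 1.0 if np.isnan(fit.pvalue) else fit.pvalue,
                        "n_cutoffs": len(cutoffs)})
    out = pd.DataFrame(results)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class DensityComparison:
    """Two-sided rank-sum comparison of density distributions."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    statistic: float
    p: float


def compare_density_distributions(group_a, group_b,
                                  labels: tuple[str, str] = ("A", "B")
                                  ) -> DensityComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test between two density samples.

    Small tie-free samples use the exact null distribution; larger samples
    use the normal approximation with continuity correction (scipy's
    ``method="auto"`` policy).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return DensityComparison(
        labels[0], labels[1], len(a), len(b),
        float(np.median(a)), float(np.median(b)),
        (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        (float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        float(res.statistic), float(res.pvalue))


def summarize_densities(densities: pd.DataFrame, threshold: float | None = None,
                        top_k: int | None = None) -> tuple[pd.DataFrame, int | None]:
    """Rank genes by density (descending, ties by gene_id) and count genes
    strictly above ``threshold`` when given."""
    out = densities.sort_values(["density", "gene_id"],
                                ascending=[False, True]).reset_index(drop=True)
    n_above = None
    if threshold is not None:
        n_above = int((out["density"] > threshold).sum())
    if top_k is not None:
        out = out.head(top_k)
    return out, n_above
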