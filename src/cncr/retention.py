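"""Intron-retention transcript usage from coverage and splice junctions.

The usage of an intron-retaining transcript (the motivating case is the
unannotated intron-3 retention event in APOE) is estimated per sample as a
ratio of two normalised quantities:

* cov_fraction  — mean per-base coverage over the target intron divided by
  mean per-base coverage over the whole gene span;
* junc_fraction — reads on the junction splicing out the target intron
  divided by reads over all annotated junctions of the gene;
* ratio = cov_fraction / junc_fraction — higher means more retention usage.

The ratio is exactly invariant under uniform scaling of sequencing depth, so
no library-size normalisation is applied. Group contrasts use the
Kruskal-Wallis omnibus test with pairwise rank-sum tests (BH-adjusted), and
associations with ordinal predictors (APOE-e4 dosage, Braak or CERAD stage)
use ordinary least squares adjusted for technical and demographic covariates
(batch, RIN, post-mortem interval, age, sex, ...).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class UndefinedQuantError(ValueError):
    """A quantification is undefined for this sample (zero denominator)."""


class CollinearityError(ValueError):
    """The design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class GeneModelIR:
    """Reference-transcript exon chain with one designated target intron."""

    gene_id: str
    chrom: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    target_intron: tuple[int, int]        # (donor, acceptor), half-open
    junctions: tuple[tuple[int, int], ...]  # annotated (donor, acceptor) pairs

    def __post_init__(self):
        s, e = self.target_intron
        if not any(s == ex_end for _, ex_end in self.exons) or \
           not any(e == ex_start for ex_start, _ in self.exons):
            raise ValueError("target intron boundaries do not match exon edges")
        if self.target_intron not in self.junctions:
            raise ValueError("target intron junction missing from annotated set")

    @classmethod
    def from_exons(cls, gene_id: str, chrom: str,
                   exons: list[tuple[int, int]], intron_index: int) -> "GeneModelIR":
        """Build from an ordered exon chain; ``intron_index`` is 1-based
        (intron i lies between exon i and exon i+1)."""
        exons = tuple(sorted(exons))
        if not 1 <= intron_index <= len(exons) - 1:
            raise ValueError("intron_index outside the exon chain")
        junctions = tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
        target = junctions[intron_index - 1]
        return cls(gene_id, chrom, (exons[0][0], exons[-1][1]), exons, target, junctions)

    @property
    def intron_bp(self) -> int:
        return self.target_intron[1] - self.target_intron[0]

    @property
    def span_bp(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class SampleSignal:
    """Per-sample coverage intervals, junction counts and metadata."""

    sample_id: str
    coverage: pd.DataFrame  # chrom, start, end, value (absent bases = depth 0)
    junction_counts: dict[tuple[int, int], int]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IRQuant:
    sample_id: str
    cov_fraction: float
    junc_fraction: float
    ratio: float


def _region_sum(coverage: pd.DataFrame, start: int, end: int) -> float:
    """Total depth x bp inside [start, end); uncovered bases contribute 0."""
    s = np.maximum(coverage["start"].to_numpy(), start)
    e = np.minimum(coverage["end"].to_numpy(), end)
    w = np.maximum(e - s, 0)
    return float(np.sum(w * coverage["value"].to_numpy()))


def cov_fraction(signal: SampleSignal, model: GeneModelIR) -> float:
    """Mean coverage over the target intron over mean coverage over the span."""
    gene_sum = _region_sum(signal.coverage, *model.span)
    if gene_sum <= 0:
        raise UndefinedQuantError(f"{signal.sample_id}: zero gene coverage")
    intron_sum = _region_sum(signal.coverage, *model.target_intron)
    gene_mean = gene_sum / model.span_bp
    intron_mean = intron_sum / model.intron_bp
    return intron_mean / gene_mean


def junc_fraction(signal: SampleSignal, model: GeneModelIR) -> float:
    """Target-junction reads over all annotated junction reads.

    Junctions absent from the annotated set (novel) are excluded from the
    denominator and logged.
    """
    annotated = set(model.junctions)
    novel = {k: v for k, v in signal.junction_counts.items()
             if k not in annotated and v > 0}
    if novel:
        log.info("%s: %d novel junction(s) excluded (%d reads)", signal.sample_id,
                 len(novel), sum(novel.values()))
    total = sum(v for k, v in signal.junction_counts.items() if k in annotated)
    if total <= 0:
        raise UndefinedQuantError(f"{signal.sample_id}: zero annotated junction reads")
    return signal.junction_counts.get(model.target_intron, 0) / total


def ir_ratio(signal: SampleSignal, model: GeneModelIR) -> IRQuant:
    """The normalised coverage-to-junction usage ratio for one sample.

    A zero junction fraction yields an infinite ratio, flagged so downstream
    models can exclude the sample.
    """
    cf = cov_fraction(signal, model)
    jf = junc_fraction(signal, model)
    if jf == 0:
        log.warning("%s: junction fraction 0 -> infinite usage flagged",
                    signal.sample_id)
        return IRQuant(signal.sample_id, cf, jf, np.inf)
    return IRQuant(signal.sample_id, cf, jf, cf / jf)


def cross_species_intron_usage(signal: SampleSignal, model: GeneModelIR) -> float:
    """Length-normalised intron coverage over total gene coverage.

    Total intron coverage divided by intron length, then by the total gene
    coverage, so values are comparable across species with different intron
    lengths, sequencing depths and expression levels.
    """
    if model.intron_bp <= 0:
        raise ValueError("intron length must be positive")
    gene_sum = _region_sum(signal.coverage, *model.span)
    if gene_sum <= 0:
        raise UndefinedQuantError(f"{signal.sample_id}: zero gene coverage")
    intron_sum = _region_sum(signal.coverage, *model.target_intron)
    return (intron_sum / model.intron_bp) / gene_sum


def quantify_cohort(signals: list[SampleSignal], model: GeneModelIR
                    ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Quantify usage for every sample, excluding undefined/infinite ones.

    Returns the per-sample table (quantities plus metadata columns) and a
    list of (sample_id, reason) exclusions.
    """
    rows, excluded = [], []
    for sig in signals:
        try:
            q = ir_ratio(sig, model)
        except UndefinedQuantError as err:
            log.info("excluding %s: %s", sig.sample_id, err)
            excluded.append((sig.sample_id, str(err)))
            continue
        if not np.isfinite(q.ratio):
            excluded.append((sig.sample_id, "infinite ratio (no target splicing)"))
            continue
        rows.append({"sample_id": q.sample_id, "cov_fraction": q.cov_fraction,
                     "junc_fraction": q.junc_fraction, "ratio": q.ratio,
                     **sig.metadata})
    return pd.DataFrame(rows), excluded


# ---------------------------------------------------------------------------
# group comparisons and covariate-adjusted models
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    groups: tuple[str, ...]
    statistic: float   # Kruskal-Wallis H (tie-corrected)
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p, fdr


def compare_groups(quants: pd.DataFrame, group_col: str,
                   value_col: str = "ratio") -> GroupComparison:
    """Kruskal-Wallis omnibus plus all pairwise two-sided rank-sum tests,
    BH-adjusted across pairs."""
    grouped = {str(k): v[value_col].to_numpy()
               for k, v in quants.groupby(group_col, sort=True, observed=True) if len(v)}
    names = tuple(grouped)
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups")
    if np.ptp(np.concatenate(list(grouped.values()))) == 0:
        h, p = 0.0, 1.0  # all values identical; H degenerates to 0
    else:
        h, p = stats.kruskal(*grouped.values())
    rows = []
    for a, b in itertools.combinations(names, 2):
        res = stats.mannwhitneyu(grouped[a], grouped[b], alternative="two-sided",
                                 method="auto")
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["fdr"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return GroupComparison(names, float(h), float(p), pairwise)


@dataclass
class AssociationResult:
    predictor: str
    slope: float
    p: float
    adj_r2: float
    n: int
    params: pd.Series
    fit: object = field(repr=False, default=None)


def _design_matrix(df: pd.DataFrame, columns, categorical, references) -> pd.DataFrame:
    parts = []
    for col in columns:
        if col in categorical:
            values = df[col].astype(str)
            cats = sorted(values.unique())
            ref = str((references or {}).get(col, cats[0]))
            if ref in cats:
                cats = [ref] + [c for c in cats if c != ref]
            coded = pd.Categorical(values, categories=cats)
            dummies = pd.get_dummies(coded, prefix=col, drop_first=True, dtype=float)
            dummies.index = df.index
            parts.append(dummies)
        else:
            parts.append(df[[col]].astype(float))
    return pd.concat(parts, axis=1)


def _check_collinearity(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    full = np.linalg.matrix_rank(mat)
    if full == mat.shape[1]:
        return
    offending = []
    for j, name in enumerate(X.columns):
        reduced = np.delete(mat, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            offending.append(name)
    raise CollinearityError(f"collinear design columns: {offending}")


def covariate_adjusted_association(quants: pd.DataFrame, predictor: str,
                                   covariates: tuple[str, ...] = (),
                                   categorical: tuple[str, ...] = (),
                                   references: dict | None = None,
                                   value_col: str = "ratio") -> AssociationResult:
    """OLS of the usage ratio on an ordinal/numeric predictor plus covariates.

    Categorical covariates are one-hot encoded against a reference level.
    Returns the predictor's slope, its two-sided p-value and the adjusted R^2.
    """
    df = quants.dropna(subset=[value_col, predictor, *covariates])
    X = _design_matrix(df, (predictor, *covariates), set(categorical), references)
    if len(df) <= X.shape[1] + 1:
        raise ValueError(f"n={len(df)} too small for {X.shape[1]} model columns")
    _check_collinearity(sm.add_constant(X, has_constant="add"))
    fit = sm.OLS(df[value_col].to_numpy(dtype=float),
                 sm.add_constant(X, has_constant="add")).fit()
    return AssociationResult(predictor, float(fit.params[predictor]),
                             float(fit.pvalues[predictor]), float(fit.rsquared_adj),
                             int(fit.nobs), fit.params, fit)


_BRAAK = {"I": "mild", "II": "mild", "III": "moderate", "IV": "moderate",
          "V": "severe", "VI": "severe"}
_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI"}


def merge_braak(stage) -> str:
    """Merge Braak & Braak stages: I/II -> mild, III/IV -> moderate,
    V/VI -> severe. Accepts Roman numerals or integers 1-6."""
    key = stage
    if isinstance(stage, (int, np.integer)) or (isinstance(stage, str) and stage.isdigit()):
        key = _ROMAN.get(int(stage))
    if not isinstance(key, str) or key.upper() not in _BRAAK:
        raise ValueError(f"unknown Braak stage: {stage!r}")
    return _BRAAK[key.upper()]


def leave_one_group_out(quants: pd.DataFrame, predictor: str,
                        covariates: tuple[str, ...] = (),
                        categorical: tuple[str, ...] = (),
                        group_col: str = "batch",
                        value_col: str = "ratio") -> pd.DataFrame:
    """Refit the covariate-adjusted model excluding each group in turn.

    A robustness check against outlying batches: the exclusion that moves the
    slope the most points at the most influential group.
    """
    groups = sorted(quants[group_col].astype(str).unique())
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for leave-one-group-out")
    rows = []
    for g in groups:
        sub = quants.loc[quants[group_col].astype(str) != g]
        if len(sub) == 0:
            raise ValueError(f"excluding {g!r} empties the data")
        res = covariate_adjusted_association(sub, predictor, covariates,
                                             categorical, value_col=value_col)
        rows.append({"excluded_group": g, "slope": res.slope, "p": res.p,
                     "adj_r2": res.adj_r2, "n": res.n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

SJ_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "motif",
              "annotated", "unique_reads", "multi_reads", "max_overhang"]


def read_junctions(path, chrom: str | None = None) -> dict[tuple[int, int], int]:
    """Read a 9-column splice-junction tab file (STAR SJ.out.tab dialect).

    Intron coordinates in the file are 1-based inclusive; they are converted
    to 0-based half-open (donor = intron_start - 1, acceptor = intron_end).
    Unique-read counts are used; duplicate keys are summed.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=SJ_COLUMNS,
                     dtype={"chrom": str})
    if chrom is not None:
        df = df.loc[df["chrom"] == chrom]
    counts: dict[tuple[int, int], int] = {}
    for s, e, u in zip(df["intron_start"], df["intron_end"], df["unique_reads"]):
        key = (int(s) - 1, int(e))
        counts[key] = counts.get(key, 0) + int(u)
    return counts


def read_sample_coverage(path) -> pd.DataFrame:
    """4-column bedGraph of per-base depth (no layout validation needed for
    single-gene coverage extracts)."""
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end", "value"],
                       dtype={"chrom": str})


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("metadata table lacks a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df
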