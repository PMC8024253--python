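"""Seeded synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the shape of the study's real inputs — a CDTS-like
constraint bedGraph, a phastCons-like conservation bedGraph, a GTF of mixed
gene biotypes, feature interval sets, and a cohort of per-sample coverage and
splice-junction files with clinical metadata — at desk scale, with the truth
(planted CNCR blocks, per-gene expected densities, per-sample retention
fractions and model coefficients) recorded alongside.

Background constraint and conservation are drawn from a correlated bivariate
normal (the real tracks are correlated; the annotation exploits the rank
disparity), with conservation mapped through the normal CDF so its marginal
is uniform on [0, 1]. Planted CNCR blocks receive constraint below the 5th
percentile of background and conservation below the 25th percentile; control
blocks (constrained AND conserved) receive the same extreme constraint but
conservation above the 95th percentile, so a correct caller recovers planted
blocks and never calls controls.

Each generator draws from its own RNG stream derived from the master seed by
a stable label, so adding a generator does not shift the others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr
from scipy.stats import norm

from ._intervals import merge_intervals, overlap_bp
from .retention import GeneModelIR, SampleSignal
from .tracks import BaseTrack, GeneModel, GenomeLayout

_STREAMS = {"genes": 1, "scores": 2, "blocks": 3, "features": 4, "snps": 5,
            "ir": 6}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[label])))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LayoutSpec:
    n_chroms: int = 3
    chrom_length: int = 600_000
    bin_width: int = 10


@dataclass
class GeneSpec:
    n_genes: int = 200
    biotype_probs: dict = field(default_factory=lambda: {
        "protein_coding": 0.5, "lncRNA": 0.22, "miRNA": 0.1,
        "snRNA": 0.06, "processed_pseudogene": 0.12})
    small_biotypes: tuple[str, ...] = ("miRNA", "snRNA")
    exon_count: tuple[int, int] = (3, 6)          # inclusive, multi-exon genes
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (200, 1500)
    small_gene_len: tuple[int, int] = (200, 800)  # single-exon small RNAs
    gap_len: tuple[int, int] = (300, 1500)


@dataclass
class BlockSpec:
    n_cncr_blocks: int = 60
    block_len: int = 600                 # multiple of the bin width
    n_control_blocks: int = 15
    genic_fraction: float = 0.7
    n_neuro_genes: int = 25
    neuro_host_prob: float = 0.7
    host_biotype_weights: dict = field(default_factory=lambda: {"lncRNA": 6.0})
    # tiny single-exon RNA genes are poor hosts: one block saturates them
    exclude_host_biotypes: tuple[str, ...] = ("miRNA", "snRNA")
    # biotypes planted densely (multiple blocks, high per-gene density);
    # other hosts get a single block and must be long enough that one block
    # keeps their density moderate, giving the planted biotype gradient
    dense_biotypes: tuple[str, ...] = ("lncRNA",)
    dense_target_density: float = 0.45
    max_blocks_per_host: int = 4
    sparse_min_span_blocks: int = 5
    constraint_quantiles: tuple[float, float] = (0.001, 0.04)
    conservation_quantiles: tuple[float, float] = (0.02, 0.20)
    control_conservation_quantiles: tuple[float, float] = (0.96, 0.995)


@dataclass
class ScoreSpec:
    correlation: float = 0.5
    # fractions of background bins left unscored, mirroring the real tracks'
    # coverage gaps (constraint map gaps are much larger than alignment gaps)
    missing_constraint: float = 0.16
    missing_conservation: float = 0.00218


@dataclass
class IRCohortSpec:
    n_samples: int = 600
    baseline_ratio: float = 0.3      # expected usage ratio at dosage 0
    dosage_effect: float = 0.1       # planted slope of the ratio per e4 allele
    braak_effect: float = 0.04       # ratio shift per Braak stage step
    noise_sd: float = 0.05           # latent per-sample ratio noise
    e4_freq: float = 0.2
    n_batches: int = 8
    batch_sd: float = 0.02
    outlier_batch: int | None = None
    outlier_shift: float = 0.15
    batch_dosage_confounded: bool = False
    depth_mean: float = 50.0
    depth_sigma: float = 0.3         # lognormal sigma of per-sample depth
    junction_rate: float = 2.0       # junction reads per depth unit
    novel_junction_rate: float = 0.02


@dataclass
class SimConfig:
    seed: int
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    blocks: BlockSpec = field(default_factory=BlockSpec)
    scores: ScoreSpec = field(default_factory=ScoreSpec)
    ir: IRCohortSpec = field(default_factory=IRCohortSpec)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.blocks.block_len % self.layout.bin_width != 0:
            raise ValueError("block_len must be a multiple of the bin width")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SimConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            cfg["seed"] = seed
        return cls(seed=cfg["seed"],
                   layout=LayoutSpec(**cfg.get("layout", {})),
                   genes=GeneSpec(**cfg.get("genes", {})),
                   blocks=BlockSpec(**cfg.get("blocks", {})),
                   scores=ScoreSpec(**cfg.get("scores", {})),
                   ir=IRCohortSpec(**cfg.get("ir", {})))


@dataclass
class SimTruth:
    """Ground-truth ledger emitted with every fixture."""

    cncr_blocks: pd.DataFrame
    control_blocks: pd.DataFrame
    gene_density: pd.DataFrame          # gene_id, expected_density, is_neuro
    neuro_genes: tuple[str, ...]
    ir_samples: pd.DataFrame | None = None
    coefficients: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# layout + genes
# ---------------------------------------------------------------------------

def simulate_layout_and_genes(config: SimConfig) -> tuple[GenomeLayout, list[GeneModel]]:
    """Generate the layout and non-overlapping genes with mixed biotypes."""
    spec = config.layout
    layout = GenomeLayout.from_lengths(
        {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)})
    rng = _rng(config.seed, "genes")
    gspec = config.genes
    biotypes = sorted(gspec.biotype_probs)
    probs = np.array([gspec.biotype_probs[b] for b in biotypes], dtype=float)
    probs = probs / probs.sum()
    cursors = {c: 0 for c in layout.chrom_names}
    genes: list[GeneModel] = []
    chrom_cycle = list(layout.chrom_names)
    for i in range(gspec.n_genes):
        biotype = str(rng.choice(biotypes, p=probs))
        strand = str(rng.choice(["+", "-"]))
        if biotype in gspec.small_biotypes:
            exon_lens = [int(rng.integers(*gspec.small_gene_len))]
            intron_lens: list[int] = []
        else:
            n_exons = int(rng.integers(gspec.exon_count[0], gspec.exon_count[1] + 1))
            exon_lens = [int(rng.integers(gspec.exon_len[0], gspec.exon_len[1] + 1))
                         for _ in range(n_exons)]
            intron_lens = [int(rng.integers(gspec.intron_len[0], gspec.intron_len[1] + 1))
                           for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        gap = int(rng.integers(gspec.gap_len[0], gspec.gap_len[1] + 1))
        chrom = None
        for cand in sorted(chrom_cycle, key=lambda c: cursors[c]):
            if cursors[cand] + gap + span <= layout.length(cand):
                chrom = cand
                break
        if chrom is None:
            raise ValueError(f"gene {i} cannot fit in the layout")
        start = cursors[chrom] + gap
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if j < len(intron_lens):
                pos += intron_lens[j]
        gid = f"G{i:04d}"
        transcripts = [(f"{gid}.t1", tuple(exons))]
        if biotype == "protein_coding" and len(exons) >= 4 and rng.random() < 0.4:
            skip = int(rng.integers(1, len(exons) - 1))
            alt = tuple(e for j, e in enumerate(exons) if j != skip)
            transcripts.append((f"{gid}.t2", alt))
        genes.append(GeneModel(gid, chrom, strand, start, pos, biotype,
                               tuple(transcripts)))
        cursors[chrom] = pos
    return layout, genes


def genes_to_gtf(genes: list[GeneModel]) -> str:
    """Serialise gene models as GTF (1-based inclusive coordinates)."""
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}")
        for tid, exons in g.transcripts:
            ts, te = exons[0][0], exons[-1][1]
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_biotype "{g.biotype}";'
            lines.append(f"{g.chrom}\tsim\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}")
            for s, e in exons:
                lines.append(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# score tracks with planted blocks
# ---------------------------------------------------------------------------

def _bin_aligned_positions(lo: int, hi: int, width: int) -> np.ndarray:
    """Bin-aligned starts s with lo <= s and s + 0 <= hi (caller adds length)."""
    first = -(-lo // width) * width
    if first > hi:
        return np.array([], dtype=np.int64)
    return np.arange(first, hi + 1, width, dtype=np.int64)


def _place_blocks(rng, layout, genes, spec: BlockSpec, width: int
                  ) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...]]:
    """Choose planted CNCR and control block intervals plus the neuro list."""
    blen = spec.block_len

    def host_eligible(g: GeneModel) -> bool:
        if g.biotype in spec.exclude_host_biotypes:
            return False
        if g.biotype in spec.dense_biotypes:
            return g.span_bp >= blen + 2 * width
        return g.span_bp >= spec.sparse_min_span_blocks * blen

    n_genic_wanted = int(round(spec.genic_fraction * spec.n_cncr_blocks))
    eligible = [g for g in genes if host_eligible(g)]
    if not eligible and n_genic_wanted > 0:
        raise ValueError("no genes large enough to host planted blocks")
    weights = np.array([spec.host_biotype_weights.get(g.biotype, 1.0)
                        for g in eligible])
    weights = weights / weights.sum() if len(eligible) else weights
    n_neuro = min(spec.n_neuro_genes, len(eligible))
    neuro_idx = (rng.choice(len(eligible), size=n_neuro, replace=False, p=weights)
                 if n_neuro else np.array([], dtype=int))
    neuro = tuple(sorted(eligible[i].gene_id for i in neuro_idx))
    neuro_set = set(neuro)
    neuro_hosts = [g for g in eligible if g.gene_id in neuro_set]
    other_hosts = [g for g in eligible if g.gene_id not in neuro_set]
    other_w = np.array([spec.host_biotype_weights.get(g.biotype, 1.0)
                        for g in other_hosts])
    other_w = other_w / other_w.sum() if len(other_hosts) else other_w

    gene_spans = pd.DataFrame({"chrom": [g.chrom for g in genes],
                               "start": [g.start for g in genes],
                               "end": [g.end for g in genes]})
    occupied: list[tuple[str, int, int]] = []

    def overlaps_occupied(chrom, s, e):
        return any(c == chrom and s < oe and os_ < e for c, os_, oe in occupied)

    def place_in_gene(g: GeneModel) -> tuple[str, int, int] | None:
        cand = _bin_aligned_positions(g.start, g.end - blen, width)
        if len(cand) == 0:
            return None
        for _ in range(20):
            s = int(rng.choice(cand))
            if not overlaps_occupied(g.chrom, s, s + blen):
                return g.chrom, s, s + blen
        return None

    def place_intergenic() -> tuple[str, int, int] | None:
        lengths = np.array([layout.length(c) for c in layout.chrom_names], dtype=float)
        for _ in range(200):
            chrom = str(rng.choice(list(layout.chrom_names), p=lengths / lengths.sum()))
            max_start = layout.length(chrom) - blen
            s = int(rng.integers(0, max_start // width + 1)) * width
            e = s + blen
            near_gene = ((gene_spans["chrom"] == chrom)
                         & (gene_spans["start"] < e + width)
                         & (gene_spans["end"] > s - width)).any()
            if not near_gene and not overlaps_occupied(chrom, s, e):
                return chrom, s, e
        return None

    planted = []
    n_genic = n_genic_wanted if eligible else 0
    attempts = 0
    while len(planted) < n_genic and (attempts := attempts + 1) < 50 * n_genic:
        if rng.random() < spec.neuro_host_prob or not other_hosts:
            host = neuro_hosts[int(rng.integers(len(neuro_hosts)))]
        else:
            host = other_hosts[int(rng.choice(len(other_hosts), p=other_w))]
        if host.biotype in spec.dense_biotypes:
            want = int(round(spec.dense_target_density * host.span_bp / blen))
            want = min(max(want, 1), spec.max_blocks_per_host)
        else:
            want = 1
        for _ in range(min(want, n_genic - len(planted))):
            block = place_in_gene(host)
            if block is None:
                break
            planted.append(block)
            occupied.append(block)
    while len(planted) < spec.n_cncr_blocks:
        block = place_intergenic()
        if block is None:
            raise ValueError("could not place a planted block; layout too crowded")
        planted.append(block)
        occupied.append(block)
    controls = []
    for _ in range(spec.n_control_blocks):
        block = place_intergenic()
        if block is None:
            raise ValueError("could not place a control block")
        controls.append(block)
        occupied.append(block)
    as_df = lambda rows: pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return as_df(planted), as_df(controls), neuro


def simulate_score_tracks(config: SimConfig, layout: GenomeLayout,
                          genes: list[GeneModel]
                          ) -> tuple[BaseTrack, BaseTrack, SimTruth]:
    """Generate the constraint and conservation tracks with planted truth."""
    width = config.layout.bin_width
    sspec, bspec = config.scores, config.blocks
    rng_s = _rng(config.seed, "scores")
    rng_b = _rng(config.seed, "blocks")
    planted, controls, neuro = _place_blocks(rng_b, layout, genes, bspec, width)

    cons_rows, cdts_rows = [], []
    rho = sspec.correlation
    for chrom in layout.chrom_names:
        starts, ends = layout.bin_edges(chrom, width)
        n = len(starts)
        z1 = rng_s.standard_normal(n)
        # constrained (low cdts) bins tend to be conserved (high cons)
        z2 = -rho * z1 + np.sqrt(1.0 - rho ** 2) * rng_s.standard_normal(n)
        cdts = 2.0 * z1                    # CDTS-like: lower = more constrained
        cons = ndtr(z2)                    # uniform marginal on [0, 1]
        protected = np.zeros(n, dtype=bool)
        for df, cons_q in ((planted, bspec.conservation_quantiles),
                           (controls, bspec.control_conservation_quantiles)):
            sub = df.loc[df["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                sel = slice(s // width, e // width)
                k = e // width - s // width
                qc = rng_b.uniform(*bspec.constraint_quantiles, size=k)
                cdts[sel] = 2.0 * norm.ppf(qc)
                cons[sel] = rng_b.uniform(*cons_q, size=k)
                protected[sel] = True
        miss_c = (rng_s.random(n) < sspec.missing_constraint) & ~protected
        miss_n = (rng_s.random(n) < sspec.missing_conservation) & ~protected
        keep_c, keep_n = ~miss_c, ~miss_n
        cdts_rows.append(pd.DataFrame({"chrom": chrom, "start": starts[keep_c],
                                       "end": ends[keep_c], "value": cdts[keep_c]}))
        cons_rows.append(pd.DataFrame({"chrom": chrom, "start": starts[keep_n],
                                       "end": ends[keep_n], "value": cons[keep_n]}))

    constraint = BaseTrack(pd.concat(cdts_rows, ignore_index=True), layout)
    conservation = BaseTrack(pd.concat(cons_rows, ignore_index=True), layout)

    merged_planted = merge_intervals(planted, list(layout.chrom_names))
    gdf = pd.DataFrame({"chrom": [g.chrom for g in genes],
                        "start": [g.start for g in genes],
                        "end": [g.end for g in genes],
                        "gene_id": [g.gene_id for g in genes]})
    ov = overlap_bp(gdf, merged_planted, by="gene_id") if len(merged_planted) else None
    gene_density = pd.DataFrame({
        "gene_id": gdf["gene_id"],
        "expected_density": (ov.loc[gdf["gene_id"]].to_numpy() / (gdf["end"] - gdf["start"]).to_numpy()
                             if ov is not None else 0.0),
        "is_neuro": gdf["gene_id"].isin(neuro),
    })
    truth = SimTruth(merged_planted, merge_intervals(controls, list(layout.chrom_names)),
                     gene_density, neuro)
    return constraint, conservation, truth


# ---------------------------------------------------------------------------
# feature tracks + SNPs
# ---------------------------------------------------------------------------

FEATURE_PRIORITY = ("coding_exon", "promoter", "enhancer", "ncRNA_exon", "intron")


def simulate_feature_tracks(config: SimConfig, layout: GenomeLayout,
                            genes: list[GeneModel], truth: SimTruth
                            ) -> dict[str, pd.DataFrame]:
    """Feature interval sets derived from the gene models plus enhancers
    covering every planted block (so high-CNC territory is regulatory)."""
    rng = _rng(config.seed, "features")
    coding, ncrna, introns, promoters = [], [], [], []
    for g in genes:
        exon_union = merge_intervals(pd.DataFrame(
            {"chrom": g.chrom,
             "start": [s for _, exs in g.transcripts for s, _ in exs],
             "end": [e for _, exs in g.transcripts for _, e in exs]}))
        target = coding if g.biotype == "protein_coding" else ncrna
        target.append(exon_union)
        prev = g.start
        for _, row in exon_union.iterrows():
            if row["start"] > prev:
                introns.append((g.chrom, prev, row["start"]))
            prev = row["end"]
        if prev < g.end:
            introns.append((g.chrom, prev, g.end))
        if g.strand == "+":
            promoters.append((g.chrom, max(0, g.start - 500), g.start))
        else:
            promoters.append((g.chrom, g.end, min(layout.length(g.chrom), g.end + 500)))
    enhancers = [(r["chrom"], max(0, r["start"] - 100),
                  min(layout.length(r["chrom"]), r["end"] + 100))
                 for _, r in truth.cncr_blocks.iterrows()]
    for _ in range(30):  # additional background enhancers
        chrom = str(rng.choice(list(layout.chrom_names)))
        s = int(rng.integers(0, layout.length(chrom) - 500))
        enhancers.append((chrom, s, s + 500))
    cols = ["chrom", "start", "end"]
    out = {
        "coding_exon": merge_intervals(pd.concat(coding, ignore_index=True)
                                       if coding else pd.DataFrame(columns=cols)),
        "ncRNA_exon": merge_intervals(pd.concat(ncrna, ignore_index=True)
                                      if ncrna else pd.DataFrame(columns=cols)),
        "intron": merge_intervals(pd.DataFrame(introns, columns=cols)),
        "promoter": merge_intervals(pd.DataFrame(promoters, columns=cols)),
        "enhancer": merge_intervals(pd.DataFrame(enhancers, columns=cols)),
    }
    return out


def simulate_snp_table(config: SimConfig, layout: GenomeLayout,
                       n_snps: int = 2000) -> pd.DataFrame:
    """Random SNP positions (1-based), sorted per chromosome."""
    rng = _rng(config.seed, "snps")
    rows = []
    lengths = np.array([layout.length(c) for c in layout.chrom_names], dtype=float)
    counts = rng.multinomial(n_snps, lengths / lengths.sum())
    rsid = 1
    for chrom, k in zip(layout.chrom_names, counts):
        pos = np.sort(rng.choice(layout.length(chrom), size=k, replace=False)) + 1
        for p in pos:
            rows.append((chrom, int(p), f"rs{rsid}"))
            rsid += 1
    return pd.DataFrame(rows, columns=["chrom", "pos", "rsid"])


# ---------------------------------------------------------------------------
# intron-retention cohort
# ---------------------------------------------------------------------------

#: exon/intron geometry of the simulated gene (bp); intron 3 is the target
IR_EXON_LENS = (150, 120, 180, 200, 160, 190)
IR_INTRON_LENS = (400, 350, 600, 300, 250)
IR_GENE_OFFSET = 1000
IR_CHROM = "chr1"


def _ir_gene_model() -> GeneModelIR:
    exons = []
    pos = IR_GENE_OFFSET
    for i, el in enumerate(IR_EXON_LENS):
        exons.append((pos, pos + el))
        pos += el
        if i < len(IR_INTRON_LENS):
            pos += IR_INTRON_LENS[i]
    return GeneModelIR.from_exons("IRGENE", IR_CHROM, exons, intron_index=3)


def expected_ratio(rho, exon_bp: float, intron_bp: float, span_bp: float,
                   n_junctions: int):
    """Expected coverage-to-junction usage ratio for retention fraction rho.

    With a fraction rho of transcripts retaining the intron: exons carry
    depth d, the target intron rho*d, the target junction (1-rho) of the
    per-junction rate and every other junction the full rate. Then
    cov_fraction = rho*span/(exon_bp + rho*intron_bp) and
    junc_fraction = (1-rho)/(J-rho).
    """
    rho = np.asarray(rho, dtype=float)
    cov = rho * span_bp / (exon_bp + rho * intron_bp)
    junc = (1.0 - rho) / (n_junctions - rho)
    return cov / junc


def invert_ratio(u, exon_bp: float, intron_bp: float, span_bp: float,
                 n_junctions: int):
    """Retention fraction rho in (0, 1) whose expected ratio is u.

    The measurement map is a ratio of quadratics in rho; inversion solves
    (span - u*intron)rho^2 + (u(intron - exon) - J*span)rho + u*exon = 0
    and takes the root in (0, 1).
    """
    u = np.asarray(u, dtype=float)
    a = span_bp - u * intron_bp
    b = u * (intron_bp - exon_bp) - n_junctions * span_bp
    c = u * exon_bp
    disc = b * b - 4.0 * a * c
    if (disc < 0).any():
        raise ValueError("usage ratio outside the invertible range")
    rho = (-b - np.sqrt(disc)) / (2.0 * a)
    if ((rho <= 0) | (rho >= 1)).any():
        raise ValueError("inverted retention fraction outside (0, 1)")
    return rho


@dataclass
class IRCohort:
    model: GeneModelIR
    signals: list[SampleSignal]
    metadata: pd.DataFrame
    truth: pd.DataFrame          # sample_id, dosage, target_ratio, rho
    coefficients: dict


_ROMAN_STAGES = ("I", "II", "III", "IV", "V", "VI")


def simulate_ir_cohort(config: SimConfig) -> IRCohort:
    """Cohort of coverage/junction signals with a planted dosage effect.

    Each sample's target usage ratio is baseline + dosage effect x e4 dosage
    + Braak effect + batch shift + Gaussian noise; the matching retention
    fraction is obtained by inverting the deterministic measurement map, and
    Poisson counting noise is applied to region coverages and junction reads.
    """
    spec = config.ir
    rng = _rng(config.seed, "ir")
    model = _ir_gene_model()
    n = spec.n_samples
    exon_bp = float(sum(IR_EXON_LENS))
    intron_bp = float(model.intron_bp)
    span_bp = float(model.span_bp)
    J = len(model.junctions)

    batch = rng.integers(1, spec.n_batches + 1, size=n)
    p = spec.e4_freq
    geno_p = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    if spec.batch_dosage_confounded:
        # high batches carry a higher e4 frequency (spurious marginal signal)
        hi = batch > spec.n_batches // 2
        p_hi = min(2 * p, 0.45)
        dosage = np.where(
            hi,
            rng.choice(3, size=n, p=[(1 - p_hi) ** 2, 2 * p_hi * (1 - p_hi), p_hi ** 2]),
            rng.choice(3, size=n, p=geno_p))
    else:
        dosage = rng.choice(3, size=n, p=geno_p)

    braak_num = rng.choice(np.arange(1, 7), size=n,
                           p=[0.15, 0.15, 0.2, 0.2, 0.15, 0.15])
    cerad = rng.choice(np.arange(0, 4), size=n, p=[0.25, 0.25, 0.25, 0.25])
    diagnosis = np.where(braak_num >= 5, "AD",
                         np.where(braak_num >= 3, "MCI", "control"))
    rin = np.clip(rng.normal(7.0, 1.0, size=n), 4.5, 10.0)
    pmi = np.clip(rng.normal(12.0, 4.0, size=n), 2.0, 30.0)
    age = np.clip(rng.normal(85.0, 6.0, size=n), 65.0, 105.0)
    sex = rng.choice(["F", "M"], size=n)
    study = rng.choice(["ROS", "MAP"], size=n)

    batch_shift = rng.normal(0.0, spec.batch_sd, size=spec.n_batches)
    if spec.outlier_batch is not None:
        batch_shift[spec.outlier_batch - 1] += spec.outlier_shift

    u = (spec.baseline_ratio + spec.dosage_effect * dosage
         + spec.braak_effect * (braak_num - 1)
         + batch_shift[batch - 1] + rng.normal(0.0, spec.noise_sd, size=n))
    u_lo, u_hi = 0.02, 4.0
    if ((u < u_lo) | (u > u_hi)).any():
        warnings.warn("target usage ratio clamped for some samples", stacklevel=2)
        u = np.clip(u, u_lo, u_hi)
    rho = invert_ratio(u, exon_bp, intron_bp, span_bp, J)
    depth = spec.depth_mean * np.exp(
        rng.normal(-0.5 * spec.depth_sigma ** 2, spec.depth_sigma, size=n))

    novel_key = (model.exons[2][1], model.exons[4][0])  # exon3 -> exon5 skip
    signals = []
    for i in range(n):
        sid = f"S{i:04d}"
        rows = []
        for s, e in model.exons:
            length = e - s
            val = rng.poisson(depth[i] * length) / length
            rows.append((model.chrom, s, e, val))
        ts, te = model.target_intron
        ival = rng.poisson(rho[i] * depth[i] * intron_bp) / intron_bp
        rows.append((model.chrom, ts, te, ival))
        coverage = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        coverage = coverage.sort_values("start").reset_index(drop=True)
        jrate = spec.junction_rate * depth[i]
        counts = {}
        for j in model.junctions:
            lam = jrate * (1.0 - rho[i]) if j == model.target_intron else jrate
            counts[j] = int(rng.poisson(lam))
        counts[novel_key] = int(rng.poisson(jrate * spec.novel_junction_rate))
        meta = {"dosage": int(dosage[i]), "batch": int(batch[i]),
                "braak": _ROMAN_STAGES[braak_num[i] - 1], "cerad": int(cerad[i]),
                "diagnosis": str(diagnosis[i]), "rin": float(rin[i]),
                "pmi": float(pmi[i]), "age_death": float(age[i]),
                "sex": str(sex[i]), "study": str(study[i])}
        signals.append(SampleSignal(sid, coverage, counts, meta))
    metadata = pd.DataFrame([{"sample_id": s.sample_id, **s.metadata}
                             for s in signals])
    truth = pd.DataFrame({"sample_id": [s.sample_id for s in signals],
                          "dosage": dosage, "target_ratio": u, "rho": rho})
    coefficients = {"baseline_ratio": spec.baseline_ratio,
                    "dosage_effect": spec.dosage_effect,
                    "braak_effect": spec.braak_effect,
                    "noise_sd": spec.noise_sd}
    return IRCohort(model, signals, metadata, truth, coefficients)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(config: SimConfig, out_dir, overwrite: bool = False) -> dict:
    """Emit every format the pipeline reads, plus a JSON manifest with the
    seed and planted truths. Re-running with the same config is
    byte-identical."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True")
    (out / "features").mkdir(parents=True, exist_ok=True)
    (out / "ir" / "coverage").mkdir(parents=True, exist_ok=True)
    (out / "ir" / "junctions").mkdir(parents=True, exist_ok=True)

    layout, genes = simulate_layout_and_genes(config)
    constraint, conservation, truth = simulate_score_tracks(config, layout, genes)
    feats = simulate_feature_tracks(config, layout, genes, truth)
    snps = simulate_snp_table(config, layout)
    cohort = simulate_ir_cohort(config)

    files = []

    def record(relpath):
        files.append(str(relpath))
        return out / relpath

    with open(record("chrom_sizes.tsv"), "w") as fh:
        for c in layout.chrom_names:
            fh.write(f"{c}\t{layout.length(c)}\n")
    record("genes.gtf").write_text(genes_to_gtf(genes))
    constraint.intervals.to_csv(record("constraint.bedgraph"), sep="\t",
                                header=False, index=False, float_format="%.6g")
    conservation.intervals.to_csv(record("conservation.bedgraph"), sep="\t",
                                  header=False, index=False, float_format="%.6g")
    for label in FEATURE_PRIORITY:
        feats[label].to_csv(record(Path("features") / f"{label}.bed"), sep="\t",
                            header=False, index=False)
    with open(record("features.yaml"), "w") as fh:
        yaml.safe_dump({"features": [{"label": lab, "bed": f"features/{lab}.bed"}
                                     for lab in FEATURE_PRIORITY],
                        "catch_all": "intergenic"}, fh, sort_keys=False)
    snps.to_csv(record("snps.tsv"), sep="\t", index=False)

    cohort.metadata.to_csv(record(Path("ir") / "metadata.tsv"), sep="\t",
                           index=False, float_format="%.6g")
    for sig in cohort.signals:
        sig.coverage.to_csv(record(Path("ir") / "coverage" / f"{sig.sample_id}.bedgraph"),
                            sep="\t", header=False, index=False, float_format="%.6g")
        with open(record(Path("ir") / "junctions" / f"{sig.sample_id}.sj.tab"), "w") as fh:
            annotated = set(cohort.model.junctions)
            for (donor, acceptor), count in sorted(sig.junction_counts.items()):
                flag = 1 if (donor, acceptor) in annotated else 0
                fh.write(f"{cohort.model.chrom}\t{donor + 1}\t{acceptor}\t1\t0\t"
                         f"{flag}\t{count}\t0\t50\n")
    with open(record(Path("ir") / "gene_model.json"), "w") as fh:
        json.dump({"gene_id": cohort.model.gene_id, "chrom": cohort.model.chrom,
                   "exons": [list(e) for e in cohort.model.exons],
                   "intron_index": 3}, fh, sort_keys=True, indent=1)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "files": sorted(files),
        "truth": {
            "cncr_blocks": truth.cncr_blocks.to_dict(orient="records"),
            "control_blocks": truth.control_blocks.to_dict(orient="records"),
            "gene_density": truth.gene_density.to_dict(orient="records"),
            "neuro_genes": list(truth.neuro_genes),
            "ir_coefficients": cohort.coefficients,
            "ir_samples": cohort.truth.to_dict(orient="records"),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
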