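import numpy as np
import pandas as pd
import pytest

from cncr.annotation import annotate, score_bins
from cncr.simulate import (
    BlockSpec,
    GeneSpec,
    IRCohortSpec,
    LayoutSpec,
    SimConfig,
    simulate_ir_cohort,
    simulate_layout_and_genes,
    simulate_score_tracks,
)
from cncr.tracks import GenomeLayout, bin_track, join_tracks


def small_sim_config(seed: int = 7) -> SimConfig:
    """Desk-sized study conditions reused across the suite."""
    return SimConfig(
        seed=seed,
        layout=LayoutSpec(n_chroms=2, chrom_length=120_000),
        genes=GeneSpec(n_genes=40),
        blocks=BlockSpec(n_cncr_blocks=12, n_control_blocks=6, n_neuro_genes=8),
        ir=IRCohortSpec(n_samples=40),
    )


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_world(small_config):
    """(layout, genes, constraint track, conservation track, truth)."""
    layout, genes = simulate_layout_and_genes(small_config)
    constraint, conservation, truth = simulate_score_tracks(small_config, layout, genes)
    return layout, genes, constraint, conservation, truth


@pytest.fixture(scope="session")
def small_annotated(small_world):
    """Scored+called bin table and AnnotationSet for the small world."""
    layout, genes, constraint, conservation, truth = small_world
    joined, _ = join_tracks(bin_track(constraint), bin_track(conservation))
    scored, ann = annotate(score_bins(joined), layout, nonconserved_rank="derive")
    return layout, genes, truth, scored, ann


@pytest.fixture(scope="session")
def full_annotated():
    """Default-scale study conditions (seed 1) for recovery checks."""
    cfg = SimConfig(seed=1)
    layout, genes = simulate_layout_and_genes(cfg)
    constraint, conservation, truth = simulate_score_tracks(cfg, layout, genes)
    joined, _ = join_tracks(bin_track(constraint), bin_track(conservation))
    scored, ann = annotate(score_bins(joined), layout, nonconserved_rank="derive")
    return cfg, layout, genes, truth, scored, ann


@pytest.fixture(scope="session")
def ir_cohort_600():
    """Full-size intron-retention cohort with the planted dosage effect."""
    return simulate_ir_cohort(SimConfig(seed=11))


def toy_layout(**lengths) -> GenomeLayout:
    return GenomeLayout.from_lengths(lengths or {"chr1": 100})


def bins_frame(n: int, rng: np.random.Generator, width: int = 10,
               chroms: tuple[str, ...] = ("chr1",)) -> pd.DataFrame:
    """Random joined-bin table tiling `n` bins across the given chromosomes."""
    per = -(-n // len(chroms))
    rows = []
    left = n
    for chrom in chroms:
        k = min(per, left)
        starts = np.arange(k) * width
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": starts + width,
                                  "cdts": rng.normal(size=k),
                                  "cons": rng.random(size=k)}))
        left -= k
    return pd.concat(rows, ignore_index=True)
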