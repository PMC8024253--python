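# cncr

Annotation of **constrained, non-conserved regions (CNCRs)** of a genome and
the analyses built on them: feature composition across CNC-score deciles,
per-gene CNCR density with biotype trends and gene-list comparisons, LDSC
thin-annot export, and quantification of intron-retaining transcript usage
from RNA-seq coverage and splice-junction counts.

## The problem and the score

Cross-species conservation alone cannot identify genomic elements under
*human-lineage-specific* purifying selection: such elements are depleted of
variation **within** humans (constrained) while being poorly conserved
**across** species. Given an intra-species constraint track (CDTS-like;
lower = more constrained) and a conservation track (phastCons-like,
probability in [0, 1]), both summarised into non-overlapping 10-bp bins and
ranked genome-wide so the highest rank marks the most constrained / most
conserved bin, each bin's **CNC score** is

```
CNC = log2( rank_constraint / rank_conservation )
```

A distribution centred at 0 means no fold change between the two rankings;
CNC = 1 means a twofold higher ranking in constraint than in conservation.
Three annotation categories follow:

| category | definition |
|---|---|
| constrained | top 12.5% of the constraint ranking |
| **CNCR** | constrained **and** CNC &ge; 1 (adjacent bins merged) |
| non-conserved | conservation rank &le; a rank threshold (on GRCh38 with the published tracks, rank &le; 25,623,592), irrespective of constraint |

Downstream, **CNCR density** of a gene is the fraction of its span
(transcription start to stop) covered by CNCRs, and **intron-retention
usage** of a designated intron is the ratio of its coverage fraction
(mean intron coverage / mean gene coverage) to its junction fraction
(spliced-out junction reads / all annotated junction reads) — a
depth-invariant estimate of the retaining transcript's proportional use.

## Worked example

Everything runs on synthetic data with planted ground truth; no external
downloads are needed. `examples/` holds one narrative script per capability:

```bash
python examples/01_build_cncr_annotation.py
```

```
151,902 of 180,000 bins carry both scores (15.4% lack constraint, 0.21% lack conservation)
constrained bins (top 12.5% constraint): 18,987
CNCR bins (constrained AND CNC >= 1):    5,468 -> 1,897 merged intervals
non-conserved intervals (derived rank threshold): 23,143
planted CNCR territory: 36,000 bp across 60 blocks (all expected to be recovered)
```

The bins lacking a score mirror the coverage gaps of the real input maps and
are dropped before ranking; the 18,987 constrained bins are exactly
floor(0.125 × 151,902); the planted blocks (extreme constraint, bottom-quartile
conservation) are all recovered as CNCRs while constrained-*and*-conserved
control blocks never are.

```bash
python examples/04_intron_retention.py
```

```
quantified 600 samples (0 excluded); mean usage ratio 0.441
Kruskal-Wallis across merged Braak stages: H = 144.6, p = 4.05e-32
e4 dosage slope: 0.1091 (planted 0.1), p = 5.2e-77, adjusted r2 = 0.611
```

The covariate-adjusted linear model recovers the planted 0.1-per-allele
dosage effect on the usage ratio; usage rises across merged Braak stages
(mild / moderate / severe) because a pathology effect is planted as well.
`examples/02_feature_composition.py` and `examples/03_gene_density.py` show
the decile composition (with fold enrichment and Yates chi-squared between
the extreme deciles) and the gene-density workflow (ranked genes, biotype
trend slopes with BH-FDR, rank-sum list comparison).

A thin CLI mirrors the library:
`cncr simulate | score | call | compose | gene-density | export-annot | ir`.

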