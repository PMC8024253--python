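"""Genomic score tracks: reading, fixed-width binning, joining, masking.

The annotation pipeline consumes two per-base (or per-window) score tracks —
an intra-species constraint score (CDTS-like, lower = more constrained) and a
cross-species conservation probability (phastCons-like, in [0, 1]) — supplied
as 4-column bedGraph. Both are summarised into non-overlapping fixed-width
bins (10 bp by default) by a coverage-weighted mean over covered bases, and
then joined so that only bins carrying both scores are scored downstream.

Coordinates are 0-based half-open everywhere in memory; GTF input (1-based
inclusive) is converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from ._intervals import empty_intervals, flag_overlaps, sort_intervals

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 10


class BedGraphParseError(ValueError):
    """Malformed bedGraph record; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path, self.lineno = path, lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp) of the working assembly."""

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if set(self.chrom_names) != set(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths disagree")
        for c, length in self.chrom_lengths.items():
            if int(length) <= 0:
                raise ValueError(f"non-positive length for {c}")

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    @property
    def order(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chrom_names)}

    def length(self, chrom: str) -> int:
        return int(self.chrom_lengths[chrom])

    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def n_bins(self, chrom: str, width: int) -> int:
        return -(-self.length(chrom) // width)  # ceil: truncated terminal bin

    def bin_edges(self, chrom: str, width: int) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_bins(chrom, width)
        starts = np.arange(n, dtype=np.int64) * width
        ends = np.minimum(starts + width, self.length(chrom))
        return starts, ends


def read_chrom_sizes(path) -> GenomeLayout:
    """Two-column TSV of chromosome name and length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    return GenomeLayout.from_lengths(dict(zip(df["chrom"], df["length"].astype(int))))


@dataclass
class BaseTrack:
    """Raw score intervals (0-based half-open), non-overlapping per chromosome."""

    intervals: pd.DataFrame  # chrom, start, end, value
    layout: GenomeLayout

    def __post_init__(self):
        df = self.intervals
        required = ["chrom", "start", "end", "value"]
        if list(df.columns[:4]) != required:
            df = df[required]
        df = sort_intervals(df, list(self.layout.chrom_names))
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals with start >= end")
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["end"].to_numpy() > self.layout.length(str(chrom))).any():
                raise ValueError(f"interval beyond end of {chrom}")
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
        if len(df) and df["start"].min() < 0:
            raise ValueError("negative start coordinate")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class BinnedTrack:
    """Fixed-width tiling of the genome; missing bins carry NaN.

    Bins tile each chromosome from position 0; the terminal bin of a
    chromosome whose length is not a multiple of the width is truncated and
    remains eligible for scoring.
    """

    layout: GenomeLayout
    width: int
    values: dict[str, np.ndarray] = field(repr=False)  # chrom -> per-bin float

    def __post_init__(self):
        for chrom in self.layout.chrom_names:
            n = self.layout.n_bins(chrom, self.width)
            if chrom not in self.values or len(self.values[chrom]) != n:
                raise ValueError(f"bin values for {chrom} do not tile the chromosome")

    def n_bins(self) -> int:
        return sum(self.layout.n_bins(c, self.width) for c in self.layout.chrom_names)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom in self.layout.chrom_names:
            starts, ends = self.layout.bin_edges(chrom, self.width)
            parts.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": ends, "value": self.values[chrom]}))
        return pd.concat(parts, ignore_index=True)


@dataclass
class MaskSet:
    """Interval blacklist (e.g. an ENCODE-style list of problematic regions)."""

    intervals: pd.DataFrame
    label: str = "blacklist"

    def __post_init__(self):
        if len(self.intervals) and (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("mask intervals with start >= end")


@dataclass(frozen=True)
class GeneModel:
    """A gene with span over all its transcripts, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty span")
        for tid, exons in self.transcripts:
            prev_end = None
            for s, e in exons:
                if s < self.start or e > self.end:
                    raise ValueError(f"{self.gene_id}/{tid}: exon outside gene span")
                if prev_end is not None and s < prev_end:
                    raise ValueError(f"{self.gene_id}/{tid}: overlapping/unsorted exons")
                prev_end = e

    @property
    def span_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bedgraph(path, layout: GenomeLayout) -> BaseTrack:
    """Read a 4-column bedGraph into a validated :class:`BaseTrack`.

    Lines beginning with ``track``, ``browser`` or ``#`` are skipped. A
    malformed record raises :class:`BedGraphParseError` naming the line;
    records on chromosomes absent from the layout, or out of bounds, are
    rejected.
    """
    chroms, starts, ends, values = [], [], [], []
    known = set(layout.chrom_names)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise BedGraphParseError(path, lineno, f"expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            if chrom not in known:
                raise BedGraphParseError(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as err:
                raise BedGraphParseError(path, lineno, str(err)) from None
            if s < 0 or e > layout.length(chrom) or s >= e:
                raise BedGraphParseError(
                    path, lineno, f"interval [{s},{e}) out of bounds for {chrom}")
            chroms.append(chrom); starts.append(s); ends.append(e); values.append(v)
    df = pd.DataFrame({"chrom": pd.Series(chroms, dtype=str),
                       "start": pd.Series(starts, dtype=np.int64),
                       "end": pd.Series(ends, dtype=np.int64),
                       "value": pd.Series(values, dtype=float)})
    return BaseTrack(df, layout)


def read_gtf(path) -> list[GeneModel]:
    """Parse a GTF into gene models, converting to 0-based half-open.

    The gene span is the min/max over all of the gene's transcript
    coordinates (falling back to the gene record when a gene has no
    transcripts); biotype is taken from the ``gene_biotype`` or ``gene_type``
    attribute. Missing ``gene_id`` or exons outside the gene span are errors.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                                disable_infer_genes=True, disable_infer_transcripts=True,
                                verbose=False)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if "gene_id" not in g.attributes or not g.attributes["gene_id"][0]:
            raise ValueError(f"gene record at {g.seqid}:{g.start} lacks gene_id")
        gid = g.attributes["gene_id"][0]
        biotype = (g.attributes.get("gene_biotype") or g.attributes.get("gene_type")
                   or ["unspecified"])[0]
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            tid = t.attributes["transcript_id"][0]
            exons = tuple(sorted((e.start - 1, e.end)
                                 for e in db.children(t, featuretype="exon")))
            transcripts.append((tid, exons))
        if transcripts:
            start = min(t.start - 1 for t in db.children(g, featuretype="transcript"))
            end = max(t.end for t in db.children(g, featuretype="transcript"))
        else:
            start, end = g.start - 1, g.end
        genes.append(GeneModel(gid, g.seqid, g.strand, start, end, biotype,
                               tuple(transcripts)))
    # records outside an explicit gene feature with no gene_id at all
    for f in db.all_features():
        if "gene_id" not in f.attributes or not f.attributes["gene_id"][0]:
            raise ValueError(f"{f.featuretype} record at {f.seqid}:{f.start} lacks gene_id")
    return genes


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    df = df.dropna(axis=1, how="all")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# binning / joining / masking
# ---------------------------------------------------------------------------

def bin_track(track: BaseTrack, width: int = DEFAULT_BIN_WIDTH,
              aggregator: str = "mean") -> BinnedTrack:
    """Summarise a raw track into fixed-width bins.

    The bin value is the coverage-weighted mean of the interval values over
    the bases each interval actually covers inside the bin; bins with zero
    covered bases are missing (NaN). This matches assigning a mean
    conservation score over only the aligned bases of a bin.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if aggregator != "mean":
        raise ValueError(f"unsupported aggregator {aggregator!r}")
    layout = track.layout
    values: dict[str, np.ndarray] = {}
    by_chrom = dict(tuple(track.intervals.groupby("chrom", sort=False)))
    for chrom in layout.chrom_names:
        L = layout.length(chrom)
        n = layout.n_bins(chrom, width)
        padded = n * width
        base = np.zeros(padded)
        covered = np.zeros(padded, dtype=bool)
        sub = by_chrom.get(chrom)
        if sub is not None:
            for s, e, v in zip(sub["start"].to_numpy(), sub["end"].to_numpy(),
                               sub["value"].to_numpy()):
                base[s:e] = v
                covered[s:e] = True
        vsum = np.where(covered, base, 0.0).reshape(n, width).sum(axis=1)
        cnt = covered.reshape(n, width).sum(axis=1)
        with np.errstate(invalid="ignore"):
            values[chrom] = np.where(cnt > 0, vsum / np.maximum(cnt, 1), np.nan)
    return BinnedTrack(layout, width, values)


@dataclass(frozen=True)
class JoinReport:
    """Accounting of bins dropped when requiring both scores."""

    n_bins: int
    n_missing_constraint: int
    n_missing_conservation: int
    n_missing_both: int

    @property
    def n_joined(self) -> int:
        return (self.n_bins - self.n_missing_constraint
                - self.n_missing_conservation + self.n_missing_both)

    @property
    def frac_missing_constraint(self) -> float:
        return self.n_missing_constraint / self.n_bins if self.n_bins else 0.0

    @property
    def frac_missing_conservation(self) -> float:
        return self.n_missing_conservation / self.n_bins if self.n_bins else 0.0


def join_tracks(constraint: BinnedTrack, conservation: BinnedTrack
                ) -> tuple[pd.DataFrame, JoinReport]:
    """Inner-join the two binned tracks on the shared bin grid.

    Bins missing either score are dropped, mirroring the exclusion of bins
    without a conservation score (insufficient species in the alignment) and
    of bins without a constraint score. Returns the joined table
    (chrom, start, end, cdts, cons) and a :class:`JoinReport`.
    """
    if constraint.layout != conservation.layout or constraint.width != conservation.width:
        raise ValueError("mismatched bin grids (layout or width differ)")
    layout, width = constraint.layout, constraint.width
    parts = []
    n_bins = n_c = n_n = n_both = 0
    for chrom in layout.chrom_names:
        a = constraint.values[chrom]
        b = conservation.values[chrom]
        ma, mb = np.isnan(a), np.isnan(b)
        n_bins += len(a)
        n_c += int(ma.sum()); n_n += int(mb.sum()); n_both += int((ma & mb).sum())
        keep = ~(ma | mb)
        if keep.any():
            starts, ends = layout.bin_edges(chrom, width)
            parts.append(pd.DataFrame({
                "chrom": chrom, "start": starts[keep], "end": ends[keep],
                "cdts": a[keep], "cons": b[keep]}))
    report = JoinReport(n_bins, n_c, n_n, n_both)
    if parts:
        joined = pd.concat(parts, ignore_index=True)
    else:
        joined = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64),
                               "cdts": pd.Series(dtype=float),
                               "cons": pd.Series(dtype=float)})
        warnings.warn("join_tracks produced no bins: every bin misses a score",
                      stacklevel=2)
    log.info("join_tracks: %d/%d bins joined (%.2f%% missing constraint, "
             "%.2f%% missing conservation)", report.n_joined, report.n_bins,
             100 * report.frac_missing_constraint, 100 * report.frac_missing_conservation)
    return joined, report


def apply_mask(bins: pd.DataFrame, mask: MaskSet, drop: bool = False) -> pd.DataFrame:
    """Flag bins overlapping the mask by >=1 bp; optionally drop them."""
    out = bins.copy()
    out["masked"] = flag_overlaps(out, mask.intervals)
    n_flagged = int(out["masked"].sum())
    log.info("apply_mask[%s]: %d/%d bins flagged", mask.label, n_flagged, len(out))
    if drop:
        out = out.loc[~out["masked"]].drop(columns="masked").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path, layout: GenomeLayout | None = None) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start)."""
    order = list(layout.chrom_names) if layout is not None else None
    df = sort_intervals(intervals, order) if len(intervals) else intervals
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_table(records: pd.DataFrame, path) -> None:
    """TSV with header; floats written at full precision so tables round-trip."""
    records.to_csv(path, sep="\t", index=False)


def write_bedgraph(track: BaseTrack | pd.DataFrame, path) -> None:
    df = track.intervals if isinstance(track, BaseTrack) else track
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])
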