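"""Genomic-interval data model, BED I/O, interval algebra and consensus peaks.

All coordinates are 0-based half-open (BED dialect). Strand is carried but
ignored for peak arithmetic. The two non-trivial operations are
:func:`consensus_peaks` (maximal regions covered by at least *k* of *n*
experiments) and :func:`classify_cooccupancy` (two-factor overlap Venn), both
of which are checked against per-base brute-force oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A malformed BED line; the message names the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus optional summit offset and a score.

    ``summit`` is a bp offset within the interval (MACS convention); ``score``
    is whatever the caller emitted (signal or -log10 p), kept non-negative.
    """

    interval: GenomicInterval
    summit: int | None = None
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < self.interval.length):
            raise ValueError("summit must lie within [0, length)")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakSet:
    """Peaks from one ChIP experiment plus experiment metadata.

    ``meta`` carries at least ``factor``; optionally ``cell_line``,
    ``condition``, ``total_mapped_reads`` and ``spikein_reads``.
    """

    peaks: list[Peak] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.meta.get("factor"):
            raise ValueError("PeakSet.meta['factor'] must be non-empty")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def label(self) -> str:
        return str(
            self.meta.get("label")
            or self.meta.get("cell_line")
            or self.meta.get("factor")
        )

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)),
            dict(self.meta),
        )

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class OverlapClassification:
    """Two-factor co-occupancy partition (A-side counting convention)."""

    a_only: PeakSet
    b_only: PeakSet
    shared: PeakSet

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.a_only), len(self.b_only), len(self.shared))


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path, kind: str = "region", meta: dict | None = None):
    """Read a BED3/BED5+ file.

    ``kind="region"`` returns a list of :class:`GenomicInterval`;
    ``kind="peak"`` returns a :class:`PeakSet` (column 5 -> score when
    present, column 4 -> name). ``track``/``browser``/``#`` lines are
    tolerated. Malformed lines raise :class:`BedParseError` naming the line.
    """
    if kind not in ("region", "peak"):
        raise ValueError(f"unknown kind {kind!r}")
    intervals: list[GenomicInterval] = []
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
            if kind == "region":
                intervals.append(iv)
            else:
                name = fields[3] if len(fields) >= 4 else ""
                score = 0.0
                if len(fields) >= 5:
                    try:
                        score = float(fields[4])
                    except ValueError as exc:
                        raise BedParseError(
                            f"{path}: line {lineno}: non-numeric score"
                        ) from exc
                peaks.append(Peak(iv, score=max(score, 0.0), name=name))
    if kind == "region":
        return intervals
    return PeakSet(peaks, dict(meta or {"factor": "unknown"}))


def write_bed(items: Iterable, path) -> None:
    """Write intervals or peaks as BED3 / BED5 (name, score for peaks)."""
    with open(path, "w") as fh:
        for item in items:
            if isinstance(item, Peak):
                fh.write(
                    f"{item.chrom}\t{item.start}\t{item.end}\t"
                    f"{item.name or '.'}\t{item.score:.17g}\n"
                )
            else:
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``min_gap`` bp.

    Output is sorted and pairwise non-overlapping; touching intervals
    (gap 0) merge whenever ``min_gap >= 0``. Strand is dropped.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= min_gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def _depth_regions(
    merged_sets: Sequence[Sequence[GenomicInterval]], k: int
) -> list[GenomicInterval]:
    """Maximal regions where >= k of the (pre-merged) sets cover a base."""
    events: dict[str, list[tuple[int, int]]] = {}
    for ivs in merged_sets:
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        depth = 0
        region_start: int | None = None
        # ends before starts at the same position so depth drops first,
        # keeping half-open semantics
        for pos, delta in sorted(events[chrom], key=lambda e: (e[0], e[1])):
            new_depth = depth + delta
            if depth < k <= new_depth:
                region_start = pos
            elif new_depth < k <= depth and region_start is not None:
                if pos > region_start:
                    out.append(GenomicInterval(chrom, region_start, pos))
                region_start = None
            depth = new_depth
    # adjacent depth-k runs separated by zero-length transitions collapse
    return merge_intervals(out, 0)


def consensus_peaks(
    peaksets: Sequence[PeakSet], k: int, mode: str = "depth"
) -> PeakSet:
    """Consensus peaks supported by at least ``k`` of ``n`` experiments.

    Each input set is merged first so one experiment contributes depth <= 1
    anywhere. ``mode="depth"`` (default) returns the maximal depth->=k
    regions; ``mode="union"`` expands each to the union of the contributing
    native merged intervals. Every consensus peak records its supporting set
    labels in ``name`` and scores the mean of supporting peak scores.
    """
    n = len(peaksets)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds number of peak sets n={n}")
    if mode not in ("depth", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    factors = {ps.meta.get("factor") for ps in peaksets}
    if len(factors) > 1:
        warnings.warn(
            f"consensus over mixed factors {sorted(map(str, factors))}",
            stacklevel=2,
        )
    merged_sets = [merge_intervals(ps.intervals(), 0) for ps in peaksets]
    cores = _depth_regions(merged_sets, k)

    if mode == "union":
        expanded = []
        for core in cores:
            pieces = [core]
            for ivs in merged_sets:
                pieces.extend(iv for iv in ivs if iv.overlaps(core))
            expanded.extend(merge_intervals(pieces, 0))
        cores = merge_intervals(expanded, 0)

    out_peaks: list[Peak] = []
    for region in cores:
        support: list[str] = []
        scores: list[float] = []
        for ps, ivs in zip(peaksets, merged_sets):
            if any(iv.overlaps(region) for iv in ivs):
                support.append(ps.label)
                scores.extend(
                    p.score for p in ps.peaks if p.interval.overlaps(region)
                )
        score = sum(scores) / len(scores) if scores else 0.0
        out_peaks.append(Peak(region, score=score, name=",".join(support)))
    factor = peaksets[0].meta.get("factor", "unknown") if peaksets else "unknown"
    return PeakSet(
        out_peaks,
        {"factor": factor, "k": k, "n_sets": n, "mode": mode},
    )


def _overlap_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _max_overlap(peak: Peak, trees: dict[str, IntervalTree]) -> int:
    tree = trees.get(peak.chrom)
    if tree is None:
        return 0
    best = 0
    for hit in tree.overlap(peak.start, peak.end):
        best = max(best, min(peak.end, hit.end) - max(peak.start, hit.begin))
    return best


def classify_cooccupancy(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> OverlapClassification:
    """Partition peaks of A and B into shared / A-only / B-only.

    A peak of A is "shared" iff it overlaps at least one peak of B by
    >= ``min_overlap`` bp; the shared count is reported from the A side.
    ``b_only`` holds the B peaks overlapping no A peak.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_trees = _overlap_trees(b.peaks)
    a_trees = _overlap_trees(a.peaks)
    shared = [p for p in a.peaks if _max_overlap(p, b_trees) >= min_overlap]
    a_only = [p for p in a.peaks if _max_overlap(p, b_trees) < min_overlap]
    b_only = [p for p in b.peaks if _max_overlap(p, a_trees) < min_overlap]

    def _sub(peaks: list[Peak], src: PeakSet, tag: str) -> PeakSet:
        meta = dict(src.meta)
        meta["subset"] = tag
        return PeakSet(peaks, meta)

    return OverlapClassification(
        a_only=_sub(a_only, a, "a_only"),
        b_only=_sub(b_only, b, "b_only"),
        shared=_sub(shared, a, "shared"),
    )
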