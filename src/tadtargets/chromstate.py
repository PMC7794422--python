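"""Chromatin-state annotation of peaks and state-wise peak density.

Consumes a ChromHMM-style segmentation (BED4: chrom, start, end, state
label). A peak is assigned to the state with maximal bp overlap, ties broken
by the segmentation's state priority order; peak density per state is
normalized to the state's genomic footprint in Gb.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd

from .intervals import BedParseError, GenomicInterval, Peak, PeakSet

UNASSIGNED = "unassigned"


@dataclass
class StateSegmentation:
    """Non-overlapping labeled segments plus a state priority order."""

    segments: list[tuple[GenomicInterval, str]]
    state_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.state_order:
            seen: list[str] = []
            for _, label in self.segments:
                if label not in seen:
                    seen.append(label)
            self.state_order = seen
        missing = {lbl for _, lbl in self.segments} - set(self.state_order)
        if missing:
            raise ValueError(f"labels missing from state_order: {sorted(missing)}")
        self._validate_disjoint()
        self._index()

    def _validate_disjoint(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, _ in self.segments:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"{prev} and {cur}"
                    )

    def _index(self) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[tuple[GenomicInterval, str]]]] = {}
        for iv, label in sorted(self.segments, key=lambda s: (s[0].chrom, s[0].start)):
            starts, segs = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            segs.append((iv, label))

    def overlapping(self, iv: GenomicInterval) -> list[tuple[GenomicInterval, str]]:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, segs = entry
        i = bisect.bisect_right(starts, iv.start) - 1
        if i < 0:
            i = 0
        out = []
        while i < len(segs) and segs[i][0].start < iv.end:
            if segs[i][0].overlaps(iv):
                out.append(segs[i])
            i += 1
        return out

    def state_bp(self) -> dict[str, int]:
        footprint = {label: 0 for label in self.state_order}
        for iv, label in self.segments:
            footprint[label] += iv.length
        return footprint

    def rank(self, label: str) -> int:
        return self.state_order.index(label)


def read_segmentation(path, state_order: list[str] | None = None) -> StateSegmentation:
    """Read a BED4 segmentation; overlapping segments are rejected."""
    segments: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"{path}: line {lineno}: segmentation needs 4 columns"
                )
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
            segments.append((iv, fields[3]))
    return StateSegmentation(segments, state_order or [])


def write_segmentation(seg: StateSegmentation, path) -> None:
    with open(path, "w") as fh:
        for iv, label in sorted(seg.segments, key=lambda s: (s[0].chrom, s[0].start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def assign_peak_state(peak: Peak, seg: StateSegmentation) -> str:
    """State label with maximal bp overlap; ties by priority; else unassigned."""
    overlap_bp: dict[str, int] = {}
    for iv, label in seg.overlapping(peak.interval):
        overlap_bp[label] = overlap_bp.get(label, 0) + iv.overlap_bp(peak.interval)
    if not overlap_bp:
        return UNASSIGNED
    return max(overlap_bp, key=lambda lbl: (overlap_bp[lbl], -seg.rank(lbl)))


def peaks_per_gb(peaks: PeakSet, seg: StateSegmentation) -> pd.DataFrame:
    """Per-state peak counts and densities (peaks per Gb of state footprint).

    Returns a DataFrame with columns state, n_peaks, state_bp, peaks_per_gb;
    peaks overlapping no state are excluded from the rows but counted in
    ``df.attrs["n_unassigned"]``.
    """
    if not seg.segments:
        raise ValueError("segmentation is empty")
    counts = {label: 0 for label in seg.state_order}
    n_unassigned = 0
    for peak in peaks:
        label = assign_peak_state(peak, seg)
        if label == UNASSIGNED:
            n_unassigned += 1
        else:
            counts[label] += 1
    footprint = seg.state_bp()
    rows = []
    for label in seg.state_order:
        bp = footprint[label]
        if bp == 0:
            assert counts[label] == 0, "peaks assigned to a zero-bp state"
        density = counts[label] / (bp / 1e9) if bp > 0 else 0.0
        rows.append(
            {"state": label, "n_peaks": counts[label], "state_bp": bp,
             "peaks_per_gb": density}
        )
    df = pd.DataFrame(rows, columns=["state", "n_peaks", "state_bp", "peaks_per_gb"])
    df.attrs["n_unassigned"] = n_unassigned
    return df


def write_density_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(f"# unassigned_peaks\t{df.attrs.get('n_unassigned', 0)}\n")
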