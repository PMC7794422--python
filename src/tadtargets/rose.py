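"""ROSE-style enhancer stitching, ranking and hockey-stick super-enhancer calls.

Peaks are stitched into enhancer regions (default gap 12.5 kb, after
removing peaks fully contained in a +/-2.5 kb TSS window), each region is
scored by background-subtracted summed track signal (floored at 0), and the
super/typical cutoff is found on the min-max-scaled rank-vs-signal curve at
the first point whose forward-difference slope exceeds 1. Regions with
signal strictly above the cutoff are super enhancers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, PeakSet, merge_intervals
from .signal import SignalTrack

DEFAULT_STITCH_GAP = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: list[Peak]
    signal: float
    rank: int = 0          # 1-based, ascending signal
    is_super: bool = False


@dataclass
class EnhancerRanking:
    enhancers: list[StitchedEnhancer] = field(default_factory=list)
    cutoff_signal: float = math.inf

    @property
    def n_super(self) -> int:
        return sum(e.is_super for e in self.enhancers)

    @property
    def n_typical(self) -> int:
        return len(self.enhancers) - self.n_super

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tn_constituents\tsignal\trank\tis_super\n")
            for e in sorted(self.enhancers, key=lambda e: -e.rank):
                iv = e.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{len(e.constituents)}\t"
                    f"{e.signal:.17g}\t{e.rank}\t{int(e.is_super)}\n"
                )

    def write_se_bed(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.enhancers:
                if e.is_super:
                    iv = e.interval
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def stitch_peaks(
    peaks: PeakSet | Sequence[Peak],
    max_gap: int = DEFAULT_STITCH_GAP,
    tss_list: Sequence[GenomicInterval] = (),
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> list[GenomicInterval]:
    """Stitch peaks into enhancer regions.

    Peaks whose interval lies entirely within any TSS +/- ``tss_exclusion``
    window are removed first (promoter-proximal exclusion); survivors are
    merged with ``min_gap = max_gap``. The TSS of each interval in
    ``tss_list`` is its start coordinate.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    peak_list = list(peaks.peaks if isinstance(peaks, PeakSet) else peaks)
    windows: dict[str, list[tuple[int, int]]] = {}
    for tss_iv in tss_list:
        windows.setdefault(tss_iv.chrom, []).append(
            (tss_iv.start - tss_exclusion, tss_iv.start + tss_exclusion + 1)
        )
    survivors = []
    for p in peak_list:
        excluded = any(
            lo <= p.start and p.end <= hi
            for lo, hi in windows.get(p.chrom, ())
        )
        if not excluded:
            survivors.append(p.interval)
    return merge_intervals(survivors, max_gap)


def score_stitched(
    regions: Sequence[GenomicInterval],
    treatment: SignalTrack,
    control: SignalTrack | None = None,
) -> np.ndarray:
    """Per-region background-subtracted summed signal, floored at 0."""
    if control is not None and treatment.units != control.units:
        raise ValueError(
            f"unit mismatch: treatment {treatment.units} vs control {control.units}"
        )
    signals = np.array([treatment.region_sum(r) for r in regions])
    if control is not None:
        signals = signals - np.array([control.region_sum(r) for r in regions])
    return np.maximum(signals, 0.0)


def hockey_stick_cutoff(signals: Sequence[float], slope_mode: str = "forward") -> float:
    """Super-enhancer signal cutoff on the scaled rank-vs-signal curve.

    Both ranks and signals are min-max scaled to [0, 1]; the cutoff is the
    (unscaled) signal at the first point whose slope exceeds 1 strictly.
    ``slope_mode="forward"`` uses the forward difference
    (y[i+1]-y[i])/(x[i+1]-x[i]); ``"tangent"`` uses the centered difference.
    All-equal inputs give an infinite cutoff (zero supers).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3:
        raise ValueError(
            "need >= 3 signals for a hockey-stick cutoff; "
            "with fewer, treat all regions as typical"
        )
    if slope_mode not in ("forward", "tangent"):
        raise ValueError(f"unknown slope_mode {slope_mode!r}")
    if s[0] == s[-1]:
        return math.inf
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    if slope_mode == "forward":
        slopes = (y[1:] - y[:-1]) / (x[1:] - x[:-1])
        idx = np.nonzero(slopes > 1.0)[0]
    else:
        slopes = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
        idx = np.nonzero(slopes > 1.0)[0] + 1
    if len(idx) == 0:
        return math.inf
    return float(s[idx[0]])


def call_super_enhancers(
    peaks: PeakSet | Sequence[Peak],
    treatment: SignalTrack,
    control: SignalTrack | None = None,
    tss_list: Sequence[GenomicInterval] = (),
    max_gap: int = DEFAULT_STITCH_GAP,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
    slope_mode: str = "forward",
) -> EnhancerRanking:
    """Stitch, score and rank enhancers; super iff signal > cutoff.

    With fewer than 3 stitched regions the cutoff is undefined and every
    region is reported typical (infinite cutoff).
    """
    peak_list = list(peaks.peaks if isinstance(peaks, PeakSet) else peaks)
    regions = stitch_peaks(peak_list, max_gap, tss_list, tss_exclusion)
    if not regions:
        return EnhancerRanking([], math.inf)
    signals = score_stitched(regions, treatment, control)
    cutoff = (
        hockey_stick_cutoff(signals, slope_mode) if len(regions) >= 3 else math.inf
    )
    enhancers = [
        StitchedEnhancer(
            interval=r,
            constituents=[p for p in peak_list if p.interval.overlaps(r)],
            signal=float(sig),
            is_super=bool(sig > cutoff),
        )
        for r, sig in zip(regions, signals)
    ]
    for rank, e in enumerate(
        sorted(enhancers, key=lambda e: e.signal), start=1
    ):
        e.rank = rank
    return EnhancerRanking(enhancers, cutoff)
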