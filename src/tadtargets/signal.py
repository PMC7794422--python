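"""Binned signal tracks, spike-in (RRPM) normalization, profiles and deltas.

A :class:`SignalTrack` is a per-chromosome vector of fixed-width bin values
in one of three units: ``raw`` (read counts), ``RPM`` (reads per million
mapped reads) or ``RRPM`` (reference-adjusted RPM: RPM additionally rescaled
by exogenous spike-in recovery, so occupancy is comparable across
conditions). Condition differences are a separate signed product
(:class:`DeltaTrack`) and are only defined on normalized tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval

UNITS = ("raw", "RPM", "RRPM")
DEFAULT_BIN_SIZE = 10


@dataclass
class SignalTrack:
    """Fixed-bin, non-negative coverage vectors keyed by chromosome."""

    data: dict[str, np.ndarray]
    bin_size: int = DEFAULT_BIN_SIZE
    units: str = "raw"

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for chrom, v in self.data.items():
            if np.any(v < 0):
                raise ValueError(f"negative bin values on {chrom}")

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.units == other.units
            and set(self.data) == set(other.data)
            and all(np.array_equal(self.data[c], other.data[c]) for c in self.data)
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def same_grid(self, other: "SignalTrack | DeltaTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )

    def region_sum(self, region: GenomicInterval) -> float:
        """Sum of bin values over the bins overlapped by ``region``.

        Bins are counted whole (regions are expected bin-aligned); a region
        off the covered grid contributes 0 with a warning.
        """
        vec = self.data.get(region.chrom)
        if vec is None:
            warnings.warn(f"region {region} off the covered grid", stacklevel=2)
            return 0.0
        lo = region.start // self.bin_size
        hi = -(-region.end // self.bin_size)  # ceil division
        if lo >= len(vec):
            warnings.warn(f"region {region} off the covered grid", stacklevel=2)
            return 0.0
        return float(vec[lo:min(hi, len(vec))].sum())

    def scaled(self, factor: float, units: str) -> "SignalTrack":
        return SignalTrack(
            {c: v * factor for c, v in self.data.items()}, self.bin_size, units
        )


@dataclass
class DeltaTrack:
    """Signed binwise difference of two like-normalized tracks."""

    data: dict[str, np.ndarray]
    bin_size: int
    units: str
    label: str = ""

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def region_mean(self, region: GenomicInterval) -> float:
        vec = self.data[region.chrom]
        lo = region.start // self.bin_size
        hi = -(-region.end // self.bin_size)
        return float(vec[lo:min(hi, len(vec))].mean())


@dataclass
class NormalizationFactors:
    """Library-size and spike-in counts for one ChIP sample.

    ``reference_spikein`` defaults to the cohort minimum (set by the caller);
    the RRPM scale is (1e6 / total_mapped_reads) x (reference / spike-in), so
    a sample recovering more exogenous spike-in chromatin is scaled down
    proportionally. The reference anchor is expressed at the sample's library
    scale: resequencing the same library c-fold deeper multiplies raw bins,
    total reads, spike-in reads and the matched reference anchor by c, and
    the RRPM track is invariant under that joint rescaling.
    """

    total_mapped_reads: float
    spikein_reads: float | None = None
    reference_spikein: float | None = None

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")


def rpm_scale(factors: NormalizationFactors) -> float:
    return 1e6 / factors.total_mapped_reads


def rrpm_scale(factors: NormalizationFactors) -> float:
    """Reference-adjusted per-million scale factor."""
    if not factors.spikein_reads:
        raise ValueError(
            "spike-in read count is zero/absent; RRPM undefined, use RPM instead"
        )
    if not factors.reference_spikein:
        raise ValueError("reference_spikein is required for RRPM")
    return (1e6 / factors.total_mapped_reads) * (
        factors.reference_spikein / factors.spikein_reads
    )


def normalize_track(
    track: SignalTrack, factors: NormalizationFactors, units: str = "RPM"
) -> SignalTrack:
    """Return a normalized copy of a raw track (RPM or RRPM)."""
    if track.units != "raw":
        raise ValueError(f"expected a raw track, got units {track.units!r}")
    if units == "RPM":
        return track.scaled(rpm_scale(factors), "RPM")
    if units == "RRPM":
        return track.scaled(rrpm_scale(factors), "RRPM")
    raise ValueError(f"unknown target units {units!r}")


def region_counts(
    regions: Sequence[GenomicInterval],
    track: SignalTrack,
    factors: NormalizationFactors | None = None,
    units: str | None = None,
) -> np.ndarray:
    """Per-region summed signal, optionally normalized.

    When ``factors`` is given the raw sums are multiplied by the RPM (or
    RRPM, if ``units="RRPM"``) scale; overlapping regions are summed
    independently (no double-count correction).
    """
    scale = 1.0
    if factors is not None:
        scale = rrpm_scale(factors) if units == "RRPM" else rpm_scale(factors)
    return np.array([track.region_sum(r) * scale for r in regions])


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class CompositeProfile:
    """Mean signal on an offset grid centered at 0 across n regions."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_regions: int
    n_padded: int = 0


@dataclass
class ProfileMatrix:
    offsets: np.ndarray
    matrix: np.ndarray
    row_names: list[str]
    n_padded: int = 0


def _rebin(vec: np.ndarray, factor: int) -> np.ndarray:
    usable = (len(vec) // factor) * factor
    return vec[:usable].reshape(-1, factor).mean(axis=1)


def _center_rows(
    track: SignalTrack, centers: Sequence[tuple[str, int]], flank: int, bin: int
) -> tuple[np.ndarray, np.ndarray, int]:
    if not centers:
        raise ValueError("no centers given")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    if bin % track.bin_size != 0:
        raise ValueError("bin must be a multiple of the track bin_size")
    factor = bin // track.bin_size
    rebinned = {c: (_rebin(v, factor) if factor > 1 else v) for c, v in track.data.items()}
    # odd grid: the bin containing the center sits at offset 0, w bins each side
    w = flank // bin
    rows = np.zeros((len(centers), 2 * w + 1))
    n_padded = 0
    for i, (chrom, pos) in enumerate(centers):
        vec = rebinned.get(chrom)
        if vec is None:
            n_padded += 1
            continue
        ic = pos // bin
        lo, hi = ic - w, ic + w + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(vec))
        if src_lo > lo or src_hi < hi:
            n_padded += 1
        if src_lo < src_hi:
            rows[i, src_lo - lo:src_hi - lo] = vec[src_lo:src_hi]
    offsets = np.arange(-w, w + 1) * float(bin)
    return offsets, rows, n_padded


def composite_profile(
    track: SignalTrack,
    centers: Sequence[tuple[str, int]],
    flank: int = 2000,
    bin: int | None = None,
) -> CompositeProfile:
    """Mean signal over a +/-flank window around each center position.

    Centers nearer than ``flank`` to a chromosome edge are zero-padded and
    counted in ``n_padded``. Offsets are bin midpoints relative to center.
    """
    bin = bin or track.bin_size
    offsets, rows, n_padded = _center_rows(track, centers, flank, bin)
    return CompositeProfile(offsets, rows.mean(axis=0), len(centers), n_padded)


def profile_matrix(
    track: SignalTrack,
    centers: Sequence[tuple[str, int]],
    flank: int,
    bin: int | None,
    sort_track: SignalTrack,
) -> ProfileMatrix:
    """One row per center, sorted descending by the per-row total of
    ``sort_track``; ties broken by genomic coordinate (stable)."""
    bin = bin or track.bin_size
    offsets, rows, n_padded = _center_rows(track, centers, flank, bin)
    _, sort_rows, _ = _center_rows(sort_track, centers, flank, bin)
    totals = sort_rows.sum(axis=1)
    # stable sort on (-total, chrom, pos)
    order = sorted(
        range(len(centers)),
        key=lambda i: (-totals[i], centers[i][0], centers[i][1]),
    )
    names = [
        f"{centers[i][0]}:{centers[i][1] - flank}-{centers[i][1] + flank}"
        for i in order
    ]
    return ProfileMatrix(offsets, rows[order], names, n_padded)


def delta_track(a: SignalTrack, b: SignalTrack) -> DeltaTrack:
    """Binwise a - b on a shared grid; refuses raw units."""
    if a.units == "raw" or b.units == "raw":
        raise ValueError("delta requires normalized tracks (RPM or RRPM), not raw")
    if a.units != b.units:
        raise ValueError(f"unit mismatch: {a.units} vs {b.units}")
    if not a.same_grid(b):
        raise ValueError("bin grids differ between tracks")
    return DeltaTrack(
        {c: a.data[c] - b.data[c] for c in a.data},
        a.bin_size,
        a.units,
        label="A minus B",
    )


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(
    path,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_lengths: dict[str, int] | None = None,
    units: str = "raw",
) -> SignalTrack:
    """Read a bedGraph into a fixed-bin track.

    Values are treated as constant per-bp heights; each bin stores the
    bp-weighted mean over its span, so a file that is constant within bins
    round-trips exactly.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            )
            spans.setdefault(chrom, []).append((start, end, value))
            max_end[chrom] = max(max_end.get(chrom, 0), end)
    data: dict[str, np.ndarray] = {}
    for chrom, entries in spans.items():
        length = (chrom_lengths or {}).get(chrom, max_end[chrom])
        n_bins = -(-length // bin_size)
        acc = np.zeros(n_bins)
        for start, end, value in entries:
            lo_bin, hi_bin = start // bin_size, -(-end // bin_size)
            for b in range(lo_bin, min(hi_bin, n_bins)):
                b_lo, b_hi = b * bin_size, (b + 1) * bin_size
                acc[b] += value * (min(end, b_hi) - max(start, b_lo)) / bin_size
        data[chrom] = acc
    return SignalTrack(data, bin_size, units)


def write_bedgraph(track: SignalTrack | DeltaTrack, path) -> None:
    """Write a track as bedGraph, run-length compressing equal bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            i = 0
            while i < len(vec):
                j = i + 1
                while j < len(vec) and vec[j] == vec[i]:
                    j += 1
                if vec[i] != 0.0:
                    fh.write(
                        f"{chrom}\t{i * track.bin_size}\t{j * track.bin_size}"
                        f"\t{vec[i]:.17g}\n"
                    )
                i = j
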