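"""Seeded generator of a toy genome with planted direct/indirect target truth.

The generator emulates the statistical structure of a multi-cell-line
repressor/activator ChIP + knockdown RNA-seq study: disjoint TADs tiling
small chromosomes (with boundary gaps), genes with TSSs inside TADs, master
peak lists with controlled cross-cell-line reproducibility and controlled
repressor/activator co-localization, triangular-bump signal tracks with
Poisson noise and per-sample spike-in counts, a ChromHMM-like segmentation,
and DE tables in which planted *direct* genes are upregulated in both cell
lines with a repressor peak in their TAD while *indirect* genes are
upregulated with a repressor-free TAD.

All randomness flows from ``SimulationConfig.seed``; each stage derives its
own fixed sub-stream so stages are individually reproducible. Per-factor
track noise uses one stream shared across conditions, so a knockdown factor
of 1.0 yields byte-identical control and knockdown tracks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .chromstate import StateSegmentation, read_segmentation, write_segmentation
from .exprstats import GeneSet, benjamini_hochberg, read_de_table, read_gmt, write_de_table, write_gmt
from .intervals import GenomicInterval, Peak, PeakSet, read_bed, write_bed
from .signal import NormalizationFactors, SignalTrack, read_bedgraph, write_bedgraph
from .targets import TAD, Gene, TADMap, read_genes, read_tads, write_genes, write_tads

STATE_ORDER = ["Promoter", "StrongEnh", "WeakEnh", "Txn", "Quies"]
CONDITIONS = ("control", "knockdown", "treatment")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture (fully serializable).

    Defaults give a 3 x 2 Mb genome with 30 TADs and 300 genes
    (30 direct / 100 indirect / 170 null), 300 repressor and 600 activator
    master peaks observed in 3 cell lines; every stage runs in seconds.
    """

    seed: int = 1
    # genome
    n_chrom: int = 3
    chrom_length: int = 2_000_000
    n_tads: int = 30
    gap_fraction: float = 0.1
    genes_per_tad: int = 10
    min_gene_length: int = 2_000
    max_gene_length: int = 20_000
    # planted gene classes
    n_direct: int = 30
    n_indirect: int = 100
    n_null: int = 170
    # peaks
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3")
    n_repressor_peaks: int = 300
    n_activator_peaks: int = 600
    peak_width_mean: int = 400
    peak_width_sd: int = 80
    reproducibility: float = 0.8
    shared_fraction: float = 0.6
    shared_offset: int = 200
    n_super_sites: int = 20
    super_height_fold: float = 10.0
    # tracks
    bin_size: int = 25
    bump_height: float = 20.0
    background_rate: float = 0.25
    knockdown_factor: float = 0.2
    activator_gain: float = 1.8
    spikein_base: int = 100_000
    # expression
    l2fc_mean: float = 3.0
    de_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("gap_fraction", "reproducibility", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if isinstance(self.cell_lines, list):
            self.cell_lines = tuple(self.cell_lines)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Planted truth: per-gene class, per-peak classes, SE sites, free TADs."""

    gene_class: dict[str, str]                 # gene_id -> direct|indirect|null
    repressor_peaks: list[dict]                # id, coords, shared, guaranteed, lines, height
    activator_peaks: list[dict]                # id, coords, shared, super, lines, height
    free_tads: list[str]

    def validate(self, tads: TADMap, genes: Sequence[Gene]) -> None:
        """Assert the planted invariants that define the fixture."""
        by_id = {g.gene_id: g for g in genes}
        rep_tads: dict[str, int] = {}
        rep2_tads: dict[str, int] = {}
        for p in self.repressor_peaks:
            tid = tads.find(p["chrom"], (p["start"] + p["end"]) // 2)
            assert tid not in set(self.free_tads), "repressor peak inside a free TAD"
            if tid is not None:
                rep_tads[tid] = rep_tads.get(tid, 0) + 1
                if len(p["lines"]) >= 2:
                    rep2_tads[tid] = rep2_tads.get(tid, 0) + 1
        for gid, klass in self.gene_class.items():
            g = by_id[gid]
            tid = tads.find(g.chrom, g.tss)
            if klass == "direct":
                assert tid is not None and rep2_tads.get(tid, 0) >= 1, (
                    f"direct gene {gid} lacks a reproducible repressor peak in its TAD"
                )
            elif klass == "indirect":
                assert tid is not None and rep_tads.get(tid, 0) == 0, (
                    f"indirect gene {gid} has a repressor peak in its TAD"
                )


# ---------------------------------------------------------------------------
# Stage 1: genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[dict[str, int], TADMap, list[Gene]]:
    """Toy chromosomes, disjoint TADs with boundary gaps, genes with in-TAD TSSs."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_tads * config.genes_per_tad
    if config.n_direct + config.n_indirect + config.n_null != n_genes:
        raise ValueError(
            "n_direct + n_indirect + n_null must equal n_tads * genes_per_tad "
            f"({config.n_direct}+{config.n_indirect}+{config.n_null} != {n_genes})"
        )
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)
    }
    # spread TADs over chromosomes as evenly as possible
    base, extra = divmod(config.n_tads, config.n_chrom)
    counts = [base + (1 if i < extra else 0) for i in range(config.n_chrom)]
    min_tad = max(20_000, config.genes_per_tad * 2_000)
    tads: list[TAD] = []
    tad_idx = 0
    for (chrom, length), m in zip(chrom_lengths.items(), counts):
        if m == 0:
            continue
        gap_total = int(round(config.gap_fraction * length))
        tad_total = length - gap_total
        if tad_total < m * min_tad:
            raise ValueError(
                f"infeasible config: {m} TADs of >= {min_tad} bp do not fit "
                f"in {tad_total} bp on {chrom}"
            )
        gap_lens = np.floor(rng.dirichlet(np.ones(m + 1)) * gap_total).astype(int)
        spare = tad_total - m * min_tad
        tad_lens = min_tad + np.floor(rng.dirichlet(np.ones(m) * 4) * spare).astype(int)
        cursor = int(gap_lens[0])
        for j in range(m):
            start, end = cursor, cursor + int(tad_lens[j])
            tads.append(TAD(GenomicInterval(chrom, start, end), f"T{tad_idx:03d}"))
            tad_idx += 1
            cursor = end + int(gap_lens[j + 1])
    tadmap = TADMap(tads)
    genes: list[Gene] = []
    idx = 0
    for t in tadmap:
        iv = t.interval
        for _ in range(config.genes_per_tad):
            tss = int(rng.integers(iv.start + 500, iv.end - 500))
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(config.min_gene_length, config.max_gene_length))
            if strand == "+":
                g_iv = GenomicInterval(
                    iv.chrom, tss, min(tss + glen, chrom_lengths[iv.chrom]), "+"
                )
            else:
                g_iv = GenomicInterval(iv.chrom, max(tss - glen + 1, 0), tss + 1, "-")
            genes.append(Gene(f"G{idx:04d}", f"GENE{idx:04d}", g_iv))
            idx += 1
    return chrom_lengths, tadmap, genes


# ---------------------------------------------------------------------------
# Stage 2: peak sets and ground truth
# ---------------------------------------------------------------------------

def _draw_width(rng: np.random.Generator, config: SimulationConfig) -> int:
    return max(150, int(round(rng.normal(config.peak_width_mean, config.peak_width_sd))))


def simulate_peaksets(
    config: SimulationConfig,
    genome: tuple[dict[str, int], TADMap, list[Gene]],
) -> tuple[dict[str, dict[str, PeakSet]], GroundTruth]:
    """Master peak lists with per-cell-line dropout, plus the planted truth.

    Every direct gene's TAD receives at least one repressor master peak
    observed in >= 2 cell lines; TADs hosting indirect genes stay entirely
    repressor-free. A ``shared_fraction`` of repressor peaks gets an
    activator peak planted within +/- ``shared_offset`` bp.
    """
    chrom_lengths, tadmap, genes = genome
    rng = np.random.default_rng(config.seed + 1)
    chroms = list(chrom_lengths)
    tad_ids = [t.tad_id for t in tadmap]
    tad_of_gene = {g.gene_id: tadmap.find(g.chrom, g.tss) for g in genes}

    n_free = -(-config.n_indirect // config.genes_per_tad)
    if (config.n_tads - n_free - 1) * config.genes_per_tad >= config.n_direct:
        n_free += 1  # spare free TAD when capacity allows
    free_set = set(rng.choice(tad_ids, size=n_free, replace=False).tolist())

    free_gene_ids = [g.gene_id for g in genes if tad_of_gene[g.gene_id] in free_set]
    peaked_gene_ids = [g.gene_id for g in genes if tad_of_gene[g.gene_id] not in free_set]
    if len(free_gene_ids) < config.n_indirect or len(peaked_gene_ids) < config.n_direct:
        raise ValueError("infeasible config: not enough gene slots for planted classes")
    indirect = set(rng.choice(free_gene_ids, size=config.n_indirect, replace=False).tolist())
    direct = set(rng.choice(peaked_gene_ids, size=config.n_direct, replace=False).tolist())
    gene_class = {
        g.gene_id: (
            "direct" if g.gene_id in direct
            else "indirect" if g.gene_id in indirect
            else "null"
        )
        for g in genes
    }

    by_id = {g.gene_id: g for g in genes}

    def draw_outside_free(width: int) -> tuple[str, int, int]:
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            center = int(rng.integers(width, chrom_lengths[chrom] - width))
            if tadmap.find(chrom, center) not in free_set:
                start = center - width // 2
                return chrom, start, start + width

    def draw_anywhere(width: int) -> tuple[str, int, int]:
        chrom = chroms[int(rng.integers(len(chroms)))]
        center = int(rng.integers(width, chrom_lengths[chrom] - width))
        start = center - width // 2
        return chrom, start, start + width

    # guaranteed repressor masters near each direct gene's TSS, inside its TAD
    rep_records: list[dict] = []
    for gid in sorted(direct):
        g = by_id[gid]
        t_iv = next(t.interval for t in tadmap if t.tad_id == tad_of_gene[gid])
        width = _draw_width(rng, config)
        center = int(
            np.clip(
                g.tss + rng.integers(-5_000, 5_001),
                t_iv.start + width, t_iv.end - width,
            )
        )
        start = center - width // 2
        rep_records.append(
            {"chrom": g.chrom, "start": start, "end": start + width, "guaranteed": True}
        )
    n_extra = config.n_repressor_peaks - len(rep_records)
    if n_extra < 0:
        raise ValueError("n_repressor_peaks smaller than the number of direct genes")
    for _ in range(n_extra):
        width = _draw_width(rng, config)
        chrom, start, end = draw_outside_free(width)
        rep_records.append(
            {"chrom": chrom, "start": start, "end": end, "guaranteed": False}
        )

    lines = list(config.cell_lines)
    for i, rec in enumerate(rep_records):
        rec["id"] = f"R{i:04d}"
        rec["shared"] = bool(rng.random() < config.shared_fraction)
        rec["height"] = float(rng.gamma(4.0, 2.5)) * (1.5 if rec["shared"] else 1.0)
        included = [cl for cl in lines if rng.random() < config.reproducibility]
        if rec["guaranteed"] and len(included) < 2:
            included = sorted(rng.choice(lines, size=2, replace=False).tolist())
        rec["lines"] = included

    act_records: list[dict] = []
    for rec in rep_records:
        if rec["shared"]:
            width = _draw_width(rng, config)
            center = (rec["start"] + rec["end"]) // 2 + int(
                rng.integers(-config.shared_offset, config.shared_offset + 1)
            )
            start = max(center - width // 2, 0)
            act_records.append(
                {"chrom": rec["chrom"], "start": start, "end": start + width,
                 "shared": True}
            )
    while len(act_records) < config.n_activator_peaks:
        width = _draw_width(rng, config)
        chrom, start, end = draw_anywhere(width)
        act_records.append({"chrom": chrom, "start": start, "end": end, "shared": False})
    act_records = act_records[: config.n_activator_peaks]

    unshared_idx = [i for i, r in enumerate(act_records) if not r["shared"]]
    super_idx = set(
        rng.choice(unshared_idx, size=min(config.n_super_sites, len(unshared_idx)),
                   replace=False).tolist()
    )
    for i, rec in enumerate(act_records):
        rec["id"] = f"A{i:04d}"
        rec["super"] = i in super_idx
        rec["height"] = float(rng.gamma(4.0, 2.5)) * (1.5 if rec["shared"] else 1.0)
        if rec["super"]:
            rec["height"] *= config.super_height_fold
        rec["lines"] = [cl for cl in lines if rng.random() < config.reproducibility]

    truth = GroundTruth(gene_class, rep_records, act_records, sorted(free_set))
    truth.validate(tadmap, genes)

    peaksets: dict[str, dict[str, PeakSet]] = {}
    for cl in lines:
        per_factor = {}
        for factor, records in (("repressor", rep_records), ("activator", act_records)):
            peaks = []
            for rec in records:
                if cl not in rec["lines"]:
                    continue
                score = rec["height"] * float(rng.uniform(0.8, 1.2))
                peaks.append(
                    Peak(
                        GenomicInterval(rec["chrom"], rec["start"], rec["end"]),
                        score=score,
                        name=rec["id"],
                    )
                )
            per_factor[factor] = PeakSet(
                sorted(peaks, key=lambda p: (p.chrom, p.start)),
                {"factor": factor, "cell_line": cl},
            )
        peaksets[cl] = per_factor
    return peaksets, truth


# ---------------------------------------------------------------------------
# Stage 3: signal tracks with spike-ins
# ---------------------------------------------------------------------------

def simulate_tracks(
    config: SimulationConfig,
    genome: tuple[dict[str, int], TADMap, list[Gene]],
    truth: GroundTruth,
    conditions: Sequence[str] = CONDITIONS,
) -> tuple[dict[str, SignalTrack], dict[str, NormalizationFactors]]:
    """Raw binned tracks per (factor, condition) plus spike-in counts.

    Triangular bumps at master peaks over Poisson background. The knockdown
    and treatment conditions scale repressor bumps by ``knockdown_factor``
    and raise activator bumps by ``activator_gain`` at shared peaks only.
    Poisson noise per factor is drawn from one stream re-seeded identically
    for each condition, so conditions differ only through planted effects.
    """
    chrom_lengths, _, _ = genome
    bs = config.bin_size
    n_bins = {c: -(-length // bs) for c, length in chrom_lengths.items()}
    tracks: dict[str, SignalTrack] = {}
    factors_out: dict[str, NormalizationFactors] = {}
    spike_rng = np.random.default_rng(config.seed + 2)
    spikeins = {}
    for fi, factor in enumerate(("repressor", "activator")):
        for condition in conditions:
            spikeins[f"{factor}_{condition}"] = int(
                round(config.spikein_base * spike_rng.uniform(0.7, 1.3))
            )
    for fi, (factor, records) in enumerate(
        (("repressor", truth.repressor_peaks), ("activator", truth.activator_peaks))
    ):
        for condition in conditions:
            expected = {
                c: np.full(nb, config.background_rate) for c, nb in n_bins.items()
            }
            for rec in records:
                h = rec["height"]
                if condition != "control":
                    if factor == "repressor":
                        h *= config.knockdown_factor
                    elif rec["shared"]:
                        h *= config.activator_gain
                center_bin = ((rec["start"] + rec["end"]) // 2) // bs
                half = max(1, (rec["end"] - rec["start"]) // (2 * bs))
                vec = expected[rec["chrom"]]
                lo = max(center_bin - half, 0)
                hi = min(center_bin + half + 1, len(vec))
                offs = np.arange(lo, hi) - center_bin
                vec[lo:hi] += h * (1.0 - np.abs(offs) / (half + 1))
            noise_rng = np.random.default_rng((config.seed + 2, fi))
            data = {
                c: noise_rng.poisson(expected[c]).astype(float)
                for c in sorted(expected)
            }
            track = SignalTrack(data, bs, "raw")
            sample = f"{factor}_{condition}"
            tracks[sample] = track
            factors_out[sample] = NormalizationFactors(
                total_mapped_reads=max(track.total(), 1.0),
                spikein_reads=spikeins[sample],
            )
    reference = min(f.spikein_reads for f in factors_out.values())
    for f in factors_out.values():
        f.reference_spikein = reference
    return tracks, factors_out


# ---------------------------------------------------------------------------
# Stage 4: differential expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    genome: tuple[dict[str, int], TADMap, list[Gene]],
    truth: GroundTruth,
    contrasts: Sequence[str] = ("knockdown", "treatment"),
):
    """DE tables per cell line per contrast (first two cell lines).

    Planted direct and indirect genes draw log2FC ~ Normal(l2fc_mean,
    de_sigma) in every table; null genes ~ Normal(0, de_sigma). P-values
    come from the z-score log2FC/de_sigma, FDR from Benjamini-Hochberg.
    """
    import pandas as pd
    from scipy import stats as sps

    _, _, genes = genome
    rng = np.random.default_rng(config.seed + 3)
    up = np.array(
        [truth.gene_class[g.gene_id] in ("direct", "indirect") for g in genes]
    )
    tables: dict[str, pd.DataFrame] = {}
    for cl in config.cell_lines[:2]:
        for contrast in contrasts:
            mean = np.where(up, config.l2fc_mean, 0.0)
            if config.de_sigma > 0:
                l2fc = rng.normal(mean, config.de_sigma)
                p = 2.0 * sps.norm.sf(np.abs(l2fc / config.de_sigma))
            else:
                l2fc = mean.copy()
                p = np.where(up, 0.0, 1.0)
            df = pd.DataFrame(
                {
                    "gene_id": [g.gene_id for g in genes],
                    "log2fc": l2fc,
                    "pvalue": p,
                    "fdr": benjamini_hochberg(p),
                }
            )
            df.attrs["cell_line"] = cl
            df.attrs["contrast"] = f"{contrast} vs control"
            tables[f"{cl}.{contrast}"] = df
    return tables


# ---------------------------------------------------------------------------
# Stage 5: segmentation and gene sets
# ---------------------------------------------------------------------------

def simulate_segmentation(
    config: SimulationConfig,
    genome: tuple[dict[str, int], TADMap, list[Gene]],
    truth: GroundTruth,
) -> StateSegmentation:
    """ChromHMM-like tiling: promoters at TSSs, enhancer states at activator
    peaks, transcription over gene bodies, quiescent elsewhere."""
    chrom_lengths, _, genes = genome
    codes = {label: i for i, label in enumerate(STATE_ORDER)}
    arrays = {
        c: np.full(length, codes["Quies"], dtype=np.int8)
        for c, length in chrom_lengths.items()
    }

    def paint(chrom: str, lo: int, hi: int, label: str) -> None:
        arr = arrays[chrom]
        arr[max(lo, 0):min(hi, len(arr))] = codes[label]

    for g in genes:  # lowest priority first; later paints overwrite
        paint(g.chrom, g.interval.start, g.interval.end, "Txn")
    for rec in truth.activator_peaks:
        center = (rec["start"] + rec["end"]) // 2
        paint(rec["chrom"], center - 1500, center + 1500, "WeakEnh")
    for rec in truth.activator_peaks:
        center = (rec["start"] + rec["end"]) // 2
        paint(rec["chrom"], center - 500, center + 500, "StrongEnh")
    for g in genes:
        paint(g.chrom, g.tss - 500, g.tss + 500, "Promoter")

    segments: list[tuple[GenomicInterval, str]] = []
    for chrom in sorted(arrays):
        arr = arrays[chrom]
        boundaries = np.nonzero(np.diff(arr))[0] + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(arr)]])
        for s, e in zip(starts, ends):
            segments.append(
                (GenomicInterval(chrom, int(s), int(e)), STATE_ORDER[arr[s]])
            )
    return StateSegmentation(segments, list(STATE_ORDER))


def simulate_gene_sets(
    config: SimulationConfig,
    genome: tuple[dict[str, int], TADMap, list[Gene]],
    truth: GroundTruth,
) -> list[GeneSet]:
    """A myogenic stand-in set (planted-up genes + half the nulls) and a
    random control set."""
    _, _, genes = genome
    rng = np.random.default_rng(config.seed + 5)
    null_ids = [g for g, k in sorted(truth.gene_class.items()) if k == "null"]
    planted = [g for g, k in sorted(truth.gene_class.items()) if k != "null"]
    extra = rng.choice(null_ids, size=len(null_ids) // 2, replace=False).tolist()
    myogenic = GeneSet("MYOGENIC_STANDIN", frozenset(planted + extra))
    control = GeneSet(
        "RANDOM_CONTROL",
        frozenset(
            rng.choice([g.gene_id for g in genes], size=50, replace=False).tolist()
        ),
    )
    return [myogenic, control]


# ---------------------------------------------------------------------------
# Bundle orchestration and on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    config: SimulationConfig
    chrom_lengths: dict[str, int]
    tads: TADMap
    genes: list[Gene]
    peaksets: dict[str, dict[str, PeakSet]]
    truth: GroundTruth
    tracks: dict[str, SignalTrack]
    norm_factors: dict[str, NormalizationFactors]
    expression: dict  # "<cell_line>.<contrast>" -> DataFrame
    gene_sets: list[GeneSet]
    segmentation: StateSegmentation

    @property
    def genome(self) -> tuple[dict[str, int], TADMap, list[Gene]]:
        return self.chrom_lengths, self.tads, self.genes


def simulate_bundle(config: SimulationConfig | None = None) -> FixtureBundle:
    """Run every generation stage in fixed order; fully seed-deterministic."""
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    peaksets, truth = simulate_peaksets(config, genome)
    tracks, norm_factors = simulate_tracks(config, genome, truth)
    expression = simulate_expression(config, genome, truth)
    segmentation = simulate_segmentation(config, genome, truth)
    gene_sets = simulate_gene_sets(config, genome, truth)
    return FixtureBundle(
        config, genome[0], genome[1], genome[2], peaksets, truth,
        tracks, norm_factors, expression, gene_sets, segmentation,
    )


def simulate_bimodal_enhancers(
    seed: int = 1,
    n_regions: int = 500,
    n_high: int = 20,
    fold: float = 50.0,
    region_len: int = 1_000,
    gap: int = 15_000,
    bin_size: int = 50,
) -> tuple[PeakSet, SignalTrack, np.ndarray]:
    """Bimodal enhancer fixture: ``n_high`` planted high-signal regions among
    ``n_regions`` total, on one chromosome, with per-region constant signal.

    Regions are spaced beyond the default stitching gap so each stays its
    own enhancer. Returns (peaks, treatment track in RPM units, planted
    super flags aligned with the peaks).
    """
    rng = np.random.default_rng(seed)
    is_high = np.zeros(n_regions, dtype=bool)
    is_high[rng.choice(n_regions, size=n_high, replace=False)] = True
    levels = np.where(
        is_high,
        fold * rng.uniform(0.9, 1.1, n_regions),
        rng.uniform(0.8, 1.2, n_regions),
    )
    pitch = region_len + gap
    n_bins = -(-(n_regions * pitch) // bin_size)
    vec = np.zeros(n_bins)
    peaks = []
    for i in range(n_regions):
        start = i * pitch
        end = start + region_len
        vec[start // bin_size:end // bin_size] = levels[i]
        peaks.append(
            Peak(GenomicInterval("chrS", start, end), score=float(levels[i]))
        )
    track = SignalTrack({"chrS": vec}, bin_size, "RPM")
    return (
        PeakSet(peaks, {"factor": "activator", "cell_line": "synthetic"}),
        track,
        is_high,
    )


def write_fixture_bundle(bundle: FixtureBundle, outdir) -> None:
    """Write the bundle as plain-text files; reading it back is lossless."""
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    bundle.config.to_yaml(out / "config.yaml")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(bundle.chrom_lengths):
            fh.write(f"{chrom}\t{bundle.chrom_lengths[chrom]}\n")
    write_tads(bundle.tads, out / "tads.bed")
    write_genes(bundle.genes, out / "genes.tsv")
    (out / "peaks").mkdir(exist_ok=True)
    for cl in sorted(bundle.peaksets):
        for factor in sorted(bundle.peaksets[cl]):
            write_bed(
                bundle.peaksets[cl][factor],
                out / "peaks" / f"{cl}.{factor}.bed",
            )
    (out / "tracks").mkdir(exist_ok=True)
    for sample in sorted(bundle.tracks):
        write_bedgraph(bundle.tracks[sample], out / "tracks" / f"{sample}.bedgraph")
    with open(out / "norm_factors.tsv", "w") as fh:
        fh.write("sample\ttotal_mapped_reads\tspikein_reads\treference_spikein\n")
        for sample in sorted(bundle.norm_factors):
            f = bundle.norm_factors[sample]
            fh.write(
                f"{sample}\t{f.total_mapped_reads:.17g}\t{f.spikein_reads:.17g}"
                f"\t{f.reference_spikein:.17g}\n"
            )
    (out / "expression").mkdir(exist_ok=True)
    for key in sorted(bundle.expression):
        write_de_table(bundle.expression[key], out / "expression" / f"{key}.tsv")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    write_segmentation(bundle.segmentation, out / "segmentation.bed")
    truth = {
        "gene_class": bundle.truth.gene_class,
        "repressor_peaks": bundle.truth.repressor_peaks,
        "activator_peaks": bundle.truth.activator_peaks,
        "free_tads": bundle.truth.free_tads,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_fixture_bundle(indir) -> FixtureBundle:
    """Read a bundle written by :func:`write_fixture_bundle`."""
    indir = Path(indir)
    config = SimulationConfig.from_yaml(indir / "config.yaml")
    chrom_lengths = {}
    with open(indir / "chrom_sizes.tsv") as fh:
        for line in fh:
            chrom, length = line.split("\t")
            chrom_lengths[chrom] = int(length)
    tads = read_tads(indir / "tads.bed")
    genes = read_genes(indir / "genes.tsv")
    peaksets: dict[str, dict[str, PeakSet]] = {}
    for path in sorted((indir / "peaks").glob("*.bed")):
        cl, factor = path.stem.split(".")
        ps = read_bed(path, kind="peak", meta={"factor": factor, "cell_line": cl})
        peaksets.setdefault(cl, {})[factor] = ps
    norm_factors: dict[str, NormalizationFactors] = {}
    with open(indir / "norm_factors.tsv") as fh:
        next(fh)
        for line in fh:
            sample, total, spike, ref = line.rstrip("\n").split("\t")
            norm_factors[sample] = NormalizationFactors(
                float(total), float(spike), float(ref)
            )
    tracks = {
        path.stem: read_bedgraph(path, config.bin_size, chrom_lengths)
        for path in sorted((indir / "tracks").glob("*.bedgraph"))
    }
    expression = {}
    for path in sorted((indir / "expression").glob("*.tsv")):
        df = read_de_table(path)
        cl, contrast = path.stem.split(".")
        df.attrs["cell_line"] = cl
        df.attrs["contrast"] = f"{contrast} vs control"
        expression[path.stem] = df
    gene_sets = read_gmt(indir / "gene_sets.gmt")
    segmentation = read_segmentation(indir / "segmentation.bed", list(STATE_ORDER))
    with open(indir / "truth.json") as fh:
        t = json.load(fh)
    truth = GroundTruth(
        t["gene_class"], t["repressor_peaks"], t["activator_peaks"], t["free_tads"]
    )
    return FixtureBundle(
        config, chrom_lengths, tads, genes, peaksets, truth,
        tracks, norm_factors, expression, gene_sets, segmentation,
    )
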