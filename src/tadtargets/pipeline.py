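"""End-to-end orchestration: bundle in, classified targets + report out.

The pipeline chains consensus peak calling, two-factor co-occupancy,
chromatin-state density, super-enhancer ranking, knockdown-delta profiles,
TAD-constrained direct/indirect target classification and preranked
enrichment. Every parameter is echoed verbatim into the machine-readable
report; reruns of the same config on the same fixture are byte-identical up
to the runtime field.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chromstate import peaks_per_gb, write_density_table
from .exprstats import consistent_upregulated, preranked_enrichment_multi
from .intervals import GenomicInterval, classify_cooccupancy, consensus_peaks, write_bed
from .rose import call_super_enhancers
from .signal import composite_profile, delta_track, normalize_track, write_bedgraph
from .simulate import FixtureBundle, read_fixture_bundle
from .targets import classify_targets, write_target_calls

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_INVARIANT_ERROR = 4


class PipelineError(Exception):
    exit_code = 1


class ConfigError(PipelineError):
    exit_code = EXIT_CONFIG_ERROR


class DataError(PipelineError):
    exit_code = EXIT_DATA_ERROR


class InvariantError(PipelineError):
    exit_code = EXIT_INVARIANT_ERROR


@dataclass
class PipelineConfig:
    """Parameters for the full run; defaults follow the module defaults."""

    bundle_dir: str = ""
    outdir: str = "tadtargets_out"
    consensus_k: int = 2
    consensus_mode: str = "depth"
    min_overlap: int = 1
    stitch_gap: int = 12_500
    tss_exclusion: int = 2_500
    flank: int = 2_000
    profile_bin: int | None = None
    l2fc_min: float = 0.0
    fdr_max: float = 0.05
    weight_p: int = 1
    n_perm: int = 1000
    seed: int = 1
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineReport:
    counts: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    version: str = __version__
    runtime_seconds: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "counts": self.counts,
            "values": self.values,
            "params": self.params,
            "version": self.version,
            "runtime_seconds": self.runtime_seconds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def write_summary_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for key in sorted(self.counts):
                fh.write(f"{key}\t{self.counts[key]}\n")
            for key in sorted(self.values):
                fh.write(f"{key}\t{self.values[key]:.6g}\n")


class _Stage:
    """Context manager that prefixes failures with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        import logging

        logging.getLogger("tadtargets").info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise DataError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(
    config: PipelineConfig, bundle: FixtureBundle | None = None
) -> PipelineReport:
    """Execute the full chain on a fixture bundle and write all outputs.

    Stages: consensus -> co-occupancy -> state density -> SE calling ->
    profiles/deltas -> target classification -> enrichment. Any stage
    failure aborts with the stage name and cause.
    """
    t0 = time.monotonic()
    report = PipelineReport(params=config.to_dict(), version=config.version)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage("load"):
        if bundle is None:
            if not config.bundle_dir:
                raise ConfigError("bundle_dir is required when no bundle is passed")
            if not Path(config.bundle_dir).is_dir():
                raise ConfigError(f"bundle_dir {config.bundle_dir!r} does not exist")
            bundle = read_fixture_bundle(config.bundle_dir)
        cell_lines = sorted(bundle.peaksets)
        report.counts["n_cell_lines"] = len(cell_lines)

    with _Stage("consensus"):
        rep_sets = [bundle.peaksets[cl]["repressor"] for cl in cell_lines]
        act_sets = [bundle.peaksets[cl]["activator"] for cl in cell_lines]
        if config.consensus_k > len(rep_sets):
            raise ConfigError(
                f"consensus_k={config.consensus_k} exceeds n={len(rep_sets)} cell lines"
            )
        rep_consensus = consensus_peaks(rep_sets, config.consensus_k, config.consensus_mode)
        act_consensus = consensus_peaks(act_sets, config.consensus_k, config.consensus_mode)
        rep_all = consensus_peaks(rep_sets, len(rep_sets), config.consensus_mode)
        report.counts["n_consensus_repressor"] = len(rep_consensus)
        report.counts["n_consensus_activator"] = len(act_consensus)
        report.counts["n_repressor_all_lines"] = len(rep_all)
        write_bed(rep_consensus, outdir / "consensus_repressor.bed")
        write_bed(act_consensus, outdir / "consensus_activator.bed")

    with _Stage("cooccupancy"):
        venn = classify_cooccupancy(rep_consensus, act_consensus, config.min_overlap)
        n_rep_only, n_act_only, n_shared = venn.counts
        report.counts["n_repressor_only"] = n_rep_only
        report.counts["n_activator_only"] = n_act_only
        report.counts["n_shared_peaks"] = n_shared
        # activator-side classes for the delta readout below
        act_venn = classify_cooccupancy(act_consensus, rep_consensus, config.min_overlap)

    with _Stage("states"):
        density = peaks_per_gb(rep_consensus, bundle.segmentation)
        write_density_table(density, outdir / "state_density.tsv")
        for row in density.itertuples():
            report.values[f"peaks_per_gb.{row.state}"] = float(row.peaks_per_gb)

    with _Stage("rose"):
        nf = bundle.norm_factors["activator_control"]
        act_rpm = normalize_track(bundle.tracks["activator_control"], nf, "RPM")
        tss_list = [
            GenomicInterval(g.chrom, g.tss, g.tss + 1) for g in bundle.genes
        ]
        ranking = call_super_enhancers(
            act_consensus, act_rpm, None, tss_list,
            max_gap=config.stitch_gap, tss_exclusion=config.tss_exclusion,
        )
        report.counts["n_super"] = ranking.n_super
        report.counts["n_typical"] = ranking.n_typical
        ranking.write_tsv(outdir / "enhancers.tsv")
        ranking.write_se_bed(outdir / "super_enhancers.bed")

    with _Stage("profiles"):
        ctrl = normalize_track(
            bundle.tracks["activator_control"],
            bundle.norm_factors["activator_control"], "RRPM",
        )
        kd = normalize_track(
            bundle.tracks["activator_knockdown"],
            bundle.norm_factors["activator_knockdown"], "RRPM",
        )
        delta = delta_track(kd, ctrl)
        delta.label = "knockdown minus control"
        write_bedgraph(delta, outdir / "delta_activator.bedgraph")
        shared_centers = [
            (p.chrom, p.interval.midpoint) for p in act_venn.shared
        ]
        only_centers = [(p.chrom, p.interval.midpoint) for p in act_venn.a_only]
        if shared_centers:
            prof = composite_profile(
                ctrl, shared_centers, config.flank, config.profile_bin
            )
            with open(outdir / "composite_shared.tsv", "w") as fh:
                fh.write("offset\tmean_signal\n")
                for off, val in zip(prof.offsets, prof.mean_signal):
                    fh.write(f"{off:.17g}\t{val:.17g}\n")
        d_shared = (
            float(np.mean([delta.region_mean(p.interval) for p in act_venn.shared]))
            if shared_centers else float("nan")
        )
        d_only = (
            float(np.mean([delta.region_mean(p.interval) for p in act_venn.a_only]))
            if only_centers else float("nan")
        )
        report.values["delta_shared_mean"] = d_shared
        report.values["delta_activator_only_mean"] = d_only

    with _Stage("classify"):
        kd_keys = sorted(k for k in bundle.expression if k.endswith(".knockdown"))
        if len(kd_keys) < 2:
            raise DataError("need knockdown DE tables from >= 2 cell lines")
        tables = [bundle.expression[k] for k in kd_keys]
        myogenic = next(
            (gs for gs in bundle.gene_sets if "MYOGENIC" in gs.name.upper()),
            bundle.gene_sets[0],
        )
        candidates = consistent_upregulated(
            tables, config.l2fc_min, config.fdr_max, universe=myogenic
        )
        evidence = {
            gid: {
                key.split(".")[0]: float(
                    df.set_index("gene_id").loc[gid, "log2fc"]
                )
                for key, df in zip(kd_keys, tables)
            }
            for gid in candidates
        }
        calls = classify_targets(
            candidates, rep_consensus, bundle.tads, bundle.genes, evidence
        )
        n_direct = sum(c.klass == "direct" for c in calls)
        n_indirect = sum(c.klass == "indirect" for c in calls)
        n_excluded = sum(c.klass == "excluded" for c in calls)
        if n_direct + n_indirect + n_excluded != len(candidates):
            raise InvariantError(
                "target classes do not partition the candidate genes"
            )
        report.counts["n_candidates"] = len(candidates)
        report.counts["n_direct"] = n_direct
        report.counts["n_indirect"] = n_indirect
        report.counts["n_excluded"] = n_excluded
        write_target_calls(
            calls, outdir / "target_calls.tsv", outdir / "target_calls.json"
        )

    with _Stage("enrichment"):
        merged = tables[0][["gene_id", "log2fc"]].merge(
            tables[1][["gene_id", "log2fc"]], on="gene_id", suffixes=("_a", "_b")
        )
        merged["score"] = (merged["log2fc_a"] + merged["log2fc_b"]) / 2.0
        merged = merged.sort_values("score", ascending=False, kind="stable")
        ranked = list(zip(merged["gene_id"], merged["score"]))
        results = preranked_enrichment_multi(
            ranked, bundle.gene_sets, config.weight_p, config.n_perm, config.seed
        )
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("gene_set\tes\tnes\tnominal_p\tfdr_q\tn_leading_edge\n")
            for r in sorted(results, key=lambda r: r.name):
                fh.write(
                    f"{r.name}\t{r.es:.17g}\t{r.nes:.17g}\t{r.nominal_p:.17g}"
                    f"\t{r.fdr_q:.17g}\t{len(r.leading_edge)}\n"
                )
        for r in results:
            if r.name == myogenic.name:
                report.values["myogenic_es"] = r.es
                report.values["myogenic_nes"] = r.nes
                report.values["myogenic_nominal_p"] = r.nominal_p

    report.runtime_seconds = time.monotonic() - t0
    report.to_json(outdir / "report.json")
    report.write_summary_tsv(outdir / "summary.tsv")
    return report
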