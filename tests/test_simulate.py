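"""Determinism and planted structure of the synthetic-data generator."""

import numpy as np
import pytest

from tadtargets import (
    SimulationConfig,
    consensus_peaks,
    delta_track,
    merge_intervals,
    normalize_track,
    read_fixture_bundle,
    simulate_bundle,
    simulate_expression,
    simulate_genome,
    simulate_peaksets,
    simulate_tracks,
    write_fixture_bundle,
)
from tadtargets.intervals import GenomicInterval


def small_config(**overrides):
    base = dict(
        n_chrom=2, chrom_length=500_000, n_tads=8, genes_per_tad=5,
        n_direct=6, n_indirect=10, n_null=24,
        n_repressor_peaks=40, n_activator_peaks=80, n_super_sites=4,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestGenome:
    def test_deterministic_given_seed(self):
        a = simulate_genome(small_config())
        b = simulate_genome(small_config())
        assert a[0] == b[0] and a[1].tads == b[1].tads and a[2] == b[2]

    def test_single_tad_holds_every_gene(self):
        cfg = small_config(
            n_chrom=1, n_tads=1, genes_per_tad=20,
            n_direct=0, n_indirect=0, n_null=20,
            gap_fraction=0.0,
        )
        _, tads, genes = simulate_genome(cfg)
        (tad,) = tads.tads
        assert all(tads.find(g.chrom, g.tss) == tad.tad_id for g in genes)

    def test_gap_fraction_accounting(self):
        cfg = small_config(gap_fraction=0.2)
        chrom_lengths, tads, _ = simulate_genome(cfg)
        genome_bp = sum(chrom_lengths.values())
        tad_bp = sum(t.interval.length for t in tads)
        assert tad_bp == pytest.approx(0.8 * genome_bp, rel=0.05)

    def test_class_counts_must_match_gene_count(self):
        with pytest.raises(ValueError, match="must equal"):
            simulate_genome(small_config(n_null=23))

    def test_infeasible_tad_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(
                small_config(
                    n_chrom=1, chrom_length=100_000, n_tads=8,
                    genes_per_tad=5, n_direct=0, n_indirect=0, n_null=40,
                )
            )


class TestPeaksets:
    def test_full_reproducibility_recovers_master_list(self):
        cfg = small_config(reproducibility=1.0)
        genome = simulate_genome(cfg)
        peaksets, truth = simulate_peaksets(cfg, genome)
        sets = [peaksets[cl]["repressor"] for cl in cfg.cell_lines]
        cons = consensus_peaks(sets, k=len(sets))
        master = merge_intervals(
            [
                GenomicInterval(r["chrom"], r["start"], r["end"])
                for r in truth.repressor_peaks
            ],
            0,
        )
        assert [p.interval for p in cons] == master

    def test_zero_reproducibility_gives_empty_consensus(self):
        # no direct genes -> no guaranteed peaks forced into >= 2 lines
        cfg = small_config(
            reproducibility=0.0, n_direct=0, n_indirect=10, n_null=30
        )
        genome = simulate_genome(cfg)
        peaksets, _ = simulate_peaksets(cfg, genome)
        sets = [peaksets[cl]["repressor"] for cl in cfg.cell_lines]
        assert len(consensus_peaks(sets, k=2)) == 0

    def test_shared_fraction_accounting(self):
        cfg = SimulationConfig(shared_fraction=0.6)
        genome = simulate_genome(cfg)
        _, truth = simulate_peaksets(cfg, genome)
        observed = np.mean([r["shared"] for r in truth.repressor_peaks])
        assert abs(observed - 0.6) <= 0.05

    def test_planted_invariants_hold(self, bundle):
        bundle.truth.validate(bundle.tads, bundle.genes)
        free = set(bundle.truth.free_tads)
        for rec in bundle.truth.repressor_peaks:
            mid = (rec["start"] + rec["end"]) // 2
            assert bundle.tads.find(rec["chrom"], mid) not in free


class TestTracks:
    def test_unit_knockdown_factor_gives_identical_tracks(self):
        cfg = small_config(knockdown_factor=1.0, activator_gain=1.0)
        genome = simulate_genome(cfg)
        _, truth = simulate_peaksets(cfg, genome)
        tracks, _ = simulate_tracks(cfg, genome, truth)
        assert tracks["repressor_control"] == tracks["repressor_knockdown"]
        assert tracks["activator_control"] == tracks["activator_knockdown"]

    def test_planted_delta_effect_at_shared_peaks(self, bundle):
        """Activator deposition rises on knockdown specifically where the
        repressor co-binds: mean delta at shared peaks exceeds the mean at
        activator-only peaks."""
        ctrl = normalize_track(
            bundle.tracks["activator_control"],
            bundle.norm_factors["activator_control"], "RRPM",
        )
        kd = normalize_track(
            bundle.tracks["activator_knockdown"],
            bundle.norm_factors["activator_knockdown"], "RRPM",
        )
        delta = delta_track(kd, ctrl)
        shared, only = [], []
        for rec in bundle.truth.activator_peaks:
            iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"])
            (shared if rec["shared"] else only).append(delta.region_mean(iv))
        assert np.mean(shared) > np.mean(only)

    def test_spikein_counts_positive_with_cohort_min_reference(self, bundle):
        ref = min(f.spikein_reads for f in bundle.norm_factors.values())
        for f in bundle.norm_factors.values():
            assert f.spikein_reads > 0
            assert f.reference_spikein == ref


class TestExpression:
    def test_zero_sigma_gives_exact_effect_sizes(self):
        cfg = small_config(de_sigma=0.0)
        genome = simulate_genome(cfg)
        _, truth = simulate_peaksets(cfg, genome)
        tables = simulate_expression(cfg, genome, truth)
        for df in tables.values():
            up = df["gene_id"].map(
                lambda g: truth.gene_class[g] in ("direct", "indirect")
            )
            assert (df.loc[up, "log2fc"] == cfg.l2fc_mean).all()
            assert (df.loc[~up, "log2fc"] == 0.0).all()

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        genome = simulate_genome(cfg)
        _, truth = simulate_peaksets(cfg, genome)
        a = simulate_expression(cfg, genome, truth)
        b = simulate_expression(cfg, genome, truth)
        assert all(a[k].equals(b[k]) for k in a)


class TestBundleIO:
    def test_round_trip_is_lossless(self, bundle, bundle_dir):
        back = read_fixture_bundle(bundle_dir)
        assert back.config == bundle.config
        assert back.chrom_lengths == bundle.chrom_lengths
        assert back.tads.tads == bundle.tads.tads
        assert back.genes == bundle.genes
        assert back.peaksets == bundle.peaksets
        assert back.truth == bundle.truth
        assert back.tracks == bundle.tracks
        assert back.norm_factors == bundle.norm_factors
        assert back.gene_sets == bundle.gene_sets
        assert all(
            back.expression[k].equals(bundle.expression[k])
            for k in bundle.expression
        )

    def test_truth_classes_partition_gene_list(self, bundle):
        assert set(bundle.truth.gene_class) == {g.gene_id for g in bundle.genes}

    def test_regenerated_bundle_is_byte_identical(self, bundle_dir, tmp_path):
        import filecmp

        cfg = SimulationConfig.from_yaml(bundle_dir / "config.yaml")
        other = tmp_path / "bundle2"
        write_fixture_bundle(simulate_bundle(cfg), other)
        cmp = filecmp.dircmp(bundle_dir, other)

        def assert_same(c):
            assert not c.diff_files and not c.left_only and not c.right_only
            for sub in c.subdirs.values():
                assert_same(sub)

        assert_same(cmp)
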