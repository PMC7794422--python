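"""BH correction, upregulation filtering, correlations, ddCt and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_bh, brute_es
from tadtargets import (
    GeneSet,
    benjamini_hochberg,
    consistent_upregulated,
    ddct_fold_change,
    pearson_by_group,
    preranked_enrichment,
    preranked_enrichment_multi,
    read_gmt,
    write_gmt,
)


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "fdr"])


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.07], [0.07]),
        ],
    )
    def test_examples(self, p, expected):
        assert benjamini_hochberg(p).tolist() == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_matches_quadratic_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 40)))
            got = benjamini_hochberg(p)
            assert np.max(np.abs(got - np.array(brute_bh(p)))) < 1e-12


class TestConsistentUpregulated:
    def tables(self, rows_a, rows_b):
        return [de_table(rows_a), de_table(rows_b)]

    def test_up_in_both_included(self):
        t = self.tables(
            [("g", 1.0, 0.001, 0.01)], [("g", 0.8, 0.002, 0.01)]
        )
        assert consistent_upregulated(t) == ["g"]

    def test_discordant_direction_excluded(self):
        t = self.tables(
            [("g", 1.0, 0.001, 0.01)], [("g", -0.5, 0.002, 0.01)]
        )
        assert consistent_upregulated(t) == []

    def test_boundary_fdr_strictly_excluded(self):
        t = self.tables(
            [("g", 1.0, 0.01, 0.05)], [("g", 1.0, 0.01, 0.01)]
        )
        assert consistent_upregulated(t, fdr_max=0.05) == []

    def test_universe_intersection(self):
        t = self.tables(
            [("g", 1.0, 0.001, 0.01), ("h", 1.0, 0.001, 0.01)],
            [("g", 1.0, 0.001, 0.01), ("h", 1.0, 0.001, 0.01)],
        )
        assert consistent_upregulated(t, universe=GeneSet("u", {"h"})) == ["h"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            consistent_upregulated([de_table([]), de_table([])])

    def test_antitone_in_thresholds(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"g{i}", float(rng.normal(0.5, 1)), 0.0, float(rng.random()))
            for i in range(200)
        ]
        t = self.tables(rows, rows)
        loose = set(consistent_upregulated(t, l2fc_min=0.0, fdr_max=0.5))
        tight_fc = set(consistent_upregulated(t, l2fc_min=1.0, fdr_max=0.5))
        tight_fdr = set(consistent_upregulated(t, l2fc_min=0.0, fdr_max=0.1))
        assert tight_fc <= loose and tight_fdr <= loose


class TestPearson:
    def expr(self, a, b):
        cols = [f"s{i}" for i in range(len(a))]
        return pd.DataFrame([a, b], index=["ga", "gb"], columns=cols)

    def test_affine_relation_r_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        e = self.expr(a, [2 * x + 1 for x in a])
        (res,) = pearson_by_group(e, "ga", "gb", {c: "all" for c in e.columns})
        assert res.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_r_minus_one(self):
        a = [1.0, 2.0, 3.0]
        e = self.expr(a, [-x for x in a])
        (res,) = pearson_by_group(e, "ga", "gb", {c: "all" for c in e.columns})
        assert res.pearson_r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(5), rng.random(5)
        e = self.expr(a, b)
        (res,) = pearson_by_group(e, "ga", "gb", {c: "g" for c in e.columns})
        r_direct = np.cov(a, b, bias=True)[0, 1] / (np.std(a) * np.std(b))
        assert abs(res.pearson_r - r_direct) < 1e-12
        t = res.pearson_r * np.sqrt(3 / (1 - res.pearson_r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=3))

    def test_zero_variance_reported_as_nan(self):
        e = self.expr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        (res,) = pearson_by_group(e, "ga", "gb", {c: "g" for c in e.columns})
        assert np.isnan(res.pearson_r)

    def test_small_group_rejected(self):
        e = self.expr([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="n=2"):
            pearson_by_group(e, "ga", "gb", {c: "g" for c in e.columns})


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20.0, 20.0, 20.0, 20.0), 1.0),
            ((19.0, 20.0, 20.0, 20.0), 2.0),
            ((20.0, 15.0, 22.0, 15.0), 4.0),
        ],
    )
    def test_examples(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(float("nan"), 1, 1, 1)


class TestEnrichment:
    def ranked(self, n, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        return [(f"g{i}", float(s)) for i, s in enumerate(scores)]

    def test_top_gene_unweighted_es_one(self):
        r = self.ranked(4)
        res = preranked_enrichment(r, GeneSet("s", {"g0"}), weight_p=0, n_perm=10)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_bottom_gene_unweighted_es_minus_one(self):
        r = self.ranked(4)
        res = preranked_enrichment(r, GeneSet("s", {"g3"}), weight_p=0, n_perm=10)
        assert res.es == pytest.approx(-1.0)
        assert res.leading_edge == ["g3"]

    def test_degenerate_sets_rejected(self):
        r = self.ranked(5)
        with pytest.raises(ValueError):
            preranked_enrichment(r, GeneSet("s", {f"g{i}" for i in range(5)}))
        with pytest.raises(ValueError):
            preranked_enrichment(r, GeneSet("s", {"absent"}))

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_matches_stepwise_oracle(self, weight_p):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            r = self.ranked(n, seed=int(rng.integers(1e6)))
            k = int(rng.integers(1, n))
            members = set(
                np.random.default_rng(int(rng.integers(1e6)))
                .choice([g for g, _ in r], size=k, replace=False)
                .tolist()
            )
            res = preranked_enrichment(r, GeneSet("s", members), weight_p, n_perm=2)
            genes = [g for g, _ in r]
            scores = [s for _, s in r]
            assert abs(res.es - brute_es(genes, scores, members, weight_p)) < 1e-12

    def test_es_bounded(self):
        r = self.ranked(50, seed=9)
        res = preranked_enrichment(r, GeneSet("s", {"g3", "g40", "g17"}), n_perm=50)
        assert -1.0 <= res.es <= 1.0
        assert res.nominal_p >= 1 / 50

    def test_multi_set_fdr_present(self):
        r = self.ranked(60, seed=10)
        sets = [
            GeneSet("top", {f"g{i}" for i in range(8)}),
            GeneSet("rand", {"g5", "g25", "g45", "g55"}),
        ]
        results = preranked_enrichment_multi(r, sets, n_perm=200, seed=4)
        top = next(x for x in results if x.name == "top")
        rand = next(x for x in results if x.name == "rand")
        assert top.fdr_q <= rand.fdr_q
        assert 0.0 <= top.fdr_q <= 1.0


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("a", {"g1", "g2"}), GeneSet("b", {"g3"})]
        write_gmt(sets, tmp_path / "x.gmt")
        assert read_gmt(tmp_path / "x.gmt") == sets


class TestContrastConcordance:
    def test_direct_targets_up_in_both_contrasts_and_correlated(self, bundle):
        """Knockdown and treatment contrasts agree on planted target genes:
        both upregulate them, and per-gene fold changes correlate positively."""
        kd = bundle.expression["CL1.knockdown"].set_index("gene_id")
        tr = bundle.expression["CL1.treatment"].set_index("gene_id")
        direct = [g for g, k in bundle.truth.gene_class.items() if k == "direct"]
        null = [g for g, k in bundle.truth.gene_class.items() if k == "null"]
        assert kd.loc[direct, "log2fc"].median() > kd.loc[null, "log2fc"].median()
        assert tr.loc[direct, "log2fc"].median() > tr.loc[null, "log2fc"].median()
        r = np.corrcoef(kd["log2fc"], tr.loc[kd.index, "log2fc"])[0, 1]
        assert r > 0
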