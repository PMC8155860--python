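"""Correlation, BH step-up, filter chain and the report table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import mirpair as mp
from conftest import toy_pair_set


def independent_bh(p):
    """Hand-rolled step-up, separate from the package implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_hand_executed_step_up(self, p, expected):
        np.testing.assert_allclose(mp.bh_adjust(p), expected)

    def test_empty_input(self):
        assert mp.bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mp.bh_adjust([0.5, 1.2])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_independent_and_statsmodels_oracles(self, seed, size):
        p = np.random.default_rng(seed).random(size)
        adj = mp.bh_adjust(p)
        np.testing.assert_allclose(adj, independent_bh(p), rtol=1e-12)
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    def test_never_decreases_p(self, rng):
        p = rng.random(500)
        assert (mp.bh_adjust(p) >= p - 1e-15).all()


class TestCorrelateAllPairs:
    def test_negated_vector_gives_r_minus_one_p_zero(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]], index=["mir1"])
        y = pd.DataFrame([[-1.0, -2.0, -3.0, -4.0, -5.0, -6.0, -7.0]], index=["g1"])
        rec = mp.correlate_all_pairs(x, y)
        assert rec.loc[0, "cor"] == pytest.approx(-1.0)
        assert rec.loc[0, "p_value"] == 0.0

    def test_matches_closed_form_and_scipy(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 7)), index=[f"mir{i}" for i in range(5)])
        y = pd.DataFrame(rng.normal(size=(8, 7)), index=[f"g{i}" for i in range(8)])
        rec = mp.correlate_all_pairs(x, y)
        n = 7
        for _, row in rec.iterrows():
            r_ref, p_ref = stats.pearsonr(x.loc[row["mirna_id"]], y.loc[row["mrna_id"]])
            assert row["cor"] == pytest.approx(r_ref, abs=1e-12)
            t = r_ref * np.sqrt(n - 2) / np.sqrt(1 - r_ref**2)
            p_closed = 2 * stats.t.sf(abs(t), n - 2)
            assert row["p_value"] == pytest.approx(p_closed, rel=1e-10)
            assert row["p_value"] == pytest.approx(p_ref, rel=1e-8)

    def test_symmetry_in_arguments(self, rng):
        x = pd.DataFrame(rng.normal(size=(1, 7)), index=["a"])
        y = pd.DataFrame(rng.normal(size=(1, 7)), index=["b"])
        fwd = mp.correlate_all_pairs(x, y)
        rev = mp.correlate_all_pairs(y, x)
        assert fwd.loc[0, "cor"] == pytest.approx(rev.loc[0, "cor"])
        assert fwd.loc[0, "p_value"] == pytest.approx(rev.loc[0, "p_value"])

    def test_candidate_count_is_product_of_de_universes(self, default_sim):
        dataset, truth, _, _ = default_sim
        rec = mp.correlate_all_pairs(
            dataset.mirna.loc[sorted(truth.de_mirnas)],
            dataset.mrna.loc[sorted(truth.de_mrnas)],
        )
        assert len(rec) == 75 * 562 == 42_150

    def test_zero_variance_feature_dropped_with_warning(self, rng, caplog):
        x = pd.DataFrame([[2.0] * 7, list(range(7))], index=["flat", "ok"], dtype=float)
        y = pd.DataFrame(rng.normal(size=(2, 7)), index=["g1", "g2"])
        with caplog.at_level("WARNING", logger="mirpair"):
            rec = mp.correlate_all_pairs(x, y)
        assert set(rec["mirna_id"]) == {"ok"}
        assert "zero-variance" in caplog.text

    def test_sample_mismatch_raises(self, rng):
        x = pd.DataFrame(rng.normal(size=(1, 7)), columns=list("abcdefg"))
        y = pd.DataFrame(rng.normal(size=(1, 7)), columns=list("abcdefh"))
        with pytest.raises(ValueError, match="sample mismatch"):
            mp.correlate_all_pairs(x, y)


class TestFilterChain:
    def test_empty_input_empty_output(self):
        ps = mp.PairSet(
            pd.DataFrame(columns=["mirna_id", "mrna_id", "cor", "p_value", "adj_p"]),
            {"total_candidates": 0},
        )
        out = mp.filter_pairs(ps)
        assert len(out) == 0
        assert out.counters["n_negative"] == 0
        assert out.counters["n_significant_negative"] == 0

    def test_stricter_alpha_gives_subset(self, small_pair_chain):
        # refilter the raw candidates at two alphas
        dataset, truth, dbs, de_mi, de_mr, _ = small_pair_chain
        sel_mi = mp.select_significant(de_mi)
        sel_mr = mp.select_significant(de_mr)
        raw = mp.correlate_all_pairs(
            dataset.mirna.loc[sel_mi["feature_id"]], dataset.mrna.loc[sel_mr["feature_id"]]
        )
        raw["adj_p"] = mp.bh_adjust(raw["p_value"].to_numpy())
        ps = mp.PairSet(raw, {"total_candidates": len(raw)})
        strict = mp.filter_pairs(ps, alpha=0.01).pair_keys()
        loose = mp.filter_pairs(ps, alpha=0.05).pair_keys()
        assert strict <= loose

    def test_counter_funnel_weakly_decreasing(self, small_pair_chain):
        *_, pair_set = small_pair_chain
        c = pair_set.counters
        assert (
            c["total_candidates"]
            >= c["n_negative"]
            >= c["n_significant_negative"]
            >= c["n_predicted_intersection"]
            == len(pair_set)
        )

    def test_noiseless_planted_pairs_all_retained(self):
        """With zero noise every planted coupling survives the full chain."""
        config = mp.scaled_config(seed=9, noise_sd=0.0, db_coverage=1.0)
        dataset, truth, dbs, _ = mp.generate_dataset(config)
        mi_ids = sorted(truth.de_mirnas)
        mr_ids = sorted(truth.de_mrnas)
        de_mi = mp.differential_expression(dataset.mirna.loc[mi_ids], dataset.groups, "plain")
        de_mr = mp.differential_expression(dataset.mrna.loc[mr_ids], dataset.groups, "plain")
        ps = mp.infer_pairs(
            dataset.mirna.loc[mi_ids], dataset.mrna.loc[mr_ids], de_mi, de_mr, dbs
        )
        assert set(truth.planted_pairs) <= ps.pair_keys()


class TestAnnotatePredictions:
    def make_set(self):
        return toy_pair_set(
            [("mir1", "g1"), ("mir1", "g2"), ("mir2", "g1")],
            cor=[-0.9, -0.8, -0.7], adj_p=[0.01, 0.02, 0.03],
        )

    def test_membership_counts_match_brute_force(self):
        dbs = [
            mp.PredictionDB("d1", frozenset({("mir1", "g1"), ("mir2", "g1")})),
            mp.PredictionDB("d2", frozenset({("mir1", "g1")})),
            mp.PredictionDB("d3", frozenset({("mir9", "g9")})),
        ]
        out = mp.annotate_predictions(self.make_set(), dbs, min_dbs=1)
        counts = dict(zip(zip(out.records["mirna_id"], out.records["mrna_id"]),
                          out.records["dat_sum"]))
        assert counts == {("mir1", "g1"): 2, ("mir2", "g1"): 1}
        assert set(counts.values()) <= {1, 2, 3}

    def test_unlisted_pair_excluded_at_min_dbs_one(self):
        dbs = [mp.PredictionDB("d1", frozenset({("mir1", "g1")}))]
        out = mp.annotate_predictions(self.make_set(), dbs, min_dbs=1)
        assert ("mir1", "g2") not in out.pair_keys()

    def test_empty_database_list_rejected(self):
        with pytest.raises(ValueError, match="database"):
            mp.annotate_predictions(self.make_set(), [])


class TestPairTable:
    def test_header_matches_report_schema(self, small_pair_chain):
        *_, pair_set = small_pair_chain
        table = mp.build_pair_table(pair_set)
        assert list(table.columns) == [
            "miRNA", "mRNA", "Cor", "Adj.pval", "FC.miRNA", "FC.mRNA", "Dat.Sum",
        ]

    def test_tie_breaks(self):
        ps = toy_pair_set(
            [("mirB", "g1"), ("mirA", "g1"), ("mirA", "g0")],
            cor=[-0.5, -0.9, -0.9],
            adj_p=[0.01, 0.01, 0.01],
            fc_mirna=[2.0, 2.0, 2.0],
            fc_mrna=[-2.0, -2.0, -2.0],
            dat_sum=[1, 1, 1],
        )
        table = mp.build_pair_table(ps)
        # equal adj_p: higher |cor| first; equal |cor|: lexicographic
        assert list(zip(table["miRNA"], table["mRNA"])) == [
            ("mirA", "g0"), ("mirA", "g1"), ("mirB", "g1"),
        ]

    def test_sorted_by_adjusted_p(self, small_pair_chain):
        *_, pair_set = small_pair_chain
        adj = mp.build_pair_table(pair_set)["Adj.pval"].astype(float)
        assert (adj.diff().dropna() >= 0).all()
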