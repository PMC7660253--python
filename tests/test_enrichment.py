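import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from karyoshift import enrichment as enr
from karyoshift import synthetic_data as syn
from karyoshift.io_model import (
    ComplexMembership,
    ExpressionFlags,
    InteractionTable,
)
from oracles import exact_mean_distribution, naive_average_linkage_leaves


def _gi(rows):
    return InteractionTable(
        rows=pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]),
        kind="genetic",
    )


def _pi(rows):
    return InteractionTable(
        rows=pd.DataFrame(rows, columns=["gene_a", "gene_b"]), kind="physical"
    )


class TestGeneFeatureVector:
    def test_physical_partition_counts(self, toy_genome):
        # g1 on chrA pairs with g2 (chrA) and g4 (chrB); g4 also pairs g3
        pi = _pi([("g1", "g2"), ("g1", "g4"), ("g3", "g4")])
        intra = enr.gene_feature_vector(
            toy_genome, pi, enr.FeatureSpec("PI_intra", "physical", "intra")
        )
        inter = enr.gene_feature_vector(
            toy_genome, pi, enr.FeatureSpec("PI_inter", "physical", "inter")
        )
        total = enr.gene_feature_vector(
            toy_genome, pi, enr.FeatureSpec("PI_mean", "physical")
        )
        assert intra["g1"] == 1 and inter["g1"] == 1 and total["g1"] == 2
        assert inter["g4"] == 2 and intra["g4"] == 0

    def test_genetic_sign_filters(self, toy_genome):
        gi = _gi([("g1", "g2", 0.2), ("g1", "g3", -0.1)])
        pos = enr.gene_feature_vector(
            toy_genome, gi, enr.FeatureSpec("GI_pos", "genetic", sign="pos")
        )
        neg = enr.gene_feature_vector(
            toy_genome, gi, enr.FeatureSpec("GI_neg", "genetic", sign="neg")
        )
        allv = enr.gene_feature_vector(
            toy_genome, gi, enr.FeatureSpec("GI", "genetic")
        )
        assert pos["g1"] == 1 and neg["g1"] == 1 and allv["g1"] == 2

    def test_empty_source_all_zero(self, toy_genome):
        vec = enr.gene_feature_vector(
            toy_genome, _gi([]), enr.FeatureSpec("GI", "genetic")
        )
        assert (vec == 0).all() and len(vec) == 4

    def test_unknown_gene_logged_and_ignored(self, toy_genome, caplog):
        gi = _gi([("g1", "gX", 0.5), ("g1", "g2", 0.5)])
        with caplog.at_level(logging.INFO, logger="karyoshift.enrichment"):
            vec = enr.gene_feature_vector(
                toy_genome, gi, enr.FeatureSpec("GI", "genetic")
            )
        assert vec["g1"] == 1
        assert "absent from the genome map" in caplog.text

    def test_complex_membership_indicator(self, toy_genome):
        cm = ComplexMembership(
            rows=pd.DataFrame({"gene": ["g2", "g4"], "complex": ["C1", "C1"]})
        )
        vec = enr.gene_feature_vector(
            toy_genome, cm, enr.FeatureSpec("Complex_member", "complex")
        )
        assert vec.to_dict() == {"g1": 0, "g2": 1, "g3": 0, "g4": 1}

    def test_expression_condition_selected(self, toy_genome):
        ef = ExpressionFlags(
            rows=pd.DataFrame(
                {"gene": ["g1", "g1"], "condition": ["GLY", "ETOH"],
                 "flag": [1, 0]}
            )
        )
        gly = enr.gene_feature_vector(
            toy_genome, ef, enr.FeatureSpec("Expr_GLY", "expression",
                                            condition="GLY")
        )
        assert gly["g1"] == 1 and gly["g2"] == 0


class TestBootstrapNull:
    def test_constant_vector_degenerate(self):
        null = enr.bootstrap_null(np.full(10, 3.0), 4, reps=100, seed=0)
        assert null.null_mean == pytest.approx(3.0)
        assert null.null_sd == 0.0

    def test_exhaustive_draw_equals_global_mean(self):
        vals = np.arange(8, dtype=float)
        null = enr.bootstrap_null(vals, 8, reps=50, seed=0)
        assert null.null_sd == 0.0
        assert null.null_mean == pytest.approx(vals.mean())

    def test_hypergeometric_toy_matches_exact_enumeration(self):
        # universe {0,0,1,1}, draws of 2: mean in {0, .5, 1} with exact
        # probabilities {1/6, 4/6, 1/6}
        vals = np.array([0.0, 0.0, 1.0, 1.0])
        exact = exact_mean_distribution(vals, 2)
        null = enr.bootstrap_null(vals, 2, reps=10_000, seed=13)
        for mean_val, prob in exact.items():
            observed = np.mean(null.samples == mean_val)
            p = float(prob)
            mc_sd = np.sqrt(p * (1 - p) / 10_000)
            assert abs(observed - p) < 4 * mc_sd

    def test_draws_are_without_replacement(self):
        # with values = 2^i every subset sum is unique and valid subsets
        # (no repeats) are exactly the k-combinations
        vals = 2.0 ** np.arange(10)
        k = 4
        valid = {sum(c) / k for c in itertools.combinations(vals, k)}
        null = enr.bootstrap_null(vals, k, reps=2000, seed=3)
        assert set(np.round(null.samples, 9)) <= {round(v, 9) for v in valid}

    def test_oversized_set_fatal(self):
        with pytest.raises(ValueError, match="exceeds"):
            enr.bootstrap_null(np.ones(3), 4, reps=10)


class TestCdfValue:
    def test_at_null_mean_is_half(self):
        null = enr.NullDistribution(100, 5, null_mean=2.0, null_sd=1.0)
        assert enr.cdf_value(2.0, null) == pytest.approx(0.5)

    def test_two_sd_above_matches_standard_normal(self):
        null = enr.NullDistribution(100, 5, null_mean=10.0, null_sd=2.0)
        assert enr.cdf_value(14.0, null) == pytest.approx(0.97725, abs=1e-5)

    def test_degenerate_null_rules(self):
        null = enr.NullDistribution(100, 5, null_mean=1.0, null_sd=0.0)
        assert enr.cdf_value(1.0, null) == 0.5
        assert enr.cdf_value(2.0, null) == 1.0
        assert enr.cdf_value(0.0, null) == 0.0

    def test_empirical_midpoint_tie_correction(self):
        null = enr.NullDistribution(
            4, 2, null_mean=0.5, null_sd=0.1,
            samples=np.array([0.0, 0.5, 0.5, 1.0]),
        )
        assert enr.cdf_value(0.5, null, method="empirical") == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        actuals=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=2, max_size=6
        ),
        method=st.sampled_from(["normal", "empirical"]),
    )
    def test_cdf_monotone_in_observed_mean_and_bounded(self, actuals, method):
        rng = np.random.default_rng(42)
        null = enr.NullDistribution(
            200, 10, null_mean=0.0, null_sd=3.0,
            samples=rng.normal(0.0, 3.0, size=200),
        )
        cdfs = [enr.cdf_value(a, null, method) for a in sorted(actuals)]
        assert all(0.0 <= c <= 1.0 for c in cdfs)
        assert all(a <= b for a, b in zip(cdfs, cdfs[1:]))

    def test_normal_and_empirical_agree_on_smooth_null(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(3, size=400).astype(float)
        null = enr.bootstrap_null(vals, 60, reps=20_000, seed=7)
        for actual in (vals.mean() - 0.1, vals.mean(), vals.mean() + 0.15):
            a = enr.cdf_value(actual, null, "normal")
            b = enr.cdf_value(actual, null, "empirical")
            assert a == pytest.approx(b, abs=0.02)


def _toy_sources(gm, cfg):
    return {
        "genetic": syn.simulate_interaction_table(gm, cfg, "genetic"),
        "physical": syn.simulate_interaction_table(gm, cfg, "physical"),
        "complex": syn.simulate_complex_membership(gm, cfg),
        "expression": syn.simulate_expression_flags(gm, cfg),
    }


class TestEnrichmentMatrix:
    def test_planted_expression_enrichment_detected(self):
        cfg = syn.SimulationConfig(
            seed=2, chromosome_lengths=[100_000] * 4, genes_per_100kb=500,
            expression_base_prob=0.1,
            planted_enriched_chromosomes={"ETOH": (["chr03"], 3.0)},
        )
        gm = syn.simulate_genome_map(cfg)
        ef = syn.simulate_expression_flags(gm, cfg)
        wide, _ = enr.enrichment_matrix(
            gm, {"expression": ef},
            specs=[enr.FeatureSpec("Expr_ETOH", "expression", condition="ETOH")],
            reps=2000, seed=4,
        )
        assert wide.loc["chr03", "Expr_ETOH"] > 0.99

    def test_degenerate_null_all_flags_one_gives_half(self):
        cfg = syn.SimulationConfig(
            seed=1, chromosome_lengths=[50_000, 50_000], genes_per_100kb=40,
            expression_base_prob=1.0,
        )
        gm = syn.simulate_genome_map(cfg)
        ef = syn.simulate_expression_flags(gm, cfg)
        wide, _ = enr.enrichment_matrix(
            gm, {"expression": ef},
            specs=[enr.FeatureSpec("Expr_GLY", "expression", condition="GLY")],
            reps=200, seed=4,
        )
        assert (wide["Expr_GLY"] == 0.5).all()

    def test_sum_and_mean_statistics_identical_rep_for_rep(self):
        cfg = syn.SimulationConfig(
            seed=3, chromosome_lengths=[80_000, 60_000, 40_000],
            genes_per_100kb=40,
        )
        gm = syn.simulate_genome_map(cfg)
        sources = _toy_sources(gm, cfg)
        a, la = enr.enrichment_matrix(gm, sources, reps=500, seed=11,
                                      statistic="mean")
        b, lb = enr.enrichment_matrix(gm, sources, reps=500, seed=11,
                                      statistic="sum")
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(la["cdf"], lb["cdf"])

    def test_duplicated_feature_columns_identical_under_shared_seed(self):
        cfg = syn.SimulationConfig(
            seed=5, chromosome_lengths=[50_000, 50_000], genes_per_100kb=40
        )
        gm = syn.simulate_genome_map(cfg)
        ef = syn.simulate_expression_flags(gm, cfg)
        specs = [
            enr.FeatureSpec("Expr_GLY", "expression", condition="GLY"),
            enr.FeatureSpec("Expr_GLY2", "expression", condition="GLY"),
        ]
        # identical feature columns resampled under per-cell substreams of
        # one shared seed: recomputing the matrix reproduces both columns
        w1, _ = enr.enrichment_matrix(gm, {"expression": ef}, specs=specs,
                                      reps=300, seed=9)
        w2, _ = enr.enrichment_matrix(gm, {"expression": ef}, specs=specs,
                                      reps=300, seed=9)
        pd.testing.assert_frame_equal(w1, w2)

    def test_zero_gene_chromosome_flagged_not_dropped(self):
        cfg = syn.SimulationConfig(
            seed=1, chromosome_lengths=[50_000, 40_000], genes_per_100kb=40
        )
        gm = syn.simulate_genome_map(cfg)
        extra = pd.concat(
            [gm.chromosomes,
             pd.DataFrame({"chrom": ["chrEmpty"], "length": [10_000]})],
            ignore_index=True,
        )
        gm2 = type(gm)(chromosomes=extra, genes=gm.genes)
        ef = syn.simulate_expression_flags(gm2, cfg)
        with pytest.warns(UserWarning, match="zero genes"):
            wide, _ = enr.enrichment_matrix(
                gm2, {"expression": ef},
                specs=[enr.FeatureSpec("Expr_GLY", "expression",
                                       condition="GLY")],
                reps=100, seed=2,
            )
        assert "chrEmpty" in wide.index
        assert np.isnan(wide.loc["chrEmpty", "Expr_GLY"])

    def test_missing_source_skipped_with_warning(self, toy_genome):
        ef = ExpressionFlags(
            rows=pd.DataFrame({"gene": ["g1"], "condition": ["GLY"],
                               "flag": [1]})
        )
        with pytest.warns(UserWarning, match="skipped"):
            wide, _ = enr.enrichment_matrix(
                toy_genome, {"expression": ef}, reps=50, seed=0
            )
        assert list(wide.columns) == ["Expr_GLY", "Expr_LAC", "Expr_ETOH",
                                      "Expr_OXD"]


class TestClusterHeatmapOrder:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(0)
        base = rng.random((4, 6))
        base[2] = base[0]
        m = pd.DataFrame(base, index=list("abcd"))
        rows, _ = enr.cluster_heatmap_order(m)
        ia, ic = rows.index("a"), rows.index("c")
        assert abs(ia - ic) == 1

    def test_anticorrelated_rows_maximal_distance(self):
        m = pd.DataFrame([[0, 1, 2.0], [2, 1, 0.0]], index=["u", "v"])
        dist = enr.correlation_distance_matrix(m, axis=0)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_zero_variance_row_assigned_max_distance(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "x"])
        with pytest.warns(UserWarning, match="zero-variance"):
            dist = enr.correlation_distance_matrix(m, axis=0)
        assert dist[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed,shape", [(17, (16, 17)), (1, (8, 10)),
                                            (2, (12, 6))])
    def test_leaf_order_matches_naive_agglomeration_oracle(self, seed, shape):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.random(shape))
        rows, cols = enr.cluster_heatmap_order(m)
        for axis, observed in ((0, rows), (1, cols)):
            dist = enr.correlation_distance_matrix(m, axis=axis)
            labels = m.index if axis == 0 else m.columns
            expected = [labels[i] for i in naive_average_linkage_leaves(dist)]
            assert observed == expected
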