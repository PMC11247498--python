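"""Enrichment, bivariate comparisons and the logistic match model."""

import numpy as np
import pandas as pd
import pytest

from phenomatch.stats import (
    SeparationError,
    category_enrichment,
    compare_counts,
    correlate,
    fit_match_model,
    gene_category_table,
)

from oracles import bh_stepup, fisher_exact_p, wilcoxon_exact_p


def enrichment_table(cells: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """cells: category -> (n_matches, n_non_matches)."""
    rows = []
    for cat, (a, b) in cells.items():
        rows += [{"category": cat, "is_match": True}] * a
        rows += [{"category": cat, "is_match": False}] * b
    return pd.DataFrame(rows)


class TestEnrichment:
    def test_odds_ratio_three(self):
        table = enrichment_table({"endo": (30, 10), "rest": (50, 50)})
        row = category_enrichment(table).set_index("category").loc["endo"]
        assert (row.a, row.b, row.c, row.d) == (30, 10, 50, 50)
        assert row.odds_ratio == pytest.approx(3.0)
        assert row.p_value == pytest.approx(fisher_exact_p(30, 10, 50, 50), rel=1e-9)

    def test_independence_gives_or_one_p_one(self):
        table = enrichment_table({"a": (20, 20), "b": (30, 30)})
        row = category_enrichment(table).set_index("category").loc["a"]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p_value == pytest.approx(1.0)

    def test_infinite_or_when_bc_zero(self):
        table = enrichment_table({"a": (10, 0), "b": (0, 10)})
        row = category_enrichment(table).set_index("category").loc["a"]
        assert row.odds_ratio == np.inf

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            category_enrichment(enrichment_table({"only": (5, 5)}))

    def test_bh_q_values_match_stepup_formula(self):
        rng = np.random.default_rng(3)
        cells = {f"c{i}": (int(rng.integers(5, 40)), int(rng.integers(5, 40)))
                 for i in range(6)}
        out = category_enrichment(enrichment_table(cells))
        expected = bh_stepup(list(out["p_value"]))
        assert np.allclose(out["q_value"], expected, atol=1e-12)
        assert (out["q_value"] <= 1.0 + 1e-12).all()

    def test_bh_hand_example(self):
        assert bh_stepup([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_cells_partition_total(self):
        table = enrichment_table({"a": (7, 3), "b": (4, 6), "c": (1, 9)})
        out = category_enrichment(table)
        assert ((out.a + out.b + out.c + out.d) == len(table)).all()

    def test_fdr_controlled_under_global_null(self):
        # all categories share the same match rate: any rejection is false
        rng = np.random.default_rng(11)
        false_any = 0
        n_sims = 500
        for _ in range(n_sims):
            cats = rng.integers(0, 6, size=300)
            match = rng.random(300) < 0.5
            table = pd.DataFrame({"category": cats, "is_match": match})
            out = category_enrichment(table)
            false_any += int((out["q_value"] < 0.05).any())
        # E[FDP] = P(any rejection) here; BH guarantees <= 0.05, Fisher's
        # discreteness makes it conservative in practice
        assert false_any / n_sims <= 0.05

    def test_gene_category_table_expands_multi_category_genes(self):
        genes = pd.DataFrame({"human_gene": ["G1", "G2"], "is_match": [True, False]})
        diseases = pd.DataFrame(
            {"human_gene": ["G1", "G1", "G2", "G3"],
             "category": ["endo", "neuro", "endo", "skeletal"]}
        )
        out = gene_category_table(genes, diseases)
        assert len(out) == 3  # G3 has no gene-level result
        assert set(out[out.human_gene == "G1"].category) == {"endo", "neuro"}
        assert bool(out[out.human_gene == "G2"].is_match.iloc[0]) is False


class TestCompareCounts:
    def test_identical_samples_give_p_near_one(self):
        assert compare_counts([1, 2, 3, 4], [1, 2, 3, 4]) >= 0.99

    def test_extreme_separation_n3_matches_exhaustive_enumeration(self):
        x, y = [1, 2, 3], [10, 11, 12]
        p = compare_counts(x, y)
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(wilcoxon_exact_p(x, y), abs=1e-12)

    def test_random_small_samples_match_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.integers(0, 30, size=4).tolist()
            y = rng.integers(0, 30, size=5).tolist()
            if len(set(x + y)) < 9:
                continue  # enumeration oracle below is for the tie-free case
            assert compare_counts(x, y) == pytest.approx(
                wilcoxon_exact_p(x, y), abs=1e-9
            )

    def test_large_planted_shift_is_detected(self):
        rng = np.random.default_rng(21)
        x = rng.poisson(8, size=500)
        y = rng.poisson(16, size=500)
        assert compare_counts(x, y) < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_counts([], [1.0])


class TestCorrelate:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert correlate(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_bivariate_normal_recovers_rho(self):
        rng = np.random.default_rng(13)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        assert correlate(x, y) == pytest.approx(0.5, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def simulate_logistic(rng, n, beta0=-0.5, beta=1.0):
    x = rng.standard_normal(n)
    p = 1 / (1 + np.exp(-(beta0 + beta * x)))
    y = rng.random(n) < p
    return pd.DataFrame({"is_match": y.astype(int), "x": x})


class TestMatchModel:
    def test_planted_slope_recovered_at_n5000(self):
        rng = np.random.default_rng(17)
        df = simulate_logistic(rng, 5000, beta=1.0)
        fit = fit_match_model(df, continuous=("x",), binary=(), categorical=None)
        assert fit.params["x"] == pytest.approx(1.0, abs=0.1)
        assert fit.converged
        lo, hi = fit.conf_int.loc["x"]
        assert lo <= fit.params["x"] <= hi

    def test_noise_features_cover_zero_at_nominal_rate(self):
        rng = np.random.default_rng(19)
        covered = np.zeros(2)
        n_reps = 200
        for _ in range(n_reps):
            df = pd.DataFrame(
                {
                    "is_match": rng.integers(0, 2, size=2000),
                    "x1": rng.standard_normal(2000),
                    "x2": rng.standard_normal(2000),
                }
            )
            fit = fit_match_model(df, continuous=("x1", "x2"), binary=())
            for i, feat in enumerate(("x1", "x2")):
                lo, hi = fit.conf_int.loc[feat]
                covered[i] += int(lo <= 0 <= hi)
        assert (covered / n_reps >= 0.90).all()
        assert (covered / n_reps <= 0.99).all()

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(23)
        bias = {}
        for n in (500, 2000, 8000):
            estimates = [
                fit_match_model(
                    simulate_logistic(rng, n, beta=1.0),
                    continuous=("x",), binary=(),
                ).params["x"]
                for _ in range(25)
            ]
            bias[n] = abs(np.mean(estimates) - 1.0)
        assert bias[8000] <= bias[500] + 0.02
        assert bias[8000] <= 0.05

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"is_match": [1, 1, 1], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="single class"):
            fit_match_model(df, continuous=("x",), binary=())

    def test_constant_feature_rejected(self):
        df = pd.DataFrame({"is_match": [0, 1, 0, 1], "x": [2.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            fit_match_model(df, continuous=("x",), binary=())

    def test_complete_separation_is_flagged(self):
        x = np.concatenate([np.full(50, -2.0), np.full(50, 2.0)])
        x += np.random.default_rng(5).normal(0, 0.01, size=100)
        df = pd.DataFrame({"is_match": (x > 0).astype(int), "x": x})
        with pytest.raises(SeparationError):
            fit_match_model(df, continuous=("x",), binary=())

    def test_categorical_contrasts_against_reference(self):
        rng = np.random.default_rng(29)
        cat = rng.choice(["a", "b", "c"], size=3000)
        eta = np.where(cat == "b", 1.0, 0.0)
        y = rng.random(3000) < 1 / (1 + np.exp(-(-0.5 + eta)))
        df = pd.DataFrame({"is_match": y.astype(int), "cat": cat})
        fit = fit_match_model(
            df, continuous=(), binary=(), categorical={"cat": "a"}
        )
        assert "cat[a]" not in fit.params.index
        assert fit.params["cat[b]"] == pytest.approx(1.0, abs=0.35)
        assert abs(fit.params["cat[c]"]) < 0.35

    def test_summary_lists_every_feature(self):
        rng = np.random.default_rng(31)
        df = simulate_logistic(rng, 500)
        fit = fit_match_model(df, continuous=("x",), binary=())
        text = fit.summary()
        assert "x" in text and "intercept" in text
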