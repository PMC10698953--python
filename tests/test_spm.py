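import numpy as np
import pandas as pd
import pytest

from kidneymorph import (
    DesignMatrix,
    add_interactions,
    bh_fdr,
    build_design,
    fit_mur,
    interaction_rate_map,
    run_spm,
    standardise,
    summarise_spm,
    unstandardise,
)
from kidneymorph.spm import VertexStats


def bh_oracle(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestStandardise:
    def test_hand_example_population_sd(self):
        out, rec = standardise(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.ravel(), [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert rec[0] == pytest.approx((2.0, 0.8164965), abs=1e-6)

    def test_idempotent(self, rng):
        x = rng.normal(5, 2, 100)
        once, _ = standardise(x)
        twice, _ = standardise(once.ravel())
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            standardise(np.ones(10))

    def test_binary_columns_pass_through_in_design(self):
        df = pd.DataFrame({"age": [50.0, 60, 70, 55], "flag": [0, 1, 0, 1]})
        dm = build_design(df, continuous=["age"], binary=["flag"])
        np.testing.assert_array_equal(dm.column("flag"), [0, 1, 0, 1])
        assert dm.column("age").std() == pytest.approx(1.0)


class TestFitMur:
    def test_exact_line_single_vertex(self):
        X = DesignMatrix(
            np.column_stack([np.ones(3), [-1.0, 0.0, 1.0]]), ["intercept", "x"]
        )
        fit = fit_mur(np.array([[-2.0], [0.0], [2.0]]), X)
        assert fit.beta_for("x")[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.beta_for("intercept")[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n_s, p, n_v = 20, 3, 5
            X = np.column_stack([np.ones(n_s), rng.normal(size=(n_s, p - 1))])
            Y = rng.normal(size=(n_s, n_v))
            dm = DesignMatrix(X, [f"c{j}" for j in range(p)])
            fit = fit_mur(Y, dm)
            for v in range(n_v):
                beta = np.linalg.solve(X.T @ X, X.T @ Y[:, v])
                np.testing.assert_allclose(fit.beta[:, v], beta, atol=1e-10)
                resid = Y[:, v] - X @ beta
                sigma2 = resid @ resid / (n_s - p)
                se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
                np.testing.assert_allclose(fit.t[:, v], beta / se, atol=1e-8)

    def test_standardised_simple_regression_equals_pearson(self, rng):
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        xs, _ = standardise(x)
        ys, _ = standardise(y)
        dm = DesignMatrix(np.column_stack([np.ones(200), xs.ravel()]), ["i", "x"])
        fit = fit_mur(ys, dm)
        assert fit.beta_for("x")[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_collinear_raises_with_names(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(X, ["intercept", "a", "b"])


class TestInteractions:
    def make_design(self):
        df = pd.DataFrame(
            {
                "age": [50.0, 60, 70, 55, 65, 45],
                "bmi": [22.0, 30, 28, 25, 27, 24],
                "ckd": [0, 1, 0, 1, 0, 1],
            }
        )
        return build_design(df, ["age", "bmi"], ["ckd"])

    def test_product_of_standardised_parent_and_flag(self):
        dm = add_interactions(self.make_design(), [("age", "ckd")])
        np.testing.assert_allclose(
            dm.column("age*ckd"), dm.column("age") * dm.column("ckd"), atol=1e-12
        )

    def test_duplicate_raises(self):
        dm = add_interactions(self.make_design(), [("age", "ckd")])
        with pytest.raises(ValueError, match="duplicate"):
            add_interactions(dm, [("age", "ckd")])

    def test_zero_flag_surfaces_rank_error(self):
        # an all-zero flag (and hence its interaction) is a zero column; the
        # rank check surfaces it as soon as it enters the design
        df = pd.DataFrame(
            {"age": [50.0, 60, 70, 55], "flag": [0, 0, 0, 0]}
        )
        with pytest.raises(ValueError, match="rank|collinear"):
            dm = build_design(df, ["age"], ["flag"])
            add_interactions(dm, [("age", "flag")])


class TestBHFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.5, 1.0])),
            [0.04, 0.04, 2.0 / 3.0, 1.0],
            atol=1e-12,
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_array_equal(bh_fdr(np.ones(5)), np.ones(5))
        assert bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_matches_independent_step_up_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 50))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]))


class TestSummaries:
    def make_stats(self, beta, p_fdr, name="cov"):
        n = len(beta)
        return VertexStats(
            name=name,
            beta=np.asarray(beta, float),
            t=np.zeros(n),
            tfce=np.zeros(n),
            p_perm=np.asarray(p_fdr, float),
            p_fdr=np.asarray(p_fdr, float),
        )

    def test_alpha_one_total_area_100(self):
        st = self.make_stats([-1.0, -0.5, 0.5, 1.0], [0.9, 0.8, 0.7, 0.6])
        row = summarise_spm([st], alpha=1.0).iloc[0]
        assert row["area_total_pct"] == pytest.approx(100.0)
        assert row["area_neg_pct"] + row["area_pos_pct"] == pytest.approx(100.0)

    def test_one_sided_effect_blank_positive_cell(self):
        st = self.make_stats([-1.0, -0.5, 0.2, 0.3], [0.001, 0.001, 0.9, 0.9])
        row = summarise_spm([st], alpha=0.05).iloc[0]
        assert row["area_neg_pct"] == pytest.approx(50.0)
        assert row["area_pos_pct"] == 0.0
        assert np.isnan(row["beta_pos_median"])  # the table's "--" cell
        assert row["beta_neg_median"] == pytest.approx(-0.75)

    def test_scope_all_uses_every_vertex(self):
        st = self.make_stats([-1.0, -0.5, 0.5, 1.0], [0.001, 0.9, 0.9, 0.001])
        sig = summarise_spm([st], scope="significant").iloc[0]
        al = summarise_spm([st], scope="all").iloc[0]
        assert sig["beta_neg_median"] == pytest.approx(-1.0)
        assert al["beta_neg_median"] == pytest.approx(-0.75)

    def test_interaction_rate_map_linearity(self, rng):
        n = 50
        stats = {
            "age": self.make_stats(rng.normal(size=n), np.ones(n), "age"),
            "age*ckd": self.make_stats(rng.normal(size=n), np.ones(n), "age*ckd"),
            "zero": self.make_stats(np.zeros(n), np.ones(n), "zero"),
        }
        combined = interaction_rate_map(stats, "age", "age*ckd")
        np.testing.assert_allclose(
            combined, stats["age"].beta + stats["age*ckd"].beta, atol=1e-12
        )
        np.testing.assert_array_equal(
            interaction_rate_map(stats, "age", "zero"), stats["age"].beta
        )


class TestUnstandardise:
    @pytest.mark.parametrize(
        "beta,sd,expected,tol",
        [
            (-0.33, 3.02, -1.0, 0.05),  # printed to whole/half mm
            (-0.30, 2.95, -0.89, 0.006),
            (0.20, 3.02, 0.60, 0.005),
            (0.20, 2.95, 0.59, 0.005),
            (0.06, 3.02, 0.18, 0.005),
        ],
    )
    def test_cohort_mm_rescalings(self, beta, sd, expected, tol):
        assert abs(unstandardise(beta, sd) - expected) <= tol

    def test_zero_and_bad_sd(self):
        assert unstandardise(0.0, 2.5) == 0.0
        with pytest.raises(ValueError):
            unstandardise(0.1, 0.0)


class TestPermutationInference:
    def test_reproducible_with_fixed_seed(self, tiny_template, tiny_geometry, rng):
        n_s, n_v = 40, tiny_template.n_vertices
        Y = rng.normal(size=(n_s, n_v))
        dm = DesignMatrix(
            np.column_stack([np.ones(n_s), rng.normal(size=n_s)]), ["i", "x"]
        )
        s1 = run_spm(Y, dm, ["x"], tiny_geometry, n_perm=100, seed=9)
        s2 = run_spm(Y, dm, ["x"], tiny_geometry, n_perm=100, seed=9)
        np.testing.assert_array_equal(s1["x"].p_perm, s2["x"].p_perm)

    def test_minimum_attainable_p(self, tiny_template, tiny_geometry, rng):
        n_s, n_v = 60, tiny_template.n_vertices
        x = rng.normal(size=n_s)
        Y = rng.normal(size=(n_s, n_v)) * 0.05 + np.outer(x, np.ones(n_v))
        dm = DesignMatrix(np.column_stack([np.ones(n_s), x]), ["i", "x"])
        stats = run_spm(Y, dm, ["x"], tiny_geometry, n_perm=100, seed=1)
        assert stats["x"].p_perm.min() == pytest.approx(1.0 / 101.0)

    def test_missing_target_raises(self, tiny_geometry, rng):
        dm = DesignMatrix(np.column_stack([np.ones(30), rng.normal(size=30)]), ["i", "x"])
        with pytest.raises(ValueError, match="target"):
            run_spm(rng.normal(size=(30, len(tiny_geometry.areas))), dm, ["nope"],
                    tiny_geometry, n_perm=100)
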