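"""Association layer: regressions with covariates, Spearman/Wilcoxon tests,
paralog contrasts, binary annotations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from agesel import association as assoc
from agesel.errors import ConfigError, UndefinedStatisticError, ValidationError
from agesel.synthetic import CohortConfig, generate_paralog_pairs


def _table(n=200, seed=0, tissue=False):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "rea": rng.normal(size=n),
            "mean_expr": rng.normal(5, 1, size=n),
        }
    )
    if tissue:
        t["tissue"] = np.tile(["brain", "liver", "gut", "skin"], n // 4)
    return t


class TestSpearman:
    def test_perfect_monotone(self):
        rho_up, _ = assoc.spearman_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        rho_dn, _ = assoc.spearman_test([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho_up == pytest.approx(1.0, abs=1e-12)
        assert rho_dn == pytest.approx(-1.0, abs=1e-12)

    def test_hand_rank_value(self):
        rho, _ = assoc.spearman_test([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            assoc.spearman_test([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            assoc.spearman_test([1, 2], [1, 2])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = assoc.spearman_test(x, y)
        rho2, p2 = assoc.spearman_test(np.exp(x), y**3 + 5 * y)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)


class TestReaRegression:
    def test_noiseless_coefficients_exact(self):
        t = _table()
        t["y"] = 1.0 + 2.0 * t["rea"] + 3.0 * t["mean_expr"]
        res = assoc.fit_rea_regression(t, "y")
        assert res.b0 == pytest.approx(1.0, abs=1e-10)
        assert res.b1 == pytest.approx(2.0, abs=1e-10)
        assert res.b2 == pytest.approx(3.0, abs=1e-10)
        assert res.n_used == len(t)

    def test_tau_covariate_used_when_present(self):
        t = _table()
        rng = np.random.default_rng(1)
        t["tau"] = rng.uniform(0, 1, len(t))
        t["y"] = 0.5 - 1.5 * t["rea"] + 0.2 * t["mean_expr"] + 4.0 * t["tau"]
        res = assoc.fit_rea_regression(t, "y")
        assert res.coefficients["tau"] == pytest.approx(4.0, abs=1e-10)
        assert res.b1 == pytest.approx(-1.5, abs=1e-10)

    def test_tissue_fixed_intercepts_absorb_tissue_means(self):
        t = _table(tissue=True)
        offsets = {"brain": 0.0, "liver": 5.0, "gut": -3.0, "skin": 1.0}
        t["y"] = 2.0 * t["rea"] + t["tissue"].map(offsets)
        res = assoc.fit_rea_regression(t, "y", covariates=())
        assert res.b1 == pytest.approx(2.0, abs=1e-9)

    def test_null_slope_is_small(self):
        rng = np.random.default_rng(987)
        t = _table(n=10_000, seed=7)
        t["y"] = rng.normal(size=len(t))  # independent of REA
        res = assoc.fit_rea_regression(t, "y")
        assert abs(res.b1) < 0.05
        assert res.p_value > 0.001

    def test_listwise_deletion_reported(self):
        t = _table()
        t["y"] = t["rea"] * 2
        t.loc[:19, "y"] = np.nan
        res = assoc.fit_rea_regression(t, "y")
        assert res.n_used == len(t) - 20

    def test_collinear_design_named(self):
        t = _table()
        t["rea_copy"] = t["rea"]
        t["y"] = t["rea"] + 1.0
        with pytest.raises(ValidationError, match="rea"):
            assoc.fit_rea_regression(t, "y", covariates=("mean_expr", "rea_copy"))

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigError):
            assoc.fit_rea_regression(_table(), "absent")


class TestParalogContrasts:
    def _pairs(self, n=50, seed=0, slope=2.0, noise=0.0):
        rng = np.random.default_rng(seed)
        p = pd.DataFrame(
            {
                "gene_a": [f"g{2*i}" for i in range(n)],
                "gene_b": [f"g{2*i+1}" for i in range(n)],
                "rea_a": rng.normal(size=n),
                "rea_b": rng.normal(size=n),
                "mean_expr_a": rng.normal(5, 1, n),
                "mean_expr_b": rng.normal(5, 1, n),
            }
        )
        d = p["rea_b"] - p["rea_a"]
        p["stat_a"] = 0.0
        p["stat_b"] = slope * d + rng.normal(0, noise, n)
        return p

    def test_exact_slope(self):
        res = assoc.paralog_contrasts(self._pairs(), "stat")
        assert res.coefficients["rea"] == pytest.approx(2.0, abs=1e-10)

    def test_orientation_invariance(self):
        p = self._pairs()
        flipped = p.copy()
        for c in ("gene", "rea", "mean_expr", "stat"):
            flipped[[f"{c}_a", f"{c}_b"]] = p[[f"{c}_b", f"{c}_a"]].to_numpy()
        a = assoc.paralog_contrasts(p, "stat")
        b = assoc.paralog_contrasts(flipped, "stat")
        assert b.coefficients["rea"] == pytest.approx(a.coefficients["rea"], abs=1e-10)
        assert b.spearman_rho == pytest.approx(a.spearman_rho, abs=1e-12)

    def test_all_zero_delta_rea_rejected(self):
        p = self._pairs()
        p["rea_b"] = p["rea_a"]
        with pytest.raises(ValidationError):
            assoc.paralog_contrasts(p, "stat")

    def test_cohort_age_contrast_negative_under_planted_map(self):
        cfg = CohortConfig(n_genes=1000, seed=5)  # default a1 < 0
        pairs = generate_paralog_pairs(cfg, 400)
        res = assoc.paralog_contrasts(pairs, "gene_age")
        assert res.coefficients["rea"] < 0
        assert res.spearman_rho < 0
        assert res.p_value < 0.01


class TestBinaryTrait:
    def test_perfect_separation(self):
        t = _table(n=1000)
        t["driver"] = t["rea"] > t["rea"].median()
        res = assoc.binary_trait_association(t, "driver")
        assert res.spearman_rho > 0.5
        assert res.wilcoxon_p < 1e-10

    def test_equal_count_bins(self):
        t = _table(n=1000)
        t["driver"] = t["rea"] > 1.0
        res = assoc.binary_trait_association(t, "driver", n_bins=10)
        assert list(res.binned_fractions["n"]) == [100] * 10

    def test_null_rejection_rate_is_nominal(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            t = _table(n=200, seed=seed)
            t["flag"] = rng.random(len(t)) < 0.3
            if not t["flag"].any() or t["flag"].all():
                continue
            res = assoc.binary_trait_association(t, "flag")
            rejections += res.wilcoxon_p < 0.05
        assert 0.01 < rejections / n_rep < 0.10

    def test_single_class_rejected(self):
        t = _table()
        t["flag"] = True
        with pytest.raises(ValidationError):
            assoc.binary_trait_association(t, "flag")
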