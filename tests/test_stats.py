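import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import ElasticNet

from micoconn.stats import (
    FeatureImportanceResult,
    ModelFit,
    cumulative_weight_share,
    density_adjusted_replication,
    elasticnet_feature_importance,
    elasticnet_kkt_violation,
    fit_metric_lmm,
    per_network_glm,
    select_model,
    sex_contrasts,
)

NETWORKS = ["visual", "somatomotor", "limbic"]


def _exact_table(n=40, age_coef=0.02, sex_coef=0.1, noise_sd=0.0, seed=0,
                 density_from_age=False):
    """Metric table with a known exact linear generating model."""
    rng = np.random.default_rng(seed)
    rows = []
    ages = rng.uniform(8, 19, size=n)
    sexes = np.where(np.arange(n) % 2 == 0, "F", "M")
    icv = rng.normal(1.4e6, 5e4, size=n)
    # subject-level offsets keep the mixed model's RE variance positive
    subject_offset = rng.normal(0, max(noise_sd, 1e-12), size=n)
    for i in range(n):
        for k, g in enumerate(NETWORKS):
            metric = (
                1.0 + 0.2 * k + age_coef * ages[i]
                + sex_coef * (sexes[i] == "M") + 1e-8 * icv[i]
                + subject_offset[i]
                + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            )
            density = (
                0.05 * ages[i] + rng.normal(0, 0.01)
                if density_from_age
                else rng.uniform(0.4, 0.6)
            )
            rows.append(
                {"subject": f"s{i}", "age": ages[i], "sex": sexes[i],
                 "icv": icv[i], "group": g, "metric": metric,
                 "density": density}
            )
    return pd.DataFrame(rows)


class TestPerNetworkGLM:
    def test_exact_recovery(self):
        table = _exact_table()
        fit = per_network_glm(table, "metric", "visual")
        age = fit.term("age")
        assert age["estimate"].iloc[0] == pytest.approx(0.02, abs=1e-8)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-8)
        assert fit.metadata["significant"]

    def test_location_invariance(self):
        table = _exact_table(noise_sd=0.05)
        base = per_network_glm(table, "metric", "visual")
        shifted = table.copy()
        shifted["metric"] = shifted["metric"] + 5.0
        after = per_network_glm(shifted, "metric", "visual")
        assert base.term("age")["estimate"].iloc[0] == pytest.approx(
            after.term("age")["estimate"].iloc[0], abs=1e-10
        )
        assert base.metadata["age_p"] == pytest.approx(
            after.metadata["age_p"], abs=1e-10
        )
        assert base.adj_r2 == pytest.approx(after.adj_r2, abs=1e-10)

    def test_unknown_group_and_tiny_data_rejected(self):
        table = _exact_table(n=3)
        with pytest.raises(ValueError):
            per_network_glm(table, "metric", "cerebellar")
        with pytest.raises(ValueError):
            per_network_glm(table.head(9), "metric", "visual")


class TestModelSelection:
    @staticmethod
    def _fit(name, aic, k, converged=True):
        return ModelFit(name, name, pd.DataFrame(), aic, k, converged=converged)

    def test_lowest_aic_wins(self):
        fits = [self._fit("a", 100, 5), self._fit("b", 98, 7),
                self._fit("c", 103, 9)]
        assert select_model(fits).name == "b"

    def test_tie_prefers_fewer_params(self):
        fits = [self._fit("big", 100.0, 7), self._fit("small", 100.0, 5)]
        assert select_model(fits).name == "small"

    def test_unconverged_excluded(self):
        fits = [self._fit("bad", 10.0, 3, converged=False),
                self._fit("ok", 50.0, 5)]
        assert select_model(fits).name == "ok"
        with pytest.raises(ValueError):
            select_model([self._fit("bad", 1.0, 2, converged=False)])


class TestMixedModels:
    def test_near_exact_coefficient_recovery(self):
        table = _exact_table(noise_sd=1e-4)
        fits = fit_metric_lmm(table, "metric")
        main = next(f for f in fits if f.name == "main")
        age = main.term("age")
        assert age["estimate"].iloc[0] == pytest.approx(0.02, abs=1e-5)

    def test_interaction_detected_when_generated(self):
        table = _exact_table(noise_sd=0.01, seed=3)
        vis = table["group"] == "visual"
        table.loc[vis, "metric"] += 0.05 * table.loc[vis, "age"]
        fits = fit_metric_lmm(table, "metric")
        byname = {f.name: f for f in fits}
        assert byname["age_by_network"].f_tests["age:network"]["p"] < 0.005
        assert "age:network" in select_model(fits).formula

    def test_requires_multiple_networks(self):
        table = _exact_table()
        with pytest.raises(ValueError):
            fit_metric_lmm(table[table["group"] == "visual"], "metric")


class TestSexContrasts:
    def test_recovers_generated_offset(self):
        table = _exact_table(sex_coef=0.5, noise_sd=1e-6)
        rows = sex_contrasts(table, "metric", "visual")
        main = rows[rows["term"] == "sex[T.M]"]
        assert main["estimate"].iloc[0] == pytest.approx(0.5, abs=1e-3)
        assert main["ci_low"].iloc[0] > 0.0

    def test_label_swap_flips_sign_exactly(self):
        table = _exact_table(sex_coef=0.3, noise_sd=0.02, seed=5)
        fwd = sex_contrasts(table, "metric", "visual")
        swapped = table.copy()
        swapped["sex"] = swapped["sex"].map({"M": "F", "F": "M"})
        rev = sex_contrasts(swapped, "metric", "visual")
        assert fwd[fwd["term"] == "sex[T.M]"]["estimate"].iloc[0] == pytest.approx(
            -rev[rev["term"] == "sex[T.M]"]["estimate"].iloc[0], rel=1e-9
        )

    def test_single_sex_group_rejected(self):
        table = _exact_table()
        table["sex"] = "F"
        with pytest.raises(ValueError):
            sex_contrasts(table, "metric", "visual")


class TestDensityReplication:
    def test_independent_density_keeps_flags(self):
        table = _exact_table(noise_sd=0.01)
        rep = density_adjusted_replication(table, "metric")
        assert not rep["flag_changed"].any()
        assert rep["significant"].all()

    def test_age_driven_density_absorbs_effect(self):
        # metric depends on age only through density
        table = _exact_table(age_coef=0.0, noise_sd=0.0, density_from_age=True)
        table["metric"] = 2.0 * table["density"] + np.random.default_rng(0).normal(
            0, 1e-4, len(table)
        )
        rep = density_adjusted_replication(table, "metric")
        assert rep["significant"].all()  # age looks significant unadjusted
        assert not rep["significant_density_adj"].any()

    def test_zero_variance_density_dropped(self):
        table = _exact_table(noise_sd=0.01)
        table["density"] = 0.5
        plain = per_network_glm(table, "metric", "visual")
        adj = per_network_glm(table, "metric", "visual",
                              extra_covariates=("density",))
        assert plain.metadata["age_p"] == pytest.approx(adj.metadata["age_p"],
                                                        abs=1e-12)


class TestElasticNet:
    def test_kkt_check_against_closed_form_single_feature(self, rng):
        """Single-feature elastic net has a soft-threshold closed form."""
        n = 60
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 1.5 * x + rng.normal(0, 0.3, size=n)
        for alpha, rho in [(0.1, 0.5), (0.8, 1.0), (0.05, 0.1)]:
            en = ElasticNet(alpha=alpha, l1_ratio=rho, max_iter=100_000,
                            tol=1e-12).fit(x[:, None], y)
            r = x @ (y - y.mean()) / n
            expect = np.sign(r) * max(abs(r) - alpha * rho, 0.0)
            expect /= (x @ x) / n + alpha * (1 - rho)
            assert en.coef_[0] == pytest.approx(expect, abs=1e-8)
            viol = elasticnet_kkt_violation(
                x[:, None], y, en.coef_, en.intercept_, alpha, rho
            )
            assert viol < 1e-6

    def test_signal_features_rank_first(self, rng):
        n, p = 90, 12
        ages = rng.uniform(8, 19, size=n)
        X = rng.normal(size=(n, p))
        X[:, 0] = 0.8 * (ages - ages.mean()) + rng.normal(0, 0.3, size=n)
        feats = pd.DataFrame(X, columns=[f"n{j}" for j in range(p)])
        res = elasticnet_feature_importance(feats, ages, seed=0)
        assert res.ranked_nodes[0] == "n0"
        assert res.validation_r2 > 0.5
        assert res.l1_ratio in (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)

    def test_constant_feature_dropped(self, rng):
        n = 40
        ages = rng.uniform(8, 19, size=n)
        feats = pd.DataFrame(
            {"flat": np.ones(n), "sig": ages + rng.normal(0, 0.5, size=n)}
        )
        res = elasticnet_feature_importance(feats, ages, seed=1)
        assert res.dropped_features == ["flat"]
        assert "flat" not in res.weights.index

    def test_share_examples(self):
        res = FeatureImportanceResult(
            weights=pd.Series({"a": 3.0, "b": -1.0, "c": 0.0, "d": 0.0}),
            validation_r2=0.5, validation_rmse=1.0, l1_ratio=0.5, alpha=0.1,
            ranked_nodes=["a", "b", "c", "d"],
            cumulative_share=np.array([0.75, 1.0, 1.0, 1.0]),
            cv_r2=0.4,
        )
        assert cumulative_weight_share(res, 1) == pytest.approx(0.75)
        assert cumulative_weight_share(res, 4) == 1.0
        with pytest.raises(ValueError):
            cumulative_weight_share(res, 0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=10))
    def test_share_monotone_nondecreasing(self, weights):
        w = pd.Series({f"n{i}": v for i, v in enumerate(weights)})
        order = w.abs().sort_values(ascending=False, kind="stable").index
        absw = w.abs().loc[order].values
        total = absw.sum()
        if total == 0:
            return
        share = np.cumsum(absw) / total
        res = FeatureImportanceResult(
            weights=w, validation_r2=0, validation_rmse=0, l1_ratio=0.5,
            alpha=0.1, ranked_nodes=list(order), cumulative_share=share,
            cv_r2=0,
        )
        vals = [cumulative_weight_share(res, k) for k in range(1, len(w) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, abs=1e-12)
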