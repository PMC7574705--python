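"""Structural-engine tests: RAM algebra, ML fitting, constraints, df."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from leanbone.model import (
    CrossLaggedPanelModel,
    Edge,
    ModelSpecError,
    PathModel,
    PathModelSpec,
    UnderIdentifiedError,
    build_clpm_spec,
    implied_covariance,
    independence_spec,
    ml_discrepancy,
    model_df,
    standardize,
)

from _oracles import path_tracing_covariance, random_acyclic_spec


def two_var_spec(a=0.7, sx=1.3, psi=0.8):
    return PathModelSpec(
        ("x", "y"),
        (Edge("x", "y", value=a),),
        (Edge("x", "x", value=sx), Edge("y", "y", value=psi)),
    )


class TestImpliedCovariance:
    def test_single_edge_closed_form(self):
        a, sx, psi = 0.7, 1.3, 0.8
        sigma = implied_covariance(two_var_spec(a, sx, psi))
        assert sigma.loc["x", "y"] == pytest.approx(a * sx)
        assert sigma.loc["y", "y"] == pytest.approx(a**2 * sx + psi)

    def test_chain_product_rule(self):
        a, b, sx = 0.5, -0.4, 2.0
        spec = PathModelSpec(
            ("x", "m", "y"),
            (Edge("x", "m", value=a), Edge("m", "y", value=b)),
            tuple(Edge(v, v, value=s) for v, s in (("x", sx), ("m", 1.0), ("y", 1.0))),
        )
        sigma = implied_covariance(spec)
        assert sigma.loc["x", "y"] == pytest.approx(a * b * sx)

    def test_matches_path_tracing_oracle(self, rng):
        for _ in range(40):
            spec, params = random_acyclic_spec(rng)
            ours = implied_covariance(spec, params).to_numpy()
            oracle = path_tracing_covariance(spec, params)
            assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_cycle_rejected(self):
        with pytest.raises(ModelSpecError, match="cycle"):
            PathModelSpec(
                ("x", "y"),
                (Edge("x", "y", value=0.5), Edge("y", "x", value=0.5)),
                (Edge("x", "x", value=1.0), Edge("y", "y", value=1.0)),
            )


class TestDiscrepancy:
    def test_saturation(self, rng):
        a = rng.normal(size=(4, 4))
        s = a @ a.T + 4 * np.eye(4)
        assert ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        # p = 1, S = 2, Sigma = 1: F = ln(1/2) + 2 - 1
        assert ml_discrepancy(np.array([[1.0]]), np.array([[2.0]])) == pytest.approx(
            np.log(0.5) + 1.0
        )

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(50):
            a = rng.normal(size=(3, 3))
            s = a @ a.T + 3 * np.eye(3)
            b = rng.normal(size=(3, 3))
            sig = b @ b.T + 3 * np.eye(3)
            assert ml_discrepancy(sig, s) >= -1e-12

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_diagonal_rescaling_invariance(self, d1, d2):
        s = np.array([[2.0, 0.3], [0.3, 1.0]])
        sig = np.array([[1.5, 0.1], [0.1, 1.2]])
        d = np.diag([d1, d2])
        assert ml_discrepancy(d @ sig @ d, d @ s @ d) == pytest.approx(
            ml_discrepancy(sig, s), rel=1e-9
        )


class TestModelDf:
    def test_saturated_zero(self):
        spec = two_var_spec()
        # all three moments fixed -> 0 free, df = 3; a fully free saturated
        # spec instead has df = 0
        free = PathModelSpec(
            ("x", "y"),
            (Edge("x", "y", label="a"),),
            (Edge("x", "x", label="sx"), Edge("y", "y", label="py")),
        )
        assert model_df(free) == 0

    def test_canonical_endogenous_block(self):
        spec = build_clpm_spec(
            ("m0", "m3", "m5"), ("b0", "b3", "b5")
        )
        # 21 moments - (9 structural + 6 variances) = 6
        assert model_df(spec) == 6
        assert spec.n_free == 15

    def test_equality_constraint_raises_df(self):
        free_ar = PathModelSpec(
            ("a", "b", "c"),
            (Edge("a", "b", label="r1"), Edge("b", "c", label="r2")),
            tuple(Edge(v, v, label=f"v{v}") for v in "abc"),
        )
        tied = PathModelSpec(
            ("a", "b", "c"),
            (Edge("a", "b", label="r"), Edge("b", "c", label="r")),
            tuple(Edge(v, v, label=f"v{v}") for v in "abc"),
        )
        assert model_df(tied) == model_df(free_ar) + 1

    def test_under_identified(self):
        with pytest.raises(UnderIdentifiedError):
            model_df(
                PathModelSpec(
                    ("x",),
                    (),
                    (Edge("x", "x", label="v"),),
                ),
                n_observed=0,
            )


class TestBuildSpec:
    def test_structural_label_counts(self):
        spec = build_clpm_spec(
            ("V0_M", "V3_M", "V5_M"),
            ("V0_B", "V3_B", "V5_B"),
            covariates=tuple(f"c{i}" for i in range(11)),
        )
        labels = set(spec.free_labels)
        betas = {l for l in labels if l.startswith("beta_")}
        gammas = {l for l in labels if l.startswith("gamma_")}
        rhos = {l for l in labels if l.startswith("rho_")}
        assert (len(betas), len(gammas), len(rhos)) == (3, 4, 2)
        # covariates: 11 variances + 55 covariances + 66 paths
        assert spec.n_free == 15 + 11 + 55 + 66

    def test_empty_covariates_pure_clpm(self):
        spec = build_clpm_spec(("m0", "m3", "m5"), ("b0", "b3", "b5"))
        assert len(spec.variables) == 6

    def test_duplicate_covariate_rejected(self):
        with pytest.raises(ModelSpecError):
            build_clpm_spec(
                ("m0", "m3", "m5"), ("b0", "b3", "b5"), covariates=("c", "c")
            )

    def test_free_v3_cov_lowers_df(self):
        df6 = model_df(build_clpm_spec(("m0", "m3", "m5"), ("b0", "b3", "b5")))
        df5 = model_df(
            build_clpm_spec(
                ("m0", "m3", "m5"), ("b0", "b3", "b5"), free_v3_disturbance_cov=True
            )
        )
        assert (df6, df5) == (6, 5)

    def test_autoregressive_start_values(self):
        spec = build_clpm_spec(("m0", "m3", "m5"), ("b0", "b3", "b5"))
        assert dict(spec.start_values)["rho_muscle"] == 0.8

    def test_edge_list_round_trip(self):
        spec = build_clpm_spec(("m0", "m3", "m5"), ("b0", "b3", "b5"))
        text = spec.to_edge_list()
        back = PathModelSpec.from_edge_list(text)
        assert set(back.free_labels) == set(spec.free_labels)
        assert len(back.directed) == len(spec.directed)


class TestFitting:
    def test_single_regression_matches_least_squares(self, rng):
        n = 400
        x = rng.normal(0, 1.4, n)
        y = 0.6 * x + rng.normal(0, 0.9, n)
        spec = PathModelSpec(
            ("x", "y"),
            (Edge("x", "y", label="a"),),
            (Edge("x", "x", label="sx"), Edge("y", "y", label="py")),
        )
        fit = PathModel(spec).fit(pd.DataFrame({"x": x, "y": y}))
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.params_["a"] == pytest.approx(slope, abs=1e-8)
        # SE agrees with OLS up to the N vs N-1 residual-variance convention
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(x)).fit()
        ratio = fit.se_["a"] / ols.bse[1]
        assert ratio == pytest.approx(np.sqrt((n - 2) / (n - 1)), rel=1e-2)

    def test_saturated_model_zero_discrepancy(self, rng):
        n = 200
        data = pd.DataFrame(
            rng.normal(size=(n, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]]),
            columns=["x", "y"],
        )
        spec = PathModelSpec(
            ("x", "y"),
            (Edge("x", "y", label="a"),),
            (Edge("x", "x", label="sx"), Edge("y", "y", label="py")),
        )
        fit = PathModel(spec).fit(data)
        assert fit.df_ == 0
        assert fit.discrepancy_ == pytest.approx(0.0, abs=1e-10)
        assert fit.chi2_ == pytest.approx(0.0, abs=1e-7)

    def test_equality_constraint_never_fits_better(self, clean_leg_data):
        visits = ("V0", "V3", "V5")
        muscle = tuple(f"{v}_leg_LM" for v in visits)
        bone = tuple(f"{v}_leg_BMD" for v in visits)
        tied = PathModel(build_clpm_spec(muscle, bone)).fit(clean_leg_data)
        free_spec = build_clpm_spec(muscle, bone)
        # untie the autoregressive labels
        directed = tuple(
            Edge(e.source, e.target, label=f"{e.label}_{i}" if e.label and e.label.startswith("rho") else e.label)
            for i, e in enumerate(free_spec.directed)
        )
        untied = PathModelSpec(
            free_spec.variables, directed, free_spec.bidirected, free_spec.exogenous
        )
        free_fit = PathModel(untied).fit(clean_leg_data)
        assert tied.discrepancy_ >= free_fit.discrepancy_ - 1e-10
        assert model_df(untied) == model_df(tied.spec_) - 2

    def test_parameter_recovery_three_se(self, clean_leg_data):
        fit = CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(clean_leg_data)
        truth = {
            "rho_muscle": 0.9226,
            "rho_bone": 1.0302,
            "beta_mb_v0": 0.0316,
            "beta_mb_v3": -0.0108,
            "beta_mb_v5": 0.0085,
            "gamma_mb_lag1": 0.0093,
            "gamma_mb_lag2": 0.0003,
            "gamma_bm_lag1": 0.0238,
            "gamma_bm_lag2": 0.0136,
        }
        for label, true in truth.items():
            z = (fit.params_[label] - true) / fit.se_[label]
            assert abs(z) < 3.5, f"{label}: z = {z:.2f}"

    def test_missing_values_rejected(self, clean_leg_data):
        broken = clean_leg_data.copy()
        broken.loc[broken.index[0], "V0_leg_LM"] = np.nan
        with pytest.raises(ModelSpecError, match="complete-case"):
            CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(broken)

    def test_unknown_column_rejected(self, clean_leg_data):
        with pytest.raises(ModelSpecError, match="unknown columns"):
            CrossLaggedPanelModel("hip_LM", "hip_BMD").fit(clean_leg_data)

    def test_forced_fallback_recorded(self, clean_leg_data):
        fit = CrossLaggedPanelModel("leg_LM", "leg_BMD", max_iter=1).fit(clean_leg_data)
        assert fit.convergence_.fallback_used
        assert fit.convergence_.converged
        ok = CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(clean_leg_data)
        assert ok.convergence_.converged

    def test_independence_spec_recovers_variances(self, rng):
        a = rng.normal(size=(300, 3))
        s = np.cov(a, rowvar=False, ddof=1)
        fit = PathModel(independence_spec(("a", "b", "c"))).fit_moments(s, 300)
        assert np.allclose(np.diag(fit.implied_cov_), np.diag(s), rtol=1e-8)


class TestStandardize:
    def test_unit_variance_identity(self, rng):
        n = 3000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(0, np.sqrt(0.75), n)
        data = pd.DataFrame({"x": x / x.std(ddof=1), "y": y / y.std(ddof=1)})
        spec = PathModelSpec(
            ("x", "y"),
            (Edge("x", "y", label="a"),),
            (Edge("x", "x", label="sx"), Edge("y", "y", label="py")),
        )
        fit = PathModel(spec).fit(data)
        est = fit.estimates_
        assert est.loc[0, "std_estimate"] == pytest.approx(est.loc[0, "estimate"], rel=1e-6)

    def test_source_rescaling_invariance(self, clean_leg_data):
        fit = CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(clean_leg_data)
        scaled = clean_leg_data.copy()
        for v in ("V0", "V3", "V5"):
            scaled[f"{v}_leg_LM"] = scaled[f"{v}_leg_LM"] * 1000.0
        fit2 = CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(scaled)
        a = fit.estimates_.set_index(["predictor", "outcome"])["std_estimate"]
        b = fit2.estimates_.set_index(["predictor", "outcome"])["std_estimate"]
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-5)

    def test_equality_constrained_edges_standardize_differently(self, clean_leg_data):
        fit = CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(clean_leg_data)
        est = fit.estimates_.set_index(["predictor", "outcome"])
        lag1 = est.loc[("V0_leg_LM", "V3_leg_LM")]
        lag2 = est.loc[("V3_leg_LM", "V5_leg_LM")]
        assert lag1["estimate"] == pytest.approx(lag2["estimate"])  # shared label
        assert lag1["std_estimate"] != pytest.approx(lag2["std_estimate"], abs=1e-4)

    def test_marginal_sd_ratio_magnitude(self, clean_leg_data):
        # 0.0316 kg->g/cm^2 rescaled by SD(LM)/SD(BMD) lands near 0.33
        fit = CrossLaggedPanelModel("leg_LM", "leg_BMD").fit(clean_leg_data)
        est = fit.estimates_.set_index(["predictor", "outcome"])
        std = est.loc[("V0_leg_LM", "V0_leg_BMD"), "std_estimate"]
        unstd = est.loc[("V0_leg_LM", "V0_leg_BMD"), "estimate"]
        sd_ratio = (
            clean_leg_data["V0_leg_LM"].std() / clean_leg_data["V0_leg_BMD"].std()
        )
        assert std == pytest.approx(unstd * sd_ratio, rel=0.02)
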