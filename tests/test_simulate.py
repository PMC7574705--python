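"""Synthetic-cohort generator: determinism, calibration, structure."""

import io

import numpy as np
import pandas as pd
import pytest

from leanbone.model import implied_covariance
from leanbone.simulate import (
    ConfigError,
    LimbDynamics,
    SyntheticConfig,
    default_leg_dynamics,
    generate_covariates,
    simulate_cohort,
    simulate_panel,
    write_cohort_csv,
    _calibrate_limb,
)

from conftest import clean_leg_config


class TestConfigValidation:
    def test_bad_n(self):
        with pytest.raises(ConfigError, match="n_participants"):
            SyntheticConfig(n_participants=0)

    def test_bad_visit_order(self):
        with pytest.raises(ConfigError, match="visit_months"):
            SyntheticConfig(visit_months=(0.0, 120.0, 48.0))

    def test_bad_sd_names_field(self):
        dyn = default_leg_dynamics()
        bad = LimbDynamics(**{**dyn.__dict__, "lm_sd": (0.0, 1.0, 1.0)})
        with pytest.raises(ConfigError, match="leg.lm_sd"):
            SyntheticConfig(leg=bad)

    def test_bad_probability(self):
        with pytest.raises(ConfigError, match="side_flag_p"):
            SyntheticConfig(side_flag_p=1.5)

    def test_nonfinite_coefficient_rejected(self):
        dyn = default_leg_dynamics()
        bad = LimbDynamics(**{**dyn.__dict__, "rho_bone": float("nan")})
        with pytest.raises(ConfigError, match="rho_bone"):
            SyntheticConfig(leg=bad)

    def test_unknown_effect_covariate(self):
        with pytest.raises(ConfigError, match="covariate_effects"):
            SyntheticConfig(covariate_effects={"leg_LM": {"weight": 1.0}})


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SyntheticConfig(n_participants=50, seed=42)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_cohort_csv(simulate_cohort(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seed_differs(self):
        a = simulate_cohort(SyntheticConfig(n_participants=50, seed=1))
        b = simulate_cohort(SyntheticConfig(n_participants=50, seed=2))
        assert not a["V0_L_leg_LM"].equals(b["V0_L_leg_LM"])


class TestCovariates:
    def test_age_mean_at_cohort_size(self):
        cov = generate_covariates(SyntheticConfig(n_participants=1286, seed=3))
        assert abs(cov["age"].mean() - 53.0) < 3 * 9.0 / np.sqrt(1286)
        assert cov["age"].min() >= 40.0

    def test_bmi_moments(self):
        cov = generate_covariates(SyntheticConfig(n_participants=8000, seed=4))
        assert cov["bmi0"].mean() == pytest.approx(27.43, abs=0.2)
        assert cov["bmi0"].std() == pytest.approx(4.23, abs=0.2)

    def test_single_participant_complete(self):
        cfg = SyntheticConfig(n_participants=1, seed=0, dropout=(0.0, 0.0, 0.0))
        df = simulate_cohort(cfg)
        assert len(df) == 1
        assert not df.drop(columns=["ethnicity"]).isna().any().any()

    def test_binary_prevalence(self):
        cov = generate_covariates(SyntheticConfig(n_participants=20000, seed=5))
        assert cov["smoking"].mean() == pytest.approx(0.24, abs=0.02)


class TestPanelStructure:
    def test_identity_dynamics(self):
        """Zero disturbances, unit AR, no cross paths: V5 equals V0 exactly."""
        dyn = LimbDynamics(
            lm_mean=(10.0, 10.0, 10.0),
            lm_sd=(1.5, 1.5, 1.5),
            bmd_mean=(1.4, 1.4, 1.4),
            bmd_sd=(0.15, 0.15, 0.15),
            rho_muscle=1.0,
            rho_bone=1.0,
            beta_mb=(0.03, 0.0, 0.0),
            gamma_mb=(0.0, 0.0),
            gamma_bm=(0.0, 0.0),
            lm_disturbance_sd=(1.5, 0.0, 0.0),
            bmd_disturbance_sd=(0.15, 0.0, 0.0),
        )
        cfg = clean_leg_config(200, seed=9, leg=dyn, arm=dyn)
        df = simulate_cohort(cfg)
        for limb in ("leg", "arm"):
            for metric in ("LM", "BMD"):
                np.testing.assert_allclose(
                    df[f"V5_L_{limb}_{metric}"],
                    df[f"V0_L_{limb}_{metric}"],
                    rtol=1e-12,
                )

    def test_v0_moment_fidelity(self):
        cfg = SyntheticConfig(n_participants=6000, seed=6, dropout=(0, 0, 0))
        df = simulate_cohort(cfg)
        n = len(df)
        for col, mean, sd in (
            ("V0_L_leg_LM", 10.58, 1.54),
            ("V0_L_arm_LM", 4.38, 0.77),
            ("V0_L_leg_BMD", 1.403, 0.146),
            ("V0_L_arm_BMD", 0.920, 0.084),
        ):
            x = df[col]
            assert abs(x.mean() - mean) < 4 * sd / np.sqrt(n), col
            # SD standard error ~ sd / sqrt(2n)
            assert abs(x.std() - sd) < 4 * sd / np.sqrt(2 * n), col

    def test_zero_crosslag_partial_correlation(self):
        """With gamma = 0, M0 is independent of B3 given B0, M3."""
        dyn = LimbDynamics(
            **{**default_leg_dynamics().__dict__, "gamma_mb": (0.0, 0.0), "gamma_bm": (0.0, 0.0)}
        )
        cfg = clean_leg_config(20000, seed=7, leg=dyn)
        df = simulate_cohort(cfg)
        cols = ["V0_L_leg_LM", "V0_L_leg_BMD", "V3_L_leg_LM", "V3_L_leg_BMD"]
        m0, b0, m3, b3 = (df[c].to_numpy() for c in cols)
        X = np.column_stack([np.ones(len(df)), b0, m3])
        rm0 = m0 - X @ np.linalg.lstsq(X, m0, rcond=None)[0]
        rb3 = b3 - X @ np.linalg.lstsq(X, b3, rcond=None)[0]
        r = np.corrcoef(rm0, rb3)[0, 1]
        assert abs(r) < 3.5 / np.sqrt(len(df))

    def test_ols_recovers_crosslag(self):
        """Regression of B3 on (B0, M0, M3) recovers gamma_mb within 3 SE."""
        cfg = clean_leg_config(20000, seed=8)
        df = simulate_cohort(cfg)
        y = df["V3_L_leg_BMD"].to_numpy()
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["V0_L_leg_BMD"],
                df["V0_L_leg_LM"],
                df["V3_L_leg_LM"],
            ]
        )
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[2, 2])
        assert abs(beta[2] - 0.0093) < 3 * se

    def test_left_right_correlation_high(self):
        df = simulate_cohort(clean_leg_config(5000, seed=10))
        r = np.corrcoef(df["V0_L_leg_LM"], df["V0_R_leg_LM"])[0, 1]
        assert r > 0.9

    def test_generative_analytic_consistency(self):
        """Empirical covariance at n = 1e5 matches the RAM implied covariance."""
        cfg = clean_leg_config(100000, seed=12)
        df = simulate_cohort(cfg)
        struct = _calibrate_limb(cfg, "leg")
        sigma = struct.implied_cov()
        endo = ["M0", "B0", "M3", "B3", "M5", "B5"]
        cols = {
            "M0": "V0_L_leg_LM", "B0": "V0_L_leg_BMD",
            "M3": "V3_L_leg_LM", "B3": "V3_L_leg_BMD",
            "M5": "V5_L_leg_LM", "B5": "V5_L_leg_BMD",
        }
        emp = df[[cols[v] for v in endo]].cov().to_numpy()
        pop = sigma.loc[endo, endo].to_numpy()
        d_emp = np.sqrt(np.diag(emp))
        d_pop = np.sqrt(np.diag(pop))
        np.testing.assert_allclose(d_emp, d_pop, rtol=0.02)
        corr_emp = emp / np.outer(d_emp, d_emp)
        corr_pop = pop / np.outer(d_pop, d_pop)
        assert np.max(np.abs(corr_emp - corr_pop)) < 0.02

    def test_covariate_effects_in_structure(self):
        """With effects on, the analytic structure exposes covariate edges."""
        cfg = SyntheticConfig(n_participants=10, seed=0)
        struct = _calibrate_limb(cfg, "leg")
        spec = struct.to_path_spec()
        assert "age" in spec.variables
        sigma = implied_covariance(spec)
        assert sigma.loc["age", "M0"] < 0  # older -> less lean mass

    def test_dropout_rates(self):
        cfg = SyntheticConfig(n_participants=8000, seed=13, dropout=(0.0, 0.3, 0.0))
        df = simulate_cohort(cfg)
        assert df["V3_L_leg_LM"].isna().mean() == pytest.approx(0.3, abs=0.02)
        assert df["V0_L_leg_LM"].notna().all()

    def test_heavy_tailed_disturbances_variance_preserved(self):
        cfg = clean_leg_config(30000, seed=14, t_dof=6.0)
        df = simulate_cohort(cfg)
        assert df["V0_L_leg_LM"].std() == pytest.approx(1.54, rel=0.05)
        k = df["V0_L_leg_LM"].kurt()
        assert k > 0.3  # heavier-tailed than Gaussian

    def test_panel_respects_external_covariates(self):
        cfg = SyntheticConfig(n_participants=500, seed=15)
        cov = generate_covariates(cfg)
        rng = np.random.default_rng(99)
        df = simulate_panel(cov, cfg, rng)
        assert len(df) == 500
        pd.testing.assert_series_equal(df["age"], cov["age"], check_names=False)
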