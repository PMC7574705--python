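"""Three-wave synthetic cohort generator for bone-muscle panel analyses.

The generator produces wide per-participant tables with per-limb, per-side
lean mass (kg) and areal BMD (g/cm^2) at three visits (nominally 0, 48 and
120 months), together with anthropometrics and the baseline covariates the
panel models adjust for.  The statistical structure mirrors exactly what
the cross-lagged panel model assumes: per limb, muscle M and bone B evolve
as

    M0 = mu + c'x + e          B0 = mu + beta0*M0 + c'x + e
    M3 = mu + rho_m*M0 + gBM1*B0 + c'x + e
    B3 = mu + rho_b*B0 + gMB1*M0 + beta3*M3 + c'x + e

and likewise V3 -> V5, with independent Gaussian disturbances, centred
covariate effects ``c'x`` and visit intercepts ``mu``.  Left and right
limbs are correlated replicates (disturbance correlation 0.95 by default);
the right side exists to exercise the side-selection rule downstream.

Default means/SDs and structural coefficients are calibrated to the scale
of a large Afro-Caribbean male cohort followed over ten years: visit means
and SDs for leg/arm LM and BMD, autoregressive coefficients near one,
contemporaneous muscle->bone effects near 0.03 g/cm^2 per kg, and small
cross-lagged effects.  Intercepts and baseline disturbance SDs are solved
analytically so that generated V0 moments match the configured targets;
later-visit disturbances are likewise solved against the target SDs, with
a floor when the configured structural coefficients already imply more
variance than the target (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import Edge, PathModelSpec

__all__ = [
    "LimbDynamics",
    "SyntheticConfig",
    "ConfigError",
    "GenerativeStructure",
    "generate_covariates",
    "simulate_panel",
    "simulate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "COVARIATE_COLUMNS",
]


class ConfigError(ValueError):
    """A synthetic-cohort configuration field is invalid."""


VISITS = ("V0", "V3", "V5")
SIDES = ("L", "R")
LIMBS = ("leg", "arm")

#: baseline covariates carried on every cohort table
COVARIATE_COLUMNS = (
    "age",
    "ethnicity",
    "arthritis",
    "fracture40",
    "alcohol",
    "smoking",
    "diabetes",
    "walking",
    "grip",
    "hospitalization",
    "glucocorticoid",
)

# ---------------------------------------------------------------------------
# analytic covariate distributions
# ---------------------------------------------------------------------------
# Continuous covariates have known first/second moments so that covariate
# effect variances can be solved analytically.  Truncated normals are
# re-located so the *post-truncation* mean hits the target.  Distributions
# for alcohol, walking and grip strength are not published for this kind of
# cohort; the defaults below are invented, plausible for community-dwelling
# middle-aged men, and documented as such.


@dataclass(frozen=True)
class _TruncNormal:
    mean: float
    sd: float
    lower: float

    def _loc(self) -> float:
        target = self.mean

        def f(mu: float) -> float:
            a = (self.lower - mu) / self.sd
            return stats.truncnorm.mean(a, np.inf, loc=mu, scale=self.sd) - target

        return float(optimize.brentq(f, self.lower - 2 * self.sd, target + self.sd))

    def moments(self) -> tuple[float, float]:
        mu = self._loc()
        a = (self.lower - mu) / self.sd
        return self.mean, float(stats.truncnorm.var(a, np.inf, loc=mu, scale=self.sd))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu = self._loc()
        a = (self.lower - mu) / self.sd
        return stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=self.sd, size=n, random_state=rng
        )


@dataclass(frozen=True)
class _Normal:
    mean: float
    sd: float

    def moments(self) -> tuple[float, float]:
        return self.mean, self.sd**2

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class _Exponential:
    scale: float

    def moments(self) -> tuple[float, float]:
        return self.scale, self.scale**2

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(self.scale, size=n)


@dataclass(frozen=True)
class _Gamma:
    shape: float
    scale: float

    def moments(self) -> tuple[float, float]:
        return self.shape * self.scale, self.shape * self.scale**2

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)


CONTINUOUS_COVARIATES = {
    "age": _TruncNormal(mean=53.0, sd=9.0, lower=40.0),  # years, cohort entry >= 40
    "height": _Normal(mean=175.4, sd=6.8),  # cm
    "bmi": _TruncNormal(mean=27.43, sd=4.23, lower=15.0),  # kg/m^2
    "grip": _TruncNormal(mean=42.0, sd=8.0, lower=10.0),  # kg (invented default)
    "alcohol": _Exponential(scale=4.0),  # units/week (invented default)
    "walking": _Gamma(shape=2.0, scale=60.0),  # min/week (invented default)
}


def _default_prevalence() -> dict[str, float]:
    # binary baseline covariates; glucocorticoid use is genuinely rare
    # (about one user in a cohort of ~1300)
    return {
        "smoking": 0.24,
        "diabetes": 0.18,
        "arthritis": 0.15,
        "fracture40": 0.04,
        "hospitalization": 0.10,
        "glucocorticoid": 1.0 / 1286.0,
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LimbDynamics:
    """Per-limb generative targets and structural coefficients.

    Means/SDs are per visit (V0, V3, V5) in metric units; structural
    coefficients are unstandardized (bone in g/cm^2 per kg of lean mass for
    the muscle->bone directions).  ``*_disturbance_sd`` of ``None`` asks the
    generator to solve the disturbance scales against the target SDs.
    """

    lm_mean: tuple[float, float, float]
    lm_sd: tuple[float, float, float]
    bmd_mean: tuple[float, float, float]
    bmd_sd: tuple[float, float, float]
    rho_muscle: float
    rho_bone: float
    beta_mb: tuple[float, float, float]
    gamma_mb: tuple[float, float]
    gamma_bm: tuple[float, float]
    lm_disturbance_sd: tuple[float, float, float] | None = None
    bmd_disturbance_sd: tuple[float, float, float] | None = None


def default_leg_dynamics() -> LimbDynamics:
    """Leg lean mass / BMD dynamics at the cohort's reported scale."""
    return LimbDynamics(
        lm_mean=(10.58, 10.42, 9.77),
        lm_sd=(1.54, 1.55, 1.51),
        bmd_mean=(1.403, 1.381, 1.390),
        bmd_sd=(0.146, 0.146, 0.166),
        rho_muscle=0.9226,
        rho_bone=1.0302,
        beta_mb=(0.0316, -0.0108, 0.0085),
        gamma_mb=(0.0093, 0.0003),
        gamma_bm=(0.0238, 0.0136),
    )


def default_arm_dynamics() -> LimbDynamics:
    """Arm lean mass / BMD dynamics at the cohort's reported scale."""
    return LimbDynamics(
        lm_mean=(4.38, 4.33, 4.05),
        lm_sd=(0.77, 0.80, 0.78),
        bmd_mean=(0.920, 0.912, 0.903),
        bmd_sd=(0.084, 0.083, 0.090),
        rho_muscle=0.7567,
        rho_bone=1.0251,
        beta_mb=(0.0371, 0.0051, 0.0123),
        gamma_mb=(-0.0068, -0.0063),
        gamma_bm=(0.1263, 0.4143),
    )


def _default_effects() -> dict[str, dict[str, float]]:
    """Centred covariate effects on each endogenous metric (metric units).

    Modest, a-priori plausible effects: older age lowers lean mass and
    BMD, taller men carry more lean mass, stronger grip tracks lean mass.
    Chosen so covariates explain roughly 10-20% of baseline variance.
    """
    return {
        "leg_LM": {"age": -0.020, "height": 0.075, "grip": 0.035},
        "arm_LM": {"age": -0.010, "height": 0.030, "grip": 0.030},
        "leg_BMD": {"age": -0.0015, "height": 0.0020, "grip": 0.0015},
        "arm_BMD": {"age": -0.0010, "height": 0.0010, "grip": 0.0012},
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full configuration for one synthetic cohort draw."""

    n_participants: int = 1286
    seed: int = 0
    visit_months: tuple[float, float, float] = (0.0, 48.0, 120.0)
    leg: LimbDynamics = field(default_factory=default_leg_dynamics)
    arm: LimbDynamics = field(default_factory=default_arm_dynamics)
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_effects
    )
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    dropout: tuple[float, float, float] = (0.0, 0.02, 0.03)
    side_flag_p: float = 0.01
    left_right_corr: float = 0.95
    t_dof: float | None = None  # heavier-tailed disturbances for robustness runs
    ethnicity_p_majority: float = 0.94

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not (
            len(self.visit_months) == 3
            and all(m >= 0 for m in self.visit_months)
            and self.visit_months[0] < self.visit_months[1] < self.visit_months[2]
        ):
            raise ConfigError("visit_months must be three strictly increasing nonnegative values")
        for limb_name in LIMBS:
            dyn: LimbDynamics = getattr(self, limb_name)
            for fname in ("lm_sd", "bmd_sd"):
                if any(s <= 0 for s in getattr(dyn, fname)):
                    raise ConfigError(f"{limb_name}.{fname}: SDs must be > 0")
            for fname in ("rho_muscle", "rho_bone"):
                if not np.isfinite(getattr(dyn, fname)):
                    raise ConfigError(f"{limb_name}.{fname}: must be finite")
            for fname in ("beta_mb", "gamma_mb", "gamma_bm"):
                if not np.all(np.isfinite(getattr(dyn, fname))):
                    raise ConfigError(f"{limb_name}.{fname}: must be finite")
        for name, p in {
            "side_flag_p": self.side_flag_p,
            **{f"dropout[{i}]": d for i, d in enumerate(self.dropout)},
            **{f"prevalence[{k}]": v for k, v in self.prevalence.items()},
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: probability must be in [0, 1]")
        if not 0.0 <= self.left_right_corr <= 1.0:
            raise ConfigError("left_right_corr: must be in [0, 1]")
        for metric, effects in self.covariate_effects.items():
            for cov in effects:
                if cov not in CONTINUOUS_COVARIATES:
                    raise ConfigError(
                        f"covariate_effects[{metric}]: no analytic moments for "
                        f"{cov!r}; allowed: {sorted(CONTINUOUS_COVARIATES)}"
                    )


# ---------------------------------------------------------------------------
# analytic calibration + implied structure
# ---------------------------------------------------------------------------

_ENDO = ("M0", "B0", "M3", "B3", "M5", "B5")


def _structural_edges(dyn: LimbDynamics) -> dict[str, dict[str, float]]:
    """Parent -> coefficient map for each endogenous variable."""
    b0, b3, b5 = dyn.beta_mb
    gmb1, gmb2 = dyn.gamma_mb
    gbm1, gbm2 = dyn.gamma_bm
    return {
        "M0": {},
        "B0": {"M0": b0},
        "M3": {"M0": dyn.rho_muscle, "B0": gbm1},
        "B3": {"B0": dyn.rho_bone, "M0": gmb1, "M3": b3},
        "M5": {"M3": dyn.rho_muscle, "B3": gbm2},
        "B5": {"B3": dyn.rho_bone, "M3": gmb2, "M5": b5},
    }


@dataclass
class GenerativeStructure:
    """Exact linear structure of one limb of the generator.

    Holds intercepts and disturbance SDs solved from the configured
    targets, plus everything needed to express the structure as a
    fixed-value :class:`PathModelSpec` (for consistency checks against the
    RAM implied-covariance algebra) or to evaluate population covariances
    directly.
    """

    limb: str
    covariates: tuple[str, ...]
    cov_var: dict[str, float]
    effects: dict[str, dict[str, float]]  # endo var -> covariate -> coef
    structural: dict[str, dict[str, float]]
    intercepts: dict[str, float]
    disturbance_sd: dict[str, float]
    sd_floor_hit: tuple[str, ...]

    @property
    def variables(self) -> tuple[str, ...]:
        return self.covariates + _ENDO

    def to_path_spec(self) -> PathModelSpec:
        directed = []
        bidirected = []
        for c in self.covariates:
            bidirected.append(Edge(c, c, value=self.cov_var[c]))
        for v in _ENDO:
            for parent, coef in self.structural[v].items():
                directed.append(Edge(parent, v, value=coef))
            for c, coef in self.effects[v].items():
                directed.append(Edge(c, v, value=coef))
            bidirected.append(Edge(v, v, value=self.disturbance_sd[v] ** 2))
        return PathModelSpec(
            variables=self.variables,
            directed=tuple(directed),
            bidirected=tuple(bidirected),
            exogenous=self.covariates,
        )

    def implied_cov(self) -> pd.DataFrame:
        """Population covariance over covariates + endogenous variables."""
        from .model import implied_covariance

        return implied_covariance(self.to_path_spec())


def _calibrate_limb(config: SyntheticConfig, limb: str) -> GenerativeStructure:
    """Solve intercepts and disturbance SDs against the configured targets.

    Works on the exact linear representation of every endogenous variable
    in the basis of (centred covariates, disturbances), whose members are
    mutually independent, so variances accumulate as weighted sums.
    """
    dyn: LimbDynamics = getattr(config, limb)
    eff_m = dict(config.covariate_effects.get(f"{limb}_LM", {}))
    eff_b = dict(config.covariate_effects.get(f"{limb}_BMD", {}))
    covs = tuple(sorted(set(eff_m) | set(eff_b)))
    cov_var = {c: CONTINUOUS_COVARIATES[c].moments()[1] for c in covs}
    structural = _structural_edges(dyn)
    effects = {
        v: (dict(eff_m) if v.startswith("M") else dict(eff_b)) for v in _ENDO
    }
    targets_mean = {
        "M0": dyn.lm_mean[0], "B0": dyn.bmd_mean[0],
        "M3": dyn.lm_mean[1], "B3": dyn.bmd_mean[1],
        "M5": dyn.lm_mean[2], "B5": dyn.bmd_mean[2],
    }
    targets_sd = {
        "M0": dyn.lm_sd[0], "B0": dyn.bmd_sd[0],
        "M3": dyn.lm_sd[1], "B3": dyn.bmd_sd[1],
        "M5": dyn.lm_sd[2], "B5": dyn.bmd_sd[2],
    }
    given = {}
    if dyn.lm_disturbance_sd is not None:
        for v, s in zip(("M0", "M3", "M5"), dyn.lm_disturbance_sd):
            given[v] = s
    if dyn.bmd_disturbance_sd is not None:
        for v, s in zip(("B0", "B3", "B5"), dyn.bmd_disturbance_sd):
            given[v] = s

    basis = list(covs) + [f"e_{v}" for v in _ENDO]
    basis_var = {**cov_var}
    weights: dict[str, dict[str, float]] = {}
    intercepts: dict[str, float] = {}
    disturbance_sd: dict[str, float] = {}
    floor_hit = []
    for v in _ENDO:
        w: dict[str, float] = {c: coef for c, coef in effects[v].items()}
        mu = targets_mean[v]
        for parent, coef in structural[v].items():
            mu -= coef * targets_mean[parent]
            for b, pw in weights[parent].items():
                w[b] = w.get(b, 0.0) + coef * pw
        struct_var = sum(pw**2 * basis_var[b] for b, pw in w.items())
        if v in given:
            sd_e = given[v]
            if sd_e < 0:
                raise ConfigError(f"{limb}: disturbance SD for {v} must be >= 0")
        else:
            gap = targets_sd[v] ** 2 - struct_var
            floor = (0.10 * targets_sd[v]) ** 2
            if v in ("M0", "B0") and gap <= 0:
                raise ConfigError(
                    f"{limb}.{v}: covariate effects imply more baseline variance "
                    f"({struct_var:.4g}) than the target SD allows "
                    f"({targets_sd[v] ** 2:.4g}); shrink covariate_effects"
                )
            if gap < floor:
                gap = floor
                floor_hit.append(v)
            sd_e = math.sqrt(gap)
        disturbance_sd[v] = sd_e
        basis_var[f"e_{v}"] = sd_e**2
        w[f"e_{v}"] = 1.0
        weights[v] = w
        intercepts[v] = mu
    return GenerativeStructure(
        limb=limb,
        covariates=covs,
        cov_var=cov_var,
        effects=effects,
        structural=structural,
        intercepts=intercepts,
        disturbance_sd=disturbance_sd,
        sd_floor_hit=tuple(floor_hit),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def generate_covariates(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the baseline covariate block (one row per participant).

    Age is truncated-normal with support above 40 years and mean 53;
    binary covariates are Bernoulli at their configured prevalences.
    Also draws baseline height (cm) and BMI (kg/m^2), which anchor the
    anthropometric trajectories in :func:`simulate_panel`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    out = pd.DataFrame({"pid": np.arange(1, n + 1)})
    out["age"] = CONTINUOUS_COVARIATES["age"].sample(rng, n)
    out["ethnicity"] = np.where(
        rng.random(n) < config.ethnicity_p_majority, "afro-caribbean", "other"
    )
    for name in ("arthritis", "fracture40", "smoking", "diabetes", "hospitalization",
                 "glucocorticoid"):
        out[name] = (rng.random(n) < config.prevalence[name]).astype(int)
    out["alcohol"] = CONTINUOUS_COVARIATES["alcohol"].sample(rng, n)
    out["walking"] = CONTINUOUS_COVARIATES["walking"].sample(rng, n)
    out["grip"] = CONTINUOUS_COVARIATES["grip"].sample(rng, n)
    out["height0"] = CONTINUOUS_COVARIATES["height"].sample(rng, n)
    out["bmi0"] = CONTINUOUS_COVARIATES["bmi"].sample(rng, n)
    out = out[["pid", *COVARIATE_COLUMNS, "height0", "bmi0"]]
    return out


def _disturbance_pair(
    rng: np.random.Generator, n: int, sd: float, corr: float, t_dof: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Left/right disturbances with the configured cross-side correlation."""

    def draw(size):
        if t_dof is None:
            return rng.standard_normal(size)
        # Student-t standardised to unit variance (robustness alternative)
        return rng.standard_t(t_dof, size) / math.sqrt(t_dof / (t_dof - 2.0))

    shared = draw(n)
    a = math.sqrt(corr)
    b = math.sqrt(1.0 - corr)
    return sd * (a * shared + b * draw(n)), sd * (a * shared + b * draw(n))


def simulate_panel(
    covariates: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the full three-wave panel given a covariate block.

    Returns the wide cohort table: anthropometrics per visit, left/right
    LM and BMD per limb per visit, side-exclusion flags, with dropout and
    flags applied last.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(covariates)
    out = covariates[["pid", *COVARIATE_COLUMNS]].copy()

    # anthropometric trajectories (height creeps slightly, BMI wobbles)
    h0 = covariates["height0"].to_numpy()
    bmi0 = covariates["bmi0"].to_numpy()
    heights = {
        "V0": h0,
        "V3": h0 + rng.normal(0.1, 0.3, n),
        "V5": h0 + rng.normal(0.2, 0.3, n),
    }
    bmis = {
        "V0": bmi0,
        "V3": bmi0 + rng.normal(0.12, 0.8, n),
        "V5": bmi0 + rng.normal(0.0, 0.9, n),
    }
    for v in VISITS:
        out[f"{v}_height"] = heights[v]
        out[f"{v}_BMI"] = bmis[v]
        out[f"{v}_weight"] = bmis[v] * (heights[v] / 100.0) ** 2

    cov_values = {
        "age": covariates["age"].to_numpy(),
        "height": h0,
        "grip": covariates["grip"].to_numpy(),
        "alcohol": covariates["alcohol"].to_numpy(),
        "walking": covariates["walking"].to_numpy(),
        "bmi": bmi0,
    }
    cov_means = {c: CONTINUOUS_COVARIATES[c].moments()[0] for c in cov_values}

    visit_of = {"M0": "V0", "B0": "V0", "M3": "V3", "B3": "V3", "M5": "V5", "B5": "V5"}
    metric_of = {v: ("LM" if v.startswith("M") else "BMD") for v in _ENDO}
    for limb in LIMBS:
        struct = _calibrate_limb(config, limb)
        values: dict[str, dict[str, np.ndarray]] = {"L": {}, "R": {}}
        for v in _ENDO:
            covterm = np.zeros(n)
            for c, coef in struct.effects[v].items():
                covterm += coef * (cov_values[c] - cov_means[c])
            eL, eR = _disturbance_pair(
                rng, n, struct.disturbance_sd[v], config.left_right_corr, config.t_dof
            )
            for side, e in (("L", eL), ("R", eR)):
                x = struct.intercepts[v] + covterm + e
                for parent, coef in struct.structural[v].items():
                    x = x + coef * values[side][parent]
                values[side][v] = x
        for v in _ENDO:
            for side in SIDES:
                out[f"{visit_of[v]}_{side}_{limb}_{metric_of[v]}"] = values[side][v]

    # side-exclusion flags: onset per visit, persisting thereafter
    for limb in LIMBS:
        for side in SIDES:
            p = config.side_flag_p if side == "L" else 0.2 * config.side_flag_p
            flag = np.zeros(n, dtype=int)
            for v in VISITS:
                flag = np.maximum(flag, (rng.random(n) < p).astype(int))
                out[f"{v}_{side}_{limb}_flag"] = flag

    # dropout last: missing-completely-at-random per visit
    value_cols = {
        v: [c for c in out.columns if c.startswith(f"{v}_") and not c.endswith("_flag")]
        for v in VISITS
    }
    for v, p in zip(VISITS, config.dropout):
        if p > 0:
            gone = rng.random(n) < p
            out.loc[gone, value_cols[v]] = np.nan
    return out


def simulate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """One reproducible cohort draw: covariates then panel, single RNG."""
    rng = np.random.default_rng(config.seed)
    cov = generate_covariates(config, rng)
    return simulate_panel(cov, config, rng)


# ---------------------------------------------------------------------------
# disk format
# ---------------------------------------------------------------------------


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the wide cohort table; full float precision for round-trips."""
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
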