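"""Absolute, parsimonious and relative fit indices for fitted path models.

Implements the chi-square test of exact fit, SRMR, RMSEA with a
noncentral-chi-square confidence interval, the Bentler-Bonett normed fit
index against the independence model, and the two-of-four adequacy rule
(nonsignificant chi-square; RMSEA upper CI < 0.08; SRMR < 0.05;
NFI > 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PathModel, independence_spec

__all__ = [
    "FitIndexSet",
    "chi_square_test",
    "srmr",
    "rmsea_with_ci",
    "bb_nfi",
    "adequacy",
    "independence_chi2",
    "compute_fit_indices",
]


def chi_square_test(
    discrepancy: float, n_samples: int, df: int, *, chi2_kind: str = "wishart"
) -> tuple[float, float]:
    """Likelihood-ratio test of exact fit: chi2 = (N-1) * F (or N * F)."""
    if discrepancy < 0:
        raise ValueError("discrepancy must be nonnegative")
    if n_samples <= 1:
        raise ValueError("need N > 1")
    if df < 0:
        raise ValueError("df must be nonnegative")
    mult = n_samples - 1 if chi2_kind == "wishart" else n_samples
    chi2 = mult * discrepancy
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), p


def srmr(sample: np.ndarray, implied: np.ndarray) -> float:
    """Standardized root mean residual over the unique covariance elements."""
    s = np.asarray(sample, float)
    m = np.asarray(implied, float)
    if s.shape != m.shape or s.shape[0] != s.shape[1]:
        raise ValueError("matrices must be square and conformable")
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    if np.any(np.diag(s) <= 0) or np.any(np.diag(m) <= 0):
        raise ValueError("diagonals must be positive")
    resid = (s - m) / d
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def rmsea_with_ci(
    chi2: float, df: int, n_samples: int, confidence: float = 0.90
) -> tuple[float, float, float]:
    """RMSEA point estimate and noncentrality-inversion confidence interval.

    The point estimate is ``sqrt(max(chi2 - df, 0) / (df * (N - 1)))``.  The
    interval inverts the noncentral chi-square CDF in its noncentrality
    parameter (root-finding to 1e-8) and maps the bounds through the same
    transform; a bound pinned at the boundary is reported as 0.
    """
    if df <= 0:
        raise ValueError("RMSEA is undefined for df = 0")
    if n_samples <= 1:
        raise ValueError("need N > 1")
    denom = df * (n_samples - 1)
    point = float(np.sqrt(max(chi2 - df, 0.0) / denom))
    alpha = 1.0 - confidence
    lo = _invert_noncentrality(chi2, df, 1.0 - alpha / 2.0)
    hi = _invert_noncentrality(chi2, df, alpha / 2.0)
    lower = float(np.sqrt(lo / denom))
    upper = float(np.sqrt(hi / denom))
    return point, lower, upper


def _invert_noncentrality(chi2: float, df: int, q: float) -> float:
    """Largest lambda with P(X_{df,lambda} <= chi2) = q; 0 at the boundary."""
    if stats.chi2.cdf(chi2, df) <= q:
        return 0.0
    f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - q
    hi = max(chi2, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e10:  # pragma: no cover
            return hi
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))


def bb_nfi(chi2_model: float, chi2_null: float) -> float:
    """Bentler-Bonett normed fit index (chi2_null - chi2_model) / chi2_null."""
    if chi2_null <= 0:
        raise ValueError("independence-model chi-square must be positive")
    return float((chi2_null - chi2_model) / chi2_null)


def independence_chi2(sample: np.ndarray, n_samples: int, *, chi2_kind: str = "wishart") -> float:
    """Chi-square of the independence model (diagonal Sigma, variances free).

    Fitted with the same engine as any other model so the null reference
    shares all numerical conventions.
    """
    sample = np.asarray(sample, float)
    p = sample.shape[0]
    spec = independence_spec(tuple(f"v{i}" for i in range(p)))
    null = PathModel(spec, chi2_kind=chi2_kind, compute_se=False)
    null.fit_moments(sample, n_samples)
    return float(null.chi2_)


@dataclass
class FitIndexSet:
    """Fit statistics for one fitted model, plus the adequacy verdict."""

    chi2: float
    df: int
    p_chi2: float
    srmr: float
    rmsea: float
    rmsea_lower: float
    rmsea_upper: float
    bb_nfi: float
    n_samples: int
    adequate: bool = field(init=False)
    criteria_met: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.adequate, self.criteria_met = adequacy(self)

    def to_series(self, name: str = "model") -> pd.Series:
        return pd.Series(
            {
                "N": self.n_samples,
                "chi2": self.chi2,
                "df": self.df,
                "chi2_p": self.p_chi2,
                "SRMR": self.srmr,
                "RMSEA": self.rmsea,
                "RMSEA_lower": self.rmsea_lower,
                "RMSEA_upper": self.rmsea_upper,
                "BB_NFI": self.bb_nfi,
                "adequate": self.adequate,
                "criteria_met": ";".join(self.criteria_met),
            },
            name=name,
        )


def adequacy(fit: FitIndexSet) -> tuple[bool, list[str]]:
    """Two-of-four adequacy rule.

    Criteria: nonsignificant chi-square (p > 0.05); RMSEA upper CI bound
    below 0.08; SRMR below 0.05; NFI above 0.95.  Adequate iff at least two
    hold.
    """
    met = []
    if fit.p_chi2 > 0.05:
        met.append("chi2_nonsignificant")
    if fit.rmsea_upper < 0.08:
        met.append("rmsea_upper_lt_0.08")
    if fit.srmr < 0.05:
        met.append("srmr_lt_0.05")
    if fit.bb_nfi > 0.95:
        met.append("nfi_gt_0.95")
    return len(met) >= 2, met


def compute_fit_indices(fitted: PathModel, confidence: float = 0.90) -> FitIndexSet:
    """Assemble the full index set for a fitted :class:`PathModel`.

    The independence model is refitted on the same sample covariance (all
    observed variables, covariate block included) for the NFI denominator.
    """
    chi2, p = chi_square_test(
        fitted.discrepancy_, fitted.n_samples_, fitted.df_, chi2_kind=fitted.chi2_kind
    )
    s = fitted.sample_cov_.to_numpy()
    m = fitted.implied_cov_.to_numpy()
    srmr_val = srmr(s, m)
    if fitted.df_ > 0:
        rmsea, lo, hi = rmsea_with_ci(chi2, fitted.df_, fitted.n_samples_, confidence)
    else:
        rmsea = lo = hi = 0.0
    null_chi2 = independence_chi2(s, fitted.n_samples_, chi2_kind=fitted.chi2_kind)
    nfi = bb_nfi(chi2, null_chi2)
    return FitIndexSet(
        chi2=chi2,
        df=fitted.df_,
        p_chi2=p,
        srmr=srmr_val,
        rmsea=rmsea,
        rmsea_lower=lo,
        rmsea_upper=hi,
        bb_nfi=nfi,
        n_samples=fitted.n_samples_,
    )
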