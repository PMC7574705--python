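"""Visit summaries, percent change, annualization and LMS z-scores.

Produces per-visit means/SDs with repeated-measures contrasts against
baseline (random-intercept linear model, visit as a categorical fixed
effect), mean per-participant percent change, its annualized rate, and
z-scores against LMS (skewness / median / coefficient-of-variation)
reference parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .simulate import VISITS

__all__ = [
    "LMSReference",
    "VisitSummary",
    "repeated_measures_summary",
    "percent_change",
    "annualize",
    "lms_zscore",
    "summary_table",
]


@dataclass(frozen=True)
class LMSReference:
    """LMS reference-distribution parameters.

    ``L`` is the Box-Cox skewness power, ``M`` the median in metric units,
    ``S`` the coefficient of variation.
    """

    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M must be > 0")
        if self.S <= 0:
            raise ValueError("S must be > 0")


def lms_zscore(x, ref: LMSReference):
    """z = ((X/M)^L - 1) / (L*S), with the log-limit form at L = 0.

    Strictly increasing in X; accepts scalars or arrays; rejects
    nonpositive X (the transform is defined on positive measurements).
    """
    arr = np.asarray(x, float)
    if np.any(arr <= 0):
        raise ValueError("LMS z-scores require X > 0")
    if abs(ref.L) < 1e-8:
        z = np.log(arr / ref.M) / ref.S
    else:
        z = ((arr / ref.M) ** ref.L - 1.0) / (ref.L * ref.S)
    return z if np.ndim(x) else float(z)


def percent_change(
    df: pd.DataFrame, metric: str, from_visit: str = "V0", to_visit: str = "V5"
) -> tuple[float, int]:
    """Mean per-participant percent change 100*(x_t - x_0)/x_0.

    Averages the individual ratios rather than taking the ratio of the
    visit means; the two differ whenever change correlates with baseline.
    Participants with a zero baseline are excluded and counted.
    Returns ``(mean_percent_change, n_excluded)``.
    """
    a = df[f"{from_visit}_{metric}"].to_numpy(float)
    b = df[f"{to_visit}_{metric}"].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    zero = ok & (a == 0)
    use = ok & (a != 0)
    if not use.any():
        raise ValueError(f"no usable pairs for {metric} {from_visit}->{to_visit}")
    pct = 100.0 * (b[use] - a[use]) / a[use]
    return float(pct.mean()), int(zero.sum())


def annualize(pct_change: float, months: float) -> float:
    """Percent change over a window converted to percent per year."""
    if months <= 0:
        raise ValueError("months must be > 0")
    return pct_change / (months / 12.0)


@dataclass
class VisitSummary:
    """Per-visit summary and baseline contrasts for one metric."""

    metric: str
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    contrasts: dict[str, tuple[float, float]]  # visit -> (estimate vs V0, p)
    pct_change: float
    annualized: float
    n_zero_baseline: int = 0

    def to_row(self) -> pd.Series:
        row = {}
        for v in self.means:
            row[f"{v}_mean"] = self.means[v]
            row[f"{v}_sd"] = self.sds[v]
            row[f"{v}_n"] = self.ns[v]
        for v, (est, p) in self.contrasts.items():
            row[f"{v}_vs_V0"] = est
            row[f"{v}_vs_V0_p"] = p
        row["pct_change_V0_V5"] = self.pct_change
        row["annualized_pct"] = self.annualized
        return pd.Series(row, name=self.metric)


def repeated_measures_summary(
    df: pd.DataFrame,
    metric: str,
    visits: tuple[str, ...] = VISITS,
    months: tuple[float, ...] = (0.0, 48.0, 120.0),
) -> VisitSummary:
    """Summarise one metric across visits with repeated-measures contrasts.

    Contrasts against baseline come from a linear model with a
    participant-level random intercept and visit as a categorical fixed
    effect, so repeated measurement within participants is accounted for.
    """
    cols = [f"{v}_{metric}" for v in visits]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"metric {metric!r} absent at visits: {missing}")
    if len(df) < 2:
        raise ValueError("need at least 2 participants for repeated-measures contrasts")
    means, sds, ns = {}, {}, {}
    for v, c in zip(visits, cols):
        x = df[c].dropna()
        means[v], sds[v], ns[v] = float(x.mean()), float(x.std(ddof=1)), int(len(x))

    long = df[cols].copy()
    long["pid"] = np.arange(len(df))
    long = long.melt(id_vars="pid", value_vars=cols, var_name="visit", value_name="value")
    long["visit"] = long["visit"].str.split("_").str[0]
    long = long.dropna(subset=["value"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("value ~ C(visit)", long, groups=long["pid"]).fit(
            reml=True, method="lbfgs"
        )
    contrasts = {}
    for v in visits[1:]:
        term = f"C(visit)[T.{v}]"
        contrasts[v] = (float(fit.params[term]), float(fit.pvalues[term]))

    pct, n_zero = percent_change(df, metric, visits[0], visits[-1])
    ann = annualize(pct, months[-1] - months[0])
    return VisitSummary(
        metric=metric,
        means=means,
        sds=sds,
        ns=ns,
        contrasts=contrasts,
        pct_change=pct,
        annualized=ann,
        n_zero_baseline=n_zero,
    )


def summary_table(df: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Visit-comparison table (one row per metric) ready for CSV export."""
    rows = [repeated_measures_summary(df, m).to_row() for m in metrics]
    return pd.DataFrame(rows)
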