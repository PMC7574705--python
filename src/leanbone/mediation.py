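"""Direct / indirect / total effect decomposition over mediation routes.

For a cross-lagged effect (say V0 muscle on V3 bone) the direct effect is
the coefficient of the direct edge, and the indirect effect sums the
coefficient products over every other directed route -- for the canonical
one-lag case the two parallel routes through same-wave muscle (V0 M -> V3 M
-> V3 B) and through persistent bone (V0 M -> V0 B -> V3 B).  Standard
errors for the composite effects use the first-order delta method on the
joint parameter covariance.  Reporting follows the conventional layout:
percentages of the total, and the |indirect|/|direct| ratio, with
divide-by-zero flags (not exceptions) when a denominator is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model import PathModel, PathModelSpec

__all__ = [
    "EffectDecomposition",
    "enumerate_mediation_paths",
    "decompose",
    "decomposition_table",
    "format_decomposition_table",
]

#: standardized-units denominator magnitude below which a derived quantity
#: is flagged rather than reported (a reporting convention, reverse-read
#: from typical published flagging behaviour; configurable per call)
FLAG_THRESHOLD = 0.01


@dataclass
class EffectDecomposition:
    """Direct/indirect/total decomposition for one predictor-outcome pair."""

    predictor: str
    outcome: str
    direct: float
    indirect: float
    total: float
    direct_se: float = np.nan
    indirect_se: float = np.nan
    total_se: float = np.nan
    direct_p: float = np.nan
    indirect_p: float = np.nan
    total_p: float = np.nan
    dir_pct: float = np.nan
    ind_pct: float = np.nan
    ratio: float = np.nan
    pct_flagged: bool = False
    ratio_flagged: bool = False
    n_paths: int = 0

    @classmethod
    def from_components(
        cls,
        direct: float,
        indirect: float,
        *,
        predictor: str = "",
        outcome: str = "",
        flag_threshold: float = FLAG_THRESHOLD,
        **kwargs,
    ) -> "EffectDecomposition":
        """Derive total, percentages, ratio and flags from the two effects."""
        total = direct + indirect
        pct_flagged = abs(total) < flag_threshold
        ratio_flagged = abs(direct) < flag_threshold
        dir_pct = np.nan if pct_flagged else 100.0 * direct / total
        ind_pct = np.nan if pct_flagged else 100.0 * indirect / total
        ratio = np.nan if ratio_flagged else abs(indirect) / abs(direct)
        return cls(
            predictor=predictor,
            outcome=outcome,
            direct=direct,
            indirect=indirect,
            total=total,
            dir_pct=dir_pct,
            ind_pct=ind_pct,
            ratio=ratio,
            pct_flagged=pct_flagged,
            ratio_flagged=ratio_flagged,
            **kwargs,
        )

    def to_row(self) -> pd.Series:
        def pct(v, flagged):
            return "Div by 0" if flagged else round(v, 1)

        return pd.Series(
            {
                "Predictor": self.predictor,
                "Outcome": self.outcome,
                "Direct": round(self.direct, 4),
                "Direct_SE": round(self.direct_se, 4),
                "Direct_p": round(self.direct_p, 4),
                "Indirect": round(self.indirect, 4),
                "Indirect_SE": round(self.indirect_se, 4),
                "Indirect_p": round(self.indirect_p, 4),
                "Total": round(self.total, 4),
                "Total_SE": round(self.total_se, 4),
                "Total_p": round(self.total_p, 4),
                "Dir_pct_of_total": pct(self.dir_pct, self.pct_flagged),
                "Ind_pct_of_total": pct(self.ind_pct, self.pct_flagged),
                "Ind_dir_ratio": "Div by 0" if self.ratio_flagged else round(self.ratio, 1),
            }
        )


def enumerate_mediation_paths(
    spec: PathModelSpec, predictor: str, outcome: str
) -> list[tuple[str, ...]]:
    """All directed routes from predictor to outcome except the direct edge.

    Routes through the exogenous covariate block cannot exist (covariates
    have no incoming structural edges), so the enumeration is confined to
    the endogenous graph by construction.
    """
    if predictor == outcome:
        raise ValueError("predictor and outcome must differ")
    for v in (predictor, outcome):
        if v not in spec.variables:
            raise ValueError(f"variable {v!r} not in the model")
    g = spec.graph()
    paths = [
        tuple(p)
        for p in nx.all_simple_paths(g, predictor, outcome)
        if len(p) > 2  # exclude the single direct edge
    ]
    return sorted(paths)


def _effect_functions(fitted: PathModel, predictor: str, outcome: str, standardized: bool):
    compiled = fitted._compiled
    spec = fitted.spec_
    paths = enumerate_mediation_paths(spec, predictor, outcome)
    has_direct = spec.graph().has_edge(predictor, outcome)

    def effects(theta: np.ndarray) -> np.ndarray:
        direct = compiled.edge_coefficient(theta, predictor, outcome) if has_direct else 0.0
        indirect = 0.0
        for path in paths:
            prod = 1.0
            for a, b in zip(path[:-1], path[1:]):
                prod *= compiled.edge_coefficient(theta, a, b)
            indirect += prod
        if standardized:
            sigma = compiled.implied(theta)
            sd = np.sqrt(np.clip(np.diag(sigma), 0.0, None))
            scale = sd[compiled.idx[predictor]] / sd[compiled.idx[outcome]]
            # a product of standardized coefficients telescopes to the
            # unstandardized product times sd(predictor)/sd(outcome)
            direct *= scale
            indirect *= scale
        return np.array([direct, indirect, direct + indirect])

    return effects, paths


def decompose(
    fitted: PathModel,
    predictor: str,
    outcome: str,
    *,
    standardized: bool = True,
    flag_threshold: float = FLAG_THRESHOLD,
) -> EffectDecomposition:
    """Decompose a fitted cross-lagged effect into direct and indirect parts.

    Requires a converged model with standard errors; delta-method SEs use a
    numerical Jacobian of (direct, indirect, total) with respect to the
    free parameters against the fitted parameter covariance.
    """
    if not fitted.convergence_.converged:
        raise RuntimeError("cannot decompose effects of a non-converged model")
    effects, paths = _effect_functions(fitted, predictor, outcome, standardized)
    theta = fitted.theta_
    est = effects(theta)
    k = len(theta)
    J = np.zeros((3, k))
    for i in range(k):
        h = 1e-6 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (effects(tp) - effects(tm)) / (2 * h)
    cov = J @ fitted.param_cov_.to_numpy() @ J.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return EffectDecomposition.from_components(
        float(est[0]),
        float(est[1]),
        predictor=predictor,
        outcome=outcome,
        flag_threshold=flag_threshold,
        direct_se=float(se[0]),
        indirect_se=float(se[1]),
        total_se=float(se[2]),
        direct_p=float(p[0]),
        indirect_p=float(p[1]),
        total_p=float(p[2]),
        n_paths=len(paths),
    )


def decomposition_table(
    fitted_models: dict[str, PathModel],
    pairs: dict[str, list[tuple[str, str]]],
    *,
    standardized: bool = True,
    flag_threshold: float = FLAG_THRESHOLD,
) -> pd.DataFrame:
    """Assemble one decomposition row per (model, predictor, outcome)."""
    rows = []
    for name, model in fitted_models.items():
        for predictor, outcome in pairs.get(name, []):
            d = decompose(
                model,
                predictor,
                outcome,
                standardized=standardized,
                flag_threshold=flag_threshold,
            )
            row = d.to_row()
            row["Model"] = name
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["Model", "Predictor", "Outcome", "Direct", "Direct_SE", "Direct_p",
                     "Indirect", "Indirect_SE", "Indirect_p", "Total", "Total_SE",
                     "Total_p", "Dir_pct_of_total", "Ind_pct_of_total", "Ind_dir_ratio"]
        )
    out = pd.DataFrame(rows)
    cols = ["Model"] + [c for c in out.columns if c != "Model"]
    return out[cols]


def format_decomposition_table(table: pd.DataFrame) -> str:
    """Human-readable rendering with 'Div by 0' flags preserved."""
    return table.to_string(index=False)
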