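"""Observed-variable path analysis by normal-theory maximum likelihood.

This module is the structural engine of the package.  A model is written
down as a :class:`PathModelSpec` -- a set of directed regression edges and
bidirected variance/covariance edges over observed variables, in the
reticular-action-model (RAM) formulation.  Equality constraints are imposed
by giving several edges the same parameter label; edges can also be fixed
to a constant.  The model-implied covariance is

    Sigma(theta) = (I - A)^-1 S (I - A)^-T

where ``A`` holds the directed-edge coefficients (A[target, source]) and
``S`` the variances/covariances.  Fitting minimises the normal-theory
discrepancy

    F = log|Sigma| + tr(S_sample Sigma^-1) - log|S_sample| - p

over the free parameters, which yields the Wishart likelihood-ratio
chi-square statistic ``(N - 1) * F`` at the optimum.

:class:`PathModel` wraps the machinery as a scikit-learn style estimator:
``fit`` consumes a DataFrame (or the sample covariance directly through
``fit_moments``) and exposes fitted attributes with trailing underscores.
:class:`CrossLaggedPanelModel` builds the canonical three-wave muscle-bone
cross-lagged structure used throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "PathModelSpec",
    "PathModel",
    "CrossLaggedPanelModel",
    "ModelSpecError",
    "UnderIdentifiedError",
    "build_clpm_spec",
    "independence_spec",
    "implied_covariance",
    "ml_discrepancy",
    "model_df",
    "standardize",
]


class ModelSpecError(ValueError):
    """The path-model specification is internally inconsistent."""


class UnderIdentifiedError(ModelSpecError):
    """More free parameters than unique covariance moments (df < 0)."""


@dataclass(frozen=True)
class Edge:
    """A single edge of a path model.

    A free edge carries a ``label`` (shared labels impose equality
    constraints); a fixed edge carries a numeric ``value`` instead.
    """

    source: str
    target: str
    label: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == (self.value is None):
            raise ModelSpecError(
                f"edge {self.source}->{self.target}: exactly one of "
                "'label' (free) or 'value' (fixed) must be given"
            )
        if self.value is not None and not np.isfinite(self.value):
            raise ModelSpecError(
                f"edge {self.source}->{self.target}: fixed value must be finite"
            )

    @property
    def free(self) -> bool:
        return self.label is not None


@dataclass(frozen=True)
class PathModelSpec:
    """Directed + bidirected edge list defining a RAM path model.

    Parameters
    ----------
    variables
        Observed variables, in the order used for all matrices.
    directed
        Regression edges ``source -> target``.
    bidirected
        Variance (``source == target``) and covariance edges.
    exogenous
        Names of variables marked as the exogenous covariate block
        (purely informational; used by mediation to skip covariate routes).
    start_values
        Optional ``(label, value)`` pairs seeding the optimiser.
    """

    variables: tuple[str, ...]
    directed: tuple[Edge, ...] = ()
    bidirected: tuple[Edge, ...] = ()
    exogenous: tuple[str, ...] = ()
    start_values: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ModelSpecError("duplicate variable names")
        known = set(self.variables)
        for e in self.directed + self.bidirected:
            for v in (e.source, e.target):
                if v not in known:
                    raise ModelSpecError(f"edge refers to unknown variable {v!r}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ModelSpecError("directed part of the model contains a cycle")
        # every variable needs exactly one variance parameter
        n_var = {v: 0 for v in self.variables}
        for e in self.bidirected:
            if e.source == e.target:
                n_var[e.source] += 1
        bad = [v for v, k in n_var.items() if k != 1]
        if bad:
            raise ModelSpecError(
                f"each variable needs exactly one variance edge; offending: {bad}"
            )
        d_labels = {e.label for e in self.directed if e.free}
        s_labels = {e.label for e in self.bidirected if e.free}
        shared = d_labels & s_labels
        if shared:
            raise ModelSpecError(
                f"labels used on both directed and bidirected edges: {sorted(shared)}"
            )
        unknown_starts = [k for k, _ in self.start_values if k not in d_labels | s_labels]
        if unknown_starts:
            raise ModelSpecError(f"start values for unknown labels: {unknown_starts}")

    # -- derived views --------------------------------------------------
    def graph(self) -> nx.DiGraph:
        """Directed subgraph, edge attribute ``edge`` holding the Edge."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for e in self.directed:
            g.add_edge(e.source, e.target, edge=e)
        return g

    @property
    def free_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.directed + self.bidirected:
            if e.free and e.label not in seen:
                seen[e.label] = None
        return tuple(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def with_start_values(self, **starts: float) -> "PathModelSpec":
        merged = dict(self.start_values)
        merged.update(starts)
        return replace(self, start_values=tuple(merged.items()))

    # -- serialisation --------------------------------------------------
    def to_edge_list(self) -> str:
        """Plain-text edge list (``a -> b [label]`` / ``a <-> b = 1.0``)."""
        lines = []
        for arrow, edges in (("->", self.directed), ("<->", self.bidirected)):
            for e in edges:
                rhs = f"[{e.label}]" if e.free else f"= {e.value!r}"
                lines.append(f"{e.source} {arrow} {e.target} {rhs}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_list(
        cls, text: str, exogenous: tuple[str, ...] = ()
    ) -> "PathModelSpec":
        directed, bidirected, variables = [], [], {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for arrow, bucket in (("<->", bidirected), ("->", directed)):
                if arrow in line:
                    lhs, rhs = line.split(arrow, 1)
                    src = lhs.strip()
                    rest = rhs.strip()
                    if "[" in rest:
                        tgt, lab = rest.split("[", 1)
                        e = Edge(src, tgt.strip(), label=lab.rstrip("]").strip())
                    elif "=" in rest:
                        tgt, val = rest.split("=", 1)
                        e = Edge(src, tgt.strip(), value=float(val))
                    else:
                        raise ModelSpecError(f"cannot parse line: {line!r}")
                    bucket.append(e)
                    variables.setdefault(e.source, None)
                    variables.setdefault(e.target, None)
                    break
        return cls(tuple(variables), tuple(directed), tuple(bidirected), exogenous)


# ---------------------------------------------------------------------------
# free functions: RAM algebra
# ---------------------------------------------------------------------------


def model_df(spec: PathModelSpec, n_observed: int | None = None) -> int:
    """Degrees of freedom: p(p+1)/2 minus the number of distinct free labels."""
    p = len(spec.variables) if n_observed is None else n_observed
    df = p * (p + 1) // 2 - spec.n_free
    if df < 0:
        raise UnderIdentifiedError(
            f"model has {spec.n_free} free parameters but only "
            f"{p * (p + 1) // 2} covariance moments (df = {df})"
        )
    return df


def implied_covariance(
    spec: PathModelSpec, params: dict[str, float] | None = None
) -> pd.DataFrame:
    """Model-implied covariance Sigma = (I-A)^-1 S (I-A)^-T.

    ``params`` maps free labels to values; fixed edges use their values.
    """
    compiled = _CompiledSpec(spec)
    theta = compiled.theta_from_mapping(params or {})
    sigma = compiled.implied(theta)
    return pd.DataFrame(sigma, index=spec.variables, columns=spec.variables)


def ml_discrepancy(sigma: np.ndarray, sample: np.ndarray) -> float:
    """Normal-theory ML fit function F(Sigma, S); zero iff Sigma == S."""
    sigma = np.asarray(sigma, float)
    sample = np.asarray(sample, float)
    p = sigma.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(sample)
    if sign_s <= 0:
        raise ValueError("sample covariance must be positive definite")
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    return float(logdet + np.trace(np.linalg.solve(sigma, sample)) - logdet_s - p)


# ---------------------------------------------------------------------------
# compiled spec: fast objective + analytic gradient
# ---------------------------------------------------------------------------


class _CompiledSpec:
    """Index-array compilation of a PathModelSpec for fast evaluation."""

    def __init__(self, spec: PathModelSpec):
        self.spec = spec
        self.variables = spec.variables
        self.p = len(spec.variables)
        self.idx = {v: i for i, v in enumerate(spec.variables)}
        self.labels = list(spec.free_labels)
        self.k = {lab: i for i, lab in enumerate(self.labels)}
        # directed entries: A[target, source]
        self.a_fix: list[tuple[int, int, float]] = []
        self.a_free: list[tuple[int, int, int]] = []
        for e in spec.directed:
            t, s = self.idx[e.target], self.idx[e.source]
            if e.free:
                self.a_free.append((t, s, self.k[e.label]))
            else:
                self.a_fix.append((t, s, e.value))
        self.s_fix: list[tuple[int, int, float]] = []
        self.s_free: list[tuple[int, int, int]] = []
        for e in spec.bidirected:
            i, j = self.idx[e.source], self.idx[e.target]
            if e.free:
                self.s_free.append((i, j, self.k[e.label]))
            else:
                self.s_fix.append((i, j, e.value))
        self._af = np.array(self.a_free, int).reshape(-1, 3)
        self._sf = np.array(self.s_free, int).reshape(-1, 3)

    # -- parameter handling --------------------------------------------
    def theta_from_mapping(self, params: dict[str, float]) -> np.ndarray:
        missing = [lab for lab in self.labels if lab not in params]
        if missing:
            raise ModelSpecError(f"missing values for free labels: {missing}")
        return np.array([params[lab] for lab in self.labels], float)

    def scale_vector(self, sample: np.ndarray | None) -> np.ndarray:
        """Characteristic magnitude per free label, for optimiser conditioning.

        Variances scale with the corresponding sample variance, covariances
        with the geometric mean of the two variances, directed coefficients
        with sd(target)/sd(source).
        """
        scale = np.ones(len(self.labels))
        if sample is None:
            return scale
        sd = np.sqrt(np.clip(np.diag(sample), 1e-12, None))
        seen = np.zeros(len(self.labels), bool)
        for i, j, k in self.s_free:
            if not seen[k]:
                scale[k] = max(sd[i] * sd[j], 1e-10)
                seen[k] = True
        for t, s, k in self.a_free:
            if not seen[k]:
                scale[k] = max(sd[t] / sd[s], 1e-10)
                seen[k] = True
        return scale

    def start_theta(self, sample: np.ndarray | None) -> np.ndarray:
        """Identity-scaled starting point.

        Directed coefficients start at 0 unless the spec supplies a start
        value (the CLPM builder seeds autoregressive labels at 0.8);
        variances/covariances start at the corresponding sample moments.
        """
        theta = np.zeros(len(self.labels))
        filled = np.zeros(len(self.labels), bool)
        for i, j, k in self.s_free:
            if not filled[k]:
                if sample is not None:
                    theta[k] = sample[i, j] if i != j else max(sample[i, i], 1e-8)
                else:
                    theta[k] = 1.0 if i == j else 0.0
                filled[k] = True
        for lab, val in self.spec.start_values:
            theta[self.k[lab]] = val
        return theta

    # -- matrices -------------------------------------------------------
    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = np.zeros((self.p, self.p))
        S = np.zeros((self.p, self.p))
        for t, s, v in self.a_fix:
            A[t, s] = v
        if len(self._af):
            A[self._af[:, 0], self._af[:, 1]] = theta[self._af[:, 2]]
        for i, j, v in self.s_fix:
            S[i, j] = v
            S[j, i] = v
        if len(self._sf):
            S[self._sf[:, 0], self._sf[:, 1]] = theta[self._sf[:, 2]]
            S[self._sf[:, 1], self._sf[:, 0]] = theta[self._sf[:, 2]]
        return A, S

    def implied(self, theta: np.ndarray) -> np.ndarray:
        A, S = self.matrices(theta)
        B = np.linalg.solve(np.eye(self.p) - A, np.eye(self.p))
        sigma = B @ S @ B.T
        return (sigma + sigma.T) / 2.0

    def edge_coefficient(self, theta: np.ndarray, source: str, target: str) -> float:
        t, s = self.idx[target], self.idx[source]
        for tt, ss, k in self.a_free:
            if (tt, ss) == (t, s):
                return float(theta[k])
        for tt, ss, v in self.a_fix:
            if (tt, ss) == (t, s):
                return float(v)
        return 0.0

    # -- objective ------------------------------------------------------
    def value_and_grad(
        self, theta: np.ndarray, sample: np.ndarray, logdet_s: float, penalty: float
    ) -> tuple[float, np.ndarray]:
        A, S = self.matrices(theta)
        B = np.linalg.solve(np.eye(self.p) - A, np.eye(self.p))
        sigma = B @ S @ B.T
        sigma = (sigma + sigma.T) / 2.0
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            # non-PD excursion: smooth basin pushing back toward smaller steps
            g = 2.0 * penalty * theta
            return penalty * (1.0 + float(theta @ theta)), g
        logdet = 2.0 * np.log(np.diag(c)).sum()
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + float(np.sum(sigma_inv * sample)) - logdet_s - self.p
        G = sigma_inv @ (sigma - sample) @ sigma_inv  # symmetric
        grad = np.zeros(len(self.labels))
        if len(self._af):
            P = sigma @ G @ B  # tr(G B E_ts Sigma) = P[s, t]
            np.add.at(grad, self._af[:, 2], 2.0 * P[self._af[:, 1], self._af[:, 0]])
        if len(self._sf):
            Q = B.T @ G @ B
            i, j, k = self._sf[:, 0], self._sf[:, 1], self._sf[:, 2]
            w = np.where(i == j, 1.0, 2.0)
            np.add.at(grad, k, w * Q[i, j])
        return f, grad


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceRecord:
    converged: bool
    optimizer: str
    fallback_used: bool
    n_iter: int
    n_fev: int
    grad_norm: float
    message: str = ""


class PathModel(BaseEstimator):
    """Maximum-likelihood path model over observed variables.

    Parameters
    ----------
    spec
        The :class:`PathModelSpec` to fit.
    chi2_kind
        ``"wishart"`` uses the (N-1) chi-square multiplier, ``"ml"`` uses N.
    optimizer, fallback_optimizer
        Primary scipy minimiser and the quasi-Newton restart invoked (with
        an enlarged evaluation budget) when the primary run fails to
        converge.  The fallback, and which optimiser produced the reported
        solution, are recorded in ``convergence_``.
    compute_se
        Whether to compute standard errors (inverse observed information of
        the discrepancy, scaled by 2/(N-1)) and standardized estimates.

    Attributes
    ----------
    params_ : pandas.Series
        Estimates per free label.
    se_, pvalues_ : pandas.Series
        Standard errors / two-sided normal p-values per free label.
    param_cov_ : pandas.DataFrame
        Estimated covariance of the free parameters.
    implied_cov_, sample_cov_ : pandas.DataFrame
        Model-implied and sample covariance matrices.
    discrepancy_, chi2_, df_, n_samples_ : float / int
        Minimised fit function and chi-square ingredients.
    estimates_ : pandas.DataFrame
        One row per directed edge with unstandardized and standardized
        estimates, SEs and p-values.
    convergence_ : ConvergenceRecord
    """

    def __init__(
        self,
        spec: PathModelSpec | None = None,
        *,
        chi2_kind: str = "wishart",
        optimizer: str = "BFGS",
        fallback_optimizer: str = "BFGS",
        max_iter: int = 500,
        fallback_max_iter: int = 5000,
        gtol: float = 1e-7,
        compute_se: bool = True,
        penalty: float = 1e8,
    ):
        self.spec = spec
        self.chi2_kind = chi2_kind
        self.optimizer = optimizer
        self.fallback_optimizer = fallback_optimizer
        self.max_iter = max_iter
        self.fallback_max_iter = fallback_max_iter
        self.gtol = gtol
        self.compute_se = compute_se
        self.penalty = penalty

    # -- data entry points ----------------------------------------------
    def fit(self, X, y=None) -> "PathModel":
        """Fit from raw data (DataFrame with spec variables as columns)."""
        spec = self._resolved_spec(X)
        if isinstance(X, pd.DataFrame):
            missing = [v for v in spec.variables if v not in X.columns]
            if missing:
                raise ModelSpecError(f"data is missing model variables: {missing}")
            data = X.loc[:, list(spec.variables)].to_numpy(float)
        else:
            data = np.asarray(X, float)
            if data.shape[1] != len(spec.variables):
                raise ModelSpecError(
                    "array width does not match the number of model variables"
                )
        if np.isnan(data).any():
            raise ModelSpecError(
                "missing values in model variables; apply the complete-case "
                "filter before fitting"
            )
        n = data.shape[0]
        sample = np.cov(data, rowvar=False, ddof=1)
        return self._fit_moments(spec, sample, n)

    def fit_moments(self, sample_cov, n_samples: int) -> "PathModel":
        """Fit from a sample covariance matrix and its sample size."""
        spec = self._resolved_spec(None)
        sample = np.asarray(sample_cov, float)
        return self._fit_moments(spec, sample, int(n_samples))

    def _resolved_spec(self, X) -> PathModelSpec:
        if self.spec is None:
            raise ModelSpecError("no model spec supplied")
        return self.spec

    # -- core fit --------------------------------------------------------
    def _fit_moments(self, spec: PathModelSpec, sample: np.ndarray, n: int) -> "PathModel":
        p = len(spec.variables)
        if sample.shape != (p, p):
            raise ModelSpecError("sample covariance has the wrong shape")
        if n <= p:
            raise ModelSpecError(f"need N > p = {p} observations, got N = {n}")
        sign, logdet_s = np.linalg.slogdet(sample)
        if sign <= 0:
            raise ModelSpecError("sample covariance is not positive definite")
        compiled = _CompiledSpec(spec)
        self.spec_ = spec
        self._compiled = compiled
        self.df_ = model_df(spec, p)
        theta0 = compiled.start_theta(sample)
        scale = compiled.scale_vector(sample)

        fun = lambda th: compiled.value_and_grad(th, sample, logdet_s, self.penalty)

        def fun_scaled(phi):
            f, g = fun(phi * scale)
            return f, g * scale

        phi0 = theta0 / scale
        res = optimize.minimize(
            fun_scaled,
            phi0,
            jac=True,
            method=self.optimizer,
            options=self._options(self.optimizer, self.max_iter),
        )
        fallback = False
        if not self._is_converged(res):
            logger.info(
                "primary optimizer %s did not converge (%s); quasi-Newton "
                "restarts with enlarged budget",
                self.optimizer,
                res.message,
            )
            fallback = True
            # restarting resets the quasi-Newton curvature model, which
            # recovers from line-search breakdowns on ill-conditioned fits
            for _ in range(4):
                res2 = optimize.minimize(
                    fun_scaled,
                    res.x,
                    jac=True,
                    method=self.fallback_optimizer,
                    options=self._options(
                        self.fallback_optimizer, self.fallback_max_iter
                    ),
                )
                if res2.fun <= res.fun:
                    res = res2
                if self._is_converged(res):
                    break
        theta = self._polish(fun_scaled, res.x) * scale
        f_val, grad = fun(theta)
        converged = bool(np.linalg.norm(grad, np.inf) < 1e-5)
        self.convergence_ = ConvergenceRecord(
            converged=converged,
            optimizer=self.fallback_optimizer if fallback else self.optimizer,
            fallback_used=fallback,
            n_iter=int(getattr(res, "nit", -1)),
            n_fev=int(getattr(res, "nfev", -1)),
            grad_norm=float(np.linalg.norm(grad, np.inf)),
            message=str(res.message),
        )
        if not converged:
            warnings.warn(
                "path model did not converge even after the quasi-Newton "
                f"fallback (grad norm {self.convergence_.grad_norm:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )

        labels = list(spec.free_labels)
        vars_ = list(spec.variables)
        self.n_samples_ = n
        self.n_obs_vars_ = p
        self.discrepancy_ = max(float(f_val), 0.0)
        self.chi2_ = self._chi2_multiplier() * self.discrepancy_
        self.params_ = pd.Series(theta, index=labels, name="estimate")
        sigma = compiled.implied(theta)
        self.implied_cov_ = pd.DataFrame(sigma, index=vars_, columns=vars_)
        self.sample_cov_ = pd.DataFrame(sample, index=vars_, columns=vars_)

        if self.compute_se:
            self._compute_uncertainty(fun, theta)
        return self

    def _options(self, method: str, max_iter: int) -> dict:
        opts: dict = {"maxiter": max_iter}
        if method == "L-BFGS-B":
            opts["maxfun"] = 20 * max_iter
            opts["gtol"] = self.gtol
            opts["ftol"] = 1e-14
        elif method in ("BFGS", "CG"):
            opts["gtol"] = self.gtol
        return opts

    def _is_converged(self, res) -> bool:
        return bool(res.success) and np.linalg.norm(res.jac, np.inf) < 1e-4

    @staticmethod
    def _polish(fun, theta: np.ndarray, iters: int = 4) -> np.ndarray:
        """Newton polish with a finite-difference Hessian of the gradient.

        Tightens the optimiser solution to near machine precision, which the
        closed-form checks (least-squares equivalence, saturation) rely on.
        """
        th = theta.copy()
        f, g = fun(th)
        for _ in range(iters):
            if np.linalg.norm(g, np.inf) < 1e-12:
                break
            H = _numeric_hessian(fun, th)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            cand = th - step
            f2, g2 = fun(cand)
            if not np.isfinite(f2) or f2 > f + 1e-12:
                break
            th, f, g = cand, f2, g2
        return th

    def _chi2_multiplier(self) -> float:
        if self.chi2_kind == "wishart":
            return float(self.n_samples_ - 1)
        if self.chi2_kind == "ml":
            return float(self.n_samples_)
        raise ValueError(f"unknown chi2_kind {self.chi2_kind!r}")

    # -- uncertainty -----------------------------------------------------
    def _compute_uncertainty(self, fun, theta: np.ndarray) -> None:
        labels = list(self.spec_.free_labels)
        H = _numeric_hessian(fun, theta)
        scale = 2.0 / self._chi2_multiplier()
        try:
            cov = scale * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = scale * np.linalg.pinv(H)
        self.param_cov_ = pd.DataFrame(cov, index=labels, columns=labels)
        var = np.diag(cov).copy()
        bad = var < 0
        if bad.any():
            warnings.warn(
                "negative information-matrix variances for "
                f"{[l for l, b in zip(labels, bad) if b]}; SEs set to NaN",
                RuntimeWarning,
                stacklevel=2,
            )
            var[bad] = np.nan
        se = np.sqrt(var)
        self.se_ = pd.Series(se, index=labels, name="se")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = theta / se
        self.zvalues_ = pd.Series(z, index=labels, name="z")
        self.pvalues_ = pd.Series(
            2.0 * stats.norm.sf(np.abs(z)), index=labels, name="p"
        )
        self.estimates_ = standardize(self)

    # -- convenience -----------------------------------------------------
    @property
    def theta_(self) -> np.ndarray:
        return self.params_.to_numpy()

    def edge_estimate(self, source: str, target: str) -> float:
        return self._compiled.edge_coefficient(self.theta_, source, target)

    def implied_sd(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.implied_cov_.to_numpy())),
            index=self.spec_.variables,
        )


def _numeric_hessian(fun, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from the analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        h = step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2.0


def standardize(fitted: PathModel) -> pd.DataFrame:
    """Standardized path coefficients with delta-method standard errors.

    Each directed coefficient is rescaled by the implied SDs of its source
    and target.  Edges sharing an equality-constrained label can therefore
    have distinct standardized values.  SEs propagate the full parameter
    covariance through a numerical Jacobian of the standardization map.
    """
    compiled: _CompiledSpec = fitted._compiled
    spec = fitted.spec_
    theta = fitted.theta_
    edges = [e for e in spec.directed if e.free]

    def std_vector(th: np.ndarray) -> np.ndarray:
        sigma = compiled.implied(th)
        sd = np.sqrt(np.clip(np.diag(sigma), 0.0, None))
        out = np.empty(len(edges))
        for i, e in enumerate(edges):
            s, t = compiled.idx[e.source], compiled.idx[e.target]
            denom = sd[t] if sd[t] > 0 else np.nan
            out[i] = th[compiled.k[e.label]] * sd[s] / denom
        return out

    std = std_vector(theta)
    rows = {
        "predictor": [e.source for e in edges],
        "outcome": [e.target for e in edges],
        "label": [e.label for e in edges],
        "estimate": [theta[compiled.k[e.label]] for e in edges],
        "se": [fitted.se_[e.label] for e in edges],
        "p": [fitted.pvalues_[e.label] for e in edges],
        "std_estimate": std,
    }
    # delta method on the standardization map
    k = len(theta)
    J = np.zeros((len(edges), k))
    for i in range(k):
        h = 1e-6 * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        J[:, i] = (std_vector(tp) - std_vector(tm)) / (2 * h)
    cov = J @ fitted.param_cov_.to_numpy() @ J.T
    var = np.clip(np.diag(cov), 0.0, None)
    std_se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = std / std_se
    rows["std_se"] = std_se
    rows["std_p"] = 2.0 * stats.norm.sf(np.abs(z))
    rows["flagged_zero_variance"] = ~np.isfinite(std)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canonical specs
# ---------------------------------------------------------------------------


def build_clpm_spec(
    muscle_vars: tuple[str, str, str],
    bone_vars: tuple[str, str, str],
    covariates: tuple[str, ...] = (),
    *,
    free_v3_disturbance_cov: bool = False,
    ar_start: float = 0.8,
) -> PathModelSpec:
    """Canonical three-wave cross-lagged panel structure.

    Endogenous block: muscle and bone at the three visits with
    contemporaneous muscle->bone paths at every visit (3 free),
    one-lag cross-paths in both directions (4 free), and autoregressive
    paths equality-constrained per construct across the two lags (2 free).
    Each covariate gets a directed edge to every endogenous variable and
    the covariate block covaries freely.

    ``free_v3_disturbance_cov`` additionally frees the mid-wave
    muscle<->bone disturbance covariance, lowering the endogenous df from
    6 to 5.
    """
    if len(muscle_vars) != 3 or len(bone_vars) != 3:
        raise ModelSpecError("need exactly three muscle and three bone variables")
    names = list(muscle_vars) + list(bone_vars) + list(covariates)
    if len(set(names)) != len(names):
        raise ModelSpecError("duplicate variable names across muscle/bone/covariates")
    m0, m3, m5 = muscle_vars
    b0, b3, b5 = bone_vars
    directed = [
        Edge(m0, b0, label="beta_mb_v0"),
        Edge(m3, b3, label="beta_mb_v3"),
        Edge(m5, b5, label="beta_mb_v5"),
        Edge(m0, b3, label="gamma_mb_lag1"),
        Edge(m3, b5, label="gamma_mb_lag2"),
        Edge(b0, m3, label="gamma_bm_lag1"),
        Edge(b3, m5, label="gamma_bm_lag2"),
        Edge(m0, m3, label="rho_muscle"),
        Edge(m3, m5, label="rho_muscle"),
        Edge(b0, b3, label="rho_bone"),
        Edge(b3, b5, label="rho_bone"),
    ]
    endo = [m0, b0, m3, b3, m5, b5]
    bidirected = [Edge(v, v, label=f"var_{v}") for v in endo]
    if free_v3_disturbance_cov:
        bidirected.append(Edge(m3, b3, label="cov_v3_disturbance"))
    for i, c in enumerate(covariates):
        bidirected.append(Edge(c, c, label=f"var_{c}"))
        for c2 in covariates[i + 1 :]:
            bidirected.append(Edge(c, c2, label=f"cov_{c}_{c2}"))
        for v in endo:
            directed.append(Edge(c, v, label=f"b_{c}_{v}"))
    variables = tuple(endo) + tuple(covariates)
    return PathModelSpec(
        variables=variables,
        directed=tuple(directed),
        bidirected=tuple(bidirected),
        exogenous=tuple(covariates),
        start_values=(("rho_muscle", ar_start), ("rho_bone", ar_start)),
    )


def independence_spec(variables: tuple[str, ...]) -> PathModelSpec:
    """Null (independence) model: free variances, all covariances zero."""
    return PathModelSpec(
        variables=tuple(variables),
        directed=(),
        bidirected=tuple(Edge(v, v, label=f"var_{v}") for v in variables),
    )


class CrossLaggedPanelModel(PathModel):
    """Three-wave muscle-bone CLPM keyed by analysis-column names.

    A thin convenience estimator: given a muscle metric base (for example
    ``"leg_LMI"``), a bone metric base (``"leg_BMD"``) and covariate
    columns, it builds the canonical spec against the wide analysis table
    (columns ``V0_<base>``, ``V3_<base>``, ``V5_<base>``) at fit time.
    """

    def __init__(
        self,
        muscle_metric: str = "leg_LM",
        bone_metric: str = "leg_BMD",
        covariates: tuple[str, ...] = (),
        *,
        free_v3_disturbance_cov: bool = False,
        chi2_kind: str = "wishart",
        optimizer: str = "BFGS",
        fallback_optimizer: str = "BFGS",
        max_iter: int = 500,
        fallback_max_iter: int = 5000,
        gtol: float = 1e-7,
        compute_se: bool = True,
        penalty: float = 1e8,
    ):
        super().__init__(
            spec=None,
            chi2_kind=chi2_kind,
            optimizer=optimizer,
            fallback_optimizer=fallback_optimizer,
            max_iter=max_iter,
            fallback_max_iter=fallback_max_iter,
            gtol=gtol,
            compute_se=compute_se,
            penalty=penalty,
        )
        self.muscle_metric = muscle_metric
        self.bone_metric = bone_metric
        self.covariates = covariates
        self.free_v3_disturbance_cov = free_v3_disturbance_cov

    def _resolved_spec(self, X) -> PathModelSpec:
        visits = ("V0", "V3", "V5")
        muscle = tuple(f"{v}_{self.muscle_metric}" for v in visits)
        bone = tuple(f"{v}_{self.bone_metric}" for v in visits)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in muscle + bone + tuple(self.covariates) if c not in X.columns]
            if missing:
                raise ModelSpecError(f"unknown columns for CLPM: {missing}")
        return build_clpm_spec(
            muscle,
            bone,
            tuple(self.covariates),
            free_v3_disturbance_cov=self.free_v3_disturbance_cov,
        )
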