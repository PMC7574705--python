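"""Independent oracles used by the test suite.

These deliberately avoid the package's RAM algebra: covariances come from
explicit enumeration of directed paths (Wright's tracing rules), so they
can certify the matrix-based implementation.
"""

from __future__ import annotations

import numpy as np

from leanbone.model import Edge, PathModelSpec


def _edge_value(spec: PathModelSpec, params: dict[str, float]) -> dict[tuple[str, str], float]:
    out = {}
    for e in spec.directed:
        out[(e.source, e.target)] = e.value if not e.free else params[e.label]
    return out


def _s_matrix(spec: PathModelSpec, params: dict[str, float]) -> dict[tuple[str, str], float]:
    out = {}
    for e in spec.bidirected:
        v = e.value if not e.free else params[e.label]
        out[(e.source, e.target)] = v
        out[(e.target, e.source)] = v
    return out


def _all_paths_coef(
    coefs: dict[tuple[str, str], float], children: dict[str, list[str]], start: str
) -> dict[str, float]:
    """Sum of coefficient products over every directed path start -> node.

    Includes the empty path (value 1 at the start node itself).  Recursive
    enumeration, memo-free on purpose: specs in tests are small.
    """
    totals: dict[str, float] = {}

    def walk(node: str, product: float) -> None:
        totals[node] = totals.get(node, 0.0) + product
        for child in children.get(node, []):
            walk(child, product * coefs[(node, child)])

    walk(start, 1.0)
    return totals


def path_tracing_covariance(
    spec: PathModelSpec, params: dict[str, float] | None = None
) -> np.ndarray:
    """Implied covariance by explicit path enumeration.

    cov(i, j) = sum_{u, v} T[u -> i] * S[u, v] * T[v -> j] where T sums
    coefficient products over all directed paths.
    """
    params = params or {}
    coefs = _edge_value(spec, params)
    s = _s_matrix(spec, params)
    children: dict[str, list[str]] = {}
    for (a, b) in coefs:
        children.setdefault(a, []).append(b)
    totals = {v: _all_paths_coef(coefs, children, v) for v in spec.variables}
    p = len(spec.variables)
    sigma = np.zeros((p, p))
    for i, vi in enumerate(spec.variables):
        for j, vj in enumerate(spec.variables):
            acc = 0.0
            seen = set()
            for (u, w), suw in s.items():
                key = frozenset((u, w))
                if key in seen:
                    continue
                seen.add(key)
                if u == w:
                    acc += totals[u].get(vi, 0.0) * suw * totals[u].get(vj, 0.0)
                else:
                    acc += suw * (
                        totals[u].get(vi, 0.0) * totals[w].get(vj, 0.0)
                        + totals[w].get(vi, 0.0) * totals[u].get(vj, 0.0)
                    )
            sigma[i, j] = acc
    return sigma


def enumerate_paths_dfs(
    spec: PathModelSpec, source: str, target: str
) -> list[tuple[str, ...]]:
    """Brute-force route enumeration (for checking the mediation module)."""
    children: dict[str, list[str]] = {}
    for e in spec.directed:
        children.setdefault(e.source, []).append(e.target)
    found: list[tuple[str, ...]] = []

    def walk(node: str, trail: tuple[str, ...]) -> None:
        if node == target:
            found.append(trail)
            return
        for child in children.get(node, []):
            if child not in trail:
                walk(child, trail + (child,))

    walk(source, (source,))
    return [p for p in found if len(p) > 2]


def random_acyclic_spec(
    rng: np.random.Generator, n_vars: int | None = None
) -> tuple[PathModelSpec, dict[str, float]]:
    """Random fixed-value acyclic spec with a positive-definite S part."""
    if n_vars is None:
        n_vars = int(rng.integers(3, 9))
    names = [f"x{i}" for i in range(n_vars)]
    directed = []
    for i in range(n_vars):
        for j in range(i + 1, n_vars):
            if rng.random() < 0.4:
                directed.append(Edge(names[i], names[j], value=float(rng.uniform(-0.9, 0.9))))
    bidirected = [
        Edge(v, v, value=float(rng.uniform(0.5, 2.0))) for v in names
    ]
    # small covariances between the first two disturbances keep S PD
    if n_vars >= 2 and rng.random() < 0.5:
        bidirected.append(Edge(names[0], names[1], value=float(rng.uniform(-0.2, 0.2))))
    return PathModelSpec(tuple(names), tuple(directed), tuple(bidirected)), {}
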