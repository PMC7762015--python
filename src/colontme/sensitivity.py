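"""Steady-state sensitivity analysis.

Three quantities of interest: cancer-cell density, total cell density (the
nine cell variables) and the minimal Jacobian eigenvalue at the equilibrium
(a proxy for convergence speed).  Equilibrium sensitivities come from
implicit differentiation of F(X*, theta) = 0,

    dX*/dtheta = -J^{-1} dF/dtheta,

with the analytic Jacobian and parameter gradient; the eigenvalue
sensitivity uses central finite differences with the equilibrium re-solved
at each perturbed parameter vector.  Rankings are computed on the
dimensionless system, as relative sensitivities theta_j * dXbar/dtheta_j,
which makes them invariant to an overall rescaling of the reference
densities.  Region averages integrate the pointwise sensitivities over the
hyperrectangle theta * (1 +/- h) with a nested Clenshaw-Curtis sparse grid
(Smolyak combination), with seeded Monte-Carlo sampling as a fallback.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import (
    CELL_NAMES,
    IMMUNE_PARAM_MASK,
    PARAM_NAMES,
    ParameterSet,
    STATE_NAMES,
    as_state,
    dfdtheta,
    jacobian,
    rhs,
    steady_state_residual,
)

__all__ = [
    "solve_equilibrium",
    "steady_state_sensitivity",
    "minimal_eigenvalue",
    "eigenvalue_sensitivity",
    "qoi_sensitivity_vector",
    "aggregate_over_region",
    "SensitivityResult",
    "compute_sensitivities",
    "rank_and_partition",
]

_C_ROW = STATE_NAMES.index("C")
_CELL_ROWS = [STATE_NAMES.index(n) for n in CELL_NAMES]
QOI_NAMES = ("cancer", "total", "eig")


def solve_equilibrium(params: ParameterSet, x0, tol: float = 1e-12) -> np.ndarray:
    """Re-solve F(X, theta) = 0 from a starting guess, in units of ``x0``."""
    x0 = as_state(x0)
    ref = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    sol = optimize.root(
        lambda y: rhs(y * ref, params),
        x0 / ref,
        jac=lambda y: jacobian(y * ref, params) * ref[None, :],
        method="hybr", tol=tol,
    )
    x = sol.x * ref
    _, norm = steady_state_residual(x, params)
    # hybr sometimes flags success=False on xtol grounds after converging;
    # the residual is the authoritative acceptance check
    if norm > 1e-8:
        raise RuntimeError(f"equilibrium re-solve failed (residual {norm:.2e})")
    return x


def _equilibrium_gate(params: ParameterSet, x_star, gate: float) -> np.ndarray:
    x = as_state(x_star)
    _, norm = steady_state_residual(x, params)
    if norm > gate:
        raise ValueError(
            f"x_star is not an equilibrium (scaled residual {norm:.2e} > {gate:g})"
        )
    return x


def steady_state_sensitivity(params: ParameterSet, x_star,
                             residual_gate: float = 1e-6) -> np.ndarray:
    """Implicit-differentiation sensitivity dX*/dtheta, shape (14, n_params)."""
    x = _equilibrium_gate(params, x_star, residual_gate)
    J = jacobian(x, params)
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"Jacobian is numerically singular at the equilibrium "
            f"(condition number {cond:.3e})"
        )
    return -np.linalg.solve(J, dfdtheta(x, params))


def finite_difference_steady_state_sensitivity(
        params: ParameterSet, x_star, rel_step: float = 1e-4) -> np.ndarray:
    """Re-solve oracle: central differences of the equilibrium itself."""
    x = as_state(x_star)
    S = np.zeros((len(STATE_NAMES), len(PARAM_NAMES)))
    for j, name in enumerate(PARAM_NAMES):
        h = rel_step * params[name]
        if h == 0.0:
            continue
        xp = solve_equilibrium(params.replace(**{name: params[name] + h}), x)
        xm = solve_equilibrium(params.replace(**{name: params[name] - h}), x)
        S[:, j] = (xp - xm) / (2.0 * h)
    return S


def minimal_eigenvalue(params: ParameterSet, x_star, which: str = "min"):
    """Extreme real part of the Jacobian spectrum at an equilibrium.

    ``which="min"`` is the literal minimum over real parts; ``which="max"``
    selects the slowest (least negative) mode.  Returns ``(value, eigvec)``.
    """
    eig, vec = np.linalg.eig(jacobian(as_state(x_star), params))
    k = int(np.argmin(eig.real)) if which == "min" else int(np.argmax(eig.real))
    return float(eig.real[k]), vec[:, k]


def eigenvalue_sensitivity(params: ParameterSet, x_star,
                           dtheta_rel: float = 1e-4, which: str = "min",
                           residual_gate: float = 1e-6) -> np.ndarray:
    """Central finite differences of the extreme eigenvalue, with the
    equilibrium re-solved before each Jacobian evaluation.

    A warning is emitted when eigenvector continuity suggests the selected
    branch crossed another one over the difference step.
    """
    x = _equilibrium_gate(params, x_star, residual_gate)
    _, v0 = minimal_eigenvalue(params, x, which=which)
    out = np.zeros(len(PARAM_NAMES))
    for j, name in enumerate(PARAM_NAMES):
        h = dtheta_rel * params[name]
        if h == 0.0:
            continue
        vals = []
        for sgn in (+0.5, -0.5):
            pert = params.replace(**{name: params[name] + sgn * h})
            xp = solve_equilibrium(pert, x)
            lam, v = minimal_eigenvalue(pert, xp, which=which)
            overlap = abs(np.vdot(v0, v)) / (np.linalg.norm(v0) * np.linalg.norm(v))
            if overlap < 0.9:
                warnings.warn(
                    f"eigenvalue ordering may have changed while perturbing "
                    f"{name} (eigenvector overlap {overlap:.2f})",
                    RuntimeWarning, stacklevel=2,
                )
            vals.append(lam)
        out[j] = (vals[0] - vals[1]) / h
    return out


def qoi_sensitivity_vector(params: ParameterSet, x_star, qoi: str,
                           x_ref=None, relative: bool = True,
                           which_eig: str = "min",
                           dtheta_rel: float = 1e-4) -> np.ndarray:
    """Per-parameter sensitivity of one quantity of interest.

    ``cancer`` and ``total`` are rows of the dimensionless equilibrium
    sensitivity (each state row divided by its reference ``x_ref``,
    defaulting to ``x_star``); ``eig`` is scale-free already.  With
    ``relative=True`` each entry is multiplied by its parameter value.
    """
    if qoi not in QOI_NAMES:
        raise ValueError(f"qoi must be one of {QOI_NAMES}")
    if qoi == "eig":
        vec = eigenvalue_sensitivity(params, x_star, dtheta_rel=dtheta_rel,
                                     which=which_eig)
    else:
        ref = as_state(x_ref if x_ref is not None else x_star)
        if np.any(ref <= 0):
            raise ValueError("dimensionless reference must be positive")
        S = steady_state_sensitivity(params, x_star) / ref[:, None]
        vec = S[_C_ROW] if qoi == "cancer" else S[_CELL_ROWS].sum(axis=0)
    if relative:
        vec = vec * params.to_array()
    return vec


# ---------------------------------------------------------------------------
# sparse-grid quadrature over a parameter hyperrectangle

def _cc_rule(level: int):
    """Nested Clenshaw-Curtis rule on [-1, 1], normalized to average
    (weights sum to 1).  Level 0 is the midpoint rule."""
    if level == 0:
        return np.array([0.0]), np.array([1.0])
    n = 2 ** level
    k = np.arange(n + 1)
    x = np.cos(np.pi * k / n)
    w = np.empty(n + 1)
    for i in range(n + 1):
        c = 1.0 if i in (0, n) else 2.0
        acc = 0.0
        for j in range(1, n // 2 + 1):
            b = 1.0 if j == n // 2 else 2.0
            acc += b / (4.0 * j * j - 1.0) * np.cos(2.0 * np.pi * j * i / n)
        w[i] = c / n * (1.0 - acc)
    return x[::-1].copy(), (w[::-1] / 2.0).copy()


def _cc_difference(level: int):
    """Difference rule Delta_l = Q_l - Q_{l-1} on the nested CC nodes."""
    x, w = _cc_rule(level)
    if level == 0:
        return x, w
    xp, wp = _cc_rule(level - 1)
    w = w.copy()
    for xi, wi in zip(xp, wp):
        idx = int(np.argmin(np.abs(x - xi)))
        w[idx] -= wi
    return x, w


def smolyak_average_nodes(dim: int, level: int):
    """Nodes and weights of the Smolyak average over [-1, 1]^dim.

    Returned as a list of ``(sparse_node, weight)`` where ``sparse_node`` is
    a tuple of ``(dimension, coordinate)`` pairs; omitted coordinates are 0.
    """
    diffs = [_cc_difference(l) for l in range(level + 1)]
    acc: dict[tuple, float] = {}
    for active in _level_multi_indices(dim, level):
        dims = [d for d, _ in active]
        rules = [diffs[l] for _, l in active]
        for combo in itertools.product(*[range(len(r[0])) for r in rules]):
            weight = 1.0
            key = []
            for (d, (xs, ws)), c in zip(zip(dims, rules), combo):
                weight *= ws[c]
                if xs[c] != 0.0:
                    key.append((d, float(xs[c])))
            k = tuple(key)
            acc[k] = acc.get(k, 0.0) + weight
    return [(k, w) for k, w in acc.items() if abs(w) > 1e-15]


def _level_multi_indices(dim: int, level: int):
    """Sparse multi-indices: assignments of positive levels to a few
    dimensions with total level at most ``level``."""
    yield ()
    for total in range(1, level + 1):
        for ndims in range(1, total + 1):
            for dims in itertools.combinations(range(dim), ndims):
                for parts in _compositions(total, ndims):
                    yield tuple(zip(dims, parts))


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


@dataclass
class RegionAverage:
    values: np.ndarray
    n_nodes: int
    n_failed: int
    method: str
    halfwidth: float
    level: int | None = None


def aggregate_over_region(params: ParameterSet, x_star, halfwidth: float,
                          qoi: str = "cancer", level: int = 2,
                          method: str = "sparse", n_mc: int = 1000,
                          seed: int = 0, relative: bool = True,
                          x_ref=None, which_eig: str = "min") -> RegionAverage:
    """Average the pointwise sensitivity of ``qoi`` over the hyperrectangle
    ``theta * (1 +/- halfwidth)``.

    Each node re-solves the equilibrium before evaluating the sensitivity;
    nodes whose equilibrium solve fails are dropped and counted.  Relative
    normalization uses the center parameter values so that a zero-halfwidth
    region reproduces the pointwise result exactly.
    """
    x = as_state(x_star)
    theta0 = params.to_array()
    ref = as_state(x_ref if x_ref is not None else x_star)
    free = theta0 > 0.0

    def evaluate(u: np.ndarray) -> np.ndarray:
        theta = theta0 * (1.0 + halfwidth * u)
        pert = ParameterSet.from_array(theta, alpha_dim=params.alpha_dim)
        xeq = solve_equilibrium(pert, x)
        return qoi_sensitivity_vector(pert, xeq, qoi, x_ref=ref,
                                      relative=False, which_eig=which_eig)

    n_failed = 0
    if halfwidth == 0.0:
        values = evaluate(np.zeros(theta0.size))
        n_nodes = 1
    elif method == "sparse":
        nodes = smolyak_average_nodes(int(free.sum()), level)
        free_idx = np.flatnonzero(free)
        total, wsum = np.zeros(theta0.size), 0.0
        for sparse_node, w in nodes:
            u = np.zeros(theta0.size)
            for d, coord in sparse_node:
                u[free_idx[d]] = coord
            try:
                total += w * evaluate(u)
                wsum += w
            except RuntimeError:
                n_failed += 1
        if wsum == 0.0:
            raise RuntimeError("all sparse-grid nodes failed to re-solve")
        values = total / wsum
        n_nodes = len(nodes)
    elif method == "mc":
        rng = np.random.default_rng(seed)
        total, count = np.zeros(theta0.size), 0
        for _ in range(n_mc):
            u = np.where(free, rng.uniform(-1.0, 1.0, theta0.size), 0.0)
            try:
                total += evaluate(u)
                count += 1
            except RuntimeError:
                n_failed += 1
        if count == 0:
            raise RuntimeError("all Monte-Carlo nodes failed to re-solve")
        values = total / count
        n_nodes = n_mc
    else:
        raise ValueError("method must be 'sparse' or 'mc'")

    if relative:
        values = values * theta0
    return RegionAverage(values=values, n_nodes=n_nodes, n_failed=n_failed,
                         method=method, halfwidth=halfwidth,
                         level=level if method == "sparse" else None)


# ---------------------------------------------------------------------------
# result container and ranking

@dataclass
class SensitivityResult:
    """Relative sensitivities of each quantity of interest per parameter."""

    param_names: tuple
    values: dict
    immune_mask: np.ndarray = field(
        default_factory=lambda: IMMUNE_PARAM_MASK.copy())
    metadata: dict = field(default_factory=dict)

    def ranking(self, qoi: str, immune_only: bool = False) -> list:
        """Parameter names with values, descending |S|; ties broken by the
        fixed symbol order."""
        vals = self.values[qoi]
        idx = [j for j in range(len(self.param_names))
               if not immune_only or self.immune_mask[j]]
        idx.sort(key=lambda j: (-abs(vals[j]), j))
        return [(self.param_names[j], float(vals[j])) for j in idx]


def compute_sensitivities(params: ParameterSet, x_star,
                          qois=QOI_NAMES, x_ref=None,
                          region_halfwidth: float = 0.0, level: int = 2,
                          which_eig: str = "min",
                          seed: int = 0) -> SensitivityResult:
    """Pointwise (or region-averaged, if ``region_halfwidth > 0``) relative
    sensitivities of the requested quantities of interest."""
    values = {}
    for qoi in qois:
        if region_halfwidth > 0.0:
            values[qoi] = aggregate_over_region(
                params, x_star, region_halfwidth, qoi=qoi, level=level,
                seed=seed, x_ref=x_ref, which_eig=which_eig).values
        else:
            values[qoi] = qoi_sensitivity_vector(
                params, x_star, qoi, x_ref=x_ref, which_eig=which_eig)
    return SensitivityResult(
        param_names=PARAM_NAMES, values=values,
        metadata={"region_halfwidth": region_halfwidth, "level": level,
                  "which_eig": which_eig},
    )


def rank_and_partition(result: SensitivityResult, k: int = 4) -> dict:
    """Top-k overall and top-k immune-only parameters for each QoI."""
    out = {}
    for qoi in result.values:
        full = result.ranking(qoi)
        immune = result.ranking(qoi, immune_only=True)
        out[qoi] = {"top": full[:k], "immune_top": immune[:k]}
    return out
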