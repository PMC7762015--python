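"""Virtual-patient dynamics: stiff integration and convergence detection.

Rates in the model span several orders of magnitude (cancer vs. cytokine
turnover), so the default integrator is stiff-capable (LSODA with the
analytic Jacobian), with rtol 1e-8 and a per-variable absolute tolerance of
1e-10 times the variable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import STATE_NAMES, ParameterSet, as_state, jacobian, rhs, \
    steady_state_residual

__all__ = [
    "Trajectory",
    "simulate",
    "detect_steady_state",
    "run_to_steady_state",
    "Envelope",
    "variation_envelope",
]


@dataclass
class Trajectory:
    """Time grid (days) and state matrix (time x 14) of one simulation."""

    t: np.ndarray
    states: np.ndarray
    cluster: int | None = None
    variation: str = "nominal"
    converged: bool = False
    convergence_time: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.t.size, len(STATE_NAMES)):
            raise ValueError("states must have shape (len(t), 14)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def total_cell_density(self) -> np.ndarray:
        return self.states[:, :9].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_days", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_days"].to_numpy(),
                   df[list(STATE_NAMES)].to_numpy(), **kwargs)


def _default_grid(t_end: float, n: int = 1500) -> np.ndarray:
    # geometric spacing resolves the fast early transient and the slow tail
    tiny = min(1e-3, t_end / 1e6)
    return np.concatenate([[0.0], np.geomspace(tiny, t_end, n - 1)])


def simulate(params: ParameterSet, init, t_end: float = 10000.0,
             rtol: float = 1e-8, atol=None, t_eval=None,
             method: str = "LSODA", scale=None, cluster: int | None = None,
             variation: str = "nominal") -> Trajectory:
    """Integrate the system from ``init`` over ``[0, t_end]`` days.

    ``scale`` sets the per-variable magnitude used for the absolute
    tolerance (default: ``max(|init|, 1)``); pass the steady state when it
    is known so small variables keep full resolution.
    """
    x0 = as_state(init)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    if scale is None:
        scale = np.maximum(np.abs(x0), 1.0)
    else:
        scale = np.asarray(scale, dtype=float)
    if atol is None:
        atol = 1e-10 * scale
    if t_eval is None:
        t_eval = _default_grid(t_end)
    sol = solve_ivp(
        lambda t, y: rhs(y, params), (0.0, float(t_end)), x0,
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        jac=lambda t, y: jacobian(y, params),
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"integration failed at t = {last_t:.3f} days: {sol.message}"
        )
    return Trajectory(sol.t, sol.y.T, cluster=cluster, variation=variation)


def detect_steady_state(traj: Trajectory, params: ParameterSet,
                        tol: float = 1e-8, scale=None):
    """First time along the trajectory where the scaled residual drops
    below ``tol``; returns ``(state, time, converged)``."""
    for k in range(traj.t.size):
        _, norm = steady_state_residual(traj.states[k], params, scale=scale)
        if norm < tol:
            traj.converged = True
            traj.convergence_time = float(traj.t[k])
            return traj.states[k].copy(), float(traj.t[k]), True
    return traj.final_state.copy(), float(traj.t[-1]), False


def run_to_steady_state(params: ParameterSet, init, tol: float = 1e-8,
                        t_end: float = 10000.0, t_max: float = 1e6,
                        scale=None, **kwargs) -> Trajectory:
    """Simulate, doubling the horizon until the residual tolerance is met.

    Raises if ``t_max`` is exceeded without convergence.
    """
    horizon = float(t_end)
    while True:
        traj = simulate(params, init, t_end=horizon, scale=scale, **kwargs)
        _, _, converged = detect_steady_state(traj, params, tol=tol, scale=scale)
        if converged:
            return traj
        horizon *= 2.0
        if horizon > t_max:
            raise RuntimeError(
                f"no steady state below residual {tol:g} within {t_max:g} days"
            )


@dataclass
class Envelope:
    """Pointwise trajectory band from one-at-a-time parameter variation."""

    t: np.ndarray
    nominal: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    runs: dict = field(default_factory=dict)
    failed: list = field(default_factory=list)

    def width(self, name: str) -> np.ndarray:
        j = STATE_NAMES.index(name)
        return self.upper[:, j] - self.lower[:, j]


def variation_envelope(params: ParameterSet, sensitive, init,
                       fraction: float = 0.10, t_end: float = 10000.0,
                       scale=None, **kwargs) -> Envelope:
    """Vary each listed parameter by ``fraction`` up and down (one at a
    time) and take the pointwise min/max across all runs plus the nominal.

    A run that fails to integrate is recorded in ``failed`` and excluded.
    """
    for name in sensitive:
        if name not in params:
            raise KeyError(f"unknown parameter in sensitive list: {name}")
    t_eval = _default_grid(float(t_end))
    nominal = simulate(params, init, t_end=t_end, t_eval=t_eval, scale=scale,
                       **kwargs)
    stack = [nominal.states]
    runs, failed = {}, []
    for name in sensitive:
        for factor in (1.0 - fraction, 1.0 + fraction):
            tag = f"{name}*{factor:g}"
            try:
                traj = simulate(params.replace(**{name: params[name] * factor}),
                                init, t_end=t_end, t_eval=t_eval, scale=scale,
                                variation=tag, **kwargs)
            except (RuntimeError, ValueError) as err:
                failed.append((tag, str(err)))
                continue
            runs[tag] = traj
            stack.append(traj.states)
    cube = np.stack(stack)
    return Envelope(t=t_eval, nominal=nominal.states,
                    lower=cube.min(axis=0), upper=cube.max(axis=0),
                    runs=runs, failed=failed)
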