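"""Reference per-cluster steady states and initial conditions.

The five immune-pattern clusters of the colon-cancer cohort each come with a
characteristic steady state — mean cell densities (cells/cm^3) and cytokine
expression levels of the above-average-size tumors in the cluster — and a
dimensionless initial condition taken from the smallest tumor in the cluster
(each variable divided by its steady-state value).  These values drive
parameter derivation and the virtual-patient simulations; the cohort module
produces objects of the same shape from deconvolution tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import STATE_NAMES, as_state

__all__ = ["ClusterSteadyState", "CLUSTERS", "steady_state", "initial_condition"]


@dataclass(frozen=True)
class ClusterSteadyState:
    """Steady-state value of every model variable plus the macrophage
    capacity M0 (naive + activated) for one patient cluster."""

    values: dict = field(repr=False)
    M0: float
    cluster: int | None = None

    def __post_init__(self):
        x = self.as_state()
        object.__setattr__(self, "values",
                           dict(zip(STATE_NAMES, map(float, x))))
        self.validate()

    def as_state(self) -> np.ndarray:
        return as_state(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_dict(self) -> dict:
        """Flat symbol -> value mapping (JSON/YAML-ready)."""
        out = dict(self.values)
        out["M0"] = float(self.M0)
        return out

    @classmethod
    def from_dict(cls, data: dict, cluster: int | None = None
                  ) -> "ClusterSteadyState":
        data = dict(data)
        M0 = float(data.pop("M0"))
        return cls(values=data, M0=M0, cluster=cluster)

    def validate(self) -> None:
        x = self.as_state()
        if np.any(x < 0) or not np.all(np.isfinite(x)):
            raise ValueError("steady-state values must be finite and >= 0")
        # DN may be near zero (one cluster sits at ~0.19 cells/cm^3); every
        # other variable must be strictly positive.
        for name, v in self.values.items():
            if name != "DN" and v <= 0:
                raise ValueError(f"steady-state {name} must be > 0, got {v}")
        if not self.M0 > self.values["M"]:
            raise ValueError("macrophage capacity M0 must exceed M at steady state")
        # Necrotic cells are half the cancer density by construction of the
        # cohort mapping (N = 0.5 C); enforce to 4 significant figures.
        ratio = self.values["N"] / self.values["C"]
        if abs(ratio - 0.5) > 5e-4:
            raise ValueError(f"N/C must be 0.5 to 4 significant figures, got {ratio}")


def _css(cluster, TN, Th, TC, Tr, DN, D, M, M0, C, N, mu1, mu2, H, Ig, Gb):
    return ClusterSteadyState(
        values=dict(TN=TN, Th=Th, TC=TC, Tr=Tr, DN=DN, D=D, M=M, C=C, N=N,
                    H=H, mu1=mu1, mu2=mu2, Ig=Ig, Gb=Gb),
        M0=M0, cluster=cluster,
    )


# Steady-state densities (cells/cm^3; cytokines in cohort expression units).
_STEADY_STATES = {
    1: _css(1, TN=1.4914e4, Th=4.6358e3, TC=2.5845e3, Tr=2.3891e3,
            DN=3.0504e2, D=6.0214e2, M=1.1798e4, M0=2.1004e4,
            C=9.1531e4, N=4.5765e4, mu1=1.6328e2, mu2=1.2987e3,
            H=8.9811e3, Ig=8.5737, Gb=1.9037e4),
    2: _css(2, TN=1.1429e4, Th=6.0411e3, TC=5.3853e3, Tr=3.3646e3,
            DN=1.0329e2, D=5.1299e2, M=8.6227e3, M0=1.6445e4,
            C=9.7064e4, N=4.8532e4, mu1=1.7552e2, mu2=1.3249e3,
            H=8.5279e3, Ig=10.5677, Gb=2.2275e4),
    3: _css(3, TN=9.2381e3, Th=1.3864e3, TC=1.1139e3, Tr=2.7910e3,
            DN=1.8878e-1, D=1.8635e2, M=6.7972e3, M0=3.2146e4,
            C=9.0029e4, N=4.5014e4, mu1=1.9866e2, mu2=1.2906e3,
            H=9.5122e3, Ig=0.8287, Gb=2.5145e4),
    4: _css(4, TN=1.3878e4, Th=2.4910e3, TC=3.2172e3, Tr=2.2783e3,
            DN=1.4196e2, D=6.2154e2, M=1.2931e4, M0=1.5761e4,
            C=9.6956e4, N=4.8478e4, mu1=1.1410e2, mu2=3.3689e2,
            H=5.1782e3, Ig=1.2703, Gb=8.1734e3),
    5: _css(5, TN=1.0262e4, Th=3.7844e3, TC=1.6853e3, Tr=2.6394e3,
            DN=8.0199e1, D=1.9084e2, M=1.1603e4, M0=2.8198e4,
            C=8.0584e4, N=4.0292e4, mu1=1.2058e2, mu2=7.1551e2,
            H=7.7848e3, Ig=5.7892, Gb=2.6260e4),
}

# Dimensionless initial conditions X(0)/X_inf from the smallest tumor of each
# cluster.  Necrotic cells start at zero everywhere.
_INITIAL_CONDITIONS = {
    1: dict(TN=0.9311, Th=1.2492, TC=2.4626, Tr=0.6872, DN=1.6328,
            D=0.0003, M=0.6737, C=3.1466e-4, N=0.0,
            mu1=0.4971, mu2=0.5124, H=1.4712, Ig=3.8892, Gb=0.2549),
    2: dict(TN=1.2302, Th=1.3155, TC=1.5210, Tr=0.5107, DN=2.0461,
            D=2.7822, M=1.2920, C=2.9672e-4, N=0.0,
            mu1=0.7578, mu2=0.1790, H=0.6036, Ig=0.9385, Gb=0.5566),
    3: dict(TN=1.1997, Th=0.8555, TC=1.6948e-4, Tr=0.6572, DN=1.0000,
            D=1.0130e-3, M=1.4150, C=3.1991e-4, N=0.0,
            mu1=0.1335, mu2=0.8419, H=1.2566, Ig=0.0, Gb=0.6851),
    4: dict(TN=1.4471, Th=0.1571, TC=0.5823, Tr=0.8910, DN=5.6827,
            D=4.2945, M=0.9259, C=2.9706e-4, N=0.0,
            mu1=0.4137, mu2=5.7720, H=1.4630, Ig=0.0, Gb=2.5629),
    5: dict(TN=0.6794, Th=2.6119, TC=1.6294, Tr=1.8819, DN=2.3538e-3,
            D=0.4542, M=0.7749, C=3.5741e-4, N=0.0,
            mu1=0.4587, mu2=2.2979, H=1.1835, Ig=0.4084, Gb=0.3457),
}

CLUSTERS = tuple(sorted(_STEADY_STATES))


def steady_state(cluster: int) -> ClusterSteadyState:
    """Reference steady state of one of the five clusters."""
    return _STEADY_STATES[cluster]


def initial_condition(cluster: int, dimensionless: bool = True) -> np.ndarray:
    """Smallest-tumor initial condition for a cluster.

    Dimensionless by default; with ``dimensionless=False`` the vector is
    multiplied componentwise by the cluster steady state to give densities.
    """
    x0 = as_state(_INITIAL_CONDITIONS[cluster])
    if dimensionless:
        return x0
    return x0 * _STEADY_STATES[cluster].as_state()
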