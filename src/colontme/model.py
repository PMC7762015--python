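"""Core ODE model of the colon tumor immune microenvironment.

The state holds nine cell densities (cells/cm^3) and five cytokine levels
(RNA-seq-derived arbitrary units, fixed per cohort):

    TN, Th, TC, Tr : naive / helper / cytotoxic / regulatory T cells
    DN, D          : naive / activated dendritic cells
    M              : activated tumor-associated macrophages (M1+M2 pooled);
                     naive macrophages are carried implicitly as M0 - M
    C, N           : cancer and necrotic cells
    H              : HMGB1 (DAMP released by necrotic cells)
    mu1            : carcinogenic cytokine pool (IL-6/17/21/22)
    mu2            : immunosuppressive pool (IL-10/CCL20)
    Ig, Gb         : IFN-gamma, TGF-beta

Dynamics are mass-action: lambda_* are production/activation rates, delta_*
decay/death rates, A_* constant influxes.  Cancer follows logistic growth
with cytokine-boosted proliferation and immune-mediated death; necrotic cells
are produced as a fraction alpha_NC of the cancer death flux.  The total
macrophage pool M0 = MN + M is conserved, so only M is integrated and the
activation terms carry a factor (M0 - M).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "STATE_NAMES",
    "CELL_NAMES",
    "CYTOKINE_NAMES",
    "PARAM_NAMES",
    "CANCER_NECROTIC_PARAMS",
    "IMMUNE_PARAM_MASK",
    "ParameterSet",
    "rhs",
    "jacobian",
    "dfdtheta",
    "steady_state_residual",
    "DimensionlessSystem",
    "nondimensionalize",
]

# Fixed state ordering: nine cell variables first, then five cytokines.
STATE_NAMES = (
    "TN", "Th", "TC", "Tr", "DN", "D", "M", "C", "N",
    "H", "mu1", "mu2", "Ig", "Gb",
)
CELL_NAMES = STATE_NAMES[:9]
CYTOKINE_NAMES = STATE_NAMES[9:]
N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

# Dynamic parameters, grouped by the equation whose balance introduces them.
PARAM_NAMES = (
    # H
    "lam_HN", "lam_HM", "lam_HTh", "lam_HTC", "lam_HTr", "delta_H",
    # mu1
    "lam_mu1Th", "lam_mu1M", "lam_mu1D", "delta_mu1",
    # mu2
    "lam_mu2M", "lam_mu2D", "lam_mu2Tr", "delta_mu2",
    # IFN-gamma
    "lam_IgTh", "lam_IgTC", "lam_IgM", "delta_Ig",
    # TGF-beta
    "lam_GbM", "lam_GbTr", "delta_Gb",
    # Th
    "lam_ThD", "lam_ThM", "lam_Thmu1", "delta_Thmu2", "delta_ThTr", "delta_Th",
    # TC
    "lam_TCTh", "lam_TCD", "delta_TCmu2", "delta_TCTr", "delta_TC",
    # Tr
    "lam_TrTh", "lam_Trmu2", "lam_TrGb", "delta_Trmu1", "delta_Tr",
    # TN
    "A_TN", "delta_TN",
    # dendritic cells
    "A_DN", "lam_DH", "lam_DC", "delta_DH", "delta_DC", "delta_D",
    # macrophages
    "lam_Mmu2", "lam_MIg", "lam_MTh", "delta_M", "M0",
    # cancer
    "lam_C", "lam_Cmu1", "C0", "delta_CGb", "delta_CIg", "delta_CTC", "delta_C",
    # necrotic cells
    "alpha_NC", "delta_N",
)
N_PARAM = len(PARAM_NAMES)
PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}

# Parameters appearing in the cancer / necrotic equations; their complement is
# the "immune-only" subset used for immune sensitivity rankings.
CANCER_NECROTIC_PARAMS = frozenset(
    {"lam_C", "lam_Cmu1", "C0", "delta_CGb", "delta_CIg", "delta_CTC",
     "delta_C", "alpha_NC", "delta_N"}
)
IMMUNE_PARAM_MASK = np.array(
    [name not in CANCER_NECROTIC_PARAMS for name in PARAM_NAMES]
)

_POSITIVE_DELTAS = (
    "delta_H", "delta_mu1", "delta_mu2", "delta_Ig", "delta_Gb",
    "delta_Th", "delta_TC", "delta_Tr", "delta_TN", "delta_D",
    "delta_M", "delta_C", "delta_N",
)


class ParameterSet(dict):
    """Named rate constants of the model, a thin mapping over ``PARAM_NAMES``.

    Also carries the cohort density scaling ``alpha_dim`` (cells/cm^3 per
    unit relative tumor size), which does not enter the dynamics.
    """

    def __init__(self, values=None, alpha_dim: float = 1.125e5, **kwargs):
        super().__init__()
        data = dict(values or {})
        data.update(kwargs)
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        for name in PARAM_NAMES:
            self[name] = float(data.get(name, 0.0))
        self.alpha_dim = float(alpha_dim)
        self.validate()

    def validate(self) -> None:
        for name in PARAM_NAMES:
            v = self[name]
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v!r}")
            if v < 0.0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        for name in _POSITIVE_DELTAS:
            if self[name] <= 0.0:
                raise ValueError(f"decay rate {name} must be > 0")
        if self["C0"] <= 0.0:
            raise ValueError("carrying capacity C0 must be > 0")
        if self["M0"] <= 0.0:
            raise ValueError("macrophage capacity M0 must be > 0")
        if not 0.0 < self["alpha_NC"] <= 1.0:
            raise ValueError("necrotic fraction alpha_NC must be in (0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([self[name] for name in PARAM_NAMES])

    @classmethod
    def from_array(cls, theta, alpha_dim: float = 1.125e5) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_PARAM,):
            raise ValueError(f"expected shape ({N_PARAM},), got {theta.shape}")
        return cls(dict(zip(PARAM_NAMES, theta)), alpha_dim=alpha_dim)

    def replace(self, **kwargs) -> "ParameterSet":
        data = {name: self[name] for name in PARAM_NAMES}
        data.update(kwargs)
        return ParameterSet(data, alpha_dim=self.alpha_dim)

    def to_dict(self) -> dict:
        """Flat symbol -> value mapping (JSON/YAML-ready)."""
        out = {name: self[name] for name in PARAM_NAMES}
        out["alpha_dim"] = self.alpha_dim
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        data = dict(data)
        alpha_dim = data.pop("alpha_dim", 1.125e5)
        return cls(data, alpha_dim=alpha_dim)


def as_state(values) -> np.ndarray:
    """Coerce a mapping or sequence into the canonical 14-vector."""
    if isinstance(values, dict):
        missing = set(STATE_NAMES) - set(values)
        if missing:
            raise KeyError(f"missing state component(s): {sorted(missing)}")
        return np.array([float(values[name]) for name in STATE_NAMES])
    x = np.asarray(values, dtype=float)
    if x.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},), got {x.shape}")
    return x


def _check_state(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(x))]
        raise ValueError(f"non-finite state component(s): {bad}")


def rhs(state, params: ParameterSet) -> np.ndarray:
    """Time derivative dX/dt (per day) of the 14-variable system."""
    x = as_state(state)
    _check_state(x)
    p = params
    TN, Th, TC, Tr, DN, D, M, C, N, H, mu1, mu2, Ig, Gb = x

    a_Th = p["lam_ThD"] * D + p["lam_ThM"] * M + p["lam_Thmu1"] * mu1
    a_TC = p["lam_TCTh"] * Th + p["lam_TCD"] * D
    a_Tr = p["lam_TrTh"] * Th + p["lam_Trmu2"] * mu2 + p["lam_TrGb"] * Gb
    a_D = p["lam_DH"] * H + p["lam_DC"] * C
    a_M = p["lam_Mmu2"] * mu2 + p["lam_MIg"] * Ig + p["lam_MTh"] * Th
    growth_C = p["lam_C"] + p["lam_Cmu1"] * mu1
    death_C = (p["delta_CGb"] * Gb + p["delta_CIg"] * Ig
               + p["delta_CTC"] * TC + p["delta_C"])

    f = np.empty(N_STATE)
    f[IDX["TN"]] = p["A_TN"] - (a_Th + a_TC + a_Tr) * TN - p["delta_TN"] * TN
    f[IDX["Th"]] = a_Th * TN - (p["delta_Thmu2"] * mu2
                                + p["delta_ThTr"] * Tr + p["delta_Th"]) * Th
    f[IDX["TC"]] = a_TC * TN - (p["delta_TCmu2"] * mu2
                                + p["delta_TCTr"] * Tr + p["delta_TC"]) * TC
    f[IDX["Tr"]] = a_Tr * TN - (p["delta_Trmu1"] * mu1 + p["delta_Tr"]) * Tr
    f[IDX["DN"]] = p["A_DN"] - a_D * DN - (p["delta_DH"] * H + p["delta_D"]) * DN
    f[IDX["D"]] = a_D * DN - (p["delta_DH"] * H + p["delta_DC"] * C
                              + p["delta_D"]) * D
    f[IDX["M"]] = a_M * (p["M0"] - M) - p["delta_M"] * M
    f[IDX["C"]] = growth_C * C * (1.0 - C / p["C0"]) - death_C * C
    f[IDX["N"]] = p["alpha_NC"] * death_C * C - p["delta_N"] * N
    f[IDX["H"]] = (p["lam_HN"] * N + p["lam_HM"] * M + p["lam_HTh"] * Th
                   + p["lam_HTC"] * TC + p["lam_HTr"] * Tr - p["delta_H"] * H)
    f[IDX["mu1"]] = (p["lam_mu1Th"] * Th + p["lam_mu1M"] * M
                     + p["lam_mu1D"] * D - p["delta_mu1"] * mu1)
    f[IDX["mu2"]] = (p["lam_mu2M"] * M + p["lam_mu2D"] * D
                     + p["lam_mu2Tr"] * Tr - p["delta_mu2"] * mu2)
    f[IDX["Ig"]] = (p["lam_IgTh"] * Th + p["lam_IgTC"] * TC
                    + p["lam_IgM"] * M - p["delta_Ig"] * Ig)
    f[IDX["Gb"]] = p["lam_GbM"] * M + p["lam_GbTr"] * Tr - p["delta_Gb"] * Gb
    return f


def jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic Jacobian J[i, j] = d(dX_i/dt)/dX_j at ``state``."""
    x = as_state(state)
    _check_state(x)
    p = params
    TN, Th, TC, Tr, DN, D, M, C, N, H, mu1, mu2, Ig, Gb = x

    a_Th = p["lam_ThD"] * D + p["lam_ThM"] * M + p["lam_Thmu1"] * mu1
    a_TC = p["lam_TCTh"] * Th + p["lam_TCD"] * D
    a_Tr = p["lam_TrTh"] * Th + p["lam_Trmu2"] * mu2 + p["lam_TrGb"] * Gb
    a_D = p["lam_DH"] * H + p["lam_DC"] * C
    a_M = p["lam_Mmu2"] * mu2 + p["lam_MIg"] * Ig + p["lam_MTh"] * Th
    growth_C = p["lam_C"] + p["lam_Cmu1"] * mu1
    death_C = (p["delta_CGb"] * Gb + p["delta_CIg"] * Ig
               + p["delta_CTC"] * TC + p["delta_C"])

    J = np.zeros((N_STATE, N_STATE))
    i = IDX

    # TN row
    J[i["TN"], i["TN"]] = -(a_Th + a_TC + a_Tr) - p["delta_TN"]
    J[i["TN"], i["Th"]] = -(p["lam_TCTh"] + p["lam_TrTh"]) * TN
    J[i["TN"], i["D"]] = -(p["lam_ThD"] + p["lam_TCD"]) * TN
    J[i["TN"], i["M"]] = -p["lam_ThM"] * TN
    J[i["TN"], i["mu1"]] = -p["lam_Thmu1"] * TN
    J[i["TN"], i["mu2"]] = -p["lam_Trmu2"] * TN
    J[i["TN"], i["Gb"]] = -p["lam_TrGb"] * TN

    # Th row
    J[i["Th"], i["TN"]] = a_Th
    J[i["Th"], i["Th"]] = -(p["delta_Thmu2"] * mu2 + p["delta_ThTr"] * Tr
                            + p["delta_Th"])
    J[i["Th"], i["Tr"]] = -p["delta_ThTr"] * Th
    J[i["Th"], i["D"]] = p["lam_ThD"] * TN
    J[i["Th"], i["M"]] = p["lam_ThM"] * TN
    J[i["Th"], i["mu1"]] = p["lam_Thmu1"] * TN
    J[i["Th"], i["mu2"]] = -p["delta_Thmu2"] * Th

    # TC row
    J[i["TC"], i["TN"]] = a_TC
    J[i["TC"], i["Th"]] = p["lam_TCTh"] * TN
    J[i["TC"], i["TC"]] = -(p["delta_TCmu2"] * mu2 + p["delta_TCTr"] * Tr
                            + p["delta_TC"])
    J[i["TC"], i["Tr"]] = -p["delta_TCTr"] * TC
    J[i["TC"], i["D"]] = p["lam_TCD"] * TN
    J[i["TC"], i["mu2"]] = -p["delta_TCmu2"] * TC

    # Tr row
    J[i["Tr"], i["TN"]] = a_Tr
    J[i["Tr"], i["Th"]] = p["lam_TrTh"] * TN
    J[i["Tr"], i["Tr"]] = -(p["delta_Trmu1"] * mu1 + p["delta_Tr"])
    J[i["Tr"], i["mu1"]] = -p["delta_Trmu1"] * Tr
    J[i["Tr"], i["mu2"]] = p["lam_Trmu2"] * TN
    J[i["Tr"], i["Gb"]] = p["lam_TrGb"] * TN

    # DN row
    J[i["DN"], i["DN"]] = -a_D - p["delta_DH"] * H - p["delta_D"]
    J[i["DN"], i["H"]] = -(p["lam_DH"] + p["delta_DH"]) * DN
    J[i["DN"], i["C"]] = -p["lam_DC"] * DN

    # D row
    J[i["D"], i["DN"]] = a_D
    J[i["D"], i["D"]] = -(p["delta_DH"] * H + p["delta_DC"] * C + p["delta_D"])
    J[i["D"], i["H"]] = p["lam_DH"] * DN - p["delta_DH"] * D
    J[i["D"], i["C"]] = p["lam_DC"] * DN - p["delta_DC"] * D

    # M row
    J[i["M"], i["M"]] = -a_M - p["delta_M"]
    J[i["M"], i["Th"]] = p["lam_MTh"] * (p["M0"] - M)
    J[i["M"], i["mu2"]] = p["lam_Mmu2"] * (p["M0"] - M)
    J[i["M"], i["Ig"]] = p["lam_MIg"] * (p["M0"] - M)

    # C row
    J[i["C"], i["C"]] = growth_C * (1.0 - 2.0 * C / p["C0"]) - death_C
    J[i["C"], i["TC"]] = -p["delta_CTC"] * C
    J[i["C"], i["mu1"]] = p["lam_Cmu1"] * C * (1.0 - C / p["C0"])
    J[i["C"], i["Ig"]] = -p["delta_CIg"] * C
    J[i["C"], i["Gb"]] = -p["delta_CGb"] * C

    # N row
    J[i["N"], i["C"]] = p["alpha_NC"] * death_C
    J[i["N"], i["TC"]] = p["alpha_NC"] * p["delta_CTC"] * C
    J[i["N"], i["Ig"]] = p["alpha_NC"] * p["delta_CIg"] * C
    J[i["N"], i["Gb"]] = p["alpha_NC"] * p["delta_CGb"] * C
    J[i["N"], i["N"]] = -p["delta_N"]

    # H row
    J[i["H"], i["N"]] = p["lam_HN"]
    J[i["H"], i["M"]] = p["lam_HM"]
    J[i["H"], i["Th"]] = p["lam_HTh"]
    J[i["H"], i["TC"]] = p["lam_HTC"]
    J[i["H"], i["Tr"]] = p["lam_HTr"]
    J[i["H"], i["H"]] = -p["delta_H"]

    # mu1 row
    J[i["mu1"], i["Th"]] = p["lam_mu1Th"]
    J[i["mu1"], i["M"]] = p["lam_mu1M"]
    J[i["mu1"], i["D"]] = p["lam_mu1D"]
    J[i["mu1"], i["mu1"]] = -p["delta_mu1"]

    # mu2 row
    J[i["mu2"], i["M"]] = p["lam_mu2M"]
    J[i["mu2"], i["D"]] = p["lam_mu2D"]
    J[i["mu2"], i["Tr"]] = p["lam_mu2Tr"]
    J[i["mu2"], i["mu2"]] = -p["delta_mu2"]

    # Ig row
    J[i["Ig"], i["Th"]] = p["lam_IgTh"]
    J[i["Ig"], i["TC"]] = p["lam_IgTC"]
    J[i["Ig"], i["M"]] = p["lam_IgM"]
    J[i["Ig"], i["Ig"]] = -p["delta_Ig"]

    # Gb row
    J[i["Gb"], i["M"]] = p["lam_GbM"]
    J[i["Gb"], i["Tr"]] = p["lam_GbTr"]
    J[i["Gb"], i["Gb"]] = -p["delta_Gb"]

    return J


def dfdtheta(state, params: ParameterSet) -> np.ndarray:
    """Analytic parameter gradient dF/dtheta, shape (14, n_params).

    Every rate enters F linearly except the carrying capacity C0, whose
    column is the hand-differentiated logistic term.
    """
    x = as_state(state)
    _check_state(x)
    p = params
    TN, Th, TC, Tr, DN, D, M, C, N, H, mu1, mu2, Ig, Gb = x
    a_M = p["lam_Mmu2"] * mu2 + p["lam_MIg"] * Ig + p["lam_MTh"] * Th
    growth_C = p["lam_C"] + p["lam_Cmu1"] * mu1
    death_C = (p["delta_CGb"] * Gb + p["delta_CIg"] * Ig
               + p["delta_CTC"] * TC + p["delta_C"])
    logistic = C * (1.0 - C / p["C0"])
    MN = p["M0"] - M
    aNC = p["alpha_NC"]

    G = np.zeros((N_STATE, N_PARAM))
    i, j = IDX, PIDX

    def put(row, name, value):
        G[i[row], j[name]] = value

    put("H", "lam_HN", N); put("H", "lam_HM", M); put("H", "lam_HTh", Th)
    put("H", "lam_HTC", TC); put("H", "lam_HTr", Tr); put("H", "delta_H", -H)

    put("mu1", "lam_mu1Th", Th); put("mu1", "lam_mu1M", M)
    put("mu1", "lam_mu1D", D); put("mu1", "delta_mu1", -mu1)

    put("mu2", "lam_mu2M", M); put("mu2", "lam_mu2D", D)
    put("mu2", "lam_mu2Tr", Tr); put("mu2", "delta_mu2", -mu2)

    put("Ig", "lam_IgTh", Th); put("Ig", "lam_IgTC", TC)
    put("Ig", "lam_IgM", M); put("Ig", "delta_Ig", -Ig)

    put("Gb", "lam_GbM", M); put("Gb", "lam_GbTr", Tr)
    put("Gb", "delta_Gb", -Gb)

    # Th activation also drains TN.
    put("Th", "lam_ThD", D * TN); put("TN", "lam_ThD", -D * TN)
    put("Th", "lam_ThM", M * TN); put("TN", "lam_ThM", -M * TN)
    put("Th", "lam_Thmu1", mu1 * TN); put("TN", "lam_Thmu1", -mu1 * TN)
    put("Th", "delta_Thmu2", -mu2 * Th)
    put("Th", "delta_ThTr", -Tr * Th)
    put("Th", "delta_Th", -Th)

    put("TC", "lam_TCTh", Th * TN); put("TN", "lam_TCTh", -Th * TN)
    put("TC", "lam_TCD", D * TN); put("TN", "lam_TCD", -D * TN)
    put("TC", "delta_TCmu2", -mu2 * TC)
    put("TC", "delta_TCTr", -Tr * TC)
    put("TC", "delta_TC", -TC)

    put("Tr", "lam_TrTh", Th * TN); put("TN", "lam_TrTh", -Th * TN)
    put("Tr", "lam_Trmu2", mu2 * TN); put("TN", "lam_Trmu2", -mu2 * TN)
    put("Tr", "lam_TrGb", Gb * TN); put("TN", "lam_TrGb", -Gb * TN)
    put("Tr", "delta_Trmu1", -mu1 * Tr)
    put("Tr", "delta_Tr", -Tr)

    put("TN", "A_TN", 1.0)
    put("TN", "delta_TN", -TN)

    put("DN", "A_DN", 1.0)
    put("DN", "lam_DH", -H * DN); put("D", "lam_DH", H * DN)
    put("DN", "lam_DC", -C * DN); put("D", "lam_DC", C * DN)
    put("DN", "delta_DH", -H * DN); put("D", "delta_DH", -H * D)
    put("D", "delta_DC", -C * D)
    put("DN", "delta_D", -DN); put("D", "delta_D", -D)

    put("M", "lam_Mmu2", mu2 * MN)
    put("M", "lam_MIg", Ig * MN)
    put("M", "lam_MTh", Th * MN)
    put("M", "delta_M", -M)
    put("M", "M0", a_M)

    put("C", "lam_C", logistic)
    put("C", "lam_Cmu1", mu1 * logistic)
    put("C", "C0", growth_C * C * C / p["C0"] ** 2)
    put("C", "delta_CGb", -Gb * C); put("N", "delta_CGb", aNC * Gb * C)
    put("C", "delta_CIg", -Ig * C); put("N", "delta_CIg", aNC * Ig * C)
    put("C", "delta_CTC", -TC * C); put("N", "delta_CTC", aNC * TC * C)
    put("C", "delta_C", -C); put("N", "delta_C", aNC * C)

    put("N", "alpha_NC", death_C * C)
    put("N", "delta_N", -N)

    return G


def steady_state_residual(state, params: ParameterSet, scale=None):
    """RHS evaluated at ``state`` scaled per variable.

    Returns ``(residual, max_norm)`` where ``residual[i] = f_i / scale_i``.
    The default scale is ``max(|state_i|, 1)`` so the norm reads as a relative
    rate of change per day.
    """
    x = as_state(state)
    f = rhs(x, params)
    if scale is None:
        s = np.maximum(np.abs(x), 1.0)
    else:
        s = np.asarray(scale, dtype=float)
        if np.any(s <= 0):
            raise ValueError("residual scale must be positive")
    r = f / s
    return r, float(np.max(np.abs(r)))


def finite_difference_jacobian(state, params: ParameterSet,
                               rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian, a cross-check for the analytic one."""
    x = as_state(state)
    J = np.zeros((N_STATE, N_STATE))
    for jcol in range(N_STATE):
        h = rel_step * max(abs(x[jcol]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[jcol] += h
        xm[jcol] -= h
        J[:, jcol] = (rhs(xp, params) - rhs(xm, params)) / (2.0 * h)
    return J


class DimensionlessSystem:
    """The model rescaled by per-variable reference values X_inf.

    With xbar = x / X_inf the rescaled field is fbar(xbar) = f(X_inf*xbar)/X_inf,
    so when X_inf is an equilibrium the all-ones vector is a steady state.
    Jacobians transform by similarity (eigenvalues unchanged); the parameter
    gradient picks up only the row scaling.
    """

    def __init__(self, params: ParameterSet, x_inf):
        x = as_state(x_inf)
        if np.any(x <= 0.0) or not np.all(np.isfinite(x)):
            bad = [STATE_NAMES[k] for k in np.flatnonzero(~(x > 0))]
            raise ValueError(
                f"reference values must be positive and finite; offending: {bad}"
            )
        self.params = params
        self.x_inf = x

    def rhs(self, xbar) -> np.ndarray:
        xbar = as_state(xbar)
        return rhs(xbar * self.x_inf, self.params) / self.x_inf

    def jacobian(self, xbar) -> np.ndarray:
        xbar = as_state(xbar)
        J = jacobian(xbar * self.x_inf, self.params)
        return J * (self.x_inf[None, :] / self.x_inf[:, None])

    def dfdtheta(self, xbar) -> np.ndarray:
        xbar = as_state(xbar)
        return dfdtheta(xbar * self.x_inf, self.params) / self.x_inf[:, None]

    def residual(self, xbar):
        r = self.rhs(xbar)
        return r, float(np.max(np.abs(r)))

    def term_coefficients(self) -> dict:
        """Scaled coefficient of every production/loss term, keyed
        ``"<equation>:<parameter>"``.

        Each coefficient is the dimensional rate multiplied by the reference
        values of its source factors and divided by the reference of the
        target variable; pure per-capita rates are scale-invariant.  The
        activation rates appear twice (e.g. ``lam_ThD`` in the Th and TN
        equations) with different scale factors, which is why the rescaled
        system cannot be expressed as a remapped ParameterSet.
        """
        p, s = self.params, dict(zip(STATE_NAMES, self.x_inf))
        c = {}

        def term(eq, name, *sources):
            factor = 1.0
            for src in sources:
                factor *= s[src]
            c[f"{eq}:{name}"] = p[name] * factor / s[eq]

        term("H", "lam_HN", "N"); term("H", "lam_HM", "M")
        term("H", "lam_HTh", "Th"); term("H", "lam_HTC", "TC")
        term("H", "lam_HTr", "Tr"); c["H:delta_H"] = p["delta_H"]
        term("mu1", "lam_mu1Th", "Th"); term("mu1", "lam_mu1M", "M")
        term("mu1", "lam_mu1D", "D"); c["mu1:delta_mu1"] = p["delta_mu1"]
        term("mu2", "lam_mu2M", "M"); term("mu2", "lam_mu2D", "D")
        term("mu2", "lam_mu2Tr", "Tr"); c["mu2:delta_mu2"] = p["delta_mu2"]
        term("Ig", "lam_IgTh", "Th"); term("Ig", "lam_IgTC", "TC")
        term("Ig", "lam_IgM", "M"); c["Ig:delta_Ig"] = p["delta_Ig"]
        term("Gb", "lam_GbM", "M"); term("Gb", "lam_GbTr", "Tr")
        c["Gb:delta_Gb"] = p["delta_Gb"]
        # activation terms: once in the activated-cell equation, once in TN's
        term("Th", "lam_ThD", "D", "TN"); term("TN", "lam_ThD", "D", "TN")
        term("Th", "lam_ThM", "M", "TN"); term("TN", "lam_ThM", "M", "TN")
        term("Th", "lam_Thmu1", "mu1", "TN"); term("TN", "lam_Thmu1", "mu1", "TN")
        term("Th", "delta_Thmu2", "mu2", "Th"); term("Th", "delta_ThTr", "Tr", "Th")
        c["Th:delta_Th"] = p["delta_Th"]
        term("TC", "lam_TCTh", "Th", "TN"); term("TN", "lam_TCTh", "Th", "TN")
        term("TC", "lam_TCD", "D", "TN"); term("TN", "lam_TCD", "D", "TN")
        term("TC", "delta_TCmu2", "mu2", "TC"); term("TC", "delta_TCTr", "Tr", "TC")
        c["TC:delta_TC"] = p["delta_TC"]
        term("Tr", "lam_TrTh", "Th", "TN"); term("TN", "lam_TrTh", "Th", "TN")
        term("Tr", "lam_Trmu2", "mu2", "TN"); term("TN", "lam_Trmu2", "mu2", "TN")
        term("Tr", "lam_TrGb", "Gb", "TN"); term("TN", "lam_TrGb", "Gb", "TN")
        term("Tr", "delta_Trmu1", "mu1", "Tr"); c["Tr:delta_Tr"] = p["delta_Tr"]
        c["TN:A_TN"] = p["A_TN"] / s["TN"]; c["TN:delta_TN"] = p["delta_TN"]
        c["DN:A_DN"] = p["A_DN"] / s["DN"]
        term("DN", "lam_DH", "H", "DN"); term("D", "lam_DH", "H", "DN")
        term("DN", "lam_DC", "C", "DN"); term("D", "lam_DC", "C", "DN")
        term("DN", "delta_DH", "H", "DN"); term("D", "delta_DH", "H", "D")
        term("D", "delta_DC", "C", "D")
        c["DN:delta_D"] = p["delta_D"]; c["D:delta_D"] = p["delta_D"]
        term("M", "lam_Mmu2", "mu2", "M"); term("M", "lam_MIg", "Ig", "M")
        term("M", "lam_MTh", "Th", "M")
        c["M:delta_M"] = p["delta_M"]; c["M:M0"] = p["M0"] / s["M"]
        c["C:lam_C"] = p["lam_C"]; term("C", "lam_Cmu1", "mu1", "C")
        c["C:C0"] = p["C0"] / s["C"]
        term("C", "delta_CGb", "Gb", "C"); term("C", "delta_CIg", "Ig", "C")
        term("C", "delta_CTC", "TC", "C"); c["C:delta_C"] = p["delta_C"]
        c["N:alpha_NC"] = p["alpha_NC"] * s["C"] / s["N"]
        c["N:delta_N"] = p["delta_N"]
        return c


def nondimensionalize(params: ParameterSet, x_inf) -> DimensionlessSystem:
    """Rescale the system so the reference state ``x_inf`` maps to all-ones.

    ``x_inf`` must be strictly positive; near-zero printed references (the
    cluster with DN_inf ~ 0.19 cells/cm^3) are used as printed, and exact
    zeros must be floored by the caller (documented floor: 1e-6 times the
    cohort median of that variable).
    """
    return DimensionlessSystem(params, x_inf)
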