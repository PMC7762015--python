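"""Cluster-specific parameter derivation from steady-state balances.

At a steady state every equation balances production against loss.  With the
steady-state value of each variable known, fixing a small number of rates
(cytokine decay and cell turnover, defaulting to 1/day) and apportioning each
multi-source flux among its terms with nonnegative shares makes the zeroed
system square, so each cluster yields a unique, nonnegative parameter set
that has the cluster steady state as an exact equilibrium.

Shares and fixed rates live in a versioned YAML config
(``colontme/config/assumptions.yaml``), never in code, so replacing the
placeholder values with literature-derived ones is a data edit.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import ParameterSet, jacobian, steady_state_residual
from .reference import ClusterSteadyState

__all__ = [
    "FLUX_GROUPS",
    "FIXED_RATE_NAMES",
    "AssumptionSet",
    "load_assumptions",
    "save_assumptions",
    "derive_parameters",
    "StabilityReport",
    "stability_report",
]

# Flux groups and the share keys each must carry.
FLUX_GROUPS = {
    "H_production": ("N", "M", "Th", "TC", "Tr"),
    "mu1_production": ("Th", "M", "D"),
    "mu2_production": ("M", "D", "Tr"),
    "Ig_production": ("Th", "TC", "M"),
    "Gb_production": ("M", "Tr"),
    "Th_activation": ("D", "M", "mu1"),
    "Th_loss": ("mu2", "Tr", "natural"),
    "TC_activation": ("Th", "D"),
    "TC_loss": ("mu2", "Tr", "natural"),
    "Tr_activation": ("Th", "mu2", "Gb"),
    "Tr_loss": ("mu1", "natural"),
    "D_activation": ("H", "C"),
    "D_loss": ("H", "C", "natural"),
    "M_activation": ("mu2", "Ig", "Th"),
    "C_production": ("base", "mu1"),
    "C_loss": ("Gb", "Ig", "TC", "natural"),
}

FIXED_RATE_NAMES = (
    "delta_H", "delta_mu1", "delta_mu2", "delta_Ig", "delta_Gb",
    "delta_TN", "delta_M",
    "turnover_Th", "turnover_TC", "turnover_Tr", "turnover_D", "turnover_C",
)

# Structural relations baked into the derivation (informational; they are
# enforced by construction, not free assumptions).
BUILTIN_RELATIONS = (
    "delta_DH and delta_D are shared between the naive and activated "
    "dendritic-cell equations",
    "C0 = 2 * C_inf (cancer capacity is twice the steady-state density)",
    "delta_N = alpha_NC * (cancer death rate) * C_inf / N_inf "
    "(necrotic balance closure)",
    "M0 is taken from the cluster steady state, M0 = MN_inf + M_inf",
)


@dataclass(frozen=True)
class AssumptionSet:
    """Fixed rates, flux shares and relations closing the steady-state system."""

    fixed_rates: dict
    shares: dict
    alpha_NC: float = 0.5
    relations: tuple = BUILTIN_RELATIONS
    version: int = 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = set(FIXED_RATE_NAMES) - set(self.fixed_rates)
        if missing:
            raise ValueError(f"missing fixed rate(s): {sorted(missing)}")
        for name in FIXED_RATE_NAMES:
            if not self.fixed_rates[name] > 0:
                raise ValueError(f"fixed rate {name} must be > 0")
        for group, keys in FLUX_GROUPS.items():
            if group not in self.shares:
                raise ValueError(f"missing flux group '{group}'")
            w = self.shares[group]
            extra = set(w) - set(keys)
            lacking = set(keys) - set(w)
            if extra or lacking:
                raise ValueError(
                    f"flux group '{group}' must have keys {keys}; "
                    f"extra={sorted(extra)} missing={sorted(lacking)}"
                )
            vals = np.array([float(w[k]) for k in keys])
            if np.any(vals < 0):
                raise ValueError(f"shares in '{group}' must be >= 0")
            if abs(vals.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"shares in '{group}' must sum to 1, got {vals.sum():.8f}"
                )
        if not 0.0 < self.alpha_NC <= 1.0:
            raise ValueError("alpha_NC must be in (0, 1]")

    def share(self, group: str, key: str) -> float:
        """Normalized share (weights renormalized to sum exactly to 1)."""
        w = self.shares[group]
        total = sum(float(v) for v in w.values())
        return float(w[key]) / total

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "fixed_rates": {k: float(v) for k, v in self.fixed_rates.items()},
            "alpha_NC": float(self.alpha_NC),
            "shares": {g: {k: float(v) for k, v in w.items()}
                       for g, w in self.shares.items()},
        }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_assumptions(source=None, cluster: int | None = None) -> AssumptionSet:
    """Load an :class:`AssumptionSet` from YAML (default: the packaged config).

    ``source`` may be a path, a YAML string starting with ``version:``, or a
    dict.  ``cluster`` applies the per-cluster override block if present.
    """
    if source is None:
        ref = importlib.resources.files("colontme") / "config" / "assumptions.yaml"
        raw = yaml.safe_load(ref.read_text())
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text())
    overrides = (raw.get("clusters") or {}).get(cluster, {}) if cluster else {}
    cfg = _merge({k: v for k, v in raw.items() if k != "clusters"}, overrides)
    return AssumptionSet(
        fixed_rates=cfg.get("fixed_rates", {}),
        shares=cfg.get("shares", {}),
        alpha_NC=float(cfg.get("alpha_NC", 0.5)),
        version=int(cfg.get("version", 1)),
    )


def save_assumptions(assumptions: AssumptionSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(assumptions.to_dict(), sort_keys=False))


def derive_parameters(x_inf: ClusterSteadyState,
                      assumptions: AssumptionSet | None = None,
                      alpha_dim: float = 1.125e5) -> ParameterSet:
    """Solve the zeroed system at the cluster steady state for all rates.

    Every balance is solved in closed form: fluxes anchored by the fixed
    turnover rates are split among their terms by the shares, so the returned
    set satisfies the steady-state residual to round-off and is nonnegative
    by construction.  A share configuration that would require a negative
    rate raises with the violated balance named.
    """
    if assumptions is None:
        assumptions = load_assumptions(cluster=getattr(x_inf, "cluster", None))
    a = assumptions
    s = x_inf.values
    fx = a.fixed_rates
    p: dict[str, float] = {}

    def production(group, flux, target_sources, extra_factor=1.0):
        """Apportion a production flux among bilinear source terms."""
        for key, (pname, source_val) in target_sources.items():
            denom = source_val * extra_factor
            if denom <= 0:
                raise ValueError(
                    f"cannot place share on '{key}' in {group}: "
                    f"source steady-state value is zero"
                )
            p[pname] = a.share(group, key) * flux / denom

    # Cytokines: fixed decay anchors the turnover flux.
    p["delta_H"] = fx["delta_H"]
    production("H_production", fx["delta_H"] * s["H"],
               {"N": ("lam_HN", s["N"]), "M": ("lam_HM", s["M"]),
                "Th": ("lam_HTh", s["Th"]), "TC": ("lam_HTC", s["TC"]),
                "Tr": ("lam_HTr", s["Tr"])})
    p["delta_mu1"] = fx["delta_mu1"]
    production("mu1_production", fx["delta_mu1"] * s["mu1"],
               {"Th": ("lam_mu1Th", s["Th"]), "M": ("lam_mu1M", s["M"]),
                "D": ("lam_mu1D", s["D"])})
    p["delta_mu2"] = fx["delta_mu2"]
    production("mu2_production", fx["delta_mu2"] * s["mu2"],
               {"M": ("lam_mu2M", s["M"]), "D": ("lam_mu2D", s["D"]),
                "Tr": ("lam_mu2Tr", s["Tr"])})
    p["delta_Ig"] = fx["delta_Ig"]
    production("Ig_production", fx["delta_Ig"] * s["Ig"],
               {"Th": ("lam_IgTh", s["Th"]), "TC": ("lam_IgTC", s["TC"]),
                "M": ("lam_IgM", s["M"])})
    p["delta_Gb"] = fx["delta_Gb"]
    production("Gb_production", fx["delta_Gb"] * s["Gb"],
               {"M": ("lam_GbM", s["M"]), "Tr": ("lam_GbTr", s["Tr"])})

    # Activated T cells: loss anchored by the turnover rate, activation flux
    # equal to the loss flux and proportional to TN.
    def tcell(kind, act_group, act_sources, loss_group, loss_sources):
        turn = fx[f"turnover_{kind}"]
        flux = turn * s[kind]
        for key, (pname, val) in loss_sources.items():
            p[pname] = a.share(loss_group, key) * turn / val
        p[f"delta_{kind}"] = a.share(loss_group, "natural") * turn
        production(act_group, flux, act_sources, extra_factor=s["TN"])
        return flux

    flux_Th = tcell(
        "Th", "Th_activation",
        {"D": ("lam_ThD", s["D"]), "M": ("lam_ThM", s["M"]),
         "mu1": ("lam_Thmu1", s["mu1"])},
        "Th_loss",
        {"mu2": ("delta_Thmu2", s["mu2"]), "Tr": ("delta_ThTr", s["Tr"])},
    )
    flux_TC = tcell(
        "TC", "TC_activation",
        {"Th": ("lam_TCTh", s["Th"]), "D": ("lam_TCD", s["D"])},
        "TC_loss",
        {"mu2": ("delta_TCmu2", s["mu2"]), "Tr": ("delta_TCTr", s["Tr"])},
    )
    flux_Tr = tcell(
        "Tr", "Tr_activation",
        {"Th": ("lam_TrTh", s["Th"]), "mu2": ("lam_Trmu2", s["mu2"]),
         "Gb": ("lam_TrGb", s["Gb"])},
        "Tr_loss",
        {"mu1": ("delta_Trmu1", s["mu1"])},
    )

    # Naive T cells: influx balances activation drain plus natural death.
    p["delta_TN"] = fx["delta_TN"]
    p["A_TN"] = flux_Th + flux_TC + flux_Tr + fx["delta_TN"] * s["TN"]

    # Dendritic cells: the activated-cell balance anchors both the loss rates
    # (shared with the naive equation for the H- and natural terms) and the
    # activation flux out of DN.
    turn_D = fx["turnover_D"]
    p["delta_DH"] = a.share("D_loss", "H") * turn_D / s["H"]
    p["delta_DC"] = a.share("D_loss", "C") * turn_D / s["C"]
    p["delta_D"] = a.share("D_loss", "natural") * turn_D
    flux_D = turn_D * s["D"]
    if s["DN"] <= 0:
        raise ValueError(
            "naive dendritic steady state is zero; floor it before deriving "
            "parameters (documented floor: 1e-6 x cohort median)"
        )
    p["lam_DH"] = a.share("D_activation", "H") * flux_D / (s["H"] * s["DN"])
    p["lam_DC"] = a.share("D_activation", "C") * flux_D / (s["C"] * s["DN"])
    p["A_DN"] = flux_D + (p["delta_DH"] * s["H"] + p["delta_D"]) * s["DN"]

    # Macrophages: activation of the naive pool (M0 - M) balances decay.
    p["delta_M"] = fx["delta_M"]
    p["M0"] = float(x_inf.M0)
    naive = p["M0"] - s["M"]
    if naive <= 0:
        raise ValueError("macrophage balance violated: M0 must exceed M_inf")
    production("M_activation", fx["delta_M"] * s["M"],
               {"mu2": ("lam_Mmu2", s["mu2"]), "Ig": ("lam_MIg", s["Ig"]),
                "Th": ("lam_MTh", s["Th"])}, extra_factor=naive)

    # Cancer: capacity C0 = 2 C_inf makes the logistic factor 1/2, so the
    # per-capita growth must be twice the per-capita death rate.
    turn_C = fx["turnover_C"]
    p["C0"] = 2.0 * s["C"]
    p["delta_CGb"] = a.share("C_loss", "Gb") * turn_C / s["Gb"]
    p["delta_CIg"] = a.share("C_loss", "Ig") * turn_C / s["Ig"]
    p["delta_CTC"] = a.share("C_loss", "TC") * turn_C / s["TC"]
    p["delta_C"] = a.share("C_loss", "natural") * turn_C
    growth = turn_C / (1.0 - s["C"] / p["C0"])
    p["lam_C"] = a.share("C_production", "base") * growth
    p["lam_Cmu1"] = a.share("C_production", "mu1") * growth / s["mu1"]

    # Necrotic cells: decay balances the captured fraction of the death flux.
    p["alpha_NC"] = a.alpha_NC
    p["delta_N"] = a.alpha_NC * turn_C * s["C"] / s["N"]

    params = ParameterSet(p, alpha_dim=alpha_dim)
    _, norm = steady_state_residual(x_inf.as_state(), params)
    if norm > 1e-10:
        raise AssertionError(
            f"derived parameters do not balance the steady state "
            f"(residual {norm:.2e})"
        )
    return params


def assumptions_from_parameters(params: ParameterSet,
                                x_inf: ClusterSteadyState) -> AssumptionSet:
    """Invert the derivation: recover the fixed rates and flux shares that
    reproduce ``params`` from the given equilibrium.

    For a parameter set consistent with the equilibrium, feeding the result
    back through :func:`derive_parameters` returns the same rates — the
    identifiability statement behind the estimation scheme.
    """
    s = x_inf.values
    p = params

    def split(group, pairs):
        fluxes = {key: p[pname] * val for key, (pname, val) in pairs.items()}
        total = sum(fluxes.values())
        if total <= 0:
            raise ValueError(f"zero total flux in group '{group}'")
        return total, {key: f / total for key, f in fluxes.items()}

    shares, fixed = {}, {}
    fixed["delta_H"] = p["delta_H"]
    _, shares["H_production"] = split("H_production", {
        "N": ("lam_HN", s["N"]), "M": ("lam_HM", s["M"]),
        "Th": ("lam_HTh", s["Th"]), "TC": ("lam_HTC", s["TC"]),
        "Tr": ("lam_HTr", s["Tr"])})
    fixed["delta_mu1"] = p["delta_mu1"]
    _, shares["mu1_production"] = split("mu1_production", {
        "Th": ("lam_mu1Th", s["Th"]), "M": ("lam_mu1M", s["M"]),
        "D": ("lam_mu1D", s["D"])})
    fixed["delta_mu2"] = p["delta_mu2"]
    _, shares["mu2_production"] = split("mu2_production", {
        "M": ("lam_mu2M", s["M"]), "D": ("lam_mu2D", s["D"]),
        "Tr": ("lam_mu2Tr", s["Tr"])})
    fixed["delta_Ig"] = p["delta_Ig"]
    _, shares["Ig_production"] = split("Ig_production", {
        "Th": ("lam_IgTh", s["Th"]), "TC": ("lam_IgTC", s["TC"]),
        "M": ("lam_IgM", s["M"])})
    fixed["delta_Gb"] = p["delta_Gb"]
    _, shares["Gb_production"] = split("Gb_production", {
        "M": ("lam_GbM", s["M"]), "Tr": ("lam_GbTr", s["Tr"])})

    for kind, act, loss in (
        ("Th", {"D": ("lam_ThD", s["D"]), "M": ("lam_ThM", s["M"]),
                "mu1": ("lam_Thmu1", s["mu1"])},
         {"mu2": ("delta_Thmu2", s["mu2"]), "Tr": ("delta_ThTr", s["Tr"]),
          "natural": (f"delta_Th", 1.0)}),
        ("TC", {"Th": ("lam_TCTh", s["Th"]), "D": ("lam_TCD", s["D"])},
         {"mu2": ("delta_TCmu2", s["mu2"]), "Tr": ("delta_TCTr", s["Tr"]),
          "natural": ("delta_TC", 1.0)}),
        ("Tr", {"Th": ("lam_TrTh", s["Th"]), "mu2": ("lam_Trmu2", s["mu2"]),
                "Gb": ("lam_TrGb", s["Gb"])},
         {"mu1": ("delta_Trmu1", s["mu1"]), "natural": ("delta_Tr", 1.0)}),
    ):
        turnover, loss_shares = split(f"{kind}_loss", loss)
        fixed[f"turnover_{kind}"] = turnover
        shares[f"{kind}_loss"] = loss_shares
        _, shares[f"{kind}_activation"] = split(f"{kind}_activation", act)
    fixed["delta_TN"] = p["delta_TN"]

    turnover_D, d_loss = split("D_loss", {
        "H": ("delta_DH", s["H"]), "C": ("delta_DC", s["C"]),
        "natural": ("delta_D", 1.0)})
    fixed["turnover_D"] = turnover_D
    shares["D_loss"] = d_loss
    _, shares["D_activation"] = split("D_activation", {
        "H": ("lam_DH", s["H"]), "C": ("lam_DC", s["C"])})

    fixed["delta_M"] = p["delta_M"]
    _, shares["M_activation"] = split("M_activation", {
        "mu2": ("lam_Mmu2", s["mu2"]), "Ig": ("lam_MIg", s["Ig"]),
        "Th": ("lam_MTh", s["Th"])})

    turnover_C, c_loss = split("C_loss", {
        "Gb": ("delta_CGb", s["Gb"]), "Ig": ("delta_CIg", s["Ig"]),
        "TC": ("delta_CTC", s["TC"]), "natural": ("delta_C", 1.0)})
    fixed["turnover_C"] = turnover_C
    shares["C_loss"] = c_loss
    _, shares["C_production"] = split("C_production", {
        "base": ("lam_C", 1.0), "mu1": ("lam_Cmu1", s["mu1"])})

    return AssumptionSet(fixed_rates=fixed, shares=shares,
                         alpha_NC=p["alpha_NC"])


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian spectrum at an equilibrium.

    ``slowest`` is the eigenvalue with the largest real part (the slowest
    decaying mode, which controls convergence speed); ``most_negative`` is
    the literal minimum over real parts, reported alongside because the
    convergence quantity of interest in the sensitivity module follows that
    definition by default.
    """

    eigenvalues: np.ndarray
    max_real_part: float
    slowest: complex
    most_negative: complex
    stable: bool


def stability_report(params: ParameterSet, x_inf) -> StabilityReport:
    x = x_inf.as_state() if hasattr(x_inf, "as_state") else x_inf
    eig = np.linalg.eigvals(jacobian(x, params))
    order = np.argsort(eig.real)
    return StabilityReport(
        eigenvalues=eig[order],
        max_real_part=float(eig.real.max()),
        slowest=complex(eig[order[-1]]),
        most_negative=complex(eig[order[0]]),
        stable=bool(eig.real.max() < 0.0),
    )
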