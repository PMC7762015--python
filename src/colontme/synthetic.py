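"""Synthetic cohort generator.

Emulates the statistical shape of a deconvolution cohort table — one row
per patient with 22 immune-cell-type fractions, tumor dimensions (cm) and
clinical labels — with K planted cluster-specific mean profiles.  Fractions
are drawn from a Dirichlet around each planted profile (the concentration
parameter sets within-cluster noise while keeping the simplex constraint),
tumor sizes are log-normal, and per-cluster cytokine expression levels are
log-normally scattered around planted means.  The hidden truth (labels,
profiles, and the per-cluster steady states implied by the density mapping)
is returned for scoring.

What this does not emulate: deconvolution estimation error structure
(correlated across cell types), gene-expression-level noise, or clinical
covariates with real survival structure — the clinical labels are decor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import CELL_TYPES, IMMUNE_MODEL_VARS, load_celltype_map
from .model import CYTOKINE_NAMES
from .reference import CLUSTERS, ClusterSteadyState, initial_condition, \
    steady_state

__all__ = [
    "GeneratorConfig",
    "default_profiles",
    "profiles_from_steady_states",
    "generate_cohort",
    "generate_from_tables",
]

_T = {name: i for i, name in enumerate(CELL_TYPES)}


def _profile(**weights) -> np.ndarray:
    """Build a simplex profile from named weights (unnamed types get a
    small floor so Dirichlet concentrations stay positive)."""
    v = np.full(len(CELL_TYPES), 1e-4)
    for name, w in weights.items():
        v[_T[name]] = w
    return v / v.sum()


def default_profiles() -> np.ndarray:
    """Five planted immune patterns with the qualitative contrasts seen in
    colon-cancer cohorts: two activated-macrophage-dominant patterns, a
    naive-macrophage-dominant outlier with almost no resting dendritic
    cells, a low-naive/high-M2 pattern, and a balanced slow-growing one."""
    profiles = [
        # 1: activated macrophages > naive, strong helper compartment
        _profile(**{"B cells naive": 0.03, "Plasma cells": 0.05,
                    "T cells CD8": 0.07, "T cells CD4 naive": 0.13,
                    "T cells CD4 memory resting": 0.10,
                    "T cells CD4 memory activated": 0.08,
                    "T cells follicular helper": 0.04,
                    "T cells regulatory (Tregs)": 0.06,
                    "NK cells activated": 0.03, "Monocytes": 0.04,
                    "Macrophages M0": 0.09, "Macrophages M1": 0.10,
                    "Macrophages M2": 0.12, "Dendritic cells resting": 0.015,
                    "Dendritic cells activated": 0.012,
                    "Mast cells resting": 0.03, "Neutrophils": 0.02}),
        # 2: cytotoxic/helper rich, macrophage poor
        _profile(**{"B cells naive": 0.04, "Plasma cells": 0.06,
                    "T cells CD8": 0.16, "T cells CD4 naive": 0.10,
                    "T cells CD4 memory resting": 0.08,
                    "T cells CD4 memory activated": 0.11,
                    "T cells follicular helper": 0.06,
                    "T cells regulatory (Tregs)": 0.09,
                    "NK cells activated": 0.05, "Monocytes": 0.03,
                    "Macrophages M0": 0.07, "Macrophages M1": 0.06,
                    "Macrophages M2": 0.05, "Dendritic cells resting": 0.006,
                    "Dendritic cells activated": 0.012,
                    "Mast cells resting": 0.02, "Neutrophils": 0.02}),
        # 3: naive-macrophage outlier, resting DCs essentially absent
        _profile(**{"B cells naive": 0.03, "Plasma cells": 0.04,
                    "T cells CD8": 0.035, "T cells CD4 naive": 0.09,
                    "T cells CD4 memory resting": 0.06,
                    "T cells CD4 memory activated": 0.025,
                    "T cells follicular helper": 0.015,
                    "T cells regulatory (Tregs)": 0.08,
                    "NK cells resting": 0.04, "Monocytes": 0.05,
                    "Macrophages M0": 0.33, "Macrophages M1": 0.04,
                    "Macrophages M2": 0.055,
                    "Dendritic cells activated": 0.005,
                    "Mast cells resting": 0.04, "Neutrophils": 0.03}),
        # 4: lowest naive macrophages, highest M2, dendritic rich
        _profile(**{"B cells naive": 0.03, "Plasma cells": 0.05,
                    "T cells CD8": 0.09, "T cells CD4 naive": 0.14,
                    "T cells CD4 memory resting": 0.09,
                    "T cells CD4 memory activated": 0.05,
                    "T cells follicular helper": 0.025,
                    "T cells regulatory (Tregs)": 0.065,
                    "NK cells activated": 0.025, "Monocytes": 0.04,
                    "Macrophages M0": 0.025, "Macrophages M1": 0.12,
                    "Macrophages M2": 0.18, "Dendritic cells resting": 0.008,
                    "Dendritic cells activated": 0.015,
                    "Mast cells resting": 0.025, "Neutrophils": 0.02}),
        # 5: balanced, naive slightly above activated macrophages
        _profile(**{"B cells naive": 0.04, "Plasma cells": 0.06,
                    "T cells CD8": 0.05, "T cells CD4 naive": 0.10,
                    "T cells CD4 memory resting": 0.11,
                    "T cells CD4 memory activated": 0.08,
                    "T cells follicular helper": 0.035,
                    "T cells regulatory (Tregs)": 0.075,
                    "NK cells resting": 0.035, "Monocytes": 0.035,
                    "Macrophages M0": 0.155, "Macrophages M1": 0.05,
                    "Macrophages M2": 0.075, "Dendritic cells resting": 0.004,
                    "Dendritic cells activated": 0.004,
                    "Mast cells resting": 0.035, "Neutrophils": 0.025}),
    ]
    return np.vstack(profiles)


def profiles_from_steady_states(sstates=None, mapping=None) -> tuple:
    """Planted profiles and cytokine means that, pushed through the density
    mapping, center each cluster on its reference steady state's immune
    composition (rescaled to the fixed immune budget).

    Each model variable's density is assigned to one representative cell
    type (the macrophage pool split evenly between M1 and M2, the naive
    remainder to M0), so the mapped immune block is exactly proportional to
    the reference one.
    """
    if sstates is None:
        sstates = {k: steady_state(k) for k in CLUSTERS}
    if mapping is None:
        mapping = load_celltype_map()
    representative = {var: mapping[var][0] for var in IMMUNE_MODEL_VARS}
    profiles, cytokines = [], []
    for k in sorted(sstates):
        ss = sstates[k]
        weights = {}
        for var in IMMUNE_MODEL_VARS:
            if var == "M":
                weights["Macrophages M1"] = 0.5 * ss["M"]
                weights["Macrophages M2"] = 0.5 * ss["M"]
            else:
                weights[representative[var]] = ss[var]
        weights["Macrophages M0"] = ss.M0 - ss["M"]
        profiles.append(_profile(**{t: w for t, w in weights.items() if w > 0}))
        cytokines.append([ss[c] for c in CYTOKINE_NAMES])
    return np.vstack(profiles), np.asarray(cytokines)


# per-cluster clinical outcome probabilities (alive, tumor-free), echoing
# the pattern that cluster 5 fares best and clusters 3-4 worst
_P_ALIVE = {1: 0.75, 2: 0.75, 3: 0.60, 4: 0.65, 5: 0.85}
_P_TUMOR_FREE = {1: 0.70, 2: 0.65, 3: 0.60, 4: 0.50, 5: 0.80}
_P_STAGE = {
    1: (0.20, 0.40, 0.25, 0.15), 2: (0.20, 0.40, 0.25, 0.15),
    3: (0.10, 0.30, 0.35, 0.25), 4: (0.15, 0.35, 0.30, 0.20),
    5: (0.30, 0.40, 0.20, 0.10),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 300 patients in five clusters (the cohort scale and cluster
    count of the motivating study); within-cluster fraction noise is
    mean-corrected logistic-normal with sigma 0.25 (a per-type coefficient
    of variation of roughly 25%, comparable to deconvolution scatter, and
    well defined even for near-zero planted fractions, where a Dirichlet of
    comparable concentration degenerates to a point mass at zero — a
    Dirichlet option remains available); log-normal tumor size with median
    0.6 cm^2 and sigma 0.5 (spanning sub-0.25 to above-1.25 cm^2 size
    bins); and a unit cancer-ratio-vs-size exponent so the cancer share of
    the total density rises with tumor size.
    """

    n_patients: int = 300
    k: int = 5
    profiles: np.ndarray | None = None
    noise_model: str = "logistic-normal"
    fraction_sigma: float = 0.25
    concentration: float = 200.0
    size_median_cm2: float = 0.6
    size_sigma: float = 0.5
    cancer_ratio_slope: float = 1.0
    alpha_dim: float = 1.125e5
    cytokine_means: np.ndarray | None = None
    cytokine_sigma: float = 0.10
    seed: int = 7

    def __post_init__(self):
        if self.profiles is None:
            self.profiles = default_profiles()[: self.k]
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (self.k, len(CELL_TYPES)):
            raise ValueError(
                f"profiles must have shape ({self.k}, {len(CELL_TYPES)})")
        if np.any(self.profiles <= 0) or not np.allclose(
                self.profiles.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("profiles must be strictly positive simplex rows")
        if self.cytokine_means is None:
            ref = [steady_state(c) for c in CLUSTERS]
            self.cytokine_means = np.array(
                [[ref[i % len(ref)][c] for c in CYTOKINE_NAMES]
                 for i in range(self.k)])
        self.cytokine_means = np.asarray(self.cytokine_means, dtype=float)
        if self.n_patients < self.k:
            raise ValueError("need at least one patient per cluster")


def generate_cohort(config: GeneratorConfig | None = None,
                    noise_free: bool = False):
    """Draw a cohort table; returns ``(DataFrame, truth)``.

    ``truth`` carries the planted labels, profiles, per-patient sizes and
    the per-cluster steady states implied by pushing the planted means
    through the density mapping at the realized sizes.  With
    ``noise_free=True`` every patient's fractions equal its cluster profile
    exactly (the zero-noise limit).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    labels = np.arange(cfg.n_patients) % cfg.k + 1
    rng.shuffle(labels)

    fractions = np.empty((cfg.n_patients, len(CELL_TYPES)))
    for i, lab in enumerate(labels):
        prof = cfg.profiles[lab - 1]
        if noise_free:
            fractions[i] = prof
        elif cfg.noise_model == "logistic-normal":
            # mean-corrected multiplicative noise keeps near-zero types
            # proportionally noisy instead of Dirichlet's point mass at 0
            z = rng.standard_normal(prof.size)
            raw = prof * np.exp(cfg.fraction_sigma * z
                                - 0.5 * cfg.fraction_sigma ** 2)
            fractions[i] = raw / raw.sum()
        elif cfg.noise_model == "dirichlet":
            fractions[i] = rng.dirichlet(cfg.concentration * prof)
        else:
            raise ValueError(
                "noise_model must be 'logistic-normal' or 'dirichlet'")

    size = cfg.size_median_cm2 * np.exp(
        cfg.size_sigma * rng.standard_normal(cfg.n_patients))
    aspect = rng.uniform(1.0, 2.5, cfg.n_patients)
    longest = np.sqrt(size * aspect)
    shortest = np.sqrt(size / aspect)

    cyt = np.empty((cfg.n_patients, len(CYTOKINE_NAMES)))
    for i, lab in enumerate(labels):
        mean = cfg.cytokine_means[lab - 1]
        noise = (np.ones_like(mean) if noise_free else np.exp(
            cfg.cytokine_sigma * rng.standard_normal(mean.size)
            - 0.5 * cfg.cytokine_sigma ** 2))
        cyt[i] = mean * noise

    df = pd.DataFrame(fractions, columns=list(CELL_TYPES))
    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(cfg.n_patients)])
    df["longest_cm"] = longest
    df["shortest_cm"] = shortest
    for j, name in enumerate(CYTOKINE_NAMES):
        df[name] = cyt[:, j]
    df["vital_status"] = [
        "Alive" if rng.random() < _P_ALIVE.get(l, 0.7) else "Dead"
        for l in labels]
    df["tumor_status"] = [
        "Tumor free" if rng.random() < _P_TUMOR_FREE.get(l, 0.6) else
        "With tumor" for l in labels]
    stages = ("I", "II", "III", "IV")
    df["stage"] = [stages[rng.choice(4, p=_P_STAGE.get(l, (0.25,) * 4))]
                   for l in labels]
    df["gender"] = rng.choice(["female", "male"], cfg.n_patients)

    truth = {
        "labels": labels,
        "profiles": cfg.profiles.copy(),
        "size_cm2": size,
        "config": cfg,
        "target_steady_states": _target_steady_states(cfg, labels, size),
    }
    return df, truth


def _target_steady_states(cfg: GeneratorConfig, labels, size) -> dict:
    """Steady states implied by the planted (noise-free) cluster means:
    the mapping applied to each planted profile at the realized mean
    above-average tumor size of the cluster."""
    mapping = load_celltype_map()
    mean_size = float(np.mean(size ** cfg.cancer_ratio_slope))
    targets = {}
    for k in range(1, cfg.k + 1):
        s_k = size[labels == k]
        big = s_k[s_k > s_k.mean()]
        if big.size == 0:
            big = s_k
        rec = dict(zip(CELL_TYPES, cfg.profiles[k - 1]))
        rec["longest_cm"] = float(np.sqrt(np.mean(
            big ** cfg.cancer_ratio_slope)))
        rec["shortest_cm"] = rec["longest_cm"]
        rec.update(dict(zip(CYTOKINE_NAMES, cfg.cytokine_means[k - 1])))
        mapped = _cohort.map_to_model_variables(
            rec, mean_size, alpha_dim=cfg.alpha_dim, mapping=mapping)
        values = {name: mapped[name] for name in
                  IMMUNE_MODEL_VARS + ("C", "N") + tuple(CYTOKINE_NAMES)}
        targets[k] = ClusterSteadyState(values=values, M0=mapped["M0"],
                                        cluster=k)
    return targets


def generate_from_tables() -> dict:
    """The five reference clusters as ready-to-use fixtures:
    ``{cluster: (ClusterSteadyState, dimensionless initial condition)}``."""
    return {k: (steady_state(k), initial_condition(k)) for k in CLUSTERS}
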