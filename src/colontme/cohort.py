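"""Cohort stage: deconvolution tables -> model variables -> clusters.

Input is one row per patient with immune-cell-type fractions (CIBERSORTx
style), the tumor's longest and shortest dimensions (cm) and optional
clinical labels.  Tumor size is the product of the two dimensions (cm^2);
total cell density is proportional to size; immune fractions are converted
to densities with a fixed immune budget of 0.4 * alpha_dim per patient; and
cancer / necrotic densities close the budget via

    C = (2/3) (Total - Immune_total),    N = 0.5 C,

so that C + N + Immune_total = Total exactly.  Patients are clustered by
K-means on the full fraction table; each cluster's steady state is the mean
over its above-average-size tumors and its initial condition is the
smallest tumor, divided componentwise by the steady state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans

from .model import CYTOKINE_NAMES, STATE_NAMES, as_state
from .reference import ClusterSteadyState

__all__ = [
    "CELL_TYPES",
    "MODEL_COLUMNS",
    "load_celltype_map",
    "compute_size",
    "map_to_model_variables",
    "map_cohort",
    "ElbowResult",
    "elbow_k",
    "ClusterAssignment",
    "cluster_patients",
    "extract_steady_state",
    "extract_initial_conditions",
    "run_pipeline",
]

# The 22 immune cell types of the standard deconvolution signature matrix.
CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated", "Monocytes",
    "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

IMMUNE_MODEL_VARS = ("TN", "Th", "TC", "Tr", "DN", "D", "M")
MODEL_COLUMNS = IMMUNE_MODEL_VARS + ("C", "N") + CYTOKINE_NAMES + (
    "M0", "Total", "Immune_total", "size_cm2")

IMMUNE_BUDGET_FRACTION = 0.4  # immune share of alpha_dim in the density map


def load_celltype_map(source=None) -> dict:
    """Model-variable -> cell-type mapping (default: packaged YAML)."""
    if source is None:
        ref = importlib.resources.files("colontme") / "config" / "celltype_map.yaml"
        raw = yaml.safe_load(ref.read_text())
    elif isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text())
    mapping = {k: tuple(v) for k, v in raw["variables"].items()}
    missing = set(IMMUNE_MODEL_VARS) - set(mapping)
    if missing:
        raise ValueError(f"cell-type map lacks model variable(s): {sorted(missing)}")
    mapping["_naive_macrophages"] = tuple(raw.get("naive_macrophages", ()))
    return mapping


def compute_size(longest: float, shortest: float) -> float:
    """Tumor size (cm^2): product of the longest and shortest dimensions."""
    if not (longest > 0 and shortest > 0):
        raise ValueError("tumor dimensions must be positive")
    return float(longest) * float(shortest)


def map_to_model_variables(record, cohort_mean_size: float,
                           alpha_dim: float = 1.125e5, mapping=None,
                           immune_scaling: str = "constant") -> dict:
    """Derive model-variable densities for one patient.

    ``immune_scaling="constant"`` fixes the immune density budget at
    ``0.4 * alpha_dim`` for every patient; ``"proportional"`` scales it with
    the patient's total density instead (``0.4 * Total``), an alternative
    for cohorts where a fixed budget would exceed the total in the smallest
    tumors.
    """
    if mapping is None:
        mapping = load_celltype_map()
    if not cohort_mean_size > 0:
        raise ValueError("cohort mean size must be positive")
    rec = dict(record)
    size = compute_size(rec["longest_cm"], rec["shortest_cm"])
    total = alpha_dim * size / cohort_mean_size

    ratio_sum = float(sum(float(rec.get(t, 0.0)) for t in CELL_TYPES))
    if ratio_sum <= 0:
        raise ValueError("sum of immune cell ratios is zero")
    if immune_scaling == "constant":
        budget = IMMUNE_BUDGET_FRACTION * alpha_dim
    elif immune_scaling == "proportional":
        budget = IMMUNE_BUDGET_FRACTION * total
    else:
        raise ValueError("immune_scaling must be 'constant' or 'proportional'")
    unit = budget / ratio_sum

    out = {}
    for var in IMMUNE_MODEL_VARS:
        out[var] = sum(float(rec.get(t, 0.0)) for t in mapping[var]) * unit
    naive_m = sum(float(rec.get(t, 0.0))
                  for t in mapping["_naive_macrophages"]) * unit
    out["M0"] = out["M"] + naive_m

    immune_total = budget
    out["C"] = (2.0 / 3.0) * (total - immune_total)
    out["N"] = 0.5 * out["C"]
    for cyt in CYTOKINE_NAMES:
        if cyt in rec:
            out[cyt] = float(rec[cyt])
    out["Total"] = total
    out["Immune_total"] = immune_total
    out["C0"] = 2.0 * out["C"]
    out["size_cm2"] = size
    return out


def map_cohort(df: pd.DataFrame, alpha_dim: float = 1.125e5, mapping=None,
               immune_scaling: str = "constant") -> pd.DataFrame:
    """Apply :func:`map_to_model_variables` to every patient row."""
    if mapping is None:
        mapping = load_celltype_map()
    sizes = df.apply(
        lambda r: compute_size(r["longest_cm"], r["shortest_cm"]), axis=1)
    mean_size = float(sizes.mean())
    rows = [map_to_model_variables(row, mean_size, alpha_dim=alpha_dim,
                                   mapping=mapping,
                                   immune_scaling=immune_scaling)
            for _, row in df.iterrows()]
    return pd.DataFrame(rows, index=df.index)


@dataclass
class ElbowResult:
    k: int
    k_range: tuple
    inertia: np.ndarray
    curvature: np.ndarray
    confident: bool


def elbow_k(fractions, k_range=range(1, 11), seed: int = 0,
            n_init: int = 10, min_drop: float = 0.15) -> ElbowResult:
    """Suggest a cluster count from the K-means inertia curve.

    The knee is placed at the last substantial relative inertia drop: the
    largest k whose drop (I[k-1]-I[k])/I[k-1] is both at least ``min_drop``
    and clearly above the residual drops beyond it.  When no drop qualifies
    — a smooth curve with no sharp knee — the maximum-curvature k is
    reported with the confidence flag cleared.
    """
    X = np.asarray(fractions, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if X.shape[0] < max(ks):
        raise ValueError("need at least max(k_range) records")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all rows identical")
    inertia = np.array([
        KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(X).inertia_
        for k in ks
    ])
    curvature = np.zeros(len(ks))
    if len(ks) >= 3:
        curvature[1:-1] = inertia[:-2] - 2.0 * inertia[1:-1] + inertia[2:]
    if len(ks) == 1 or inertia.max() <= inertia.min():
        return ElbowResult(ks[0], tuple(ks), inertia, curvature,
                           confident=False)
    drops = (inertia[:-1] - inertia[1:]) / np.maximum(inertia[:-1], 1e-300)
    for j in range(len(drops) - 1, -1, -1):
        tail = np.median(drops[j + 1:]) if j + 1 < len(drops) else 0.0
        if drops[j] >= max(min_drop, 3.0 * tail):
            return ElbowResult(ks[j + 1], tuple(ks), inertia, curvature,
                               confident=True)
    best = int(np.argmax(curvature)) if len(ks) >= 3 else 0
    return ElbowResult(ks[best], tuple(ks), inertia, curvature,
                       confident=False)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..K per patient
    K: int
    centers: pd.DataFrame  # per-cluster mean immune profile
    inertia: float


def cluster_patients(fractions, K: int, seed: int = 0, n_init: int = 10,
                     max_retries: int = 5) -> ClusterAssignment:
    """K-means over the full fraction table; deterministic given the seed."""
    X = np.asarray(fractions, dtype=float)
    if K > X.shape[0]:
        raise ValueError("K exceeds the number of records")
    columns = (list(fractions.columns)
               if isinstance(fractions, pd.DataFrame)
               else list(range(X.shape[1])))
    for attempt in range(max_retries):
        km = KMeans(n_clusters=K, random_state=seed + attempt,
                    n_init=n_init).fit(X)
        counts = np.bincount(km.labels_, minlength=K)
        if counts.min() > 0:
            centers = pd.DataFrame(km.cluster_centers_, columns=columns,
                                   index=np.arange(1, K + 1))
            return ClusterAssignment(labels=km.labels_ + 1, K=K,
                                     centers=centers,
                                     inertia=float(km.inertia_))
    raise RuntimeError(f"empty cluster persisted over {max_retries} re-inits")


def extract_steady_state(mapped: pd.DataFrame,
                         cluster: int | None = None) -> ClusterSteadyState:
    """Cluster steady state: mean of the mapped variables over the
    above-average-size tumors in the cluster."""
    missing = [c for c in CYTOKINE_NAMES if c not in mapped.columns]
    if missing:
        raise ValueError(
            f"cytokine column(s) {missing} required to build a steady state"
        )
    subset = mapped[mapped["size_cm2"] > mapped["size_cm2"].mean()]
    if subset.empty:
        subset = mapped  # all sizes identical: every tumor is "largest"
    values = {name: float(subset[name].mean()) for name in STATE_NAMES}
    return ClusterSteadyState(values=values, M0=float(subset["M0"].mean()),
                              cluster=cluster)


def extract_initial_conditions(mapped: pd.DataFrame,
                               x_inf: ClusterSteadyState) -> np.ndarray:
    """Dimensionless initial condition: the smallest tumor's variables
    divided by the steady state.

    Ties on size break by row order (patient id order).  Negative closure
    values (a tumor smaller than the fixed immune budget) are clipped to
    zero, matching the convention that the smallest tumors start with
    essentially no cancer or necrotic mass.
    """
    ref = x_inf.as_state()
    if np.any(ref <= 0):
        raise ValueError(
            "steady state has nonpositive components; floor them first "
            "(documented floor: 1e-6 x cohort median)"
        )
    order = np.lexsort((np.arange(len(mapped)), mapped["size_cm2"].to_numpy()))
    row = mapped.iloc[order[0]]
    x0 = as_state({name: max(float(row[name]), 0.0) for name in STATE_NAMES})
    return x0 / ref


def run_pipeline(df: pd.DataFrame, K: int = 5, seed: int = 0,
                 alpha_dim: float = 1.125e5, mapping=None,
                 immune_scaling: str = "constant") -> dict:
    """Cluster a cohort and extract per-cluster steady states and
    dimensionless initial conditions."""
    fractions = df[list(CELL_TYPES)]
    assignment = cluster_patients(fractions, K, seed=seed)
    mapped = map_cohort(df, alpha_dim=alpha_dim, mapping=mapping,
                        immune_scaling=immune_scaling)
    steady_states, initial_conditions = {}, {}
    for k in range(1, K + 1):
        members = mapped[assignment.labels == k]
        ss = extract_steady_state(members, cluster=k)
        steady_states[k] = ss
        initial_conditions[k] = extract_initial_conditions(members, ss)
    return {
        "assignment": assignment,
        "mapped": mapped,
        "steady_states": steady_states,
        "initial_conditions": initial_conditions,
    }
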