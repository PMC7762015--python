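#!/usr/bin/env python
"""Virtual-patient trajectories for the five clusters.

Integrates each cluster from its smallest-tumor initial condition to
steady state, writes the trajectory tables, and adds the +/-10% variation
envelope over the four most sensitive parameters (the shaded-band
construction).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from colontme.dynamics import detect_steady_state, run_to_steady_state, \
    variation_envelope
from colontme.estimation import derive_parameters
from colontme.model import STATE_NAMES
from colontme.reference import CLUSTERS, initial_condition, steady_state
from colontme.sensitivity import compute_sensitivities

OUT = Path(__file__).resolve().parents[1] / "results" / "trajectories"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for k in CLUSTERS:
        ss = steady_state(k)
        params = derive_parameters(ss)
        scale = ss.as_state()
        init = initial_condition(k) * scale

        traj = run_to_steady_state(params, init, tol=1e-8, scale=scale,
                                   cluster=k)
        state, t_conv, _ = detect_steady_state(traj, params, tol=1e-8,
                                               scale=scale)
        traj.to_csv(OUT / f"cluster{k}.csv")

        result = compute_sensitivities(params, scale, qois=("cancer",))
        top4 = [name for name, _ in result.ranking("cancer")[:4]]
        env = variation_envelope(params, top4, init, fraction=0.10,
                                 t_end=traj.t[-1], scale=scale)
        band = pd.DataFrame({"time_days": env.t})
        for j, name in enumerate(STATE_NAMES):
            band[f"{name}_lower"] = env.lower[:, j]
            band[f"{name}_upper"] = env.upper[:, j]
        band.to_csv(OUT / f"cluster{k}_band.csv", index=False)

        rel_c = env.width("C")[-1] / state[STATE_NAMES.index("C")]
        summary[k] = {
            "convergence_time_days": t_conv,
            "final_cancer_density": float(state[STATE_NAMES.index("C")]),
            "top_sensitive_parameters": top4,
            "final_cancer_band_relative_width": float(rel_c),
        }
        print(f"cluster {k}: steady state at t = {t_conv:.1f} d, "
              f"C = {state[STATE_NAMES.index('C')]:.4g} cells/cm^3, "
              f"band width {100 * rel_c:.1f}% of C")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    finals = {k: v["final_cancer_density"] for k, v in summary.items()}
    print(f"smallest steady-state tumor: cluster "
          f"{min(finals, key=finals.get)}")


if __name__ == "__main__":
    main()
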