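#!/usr/bin/env python
"""Ranked steady-state sensitivities per cluster.

Relative sensitivities of cancer density, total cell density and the
minimal Jacobian eigenvalue with respect to every rate, on the
dimensionless system, with the immune-only subset (parameters outside the
cancer and necrotic equations) ranked separately.
"""

from pathlib import Path

import pandas as pd

from colontme.estimation import derive_parameters
from colontme.reference import CLUSTERS, steady_state
from colontme.sensitivity import compute_sensitivities, rank_and_partition

OUT = Path(__file__).resolve().parents[1] / "results" / "sensitivity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for k in CLUSTERS:
        ss = steady_state(k)
        params = derive_parameters(ss)
        result = compute_sensitivities(params, ss.as_state())
        rows = []
        for qoi in result.values:
            for rank, (name, value) in enumerate(result.ranking(qoi), 1):
                rows.append({"qoi": qoi, "rank": rank, "parameter": name,
                             "sensitivity": value})
            for rank, (name, value) in enumerate(
                    result.ranking(qoi, immune_only=True), 1):
                rows.append({"qoi": f"{qoi}_immune", "rank": rank,
                             "parameter": name, "sensitivity": value})
        pd.DataFrame(rows).to_csv(OUT / f"cluster{k}.csv", index=False)

        ranked = rank_and_partition(result, k=4)
        top = ", ".join(n for n, _ in ranked["cancer"]["top"])
        imm = ", ".join(n for n, _ in ranked["cancer"]["immune_top"])
        print(f"cluster {k}: cancer-density top 4: {top}")
        print(f"           immune-only top 4: {imm}")


if __name__ == "__main__":
    main()
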