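#!/usr/bin/env python
"""Reporting outputs: slope lines, GlobalT slope surfaces, representative
networks.

From the model-1 fit: the per-group within-DMN strength-vs-metric lines
(the group contrasts are slope differences between these lines).  From the
model-2 fit: the slope surfaces over a GlobalT grid, plus representative
networks at GlobalT 38 and 60 for each group (top 15% of edges by
predicted strength).

Writes results/slope_lines.tsv, results/slope_surfaces.tsv,
results/repnet_edge_counts.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import netlmm as nl

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    nodes = nl.generate_node_layout(80, 20, 160.0, seed=7)
    subjects = nl.generate_subject_table(15, seed=1)
    coh1 = nl.simulate_oracle_cohort(
        nodes, subjects, nl.default_ground_truth("model1", seed=42)
    )
    fit1 = nl.fit_lmm(nl.assemble_design_matrix(coh1.edge_table(), "model1"))
    lines = nl.slope_lines(fit1)
    lines.round(5).to_csv(RESULTS / "slope_lines.tsv", sep="\t", index=False)
    print("within-DMN strength-vs-metric slopes (model 1):")
    print(lines.round(4).to_string(index=False))

    coh2 = nl.simulate_oracle_cohort(
        nodes, subjects, nl.default_ground_truth("model2", seed=43)
    )
    table2 = coh2.edge_table()
    fit2 = nl.fit_lmm(nl.assemble_design_matrix(table2, "model2"))
    grid = np.linspace(38.0, 60.0, 12)
    rows = []
    for s in nl.slope_surfaces(fit2, grid):
        for t, v in zip(s.globalT_grid, s.slope):
            rows.append({"group": s.group, "metric": s.metric, "globalT": t,
                         "slope": v})
    pd.DataFrame(rows).round(5).to_csv(
        RESULTS / "slope_surfaces.tsv", sep="\t", index=False
    )

    counts = []
    for group in nl.cohort.GROUP_ORDER:
        for t in (38.0, 60.0):
            nodes_out, edges = nl.representative_network(
                fit2, group, t, coh2, retain_fraction=0.15, table=table2
            )
            counts.append(
                {"group": group, "globalT": t, "edges": len(edges),
                 "within_dmn_edges": int((edges["edge_class"] == "within_dmn").sum()),
                 "slope_eff": nodes_out["slope_efficiency"].iloc[0].round(4)}
            )
    pd.DataFrame(counts).to_csv(
        RESULTS / "repnet_edge_counts.tsv", sep="\t", index=False
    )
    print("\nrepresentative networks (top 15% predicted edges):")
    print(pd.DataFrame(counts).to_string(index=False))


if __name__ == "__main__":
    main()
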