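#!/usr/bin/env python
"""Summarize the small-world metrics of the simulated connectomes.

Computes nodal Onnela clustering and global efficiency per subject (these
are the frozen model covariates of the oracle cohort) and contrasts their
distributions inside versus outside the DMN block.

Writes results/metric_summary.tsv.
"""

from pathlib import Path

import pandas as pd

import netlmm as nl

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    nodes = nl.generate_node_layout(80, 20, 160.0, seed=7)
    subjects = nl.generate_subject_table(15, seed=1)
    cohort = nl.simulate_oracle_cohort(
        nodes, subjects, nl.default_ground_truth("model1", seed=42)
    )

    frames = []
    dmn_of = nodes.set_index("node_id")["dmn"]
    for sid, met in cohort.metrics.items():
        m = met.copy()
        m["dmn"] = dmn_of.reindex(m["node_id"]).to_numpy()
        frames.append(m)
    allmet = pd.concat(frames)
    summary = allmet.groupby("dmn")[["clustering", "efficiency", "degree"]].agg(
        ["mean", "std"]
    )
    summary.round(4).to_csv(RESULTS / "metric_summary.tsv", sep="\t")
    print("nodal metrics by DMN membership (all subjects pooled):")
    print(summary.round(4).to_string())
    print("\nDMN nodes sit in a denser, closer block, so both their "
          "clustering and efficiency run higher than the rest of the brain.")


if __name__ == "__main__":
    main()
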