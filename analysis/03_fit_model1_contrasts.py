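#!/usr/bin/env python
"""Primary analysis: fit model 1 and test the twelve group contrasts.

Assembles the 43-column edge design (group x metric x DMN interactions
plus confounders), fits the subject-random-intercept mixed model by REML,
and evaluates every group-vs-control slope difference within and outside
the DMN, with two-stage adaptive FDR across the twelve contrasts.  Because
the cohort is oracle-mode, the estimates can be compared against the
generative truth.

Writes results/model1_contrasts.tsv.
"""

from pathlib import Path

import netlmm as nl
from netlmm.cohort import DEFAULT_GROUP_DIFFERENCES

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    nodes = nl.generate_node_layout(80, 20, 160.0, seed=7)
    subjects = nl.generate_subject_table(15, seed=1)
    cohort = nl.simulate_oracle_cohort(
        nodes, subjects, nl.default_ground_truth("model1", seed=42)
    )
    design = nl.assemble_design_matrix(cohort.edge_table(), "model1")
    fit = nl.fit_lmm(design)
    print(f"model 1: {fit.n_rows} edge rows, {fit.n_subjects} subjects, "
          f"sigma_e={fit.sigma_e:.4f}, sigma_b={fit.sigma_b:.4f}, "
          f"converged={fit.converged}")

    coll = nl.collinearity_check(design)
    print(f"collinearity check: max |r| = {coll['r'].abs().max():.3f} "
          f"({int(coll['flagged'].sum())} pairs flagged)")

    tab = nl.contrast_table(fit, q=0.05)
    tab["truth"] = [
        DEFAULT_GROUP_DIFFERENCES[(g, m, loc if loc == "within" else "outside")]
        for g, loc, m in zip(tab["group"], tab["location"], tab["metric"])
    ]
    tab["within_2se"] = (tab["estimate"] - tab["truth"]).abs() <= 2 * tab["se"]
    tab.round(5).to_csv(RESULTS / "model1_contrasts.tsv", sep="\t", index=False)
    print(tab.round(4).to_string(index=False))
    print(f"\n{int(tab['within_2se'].sum())}/12 contrasts recovered the "
          "generative effect within 2 SE.")


if __name__ == "__main__":
    main()
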