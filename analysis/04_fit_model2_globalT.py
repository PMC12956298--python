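#!/usr/bin/env python
"""Secondary analysis: GlobalT moderation of the DMN slopes (model 2).

Fits the 79-column model adding GlobalT and all of its interactions, then
tests how the metric-slope difference of each group versus the control is
moderated by global cognitive performance, with adaptive FDR across the
twelve moderation contrasts.

Writes results/model2_moderation_contrasts.tsv.
"""

from pathlib import Path

import netlmm as nl
from netlmm.cohort import DEFAULT_GLOBALT_MODERATION

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    nodes = nl.generate_node_layout(80, 20, 160.0, seed=7)
    subjects = nl.generate_subject_table(15, seed=1)
    cohort = nl.simulate_oracle_cohort(
        nodes, subjects, nl.default_ground_truth("model2", seed=43)
    )
    design = nl.assemble_design_matrix(cohort.edge_table(), "model2")
    fit = nl.fit_lmm(design)
    print(f"model 2: {fit.n_rows} edge rows, {len(fit.params)} fixed effects, "
          f"sigma_e={fit.sigma_e:.4f}, sigma_b={fit.sigma_b:.4f}")

    tab = nl.contrast_table(fit, moderated_by_globalT=True, q=0.05)
    tab["truth"] = [
        DEFAULT_GLOBALT_MODERATION[(g, m, loc if loc == "within" else "outside")]
        for g, loc, m in zip(tab["group"], tab["location"], tab["metric"])
    ]
    tab["within_2se"] = (tab["estimate"] - tab["truth"]).abs() <= 2 * tab["se"]
    tab.round(5).to_csv(
        RESULTS / "model2_moderation_contrasts.tsv", sep="\t", index=False
    )
    print(tab.round(4).to_string(index=False))
    print(f"\n{int(tab['within_2se'].sum())}/12 moderation contrasts recovered "
          "the generative effect within 2 SE.")


if __name__ == "__main__":
    main()
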