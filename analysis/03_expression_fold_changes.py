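#!/usr/bin/env python
"""Relative expression of Dhn1/SOD/POD/CAT from the simulated CT table.

Collapses technical replicates, normalizes to alpha-tubulin, calibrates to
each genotype's well-watered control and reports 2^-ddCT fold changes,
followed by the per-gene factorial ANOVA of the fold changes.  Writes
results/simulated/fold_changes.csv and expression_anova.csv.
"""

from pathlib import Path

import pandas as pd

from droughtscreen.design_stats import anova_two_factor, format_anova
from droughtscreen.expression import relative_expression, summarize_fold_changes
from droughtscreen.io import read_table, write_table

RESULTS = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    ct_path = RESULTS / "ct_table.csv"
    if not ct_path.exists():
        raise SystemExit("run 02_simulate_trial.py first")
    ct = read_table(ct_path, "ct")
    folds = relative_expression(ct)
    write_table(folds, RESULTS / "fold_changes.csv")
    summary = summarize_fold_changes(folds)
    write_table(summary, RESULTS / "fold_change_summary.csv")

    print("fold change vs control (geometric mean over biological replicates):")
    wide = summary.pivot_table(
        index=["gene", "treatment"], columns="genotype", values="fold_change"
    ).round(2)
    print(wide.to_string())

    rows = []
    for gene, sub in folds.groupby("gene"):
        res = anova_two_factor(
            sub.rename(columns={"treatment": "stress_level", "fold_change": "value"})
        )
        print()
        print(format_anova(res, trait=f"{gene} fold change"))
        tab = res.table.reset_index(names="source")
        tab.insert(0, "gene", gene)
        tab["cv_percent"] = res.cv_percent
        rows.append(tab)
    write_table(pd.concat(rows, ignore_index=True), RESULTS / "expression_anova.csv")
    print(f"\ntables under {RESULTS}")


if __name__ == "__main__":
    main()
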