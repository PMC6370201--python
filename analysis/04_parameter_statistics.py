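#!/usr/bin/env python
"""Statistics layer over a grid run.

Reads results/grid_summary.csv and scratch/grid_per_dyad.csv (produced by
03_run_config_grid.py) and reproduces the analysis layer of the validation:
cross tables with Fisher's exact test and Cramer's V per parameter family,
an ordinal (proportional-odds) regression of the identification rate on
dummy-coded parameters, Kruskal-Wallis tests of per-sequence scores, and
the sequential good/acceptable gating across conditions.
"""

import argparse
from pathlib import Path

import pandas as pd

from dyadsync import classify_ir, sequential_selection
from dyadsync.study import PARAMETER_FAMILIES, crosstab_ir, kruskal_by_sequence, ordinal_ir_regression
from dyadsync.io import read_result_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0, help="seed for Monte-Carlo Fisher p-values")
    parser.add_argument("--condition", default="artificial")
    args = parser.parse_args()

    summary = read_result_table(ROOT / "results" / "grid_summary.csv")
    per_dyad = read_result_table(ROOT / "scratch" / "grid_per_dyad.csv")
    per_dyad["error"] = per_dyad["error"].fillna("")
    cond = summary[summary["condition"] == args.condition]
    results = ROOT / "results"

    # cross tables + Fisher + Cramer's V
    rows = []
    print(f"== parameter influence on combined IR ({args.condition} condition) ==")
    for family in PARAMETER_FAMILIES:
        if cond[family].nunique() < 2:
            continue
        res = crosstab_ir(cond, family, seed=args.seed)
        rows.append({"family": family, "fisher_p": res.fisher_p, "cramers_v": res.cramers_v})
        print(f"{family:>10}: Fisher p = {res.fisher_p:.4g}, Cramer's V = {res.cramers_v:.2f}")
        print(res.table.to_string(), "\n")
    pd.DataFrame(rows).to_csv(results / "crosstabs.csv", index=False)

    # ordinal regression of IR on dummy-coded parameters
    try:
        coef = ordinal_ir_regression(cond)
        coef.to_csv(results / "ordinal_regression.csv", index=False)
        print("== proportional-odds regression of IR (reference groups: "
              "WCLC, raw, none, 75, 0.25) ==")
        print(coef.to_string(index=False))
    except ValueError as exc:
        print(f"ordinal regression skipped: {exc}")

    # Kruskal-Wallis by sequence
    detail = per_dyad[(per_dyad["condition"] == args.condition) & (per_dyad["error"] == "")]
    print("\n== sequence effects (Kruskal-Wallis) ==")
    kw_rows = []
    for label in ("sync", "nosync"):
        h, p, _ = kruskal_by_sequence(detail, sync_label=label)
        name = "kappa" if label == "sync" else "pr_out"
        kw_rows.append({"dependent": name, "H": h, "p": p})
        print(f"{name}: H = {h:.2f}, p = {p:.3g}")
    pd.DataFrame(kw_rows).to_csv(results / "kruskal.csv", index=False)

    # sequential gating across conditions
    evaluations = {}
    for condition, group in summary.groupby("condition"):
        evaluations[condition] = {
            row["config_id"]: classify_ir(
                [row["kappa_min"], row["kappa_max"]], [row["pr_out_min"], row["pr_out_max"]]
            )
            for _, row in group.iterrows()
        }
    stages = sequential_selection(evaluations)
    print("\n== sequential selection ==")
    print(f"good IR on artificial (stage 1): {len(stages['stage1'])} configs")
    for cid in stages["stage1"]:
        print(f"  {cid}")
    print(f"good/acceptable on isolated (stage 2): {len(stages['stage2'])} configs")
    for cid in stages["stage2"]:
        print(f"  {cid}")
    print(f"good/acceptable on embedded (stage 3): {len(stages['stage3'])} configs")


if __name__ == "__main__":
    main()
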