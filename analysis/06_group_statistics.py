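#!/usr/bin/env python
"""Assumption-routed group statistics on the normalised assay outputs.

Runs the full routing (Shapiro–Wilk + Brown–Forsythe, optional log
transform, Dunnett or Conover–Iman/BH) on zeaxanthin-per-chlorophyll and
on ZEP relative expression, printing the branch taken and the starred
contrasts.
"""

import argparse
from pathlib import Path

import pandas as pd

from npqkit.stats_flow import GroupedData, route_and_test, significance_stars


def analyse(name: str, df: pd.DataFrame, value_col: str, seed: int) -> pd.DataFrame:
    d = GroupedData(values=df[value_col].to_numpy(),
                    factors=df[["accession", "treatment"]])
    route = route_and_test(d, seed=seed)
    print(f"\n== {name} ==")
    print(f"Shapiro p={route.shapiro_p:.3g}, Brown-Forsythe p="
          f"{route.brown_forsythe_p:.3g}, transform={route.transform_applied}, "
          f"branch={route.branch}")
    out = route.comparisons.copy()
    out["stars"] = out["adjusted_p"].map(significance_stars)
    print(out[["family", "contrast", "adjusted_p", "stars"]].round(4)
          .to_string(index=False))
    out.insert(0, "variable", name)
    return out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--assays", type=Path, default=Path("results/assays"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pig = pd.read_csv(args.assays / "pigments_normalized.csv")
    expr = pd.read_csv(args.assays / "relative_expression.csv")
    zep = expr[expr.target == "ZEP"]

    tables = [
        analyse("zeaxanthin_per_chl", pig, "zeaxanthin_per_chl", args.seed),
        analyse("zep_rel_expr", zep, "rel_expr", args.seed),
    ]
    pd.concat(tables, ignore_index=True).to_csv(
        args.out / "assay_contrasts.csv", index=False)
    print(f"\nWrote {args.out / 'assay_contrasts.csv'}")


if __name__ == "__main__":
    main()
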