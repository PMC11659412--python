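#!/usr/bin/env python
"""Generate the synthetic experiments every later stage analyses.

Writes, under results/data/:
  * chilling_traces.csv      — warm vs chilling night, 3 accessions x 8 discs
  * infiltration_traces.csv  — water vs DTT infiltration before a chilling night
  * ground_truth_*.csv       — the generator's per-disc true parameters
  * spectra.csv              — reflectance sweeps over de-epoxidation level
  * pigments.csv / ct.csv / metabolites.csv / calibration.csv — assay tables
"""

import argparse
from pathlib import Path

import pandas as pd

from npqkit.io import write_traces_csv
from npqkit.synthetic import (
    default_chilling_design,
    default_infiltration_design,
    simulate_assay_tables,
    simulate_plate_experiment,
    simulate_spectrum,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for name, design in (
        ("chilling", default_chilling_design(seed=args.seed)),
        ("infiltration", default_infiltration_design(seed=args.seed + 1)),
    ):
        traces, _, gt = simulate_plate_experiment(design)
        write_traces_csv(traces, out / f"{name}_traces.csv")
        gt.to_csv(out / f"ground_truth_{name}.csv", index=False)
        print(f"{name}: {len(traces)} discs across {len(design.cells)} cells")

    rows = []
    for i, level in enumerate(x / 10 for x in range(11)):
        for wl, r in simulate_spectrum(level, seed=args.seed * 100 + i):
            rows.append({"sample_id": f"sweep_{i}", "deepox_level": level,
                         "wavelength_nm": wl, "reflectance": r})
    pd.DataFrame(rows).to_csv(out / "spectra.csv", index=False)
    print(f"spectra: 11 de-epoxidation levels, {len(rows)} readings")

    for name, df in simulate_assay_tables(seed=args.seed + 2).items():
        df.to_csv(out / f"{name}.csv", index=False)
        print(f"{name}: {len(df)} rows")


if __name__ == "__main__":
    main()
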