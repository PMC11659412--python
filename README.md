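# npqkit

Analysis toolkit for chlorophyll-fluorescence quenching assays on leaf
discs, built for studying how chilling nights reprogram photoprotection in
C4 grasses (*Miscanthus* accessions of contrasting chilling tolerance),
and for anyone running plate-based PAM induction assays with warm/stress
treatment contrasts.

## The problem

Chilling slows carbon fixation, so absorbed light must be dumped as heat —
non-photochemical quenching (NPQ), measured from the drop of maximal
fluorescence under light (Stern–Volmer: NPQ = F_m/F_m′ − 1). Some
accessions accumulate zeaxanthin during the chilling *night*, leaving
quenching engaged before dawn. That sustained quenching depresses the
measured dark F_m, so both F_v/F_m = (F_m − F_o)/F_m and conventional NPQ
underestimate the true state. The adjusted quantity NPQ_A reconstructs the
unquenched maximum from warm-treated discs:

    F_m_true = F_o_cold / (1 − Fv_warm/Fm_warm)
    NPQ_A(dark) = F_m_true/F_m_cold − 1        (the sustained quenching)
    NPQ_A(t)    = F_m_true/F_m′(t) − 1

Light-phase curves are fit to a rectangular hyperbola A·t/(t + K); the
induction rate is the initial slope A/K (min⁻¹). Around this core the
package provides leaf reflectance indices (PRI/ARI/CRI) with integer-nm
binning, external-standard calibration with LOQ/LOD gating and
chlorophyll/weight normalisation, dual-reference ddCt expression, and an
assumption-routed statistics layer (Shapiro–Wilk + Brown–Forsythe →
Dunnett vs control, or Kruskal–Wallis → Conover–Iman with
Benjamini–Hochberg). A seeded synthetic-data generator gives every stage a
ground truth, so the whole pipeline is validated by parameter recovery.
See `docs/methods.md` for the model details and conventions.

## Worked example

```python
from npqkit import run_demo
bundle = run_demo(out_dir="results/demo", seed=1)
print(bundle.recovery[["accession", "treatment", "q_s_true",
                       "npq_a_dark_est", "rate_true", "npq_a"]].round(3))
```

```
  accession treatment  q_s_true  npq_a_dark_est  rate_true  npq_a
0     MsaRB     chill      0.30           0.298      2.905  2.943
1     MsaRB      warm      0.00          -0.000      1.750  1.737
2     MsiCR     chill      0.02           0.029      1.248  1.222
3     MsiCR      warm      0.00           0.000      1.750  1.729
4      MxgI     chill      0.10           0.098      1.414  1.485
5      MxgI      warm      0.00          -0.000      1.750  1.767
```

The demo simulates the default chilling experiment (three accessions ×
warm/chilling night, 8 discs per cell, 1% multiplicative noise) and runs
the full pipeline. `q_s_true` is the sustained dark quenching injected by
the generator and `npq_a_dark_est` its estimate from the NPQ_A dark point:
the high-tolerance accession's q_s = 0.30 is recovered as 0.298 while the
warm controls sit at zero. `rate_true` vs `npq_a` compares the designed
adjusted induction rate (min⁻¹) with the fitted one — under chilling the
high-tolerance accession induces quenching at ~2.9 min⁻¹, more than double
the low-tolerance accession's ~1.2 min⁻¹, while all warm cells agree at
1.75 min⁻¹. Per-flash curves, per-disc fits, group rates, routed
statistics and a reproducibility manifest are written under `out_dir`.

## Analysis scripts

The `analysis/` drivers reproduce the full study graph on synthetic
experiments and narrate what they find:

1. `01_simulate_experiments.py` — generate traces, spectra and assay tables
2. `02_quenching_pipeline.py` — NPQ/NPQ_A curves, fits, group statistics
3. `03_infiltration_rates.py` — DTT vs water relative induction rates
4. `04_reflectance_indices.py` — PRI/ARI/CRI across a de-epoxidation sweep
5. `05_assay_normalization.py` — pigments per chlorophyll, ddCt, metabolites
6. `06_group_statistics.py` — assumption-routed contrasts on assay outputs

Run them in order from the repository root; outputs land under `results/`.

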