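# Methods

## Scope and model

`npqkit` analyses pulse-amplitude-modulated (PAM) chlorophyll-fluorescence
assays on leaf discs, built around the question of how chilling nights
reprogram photoprotection in C4 grasses. A disc is dark-adapted overnight
(warm control or chilling), its minimal and maximal dark fluorescence
(F_o, F_m) measured, then exposed to 10 min of actinic light (2000
µmol m⁻² s⁻¹) followed by 10 min of darkness while saturating flashes
sample the momentary maximal fluorescence F_m′. The package computes:

* **F_v/F_m** = (F_m − F_o)/F_m, the dark-adapted maximum quantum yield of
  photosystem II;
* **NPQ**(t) = F_m/F_m′(t) − 1, Stern–Volmer non-photochemical quenching;
* **NPQ_A**, quenching adjusted for dark-sustained quenching. Chilling can
  leave zeaxanthin-dependent quenching engaged at the end of the night,
  depressing the measured dark F_m and making both F_v/F_m and NPQ
  underestimates. The unquenched maximum is reconstructed from warm-treated
  (unstressed) discs:

      F_m_true = F_o_cold / (1 − Fv_warm/Fm_warm)
      NPQ_A at the dark point = F_m_true / F_m_cold − 1
      NPQ_A at light points   = F_m_true / F_m′ − 1

  The published transcription of the dark-point formula is typographically
  garbled (an unbalanced parenthesis; read literally it does not vanish when
  the warm and cold yields agree). The implemented form is the one forced by
  the stated purpose — the reconstructed F_m_true is the cold disc's F_o
  divided by the warm non-photochemical fraction — and by the companion
  relation F_m_true = F_m_cold·(NPQ_A_dark + 1). The literal transcription
  is retained behind `literal=True` (with a warning) for audit.

  Two exact identities pin the implementation down: NPQ_A ≡ NPQ whenever
  the warm reference equals the cold disc's own yield, and
  (NPQ_A + 1) = (NPQ + 1)(NPQ_A_dark + 1) at every flash.

* **Induction kinetics.** Light-phase curves are fit by least squares to the
  rectangular hyperbola NPQ(t) = A·t/(t + K) (amplitude A, half-saturation
  time K in minutes), and the *induction rate* is the initial slope A/K
  (min⁻¹). The primary sources cite a companion method for the hyperbola
  without printing it; the rectangular form is the simplest two-parameter
  hyperbola consistent with a "rate of kinetics", and both A and A/K are
  exported so either convention can be compared downstream. Because an
  NPQ_A curve rides on its dark point while the through-origin hyperbola
  models only the light-driven rise, the curve's own dark point is
  subtracted before fitting an NPQ_A curve. This is not an approximation:
  the induced component of NPQ_A equals (1 + NPQ_A_dark)·NPQ exactly, which
  is itself a rectangular hyperbola, so the subtraction recovers the
  generative amplitude and half-time without bias.

## Conventions and numerical choices

* **Phase labelling.** The light phase is the half-open interval
  [light-on, light-off); a flash at exactly t = 10 min belongs to the dark
  phase. The two built-in flash schedules (`cf_imager`, `fluorcam`) then
  contain 12 and 13 light-phase flashes respectively.
* **Negative NPQ** (F_m′ > F_m, common at the first flash under noise) is
  retained, not clipped — clipping would bias slope fits low — but each
  occurrence raises a warning and the pipeline counts them in its manifest.
* **Hyperbola fitting.** Initialisation A₀ = max(NPQ), K₀ = time to half
  maximum by linear interpolation; bounds A ∈ [0, 3·max], K ∈ [0.01, 100]
  min; `scipy.optimize.curve_fit`. A curve with no positive value returns a
  degenerate fit with amplitude 0 (induction rate 0) instead of an
  optimiser run; fewer than 4 usable points is an error.
* **Warm-reference pooling.** By default the warm reference is the mean
  F_v/F_m of all warm-treated discs of the same accession in the
  experiment; a single pooled reference is available. Note that a shared
  reference correlates the NPQ_A values of discs that use it, which mildly
  inflates the apparent precision of between-group contrasts on NPQ_A when
  effects are truly null — visible in the type-I checks, and intrinsic to
  the method rather than to this implementation.
* **Relative rates** under chemical infiltration are reported as the
  retained fraction, 100·treated/control (so 76% means the reductant left
  three-quarters of the control rate), with a percent-change variant behind
  a flag.
* **Trace CSV round-trip** is bit-exact: the reader uses round-trip float
  parsing, so written and re-read tables carry identical doubles.

## Reflectance

Sub-nanometre reflectance readings are converted to integer nanometres by
truncation toward zero ("converted to integers"; nearest-integer rounding
is available, the difference being sub-noise for smooth leaf spectra) and
averaged within each bin. Indices, computed per measurement and only then
averaged across replicates:

    PRI = (R531 − R570)/(R531 + R570)
    ARI = R800/R550 − 1/R700        (as printed by the source protocol)
    CRI = 1/R510 − 1/R550

The printed ARI mixes a ratio with a reciprocal; the common literature form
R800·(1/R550 − 1/R700) is available via `canonical=True` rather than
guessing the intent.

## Calibrated assays

External-standard calibration fits an ordinary least-squares line (fitted
intercept by default; through-origin behind a flag) and inverts it to
concentrations. Validated lower limits of quantification/detection:
21 µg/ml for lutein, antheraxanthin and zeaxanthin; 20 µg/ml for
violaxanthin; 35 and 25 µg/ml for chlorophyll a and b. Sub-limit values
are flagged but retained — dark-night zeaxanthin means sit below the LOQ
and censoring them would discard the signal of interest. Pigments are
normalised to total chlorophyll (a + b) as a mass ratio; the
xanthophyll-cycle pool V + A + Z is always recomputed from components.
Metabolite amounts are the calibrated concentration scaled by the 50-µl
extract volume and divided by tissue weight (per mg). Relative transcript
abundance uses the ddCt method with amplification efficiency fixed at 2 and
ΔCt referenced to the arithmetic mean of the Ubiquitin and EF1α Cts (for
two references at efficiency 2 this coincides with geometric-mean
normalisation at the expression level).

## Statistics

Routing mirrors the experimental design (accessions compared against a
low-tolerance control accession; treatments against the warm control):
Shapiro–Wilk on saturated-model residuals and Brown–Forsythe
(median-centred Levene) across cells; on failure of either at α = 0.05 a
natural-log transform is attempted (positive data only) and the checks
repeated; if assumptions still fail, the branch is nonparametric. The
parametric branch runs a factorial ANOVA omnibus and Dunnett many-to-one
comparisons (scipy's multivariate-t implementation, seeded; the
single-comparison case is computed analytically as the pooled two-sample
t-test, to which Dunnett reduces exactly). The nonparametric branch runs
Kruskal–Wallis and Conover–Iman rank comparisons (pooled-rank variance
shrunk by the Kruskal–Wallis H, t reference on N − k df) with
Benjamini–Hochberg adjustment; two-group families fall back to the
Wilcoxon rank-sum test. Each many-to-one set sharing a control is treated
as one correction family, matching the two separately-starred families in
the source figures. Adjusted p-values are floored at their unadjusted
values. Constant data route nonparametric and degenerate rank tests raise
rather than fabricate p-values.

## Synthetic data

Generators are pure functions of (parameters, seed) and emit the same CSV
dialects the readers consume. A trace is generated by inverting the
quenching equations: total quenching q_s + A·t/(t+K) in the light,
exponential relaxation of the induced part toward q_s in the dark
(calibrated so `relaxation_fraction`, default 0.8, has relaxed by the last
flash), F_m′ = F_m_unquenched/(1 + NPQ_total), observed dark
F_m = F_m_unquenched/(1 + q_s). Noise is multiplicative log-normal with
unit mean (fluorescence is positive and detector noise roughly
proportional), default CV 1%. By default F_o is left unquenched, the
configuration under which the NPQ_A dark point recovers q_s exactly at
zero noise; a `cold_fvfm_target` knob rescales F_o instead, to probe the
estimator's sensitivity to F_o quenching, which real leaves may exhibit
and the adjustment cannot distinguish.

The default plate designs fix the study conditions once: three accessions
(high/moderate/low chilling tolerance), 8 replicate discs per cell,
unstressed F_v/F_m = 0.8, F_m_unquenched = 3000 a.u. After a chilling
night the high-tolerance accession carries q_s = 0.30 (moderate 0.10, low
0.02) and an adjusted induction rate of 2.905 min⁻¹ — 66% above its own
warm control (1.75 min⁻¹) and 133% above the low-tolerance accession
(1.247 min⁻¹). The infiltration design scales amplitudes so DTT retains
76%/50%/23% of the water-control rate in the high/moderate/low accessions.
Assay tables encode a 3-fold high:low zeaxanthin ratio under chilling,
ZEP transcriptional upregulation (2.5-fold) in the moderate- and
low-tolerance accessions only, and a 3-fold dehydroascorbate rise in the
high-tolerance accession; Ct tables are produced by inverting the ddCt
relation, calibration tables are exact lines so zero assay noise implies
exact recovery.

What the generator does *not* emulate: photoinhibition (q_s is stationary
within a trace), F_o quenching by default, temperature drift during the
20-min equilibration of chilled plates (metadata only, no correction),
flash-induced actinic effects, plate-position effects, and any mechanistic
VDE/ZEP enzyme kinetics. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated observation model, not
robustness to these real-data complications.

## Problem sizes

Default runs use 8 discs per cell (48–72 traces per experiment), 50 discs
per level in sustained-quenching recovery (4 levels), 100 curves for
slope-bias estimates, 1000 simulated experiments for the family-wise
error check, and 11-level reflectance sweeps at 0.3-nm resolution. These
sizes keep every stage's Monte-Carlo error well below the effects being
measured while completing in seconds.

## Known limitations

* The hyperbola convention (rectangular, rate = A/K) cannot be verified
  against the uncited companion equation; both A and A/K are exported.
* Dunnett p-values for k ≥ 2 comparisons come from stochastic
  multivariate-t integration (seeded, reproducible; tolerance ~±0.002).
* The dark-relaxation phase is stored and simulated but not fitted — no
  relaxation parameter is part of the analysis surface.
* Below-LOQ handling is flag-and-retain only; censored estimators are out
  of scope.
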