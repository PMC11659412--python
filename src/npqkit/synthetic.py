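"""Seeded generators of synthetic PAM traces, spectra, and assay tables.

Every generator is a pure function of (parameters, seed) and emits the
same formats the readers consume, so each analysis stage can be scored
against known ground truth (parameter recovery) without external data.

Observation model for a trace (inverting the quenching equations):

    NPQ_total(t in light) = q_s + A * t / (t + K)
    F_m'(t)               = F_m_unquenched / (1 + NPQ_total(t))
    dark F_m (observed)   = F_m_unquenched / (1 + q_s)

where ``q_s`` is the sustained quenching retained through the chilling
night. By default F_o is left unquenched, so the drop in dark F_m (and
hence in apparent F_v/F_m) is attributable entirely to sustained
quenching — the premise the adjusted-NPQ estimator is built on, under
which its dark point recovers q_s exactly at zero noise. The optional
``cold_fvfm_target`` knob instead rescales F_o to hit a chosen cold
yield, to probe the estimator's sensitivity to F_o quenching.

During the dark phase the light-induced component relaxes exponentially
toward q_s; ``relaxation_fraction`` is the fraction relaxed by the end of
the dark phase. Noise is multiplicative log-normal (fluorescence is
positive; detector noise roughly scales with signal) with unit mean.

The default plate design mirrors the source study's effect structure for
three accessions of contrasting chilling tolerance: after a chilling
night the high-tolerance accession carries q_s = 0.30 and an adjusted
induction rate 133% above the low-tolerance control, the within-accession
chilling-vs-warm rate gain for the high-tolerance accession is 66%, and
reductant (DTT) infiltration retains 76% / 23% of the water-control rate
in the high-/low-tolerance accessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fluor_core import (
    PROTOCOLS,
    DarkYields,
    FlashProtocol,
    FlashRecord,
    FluorescenceTrace,
)

__all__ = [
    "TraceGroundTruth",
    "CellParams",
    "ExperimentDesign",
    "default_chilling_design",
    "default_infiltration_design",
    "simulate_trace",
    "simulate_plate_experiment",
    "simulate_spectrum",
    "simulate_assay_tables",
]

ACCESSIONS = ("MsaRB", "MxgI", "MsiCR")  # high / moderate / low chilling tolerance


@dataclass(frozen=True)
class TraceGroundTruth:
    """True parameters behind one simulated disc."""

    f_o_true: float = 600.0
    f_m_unquenched: float = 3000.0
    q_s: float = 0.0                  # sustained dark quenching
    amplitude: float = 2.0            # light-induced NPQ asymptote A
    half_time: float = 1.0            # K, minutes
    relaxation_fraction: float = 0.8  # induced NPQ relaxed by end of dark phase
    noise_cv: float = 0.01
    f_s_fraction: float = 0.6         # F_s emitted as this fraction of F_m' (provenance only)
    cold_fvfm_target: float | None = None

    def __post_init__(self) -> None:
        if self.q_s < 0:
            raise ValueError("q_s must be >= 0")
        if not (0 < self.f_o_true < self.f_m_unquenched):
            raise ValueError("need 0 < f_o_true < f_m_unquenched")

    @property
    def dark_f_m(self) -> float:
        return self.f_m_unquenched / (1.0 + self.q_s)

    @property
    def dark_f_o(self) -> float:
        if self.cold_fvfm_target is not None:
            return self.dark_f_m * (1.0 - self.cold_fvfm_target)
        return self.f_o_true

    @property
    def induction_rate(self) -> float:
        return self.amplitude / self.half_time


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative log-normal noise with relative SD ``cv``."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _npq_total(gt: TraceGroundTruth, t: float, protocol: FlashProtocol) -> float:
    if protocol.phase_of(t) == "light":
        tl = t - protocol.light_on_min
        return gt.q_s + gt.amplitude * tl / (tl + gt.half_time)
    t_end = protocol.light_off_min - protocol.light_on_min
    npq_end = gt.amplitude * t_end / (t_end + gt.half_time)
    dark_len = max(protocol.flash_times_min[-1] - protocol.light_off_min, 1e-9)
    frac = min(gt.relaxation_fraction, 1.0 - 1e-12)
    # exponential decay calibrated so `relaxation_fraction` of the induced
    # component is gone by the final flash of the dark phase
    rate = -math.log(1.0 - frac) / dark_len
    return gt.q_s + npq_end * math.exp(-rate * (t - protocol.light_off_min))


def simulate_trace(
    gt: TraceGroundTruth,
    protocol: FlashProtocol,
    seed: int | np.random.Generator,
    disc_id: str = "disc",
    metadata: dict | None = None,
) -> FluorescenceTrace:
    """One disc's PAM trace under the observation model above."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_o = gt.dark_f_o * float(_lognormal_factor(rng, gt.noise_cv))
    f_m = gt.dark_f_m * float(_lognormal_factor(rng, gt.noise_cv))
    f_m = max(f_m, f_o * (1.0 + 1e-6))  # physical constraint F_m > F_o
    flashes = []
    for t in protocol.flash_times_min:
        fmp = gt.f_m_unquenched / (1.0 + _npq_total(gt, t, protocol))
        fmp *= float(_lognormal_factor(rng, gt.noise_cv))
        flashes.append(FlashRecord(time_min=t, f_s=gt.f_s_fraction * fmp, f_m_prime=fmp))
    return FluorescenceTrace(
        disc_id=disc_id,
        dark=DarkYields(f_o=f_o, f_m=f_m),
        flashes=tuple(flashes),
        protocol=protocol,
        metadata=dict(metadata or {}),
    )


@dataclass(frozen=True)
class CellParams:
    """Ground-truth quenching parameters of one accession x treatment cell."""

    q_s: float
    amplitude: float
    half_time: float

    @property
    def induction_rate(self) -> float:
        return self.amplitude / self.half_time


@dataclass(frozen=True)
class ExperimentDesign:
    """A plate experiment: per-cell ground truth plus replication and noise."""

    cells: dict[tuple[str, str], CellParams]
    seed: int
    replicates: int = 8
    noise_cv: float = 0.01
    protocol: str = "cf_imager"
    f_m_unquenched: float = 3000.0
    unstressed_fvfm: float = 0.8
    relaxation_fraction: float = 0.8
    accession_sd: float = 0.0   # between-disc variation of q_s and A (relative)

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("design has no cells")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def default_chilling_design(seed: int, replicates: int = 8,
                            noise_cv: float = 0.01) -> ExperimentDesign:
    """Warm vs chilling night for three accessions (field-assay analogue).

    Warm-night kinetics are common to all accessions (A = 2.1, K = 1.2,
    rate 1.75 min^-1, q_s = 0). Chilling-night cells encode the headline
    contrasts: the high-tolerance accession reaches rate 2.905 (a 66%
    within-accession gain and 133% above the low-tolerance accession's
    1.247) with q_s = 0.30; the moderate accession sits between.
    """
    warm = CellParams(q_s=0.0, amplitude=2.1, half_time=1.2)
    cells = {
        ("MsaRB", "warm"): warm,
        ("MxgI", "warm"): warm,
        ("MsiCR", "warm"): warm,
        ("MsaRB", "chill"): CellParams(q_s=0.30, amplitude=2.324, half_time=0.8),
        ("MxgI", "chill"): CellParams(q_s=0.10, amplitude=1.414, half_time=1.0),
        ("MsiCR", "chill"): CellParams(q_s=0.02, amplitude=1.497, half_time=1.2),
    }
    return ExperimentDesign(cells=cells, seed=seed, replicates=replicates,
                            noise_cv=noise_cv)


def default_infiltration_design(seed: int, replicates: int = 8,
                                noise_cv: float = 0.01) -> ExperimentDesign:
    """Chilling night with water vs DTT infiltration.

    DTT scales the light-induced amplitude so the retained adjusted
    induction rate is 76% (high tolerance), 50% (moderate) and 23% (low
    tolerance) of the water control.
    """
    base = default_chilling_design(seed, replicates, noise_cv)
    retained = {"MsaRB": 0.76, "MxgI": 0.50, "MsiCR": 0.23}
    cells = {}
    for acc in ACCESSIONS:
        chill = base.cells[(acc, "chill")]
        cells[(acc, "chill+water")] = chill
        cells[(acc, "chill+DTT")] = replace(
            chill, amplitude=chill.amplitude * retained[acc])
        cells[(acc, "warm")] = base.cells[(acc, "warm")]
    return ExperimentDesign(cells=cells, seed=seed, replicates=replicates,
                            noise_cv=noise_cv)


def simulate_plate_experiment(
    design: ExperimentDesign,
) -> tuple[list[FluorescenceTrace], pd.DataFrame, pd.DataFrame]:
    """All discs of a design: traces, tidy metadata, and a ground-truth table."""
    protocol = PROTOCOLS[design.protocol]
    root = np.random.SeedSequence(design.seed)
    cell_keys = sorted(design.cells)
    seeds = root.spawn(len(cell_keys) * design.replicates)
    f_o_true = design.f_m_unquenched * (1.0 - design.unstressed_fvfm)

    traces, meta_rows, gt_rows = [], [], []
    wells = _well_names()
    idx = 0
    for (acc, trt) in cell_keys:
        cp = design.cells[(acc, trt)]
        for rep in range(1, design.replicates + 1):
            rng = np.random.default_rng(seeds[idx])
            q_s, amp = cp.q_s, cp.amplitude
            if design.accession_sd > 0:
                q_s = max(q_s * float(_lognormal_factor(rng, design.accession_sd)), 0.0)
                amp = amp * float(_lognormal_factor(rng, design.accession_sd))
            gt = TraceGroundTruth(
                f_o_true=f_o_true,
                f_m_unquenched=design.f_m_unquenched,
                q_s=q_s,
                amplitude=amp,
                half_time=cp.half_time,
                relaxation_fraction=design.relaxation_fraction,
                noise_cv=design.noise_cv,
            )
            disc_id = f"{acc}_{trt}_r{rep}"
            well = wells[idx % len(wells)]
            meta = {"accession": acc, "treatment": trt, "replicate": rep,
                    "well": well}
            traces.append(simulate_trace(gt, protocol, rng, disc_id=disc_id,
                                         metadata=meta))
            meta_rows.append({"disc_id": disc_id, **meta})
            gt_rows.append({
                "disc_id": disc_id, "accession": acc, "treatment": trt,
                "replicate": rep, "q_s": gt.q_s, "amplitude": gt.amplitude,
                "half_time": gt.half_time,
                "induction_rate": gt.induction_rate,
            })
            idx += 1
    return traces, pd.DataFrame(meta_rows), pd.DataFrame(gt_rows)


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def simulate_spectrum(
    deepox_level: float,
    seed: int | np.random.Generator,
    noise_sd: float = 0.002,
    step_nm: float = 0.3,
) -> list[tuple[float, float]]:
    """Sub-nm leaf reflectance, 400-900 nm, with a 531-nm de-epoxidation dip.

    The baseline is a smooth green-leaf shape (green bump at 550 nm, red
    edge near 715 nm, NIR plateau). Xanthophyll de-epoxidation depresses
    the 531-nm region in proportion to ``deepox_level`` in [0, 1], which
    is what makes PRI decrease with de-epoxidation.
    """
    if not 0.0 <= deepox_level <= 1.0:
        raise ValueError("deepox_level must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wl = np.arange(400.0, 900.0 + 1e-9, step_nm)
    base = 0.05 + 0.45 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    green = 0.06 * np.exp(-((wl - 550.0) ** 2) / (2.0 * 30.0**2))
    dip = 0.03 * deepox_level * np.exp(-((wl - 531.0) ** 2) / (2.0 * 8.0**2))
    refl = base + green - dip
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=wl.shape)
    refl = np.clip(refl, 1e-4, None)
    return list(zip(wl.tolist(), refl.tolist()))


@dataclass(frozen=True)
class AssayEffects:
    """Designed group effects for the pigment / transcript / metabolite tables.

    Fold changes are chilling-night vs warm-night within accession; the
    zeaxanthin ratio is high- vs low-tolerance accession under chilling.
    """

    zeaxanthin_warm: float = 1.0           # µg/ml extract, sub-LOQ baseline
    zeaxanthin_chill: dict[str, float] = field(
        default_factory=lambda: {"MsaRB": 9.0, "MxgI": 5.0, "MsiCR": 3.0})
    violaxanthin_mean: float = 30.0
    antheraxanthin_mean: float = 4.0
    lutein_mean: float = 40.0
    chlorophyll_a_mean: float = 80.0
    chlorophyll_b_mean: float = 30.0
    zep_fold_chill: dict[str, float] = field(
        default_factory=lambda: {"MsaRB": 1.0, "MxgI": 2.5, "MsiCR": 2.5})
    vde_fold_chill: float = 1.0
    psbs_fold_chill: float = 0.5
    ascorbate_warm: float = 0.40           # units per mg tissue
    dha_warm: float = 0.10
    dha_fold_chill: dict[str, float] = field(
        default_factory=lambda: {"MsaRB": 3.0, "MxgI": 1.5, "MsiCR": 1.0})
    noise_cv: float = 0.15
    ct_noise_sd: float = 0.15


def simulate_assay_tables(
    seed: int,
    replicates: int = 7,
    effects: AssayEffects | None = None,
    accessions: tuple[str, ...] = ACCESSIONS,
    treatments: tuple[str, ...] = ("warm", "chill"),
) -> dict[str, pd.DataFrame]:
    """Pigment, qPCR-Ct, metabolite, and calibration tables with known effects.

    Ct tables are generated by inverting the ddCt relation from the designed
    fold changes (references at Ct 20 and 22); pigment and metabolite
    replicates carry log-normal noise; calibration points are exact lines
    (slope 1000 area units per µg/ml through the origin) so zero assay
    noise means exact recovery.
    """
    eff = effects or AssayEffects()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pig_rows = []
    for acc in accessions:
        for trt in treatments:
            zea = eff.zeaxanthin_chill[acc] if trt != "warm" else eff.zeaxanthin_warm
            means = {
                "zeaxanthin": zea,
                "antheraxanthin": eff.antheraxanthin_mean,
                "violaxanthin": eff.violaxanthin_mean - zea,  # pool conserved
                "lutein": eff.lutein_mean,
                "chlorophyll_a": eff.chlorophyll_a_mean,
                "chlorophyll_b": eff.chlorophyll_b_mean,
            }
            for rep in range(1, replicates + 1):
                row = {"sample_id": f"{acc}_{trt}_r{rep}", "accession": acc,
                       "treatment": trt, "replicate": rep}
                for analyte, mu in means.items():
                    row[analyte] = mu * float(_lognormal_factor(rng, eff.noise_cv))
                pig_rows.append(row)

    ct_rows = []
    fold_by_gene = {
        "ZEP": lambda acc: eff.zep_fold_chill[acc],
        "VDE": lambda acc: eff.vde_fold_chill,
        "PsbS": lambda acc: eff.psbs_fold_chill,
    }
    base_dct = 3.0  # target sits 3 cycles above the reference mean in warm controls
    for gene, fold_of in fold_by_gene.items():
        for acc in accessions:
            for trt in treatments:
                fold = fold_of(acc) if trt != "warm" else 1.0
                dct = base_dct - math.log2(fold)
                for rep in range(1, replicates + 1):
                    ct_ref1 = 20.0 + rng.normal(0, eff.ct_noise_sd)
                    ct_ref2 = 22.0 + rng.normal(0, eff.ct_noise_sd)
                    ct_target = 0.5 * (ct_ref1 + ct_ref2) + dct + rng.normal(
                        0, eff.ct_noise_sd)
                    ct_rows.append({
                        "sample_id": f"{acc}_{trt}_r{rep}", "accession": acc,
                        "treatment": trt, "replicate": rep, "target": gene,
                        "ct_target": ct_target, "ct_ref1": ct_ref1,
                        "ct_ref2": ct_ref2,
                    })

    cal_slope, extract_ml = 1000.0, 0.05
    met_rows = []
    for acc in accessions:
        for trt in treatments:
            means = {
                "ascorbate": eff.ascorbate_warm,
                "dehydroascorbate": eff.dha_warm * (
                    eff.dha_fold_chill[acc] if trt != "warm" else 1.0),
            }
            for rep in range(1, replicates + 1):
                weight = float(rng.uniform(20.0, 30.0))
                for analyte, per_mg in means.items():
                    amount = per_mg * float(_lognormal_factor(rng, eff.noise_cv))
                    conc = amount * weight / extract_ml  # units per ml extract
                    met_rows.append({
                        "sample_id": f"{acc}_{trt}_r{rep}", "accession": acc,
                        "treatment": trt, "replicate": rep, "analyte": analyte,
                        "peak_area": cal_slope * conc,
                        "sample_weight_mg": weight,
                        "true_amount_per_mg": amount,
                    })

    cal_rows = []
    for analyte in ("zeaxanthin", "antheraxanthin", "violaxanthin", "lutein",
                    "chlorophyll_a", "chlorophyll_b", "ascorbate",
                    "dehydroascorbate"):
        for conc in (0.0, 5.0, 10.0, 25.0, 50.0, 100.0):
            cal_rows.append({"analyte": analyte, "concentration": conc,
                             "response": cal_slope * conc})

    return {
        "pigments": pd.DataFrame(pig_rows),
        "ct": pd.DataFrame(ct_rows),
        "metabolites": pd.DataFrame(met_rows),
        "calibration": pd.DataFrame(cal_rows),
    }
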