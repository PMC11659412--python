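"""Calibrated quantification assays and their normalisations.

Covers three assay families that share an external-standard workflow:

* HPLC xanthophyll-cycle pigments — a linear calibration (peak area vs
  concentration) per analyte, limit-of-quantification/detection gating at
  the instrument's validated limits, and normalisation to total chlorophyll
  (a + b) to absorb extraction variation;
* LC-MS metabolites (ascorbate / dehydroascorbate) — the same calibration
  op plus normalisation by tissue weight in a fixed 50 µl extract;
* RT-qPCR transcripts — relative expression by the ddCt method against the
  mean of two reference genes (Ubiquitin and EF1a), amplification
  efficiency fixed at 2.

Below-LOQ concentrations are flagged but retained: group means of
low-abundance pigments (dark zeaxanthin) are reported, not censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import NormalizationError

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "PigmentRecord",
    "CtRecord",
    "MetaboliteRecord",
    "DEFAULT_LIMITS",
    "fit_calibration",
    "quantify",
    "normalize_to_chlorophyll",
    "relative_expression",
    "normalize_metabolite",
]

# Validated lower limits of quantification/detection, µg/ml (single printed
# limit serves as both LOQ and LOD for each compound).
DEFAULT_LIMITS: dict[str, tuple[float, float]] = {
    "lutein": (21.0, 21.0),
    "antheraxanthin": (21.0, 21.0),
    "zeaxanthin": (21.0, 21.0),
    "violaxanthin": (20.0, 20.0),
    "chlorophyll_a": (35.0, 35.0),
    "chlorophyll_b": (25.0, 25.0),
}

PIGMENTS = ("zeaxanthin", "antheraxanthin", "violaxanthin", "lutein")
XANTHOPHYLL_CYCLE = ("violaxanthin", "antheraxanthin", "zeaxanthin")


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary least-squares line response = slope*conc + intercept."""

    analyte: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    loq: float
    lod: float


@dataclass(frozen=True)
class QuantResult:
    concentration: float
    below_loq: bool
    below_lod: bool


@dataclass(frozen=True)
class PigmentRecord:
    """Per-sample pigment concentrations (µg/ml extract) with LOQ flags.

    After :func:`normalize_to_chlorophyll`, ``normalized`` holds each
    pigment as a mass ratio to total chlorophyll (a + b). The xanthophyll-
    cycle pool V + A + Z is always computed from components, never stored
    independently.
    """

    sample_id: str
    concentrations: dict[str, float]        # pigment -> µg/ml
    chlorophyll_a: float
    chlorophyll_b: float
    flags: dict[str, QuantResult] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def xanthophyll_pool(self) -> float:
        return sum(self.concentrations.get(p, 0.0) for p in XANTHOPHYLL_CYCLE)

    @property
    def normalized_pool(self) -> float:
        return sum(self.normalized.get(p, 0.0) for p in XANTHOPHYLL_CYCLE)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement with two reference-gene Cts."""

    sample_id: str
    target: str
    ct_target: float
    ct_ref1: float  # Ubiquitin
    ct_ref2: float  # EF1a

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_ref1", self.ct_ref1),
                         ("ct_ref2", self.ct_ref2)):
            if not np.isfinite(ct):
                raise ValueError(f"{self.sample_id}/{self.target}: {name} is not finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - 0.5 * (self.ct_ref1 + self.ct_ref2)


@dataclass(frozen=True)
class MetaboliteRecord:
    sample_id: str
    analyte: str           # "ascorbate" | "dehydroascorbate"
    peak_area: float
    sample_weight_mg: float

    def __post_init__(self) -> None:
        if not self.sample_weight_mg > 0:
            raise ValueError(f"{self.sample_id}: sample weight must be positive")


def fit_calibration(
    points: list[tuple[float, float]],
    loq: float | None = None,
    lod: float | None = None,
    analyte: str = "",
    through_origin: bool = False,
) -> CalibrationCurve:
    """Fit an external-standard line to (concentration, response) pairs.

    The intercept is fitted by default; ``through_origin=True`` forces it to
    zero. When LOQ/LOD are not supplied they fall back to the validated
    defaults for the named analyte (0 if unknown).
    """
    pts = [(float(c), float(r)) for c, r in points]
    conc = np.array([c for c, _ in pts])
    resp = np.array([r for _, r in pts])
    if len(np.unique(conc)) < 2:
        raise NormalizationError(
            f"calibration for {analyte or '<analyte>'}: need >= 2 distinct "
            "concentrations"
        )
    if through_origin:
        slope = float(np.sum(conc * resp) / np.sum(conc**2))
        intercept = 0.0
        pred = slope * conc
        ss_res = float(np.sum((resp - pred) ** 2))
        ss_tot = float(np.sum((resp - resp.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = sps.linregress(conc, resp)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2
    if slope <= 0:
        raise NormalizationError(f"calibration for {analyte}: non-positive slope")
    default_loq, default_lod = DEFAULT_LIMITS.get(analyte, (0.0, 0.0))
    loq = default_loq if loq is None else float(loq)
    lod = default_lod if lod is None else float(lod)
    if not loq >= lod >= 0:
        raise ValueError(f"require loq >= lod >= 0, got loq={loq}, lod={lod}")
    return CalibrationCurve(analyte=analyte, points=tuple(pts), slope=slope,
                            intercept=intercept, r_squared=r2, loq=loq, lod=lod)


def quantify(curve: CalibrationCurve, response: float) -> QuantResult:
    """Invert the calibration line; flag (never null) sub-limit values.

    Negative back-calculated concentrations clip to 0 with a below-LOD flag.
    """
    conc = (float(response) - curve.intercept) / curve.slope
    if conc <= 0:
        return QuantResult(concentration=0.0, below_loq=True, below_lod=True)
    return QuantResult(
        concentration=conc,
        below_loq=conc < curve.loq,
        below_lod=conc < curve.lod,
    )


def normalize_to_chlorophyll(rec: PigmentRecord) -> PigmentRecord:
    """Divide every pigment by total chlorophyll (a + b), a mass ratio."""
    chl = rec.chlorophyll_a + rec.chlorophyll_b
    if chl <= 0:
        raise NormalizationError(
            f"{rec.sample_id}: total chlorophyll must be positive to normalize"
        )
    normalized = {p: c / chl for p, c in rec.concentrations.items()}
    return replace(rec, normalized=normalized)


def relative_expression(rec: CtRecord, calibrator: CtRecord,
                        reference_scale: str = "ct_mean") -> float:
    """ddCt relative expression, 2^-(dCt_sample - dCt_calibrator).

    dCt is the target Ct minus the mean of the two reference-gene Cts
    (``reference_scale="ct_mean"``, default). The alternative
    ``"geometric"`` normalises at the expression level by the geometric
    mean of the two references — identical for two references with
    efficiency 2, kept as an explicit flag for clarity.
    """
    if rec.target != calibrator.target:
        raise ValueError(
            f"records target different genes: {rec.target!r} vs {calibrator.target!r}"
        )
    if reference_scale not in ("ct_mean", "geometric"):
        raise ValueError(f"unknown reference_scale {reference_scale!r}")
    # With two references and efficiency 2, the geometric-mean-of-expression
    # normaliser equals 2^-mean(Ct_refs): the two scales coincide.
    return float(2.0 ** -(rec.delta_ct - calibrator.delta_ct))


def normalize_metabolite(
    rec: MetaboliteRecord,
    curve: CalibrationCurve,
    extract_volume_ul: float = 50.0,
) -> tuple[float, QuantResult]:
    """Amount of metabolite per mg tissue from a peak area.

    The calibrated concentration (per ml of the final extract) is scaled by
    the extract volume (default 50 µl) and divided by the tissue weight.
    Returns (amount_per_mg, quantification flags).
    """
    q = quantify(curve, rec.peak_area)
    amount = q.concentration * (extract_volume_ul / 1000.0) / rec.sample_weight_mg
    return amount, q
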