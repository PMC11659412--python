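"""Adjusted NPQ (NPQ_A): correcting F_m underestimated by dark-sustained quenching.

After a chilling night, quenching that persists through the dark period
(zeaxanthin-dependent sustained quenching) depresses the measured dark F_m,
so conventional NPQ — referenced to that F_m — understates the true
quenching. The adjustment reconstructs the unquenched maximal fluorescence
from warm-treated discs of the same material:

    F_m_true = F_o_cold / (1 - Fv_warm/Fm_warm)
    NPQ_A at the dark point  = F_m_true / F_m_cold - 1
    NPQ_A at light points    = F_m_true / F_m'    - 1

When the cold disc's yield equals the warm reference, F_m_true = F_m_cold
and NPQ_A reduces to NPQ exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import fmean

from .errors import LiteralFormulaWarning, MissingReferenceError
from .fluor_core import (
    DarkYields,
    FluorescenceTrace,
    NPQPoint,
    compute_fvfm,
)

__all__ = [
    "WarmReference",
    "NPQACurve",
    "npq_a_dark_point",
    "f_m_true",
    "npq_a_curve",
    "pool_warm_reference",
]


@dataclass(frozen=True)
class WarmReference:
    """Pooled F_v/F_m of warm-treated (unstressed) discs."""

    fvfm_warm: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.fvfm_warm < 1):
            raise ValueError(f"fvfm_warm must lie in (0, 1), got {self.fvfm_warm}")


@dataclass(frozen=True)
class NPQACurve:
    """Adjusted quenching for one disc.

    ``npq_a_dark`` is the sustained quenching present before light-on
    (the t=0 value of the adjusted induction curve under one convention;
    the first-flash point is the other — both are exported downstream).
    """

    disc_id: str
    npq_a_dark: float
    f_m_true: float
    points: tuple[NPQPoint, ...]
    warm_ref_fvfm: float
    light_on_min: float = 0.0

    def times(self) -> list[float]:
        return [p.time_min for p in self.points]

    def values(self) -> list[float]:
        return [p.npq for p in self.points]

    def light_points(self) -> list[NPQPoint]:
        return [p for p in self.points if p.phase == "light"]


def npq_a_dark_point(dark_cold: DarkYields, ref: WarmReference,
                     literal: bool = False) -> float:
    """Sustained quenching of a cold disc relative to the warm reference.

    Equals ``F_m_true / F_m_cold - 1`` with
    ``F_m_true = F_o_cold / (1 - fvfm_warm)``; equivalently
    ``(1 - fvfm_cold) / (1 - fvfm_warm) - 1``. Zero when warm and cold
    yields agree.

    ``literal=True`` evaluates the published transcription of the formula
    verbatim for audit. That transcription is internally inconsistent (it
    returns r/(1-r) instead of 0 when warm = cold), so a warning is issued.
    """
    fvfm_warm = ref.fvfm_warm
    if fvfm_warm >= 1.0:
        raise ZeroDivisionError(
            f"warm reference {ref.source or '<unnamed>'} has F_v/F_m = 1; "
            "unquenched F_m would be infinite"
        )
    fvfm_cold = compute_fvfm(dark_cold)
    if literal:
        warnings.warn(
            "evaluating the literal dark-point transcription; it does not "
            "vanish when warm and cold yields are equal",
            LiteralFormulaWarning,
            stacklevel=2,
        )
        numer = dark_cold.f_o * fvfm_warm / (1.0 - dark_cold.f_o / dark_cold.f_m)
        denom = dark_cold.f_o * (1.0 - fvfm_warm)
        return numer / denom - 1.0
    return (1.0 - fvfm_cold) / (1.0 - fvfm_warm) - 1.0


def f_m_true(dark_cold: DarkYields, npq_a_dark: float) -> float:
    """Reconstructed unquenched maximal fluorescence, F_m_cold * (NPQ_A_dark + 1)."""
    if npq_a_dark < -1:
        raise ValueError(f"npq_a_dark must be >= -1, got {npq_a_dark}")
    return dark_cold.f_m * (npq_a_dark + 1.0)


def npq_a_curve(trace: FluorescenceTrace, ref: WarmReference,
                literal: bool = False) -> NPQACurve:
    """Adjusted quenching at every flash of a trace.

    Satisfies the exact identity ``npq_a + 1 = (npq + 1) * (npq_a_dark + 1)``
    at each flash, and reduces pointwise to the unadjusted curve when the
    warm reference equals the cold disc's own yield.
    """
    qs = npq_a_dark_point(trace.dark, ref, literal=literal)
    fm_true = f_m_true(trace.dark, qs)
    points = tuple(
        NPQPoint(
            time_min=fl.time_min,
            npq=fm_true / fl.f_m_prime - 1.0,
            phase=trace.protocol.phase_of(fl.time_min),
        )
        for fl in trace.flashes
    )
    return NPQACurve(
        disc_id=trace.disc_id,
        npq_a_dark=qs,
        f_m_true=fm_true,
        points=points,
        warm_ref_fvfm=ref.fvfm_warm,
        light_on_min=trace.protocol.light_on_min,
    )


def pool_warm_reference(
    traces: list[FluorescenceTrace],
    warm_label: str = "warm",
    by_accession: bool = True,
) -> dict[str, WarmReference] | WarmReference:
    """Build warm references by pooling F_v/F_m over warm-treated discs.

    Default policy: mean F_v/F_m of all warm-treated discs of the same
    accession (the source material pools warm samples without specifying a
    pairing). With ``by_accession=False`` a single pooled reference is
    returned. Treatment labels starting with ``warm_label`` count as warm,
    so infiltration variants such as ``"warm+DTT"`` pool with their own kind
    only when labelled identically.
    """
    warm = [t for t in traces if str(t.metadata.get("treatment", "")) == warm_label]
    if not warm:
        raise MissingReferenceError(
            f"no discs with treatment {warm_label!r}; cannot build a warm reference"
        )
    if not by_accession:
        vals = [compute_fvfm(t.dark) for t in warm]
        return WarmReference(fvfm_warm=fmean(vals),
                             source=f"pooled {len(vals)} warm discs")
    refs: dict[str, WarmReference] = {}
    accessions = {str(t.metadata.get("accession", "")) for t in warm}
    for acc in sorted(accessions):
        vals = [compute_fvfm(t.dark) for t in warm
                if str(t.metadata.get("accession", "")) == acc]
        refs[acc] = WarmReference(
            fvfm_warm=fmean(vals),
            source=f"accession {acc}: {len(vals)} warm discs",
        )
    return refs
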