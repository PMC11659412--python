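"""Data model for pulse-amplitude-modulated (PAM) leaf-disc assays.

A leaf disc is dark-adapted overnight, its minimal (F_o) and maximal (F_m)
dark fluorescence are measured, and the disc is then exposed to 10 min of
actinic light followed by 10 min of darkness while saturating flashes record
the momentary maximal fluorescence F_m'. Non-photochemical quenching is
quantified under the Stern–Volmer model as

    NPQ(t) = F_m / F_m'(t) - 1

and the dark-adapted maximum quantum yield of photosystem II as

    F_v/F_m = (F_m - F_o) / F_m.

Steady-state fluorescence F_s is stored for provenance but enters no
computed quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import InvalidMeasurementError, NegativeNPQWarning

__all__ = [
    "FlashProtocol",
    "DarkYields",
    "FlashRecord",
    "FluorescenceTrace",
    "NPQPoint",
    "NPQCurve",
    "CF_IMAGER",
    "FLUORCAM",
    "PROTOCOLS",
    "compute_fvfm",
    "compute_npq_curve",
]


@dataclass(frozen=True)
class FlashProtocol:
    """Timing and intensity of a saturating-flash schedule.

    Times are minutes relative to actinic light-on. The light phase is the
    half-open interval [light_on_min, light_off_min): a flash at exactly
    light-off belongs to the dark phase.
    """

    label: str
    flash_times_min: tuple[float, ...]
    light_on_min: float = 0.0
    light_off_min: float = 10.0
    actinic_ppfd: float = 2000.0
    flash_ppfd: float = 3200.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.flash_times_min)
        object.__setattr__(self, "flash_times_min", times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"flash times of {self.label!r} must be strictly increasing")
        if not self.light_off_min > self.light_on_min:
            raise ValueError("light_off_min must exceed light_on_min")

    def phase_of(self, time_min: float) -> str:
        """Classify a flash time as ``"light"`` or ``"dark"``."""
        return "light" if self.light_on_min <= time_min < self.light_off_min else "dark"

    def light_times(self) -> tuple[float, ...]:
        return tuple(t for t in self.flash_times_min if self.phase_of(t) == "light")


# Built-in presets: the two imaging instruments' printed flash schedules.
CF_IMAGER = FlashProtocol(
    label="cf_imager",
    flash_times_min=(0, 0.33, 0.67, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                     10.33, 10.67, 11, 12, 13, 16, 19, 22),
    actinic_ppfd=2000.0,
    flash_ppfd=6000.0,
)
FLUORCAM = FlashProtocol(
    label="fluorcam",
    flash_times_min=(0, 0.263, 0.413, 0.747, 1.08, 2.08, 3.08, 4.08, 5.08,
                     6.08, 7.08, 8.08, 9.08, 10.08, 10.263, 10.413, 10.913,
                     11.913, 15.08, 20.08),
    actinic_ppfd=2000.0,
    flash_ppfd=3200.0,
)
PROTOCOLS: dict[str, FlashProtocol] = {p.label: p for p in (CF_IMAGER, FLUORCAM)}


@dataclass(frozen=True)
class DarkYields:
    """Dark-adapted minimal and maximal fluorescence of one disc (a.u.)."""

    f_o: float
    f_m: float

    def __post_init__(self) -> None:
        if not (self.f_m > self.f_o > 0):
            raise InvalidMeasurementError(
                f"dark yields require f_m > f_o > 0, got f_o={self.f_o}, f_m={self.f_m}"
            )

    @property
    def f_v(self) -> float:
        return self.f_m - self.f_o

    @property
    def fvfm(self) -> float:
        return compute_fvfm(self)


@dataclass(frozen=True)
class FlashRecord:
    """One saturating flash: time plus steady-state and maximal fluorescence."""

    time_min: float
    f_s: float
    f_m_prime: float


@dataclass(frozen=True)
class FluorescenceTrace:
    """One leaf disc's full PAM record.

    ``metadata`` carries accession / treatment / replicate labels (and any
    bookkeeping such as plate well or equilibration notes); it never feeds
    a computation.
    """

    disc_id: str
    dark: DarkYields
    flashes: tuple[FlashRecord, ...]
    protocol: FlashProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flashes", tuple(self.flashes))
        allowed = set(self.protocol.flash_times_min)
        for fl in self.flashes:
            if fl.f_m_prime <= 0:
                raise InvalidMeasurementError(
                    f"disc {self.disc_id}: f_m_prime must be positive at t={fl.time_min}"
                )
            if fl.time_min not in allowed and not any(
                math.isclose(fl.time_min, t, abs_tol=1e-9) for t in allowed
            ):
                raise InvalidMeasurementError(
                    f"disc {self.disc_id}: flash time {fl.time_min} not in protocol "
                    f"{self.protocol.label!r}"
                )


@dataclass(frozen=True)
class NPQPoint:
    time_min: float
    npq: float
    phase: str  # "light" | "dark"


@dataclass(frozen=True)
class NPQCurve:
    """Per-flash Stern–Volmer quenching values for one disc."""

    disc_id: str
    points: tuple[NPQPoint, ...]
    light_on_min: float = 0.0

    def times(self) -> list[float]:
        return [p.time_min for p in self.points]

    def values(self) -> list[float]:
        return [p.npq for p in self.points]

    def light_points(self) -> list[NPQPoint]:
        return [p for p in self.points if p.phase == "light"]


def compute_fvfm(dark: DarkYields) -> float:
    """Maximum quantum yield of PSII, (F_m - F_o)/F_m, in (0, 1)."""
    return (dark.f_m - dark.f_o) / dark.f_m


def compute_npq_curve(trace: FluorescenceTrace) -> NPQCurve:
    """Stern–Volmer NPQ = F_m/F_m' - 1 at every flash of a trace.

    F_m' > F_m yields a negative NPQ; such values are retained (clipping
    would bias downstream slope fits) but a :class:`NegativeNPQWarning`
    is emitted.
    """
    points = []
    for fl in trace.flashes:
        if fl.f_m_prime > trace.dark.f_m:
            warnings.warn(
                f"disc {trace.disc_id}: F_m'={fl.f_m_prime} exceeds dark F_m="
                f"{trace.dark.f_m} at t={fl.time_min} min (negative NPQ retained)",
                NegativeNPQWarning,
                stacklevel=2,
            )
        points.append(
            NPQPoint(
                time_min=fl.time_min,
                npq=trace.dark.f_m / fl.f_m_prime - 1.0,
                phase=trace.protocol.phase_of(fl.time_min),
            )
        )
    return NPQCurve(disc_id=trace.disc_id, points=tuple(points),
                    light_on_min=trace.protocol.light_on_min)
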