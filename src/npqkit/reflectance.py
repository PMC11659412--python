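"""Leaf reflectance spectra: integer-nm binning and pigment indices.

Spectrometers report reflectance at sub-nanometre resolution; readings are
binned to integer nanometres (wavelength truncated toward zero, readings in
the same bin averaged) before indices are computed:

    PRI = (R531 - R570) / (R531 + R570)   photochemical reflectance index,
                                          decreases with xanthophyll
                                          de-epoxidation
    ARI = R800/R550 - 1/R700              anthocyanin reflectance index,
                                          as printed by the source protocol
    CRI = 1/R510 - 1/R550                 carotenoid reflectance index

The printed ARI mixes a ratio term with a reciprocal term; the more common
literature form R800*(1/R550 - 1/R700) is available via ``canonical=True``
without guessing which was intended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import MissingBandError

__all__ = ["ReflectanceSpectrum", "bin_spectrum", "pri", "ari", "cri", "index_table"]

INDEX_BANDS_NM = (510, 531, 550, 570, 700, 800)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Integer-nm binned reflectance with index accessors."""

    bins: dict[int, float]
    source_resolution: float = 1.0
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def band(self, nm: int) -> float:
        if nm not in self.bins:
            raise MissingBandError(nm)
        r = self.bins[nm]
        if not (r > 0 and math.isfinite(r)):
            raise ValueError(f"band {nm} nm has non-positive reflectance {r}")
        return r

    @property
    def pri(self) -> float:
        return pri(self)

    @property
    def ari(self) -> float:
        return ari(self)

    @property
    def cri(self) -> float:
        return cri(self)


def bin_spectrum(
    samples: list[tuple[float, float]],
    method: str = "truncate",
    sample_id: str = "",
    metadata: dict | None = None,
) -> ReflectanceSpectrum:
    """Assign sub-nm readings to integer-nm bins and average within bins.

    ``method="truncate"`` (default) truncates the wavelength toward zero,
    so 530.9 nm lands in bin 530; ``method="round"`` uses nearest-integer
    rounding. For smooth leaf spectra the difference is below measurement
    noise.
    """
    if not samples:
        raise ValueError("cannot bin an empty spectrum")
    if method == "truncate":
        key = lambda wl: int(wl)  # int() truncates toward zero
    elif method == "round":
        key = lambda wl: int(round(wl))
    else:
        raise ValueError(f"unknown binning method {method!r}")

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    resolutions = []
    prev_wl = None
    for wl, r in samples:
        if not (math.isfinite(wl) and math.isfinite(r)):
            raise ValueError(f"non-finite spectrum sample ({wl}, {r})")
        b = key(wl)
        sums[b] = sums.get(b, 0.0) + r
        counts[b] = counts.get(b, 0) + 1
        if prev_wl is not None:
            resolutions.append(abs(wl - prev_wl))
        prev_wl = wl
    bins = {b: sums[b] / counts[b] for b in sums}
    res = min(resolutions) if resolutions else 1.0
    return ReflectanceSpectrum(bins=bins, source_resolution=res,
                               sample_id=sample_id, metadata=metadata or {})


def pri(s: ReflectanceSpectrum) -> float:
    """Photochemical reflectance index, (R531 - R570)/(R531 + R570), in [-1, 1]."""
    r531, r570 = s.band(531), s.band(570)
    return (r531 - r570) / (r531 + r570)


def ari(s: ReflectanceSpectrum, canonical: bool = False) -> float:
    """Anthocyanin reflectance index.

    Default follows the source protocol verbatim: R800/R550 - 1/R700.
    ``canonical=True`` computes the common literature form
    R800 * (1/R550 - 1/R700).
    """
    r550, r700, r800 = s.band(550), s.band(700), s.band(800)
    if canonical:
        return r800 * (1.0 / r550 - 1.0 / r700)
    return r800 / r550 - 1.0 / r700


def cri(s: ReflectanceSpectrum) -> float:
    """Carotenoid reflectance index, 1/R510 - 1/R550."""
    return 1.0 / s.band(510) - 1.0 / s.band(550)


def index_table(spectra: list[ReflectanceSpectrum]) -> pd.DataFrame:
    """Per-sample index table; indices are computed per measurement and only
    then averaged across replicates by the caller (never indices of an
    averaged spectrum)."""
    rows = []
    for s in spectra:
        rows.append({
            "sample_id": s.sample_id,
            "pri": pri(s),
            "ari": ari(s),
            "cri": cri(s),
            "ambient_ppfd": s.metadata.get("ambient_ppfd"),
            **{k: v for k, v in s.metadata.items() if k != "ambient_ppfd"},
        })
    return pd.DataFrame(rows)
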