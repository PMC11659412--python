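"""Long-format CSV input/output for PAM traces and plate layouts.

One trace occupies one dark row (``f_o``/``f_m`` filled, ``time_min`` empty)
plus one row per saturating flash (``time_min``/``f_s``/``f_m_prime`` filled).
Floats survive the round trip bit-exactly (pandas writes full ``repr``
precision by default).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .fluor_core import (
    PROTOCOLS,
    DarkYields,
    FlashProtocol,
    FlashRecord,
    FluorescenceTrace,
)

__all__ = ["write_traces_csv", "read_traces_csv", "read_plate_layout"]

TRACE_COLUMNS = [
    "disc_id", "accession", "treatment", "replicate", "protocol",
    "time_min", "f_s", "f_m_prime", "f_o", "f_m",
]

_META_KEYS = ("accession", "treatment", "replicate")


def write_traces_csv(traces: list[FluorescenceTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        meta = {k: tr.metadata.get(k, "") for k in _META_KEYS}
        base = {"disc_id": tr.disc_id, "protocol": tr.protocol.label, **meta}
        rows.append({**base, "time_min": None, "f_s": None, "f_m_prime": None,
                     "f_o": tr.dark.f_o, "f_m": tr.dark.f_m})
        for fl in tr.flashes:
            rows.append({**base, "time_min": fl.time_min, "f_s": fl.f_s,
                         "f_m_prime": fl.f_m_prime, "f_o": None, "f_m": None})
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces_csv(
    path: str | Path,
    protocols: dict[str, FlashProtocol] | None = None,
) -> list[FluorescenceTrace]:
    """Parse a long-format trace table back into :class:`FluorescenceTrace`s.

    Raises :class:`SchemaError` naming the offending column or disc when the
    table is malformed.
    """
    protocols = protocols if protocols is not None else PROTOCOLS
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table {path} lacks column(s): {', '.join(missing)}")

    traces = []
    for disc_id, sub in df.groupby("disc_id", sort=False):
        dark_rows = sub[sub["time_min"].isna()]
        if len(dark_rows) != 1:
            raise SchemaError(f"disc {disc_id}: expected exactly one dark row, "
                              f"found {len(dark_rows)}")
        dark_row = dark_rows.iloc[0]
        proto_name = str(dark_row["protocol"])
        if proto_name not in protocols:
            raise SchemaError(f"disc {disc_id}: unknown protocol {proto_name!r}")
        flash_rows = sub[sub["time_min"].notna()].sort_values("time_min")
        meta = {k: _clean_meta(dark_row[k]) for k in _META_KEYS}
        traces.append(
            FluorescenceTrace(
                disc_id=str(disc_id),
                dark=DarkYields(f_o=float(dark_row["f_o"]), f_m=float(dark_row["f_m"])),
                flashes=tuple(
                    FlashRecord(time_min=float(r.time_min), f_s=float(r.f_s),
                                f_m_prime=float(r.f_m_prime))
                    for r in flash_rows.itertuples()
                ),
                protocol=protocols[proto_name],
                metadata={k: v for k, v in meta.items() if v is not None},
            )
        )
    return traces


_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


def read_plate_layout(path: str | Path) -> dict[str, dict]:
    """Map 96-well positions (A1–H12) to accession/treatment/replicate labels."""
    df = pd.read_csv(path)
    if "well" not in df.columns:
        raise SchemaError(f"plate layout {path} lacks column 'well'")
    layout: dict[str, dict] = {}
    for i, row in df.iterrows():
        well = str(row["well"]).strip()
        if not _WELL_RE.match(well):
            raise SchemaError(f"plate layout row {i}: invalid well {well!r}")
        layout[well] = {k: _clean_meta(row[k]) for k in _META_KEYS if k in df.columns}
    return layout


def _clean_meta(value):
    if pd.isna(value) or value == "":
        return None
    # replicate numbers come back from CSV as floats
    if isinstance(value, float) and value.is_integer():
        return int(value)
    return value
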