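"""Thin read-only adapter for FCS 3.0/3.1 list-mode files.

Only what the pipeline needs: the TEXT segment is parsed for ``$PnN``
parameter names, and the DATA segment decoded for ``$DATATYPE`` F
(float32), D (float64) or I (fixed-width unsigned int) in list mode.
Channel names are mapped to the logical fsc/ssc/fl columns via a plain
``{logical: $PnN}`` dictionary.  FCS writing is out of scope.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .events import EVENT_COLUMNS, EventMeta, EventTable, EventTableError


class FcsFormatError(EventTableError):
    """Raised for files that are not decodable FCS 3.x list-mode data."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    # Escaped (doubled) delimiters inside values are not supported; no
    # Accuri-class instrument emits them for the keys used here.
    parts = raw[1:].split(delim)
    fields = [p.decode("utf-8", errors="replace") for p in parts if p != b""]
    kv: dict[str, str] = {}
    for key, value in zip(fields[::2], fields[1::2]):
        kv[key.strip().upper()] = value.strip()
    return kv


def read_fcs(
    path: str | Path,
    channel_names: Mapping[str, str],
    meta: EventMeta | None = None,
) -> EventTable:
    """Read an FCS file into an :class:`EventTable`.

    Parameters
    ----------
    path:
        FCS 3.0 or 3.1 file.
    channel_names:
        Mapping from logical channel (``fsc_h``, ``ssc_h``, ``fl1`` ...
        ``fl4``) to the instrument's ``$PnN`` parameter name
        (e.g. ``{"fsc_h": "FSC-H", ...}``).
    meta:
        Acquisition metadata; defaults applied if omitted.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FcsFormatError(f"{path}: too short to be an FCS file")
    version = blob[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise FcsFormatError(f"{path}: malformed header offsets") from exc
    kv = _parse_text_segment(blob[text_start : text_end + 1])

    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    datatype = kv["$DATATYPE"].upper()
    mode = kv.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode supported, got $MODE={mode}")
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    data_start = int(kv.get("$BEGINDATA") or int(blob[26:34]))
    data_end = int(kv.get("$ENDDATA") or int(blob[34:42]))
    raw = blob[data_start : data_end + 1]

    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(kv.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)]

    if datatype == "F":
        arr = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=f"{order}f4")
        matrix = arr.reshape(n_tot, n_par).astype(float)
    elif datatype == "D":
        arr = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=f"{order}f8")
        matrix = arr.reshape(n_tot, n_par).astype(float)
    elif datatype == "I":
        widths = [b // 8 for b in bits]
        if any(b % 8 for b in bits):
            raise FcsFormatError(f"{path}: non-byte-aligned integer widths")
        row_size = sum(widths)
        matrix = np.empty((n_tot, n_par), dtype=float)
        fmt_for = {1: "B", 2: "H", 4: "I", 8: "Q"}
        for j, w in enumerate(widths):
            if w not in fmt_for:
                raise FcsFormatError(f"{path}: unsupported $PnB={bits[j]}")
        for row in range(n_tot):
            off = row * row_size
            col_off = 0
            for j, w in enumerate(widths):
                (val,) = struct.unpack_from(
                    order + fmt_for[w], raw, off + col_off
                )
                matrix[row, j] = float(val)
                col_off += w
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE={datatype}")

    frame = pd.DataFrame(matrix, columns=names)
    missing = [n for n in channel_names.values() if n not in frame.columns]
    if missing:
        raise FcsFormatError(f"{path}: FCS parameters not found: {missing}")
    df = pd.DataFrame(
        {logical: frame[pn].to_numpy() for logical, pn in channel_names.items()}
    )
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    if meta is None:
        meta = EventMeta(sample_id=path.stem)
    return EventTable(df, meta)
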