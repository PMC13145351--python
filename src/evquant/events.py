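"""Per-event flow cytometry data model and columnar text I/O.

The canonical on-disk format is a CSV file with a commented metadata
header (lines of the form ``# key: value``) followed by one row per
event.  Intensities stay on the instrument's linear arbitrary-unit
scale; no transformation is applied at I/O time.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical event columns, in on-disk order
EVENT_COLUMNS = ("fsc_h", "ssc_h", "fl1", "fl2", "fl3", "fl4")

DEFAULT_TRIGGER_FSC_H = 500.0
DEFAULT_TRIGGER_SSC_H = 1000.0


class EventTableError(ValueError):
    """Raised for malformed event tables or files."""


class MissingColumnError(EventTableError):
    """A mapped channel column is absent from the input."""


class EmptyTableError(EventTableError):
    """The input file contains no event rows."""


@dataclass(frozen=True)
class ChannelMap:
    """Maps logical channel names to column identifiers.

    One logical channel maps to exactly one column.  ``wavelengths``
    optionally records (excitation, emission) metadata per fluorescence
    channel.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in EVENT_COLUMNS}
    )
    wavelengths: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fl1": (488.0, 533.0),
            "fl2": (488.0, 585.0),
            "fl3": (488.0, 670.0),
            "fl4": (640.0, 675.0),
        }
    )

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.columns]
        if missing:
            raise EventTableError(f"channel map lacks logical channels: {missing}")
        targets = list(self.columns.values())
        if len(set(targets)) != len(targets):
            raise EventTableError("channel map is not one-to-one")

    def rename_to_logical(self, df: pd.DataFrame) -> pd.DataFrame:
        """Return ``df`` restricted to mapped columns, renamed to logical names."""
        for logical, col in self.columns.items():
            if col not in df.columns:
                raise MissingColumnError(
                    f"column {col!r} (logical channel {logical!r}) not found"
                )
        out = df[[self.columns[c] for c in EVENT_COLUMNS]].copy()
        out.columns = list(EVENT_COLUMNS)
        return out


@dataclass
class EventMeta:
    """Acquisition metadata carried alongside the event matrix."""

    sample_id: str = "unnamed"
    analyzed_volume_ul: float = 20.0
    trigger_fsc_h: float = DEFAULT_TRIGGER_FSC_H
    trigger_ssc_h: float = DEFAULT_TRIGGER_SSC_H
    dilution_chain_ref: str | None = None
    condition_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.analyzed_volume_ul > 0):
            raise EventTableError("analyzed_volume_ul must be > 0")
        self.condition_tags = frozenset(self.condition_tags)


class EventTable:
    """Immutable table of flow events plus acquisition metadata.

    Invariants enforced at construction:

    * all intensities are finite and >= 0;
    * every retained event satisfies the acquisition-trigger contract
      ``fsc_h >= trigger_fsc_h OR ssc_h >= trigger_ssc_h``
      (violating rows are dropped, and the count recorded in
      ``n_dropped_trigger``).
    """

    def __init__(self, data: pd.DataFrame, meta: EventMeta | None = None):
        meta = meta if meta is not None else EventMeta()
        df = pd.DataFrame(data).reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumnError(f"event table lacks columns: {missing}")
        df = df[list(EVENT_COLUMNS)].astype(float)
        values = df.to_numpy()
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise EventTableError("intensities must be finite and >= 0")
        keep = (df["fsc_h"] >= meta.trigger_fsc_h) | (df["ssc_h"] >= meta.trigger_ssc_h)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "sample %s: dropped %d/%d events below acquisition trigger",
                meta.sample_id, n_dropped, len(df),
            )
        self._df = df.loc[keep].reset_index(drop=True)
        self.meta = meta
        self.n_dropped_trigger = n_dropped

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self._df.equals(other._df) and self.meta == other.meta

    @property
    def df(self) -> pd.DataFrame:
        """The event matrix (copy; columns in canonical order)."""
        return self._df.copy()

    def channel(self, name: str) -> np.ndarray:
        if name not in EVENT_COLUMNS:
            raise MissingColumnError(f"unknown channel {name!r}")
        return self._df[name].to_numpy()

    def with_meta(self, **kwargs) -> "EventTable":
        return EventTable(self._df, replace(self.meta, **kwargs))


def _meta_to_header(meta: EventMeta) -> list[str]:
    lines = [
        f"# sample_id: {meta.sample_id}",
        f"# analyzed_volume_ul: {meta.analyzed_volume_ul!r}",
        f"# trigger_fsc_h: {meta.trigger_fsc_h!r}",
        f"# trigger_ssc_h: {meta.trigger_ssc_h!r}",
    ]
    if meta.dilution_chain_ref is not None:
        lines.append(f"# dilution_chain_ref: {meta.dilution_chain_ref}")
    if meta.condition_tags:
        lines.append(f"# condition_tags: {','.join(sorted(meta.condition_tags))}")
    return lines


def _meta_from_header(lines: Iterable[str]) -> EventMeta:
    kv: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            kv[key.strip()] = value.strip()
    kwargs: dict = {}
    if "sample_id" in kv:
        kwargs["sample_id"] = kv["sample_id"]
    for key in ("analyzed_volume_ul", "trigger_fsc_h", "trigger_ssc_h"):
        if key in kv:
            kwargs[key] = float(kv[key])
    if "dilution_chain_ref" in kv:
        kwargs["dilution_chain_ref"] = kv["dilution_chain_ref"]
    if "condition_tags" in kv:
        kwargs["condition_tags"] = frozenset(
            t for t in kv["condition_tags"].split(",") if t
        )
    return EventMeta(**kwargs)


def write_events(table: EventTable, path: str | Path) -> Path:
    """Write an EventTable to columnar text with a ``# key: value`` header.

    The float formatting uses Python's shortest round-trip repr, so
    ``read_events(write_events(t)) == t`` holds exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in _meta_to_header(table.meta):
            fh.write(line + "\n")
        fh.write(",".join(EVENT_COLUMNS) + "\n")
        for row in table.df.itertuples(index=False):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_events(
    path: str | Path,
    channel_map: ChannelMap | None = None,
    meta: EventMeta | None = None,
) -> EventTable:
    """Read an event table from columnar text (CSV with ``#`` header).

    ``meta`` overrides any metadata found in the file header.  Events
    violating the acquisition-trigger contract are dropped with a
    logged count (mirroring instrument behaviour), never errored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                header_lines.append(line)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise EmptyTableError(f"{path} contains no event data") from None
    if meta is None:
        meta = _meta_from_header(header_lines)
    cmap = channel_map if channel_map is not None else ChannelMap()
    try:
        df = cmap.rename_to_logical(df)
    except MissingColumnError as exc:
        raise MissingColumnError(f"{path}: {exc}") from None
    return EventTable(df, meta)
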