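"""Delimited-text I/O for spike-time, trace-metadata and behavior tables.

Canonical formats (TSV or CSV, header row, UTF-8, '.' decimal):

* spike file — long format, one spike per row: ``trace_id, spike_time_s``
  (or ``spike_time_ms``, converted on read; seconds is the default unit);
* trace metadata — one row per trace:
  ``trace_id, genotype, cell_type, group_role, duration_s``;
* behavior file — one row per animal:
  ``animal_id, genotype, assay, value[, onset_time_s]`` where an empty
  ``onset_time_s`` means right-censored.

Ingestion is tolerant (rows may arrive unsorted, assay labels are
case-folded, duplicate spike times collapse with a warning); output is
strict (sorted, validated, 12-significant-digit floats so tables round-trip).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import ASSAYS, BehavioralRecord, SpikeTrain
from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "read_spike_trains",
    "read_behavior",
    "read_table",
    "write_table",
    "DEFAULT_DURATION_S",
]

#: recording length assumed when no metadata table is supplied
DEFAULT_DURATION_S = 180.0

_FLOAT_FORMAT = "%.12g"


def _sep_for(path: Union[str, Path]) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_frame(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _parse_float_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    raw = df[col].to_numpy()
    out = np.empty(raw.shape, dtype=float)
    for i, cell in enumerate(raw):
        try:
            out[i] = float(cell)
        except ValueError:
            # +2: one for the header row, one for 1-based numbering
            raise ParseError(
                f"{path}, line {i + 2}: cannot parse {col}={cell!r} as a number"
            ) from None
    return out


def read_spike_trains(
    path: Union[str, Path],
    metadata_path: Union[str, Path, None] = None,
    *,
    default_duration_s: float = DEFAULT_DURATION_S,
) -> List[SpikeTrain]:
    """Read a long-format spike file (plus optional trace-metadata table).

    One :class:`SpikeTrain` is returned per distinct ``trace_id``, spikes
    sorted ascending; exact duplicate times within a trace are collapsed to
    one with a warning.  A ``spike_time_ms`` column is accepted in place of
    ``spike_time_s`` and converted.  Traces listed in the metadata table but
    absent from the spike file become zero-spike trains (a silent recording
    is still a trace).
    """
    path = Path(path)
    df = _read_frame(path, ["trace_id"])
    if "spike_time_s" in df.columns:
        times = _parse_float_column(df, "spike_time_s", path)
    elif "spike_time_ms" in df.columns:
        times = _parse_float_column(df, "spike_time_ms", path) / 1000.0
    else:
        raise FormatError(f"{path}: missing required column 'spike_time_s'")
    bad = np.flatnonzero(times < 0)
    if bad.size:
        raise ParseError(f"{path}, line {bad[0] + 2}: negative spike time {times[bad[0]]}")

    meta: Dict[str, dict] = {}
    if metadata_path is not None:
        mdf = _read_frame(
            metadata_path, ["trace_id", "genotype", "cell_type", "group_role", "duration_s"]
        )
        durations = _parse_float_column(mdf, "duration_s", Path(metadata_path))
        for row, dur in zip(mdf.itertuples(index=False), durations):
            meta[row.trace_id] = {
                "genotype": row.genotype,
                "cell_type": row.cell_type,
                "group_role": row.group_role,
                "duration_s": float(dur),
            }

    trains: List[SpikeTrain] = []
    grouped: Dict[str, np.ndarray] = {
        tid: times[(df["trace_id"] == tid).to_numpy()] for tid in df["trace_id"].unique()
    }
    trace_ids = list(grouped)
    for tid in meta:  # metadata-only traces: no spikes observed
        if tid not in grouped:
            trace_ids.append(tid)
            grouped[tid] = np.empty(0)
    for tid in trace_ids:
        spikes = np.sort(grouped[tid])
        uniq = np.unique(spikes)
        if uniq.size < spikes.size:
            warnings.warn(
                f"trace {tid!r}: collapsed {spikes.size - uniq.size} duplicate spike time(s)",
                stacklevel=2,
            )
            spikes = uniq
        info = meta.get(tid, {})
        duration = info.get("duration_s", default_duration_s)
        if spikes.size and spikes[-1] > duration:
            raise ValidationError(
                f"trace {tid!r}: spike at {spikes[-1]} s beyond duration {duration} s"
            )
        trains.append(
            SpikeTrain(
                trace_id=tid,
                spikes=spikes,
                duration_s=duration,
                genotype=info.get("genotype", ""),
                cell_type=info.get("cell_type", ""),
                group_role=info.get("group_role", "control"),
            )
        )
    return trains


def read_behavior(path: Union[str, Path]) -> List[BehavioralRecord]:
    """Read a behavior table into validated :class:`BehavioralRecord` rows.

    Assay labels are case-folded; unknown assays and negative values raise.
    """
    path = Path(path)
    df = _read_frame(path, ["animal_id", "genotype", "assay", "value"])
    values = _parse_float_column(df, "value", path)
    has_onset = "onset_time_s" in df.columns
    records: List[BehavioralRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        assay = str(row.assay).strip().casefold()
        if assay not in ASSAYS:
            raise ValidationError(
                f"{path}, line {i + 2}: unknown assay {row.assay!r}; "
                f"allowed: {', '.join(ASSAYS)}"
            )
        onset: Optional[float] = None
        if has_onset:
            cell = str(row.onset_time_s).strip()
            if cell not in ("", "NA", "nan"):
                try:
                    onset = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {i + 2}: cannot parse onset_time_s={cell!r}"
                    ) from None
        try:
            records.append(
                BehavioralRecord(
                    animal_id=str(row.animal_id),
                    genotype=str(row.genotype),
                    assay=assay,
                    value=float(values[i]),
                    onset_time_s=onset,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {i + 2}: {exc}") from None
    return records


def write_table(rows: Union[pd.DataFrame, Sequence[dict]], path: Union[str, Path]) -> None:
    """Write a homogeneous table as TSV (or CSV by extension) with header.

    Floats are rendered with 12 significant digits so write → read
    round-trips numerically; an empty table writes a header-only file.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` with type inference."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep=_sep_for(path))
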