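"""Reading and writing pupil traces and event tables.

A pupil trace is a uniformly sampled time series of pupil size, either in
millimetres of diameter or in the device's arbitrary area units, with a
per-sample validity flag (``False`` marks a missing sample, e.g. during an
eye blink when the tracker loses the pupil).  Files are plain delimited text
(tab or comma) with a header row; see :func:`read_trace` / :func:`write_trace`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PupilTrace",
    "EventTable",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "area_to_diameter",
]

#: Tolerance (s) on the deviation of successive time steps from 1/rate.
TIME_TOLERANCE = 1e-6

#: Physically plausible upper bound on human pupil diameter (mm).
MAX_DIAMETER_MM = 12.0


class TraceFormatError(ValueError):
    """Raised when a trace file violates the expected tabular format."""


@dataclass
class PupilTrace:
    """Uniformly sampled pupil time series.

    Attributes
    ----------
    time : np.ndarray
        Sample times in seconds, strictly increasing, uniform step 1/rate.
    pupil : np.ndarray
        Pupil size per sample; mm diameter or device area units per `unit`.
    rate : float
        Sampling rate in Hz.
    unit : str
        Either ``"mm"`` (diameter) or ``"area_au"`` (device area units).
    valid : np.ndarray
        Boolean per sample; ``False`` marks a missing sample.
    run_id : str
        Free-form label for the recording run.
    """

    time: np.ndarray
    pupil: np.ndarray
    rate: float
    unit: str = "mm"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    run_id: str = ""
    #: True for band-passed/centred traces, whose values hover around zero
    #: and are exempt from the physical diameter range check.
    centred: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.pupil)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.time) == len(self.pupil) == len(self.valid)):
            raise ValueError("time, pupil and valid must have equal length")
        if self.unit not in ("mm", "area_au"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise TraceFormatError("time must be strictly increasing")
            if np.max(np.abs(steps - 1.0 / self.rate)) > TIME_TOLERANCE:
                raise TraceFormatError(
                    "timestamps are not uniform at the stated rate "
                    f"({self.rate} Hz)"
                )
        if self.unit == "mm" and not self.centred:
            finite = self.pupil[np.isfinite(self.pupil) & self.valid]
            if finite.size and (np.any(finite <= 0) or np.any(finite >= MAX_DIAMETER_MM)):
                raise ValueError(
                    "mm-diameter trace has values outside (0, 12) mm"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Span of the trace in seconds (last minus first timestamp)."""
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def copy(self) -> "PupilTrace":
        return replace(
            self,
            time=self.time.copy(),
            pupil=self.pupil.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class EventTable:
    """Trial/event table: onsets, durations and condition labels."""

    onset: np.ndarray
    duration: np.ndarray
    condition: np.ndarray
    response_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.duration = np.asarray(self.duration, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.response_time is not None:
            self.response_time = np.asarray(self.response_time, dtype=float)
        if len(self.onset) != len(self.duration) or len(self.onset) != len(self.condition):
            raise ValueError("onset, duration and condition must align")
        if len(self.onset) > 1 and np.any(np.diff(self.onset) <= 0):
            raise ValueError("trial onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset)


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting tab vs comma from the header."""
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
    except OSError as exc:
        raise TraceFormatError(f"cannot read {path}: {exc}") from exc
    if not header.strip():
        raise TraceFormatError(f"{path} is empty")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_trace(
    path: str | Path,
    rate: float,
    unit: str = "mm",
    run_id: str | None = None,
    centred: bool = False,
) -> PupilTrace:
    """Read a pupil trace from delimited text.

    The file must have a header naming at least ``time_s`` and ``pupil``
    columns (an optional ``valid`` column holds 0/1 flags).  Blank or
    non-numeric pupil cells become invalid samples.  Timestamps are validated
    against ``rate``; non-uniform timestamps raise :class:`TraceFormatError`.
    """
    df = _read_table(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" not in cols or "pupil" not in cols:
        raise TraceFormatError(
            f"{path}: header must name time_s and pupil columns, got {list(df.columns)}"
        )
    time = pd.to_numeric(df[cols["time_s"]], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(time)):
        raise TraceFormatError(f"{path}: non-numeric timestamps")
    pupil = pd.to_numeric(df[cols["pupil"]], errors="coerce").to_numpy(float)
    valid = np.isfinite(pupil)
    if "valid" in cols:
        valid &= pd.to_numeric(df[cols["valid"]], errors="coerce").fillna(0).to_numpy(float) != 0
    return PupilTrace(
        time=time,
        pupil=pupil,
        rate=rate,
        unit=unit,
        valid=valid,
        run_id=run_id if run_id is not None else Path(path).stem,
        centred=centred,
    )


def write_trace(trace: PupilTrace, path: str | Path, sep: str = "\t") -> None:
    """Write a trace as delimited text with ``time_s``, ``pupil``, ``valid`` columns."""
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "pupil": trace.pupil,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_events(path: str | Path) -> EventTable:
    """Read a trial table (``onset_s``, ``duration_s``, ``condition``, optional ``rt_s``)."""
    df = _read_table(path)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("onset_s", "duration_s", "condition"):
        if required not in cols:
            raise TraceFormatError(f"{path}: missing column {required}")
    rt = None
    if "rt_s" in cols:
        rt = pd.to_numeric(df[cols["rt_s"]], errors="coerce").to_numpy(float)
    return EventTable(
        onset=df[cols["onset_s"]].to_numpy(float),
        duration=df[cols["duration_s"]].to_numpy(float),
        condition=df[cols["condition"]].to_numpy(),
        response_time=rt,
    )


def write_events(events: EventTable, path: str | Path, sep: str = "\t") -> None:
    data = {
        "onset_s": events.onset,
        "duration_s": events.duration,
        "condition": events.condition,
    }
    if events.response_time is not None:
        data["rt_s"] = events.response_time
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.10g")


def area_to_diameter(
    trace: PupilTrace,
    scale: float,
    convention: str = "standard",
) -> PupilTrace:
    """Convert a trace in device area units to mm diameter.

    Each area reading ``A`` (a.u.) maps to physical area ``A/scale`` (mm^2),
    and then — assuming a circular pupil — to a diameter
    ``d = 2*sqrt((A/scale)/pi)`` mm.  ``convention="paper_literal"`` instead
    applies ``sqrt(A_mm2/pi)``, i.e. the radius, reproducing the formula some
    legacy pipelines print; the default is the geometrically correct diameter.
    Invalid samples are preserved.
    """
    if trace.unit != "area_au":
        raise ValueError("trace must be in area_au units")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if convention not in ("standard", "paper_literal"):
        raise ValueError(f"unknown diameter convention {convention!r}")
    area_mm2 = trace.pupil / scale
    finite = np.isfinite(area_mm2)
    if np.any(area_mm2[finite] < 0):
        raise ValueError("negative pupil area")
    radius_like = np.sqrt(area_mm2 / math.pi)
    diam = radius_like if convention == "paper_literal" else 2.0 * radius_like
    # A zero-area sample maps to d = 0, which the mm invariant would reject as
    # nonphysical, so flag it invalid.
    valid = trace.valid & finite & (diam > 0) & (diam < MAX_DIAMETER_MM)
    return PupilTrace(
        time=trace.time.copy(),
        pupil=diam,
        rate=trace.rate,
        unit="mm",
        valid=valid,
        run_id=trace.run_id,
    )
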