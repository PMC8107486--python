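"""Plain-text I/O and validated containers for continuous IOP telemetry.

Traces are delimited text with columns ``time_s, iop_mmhg``; experiment
schedules list labelled protocol epochs with columns
``label, eccentricity_deg, start_s, end_s, repetition``.  Lines starting
with ``#`` are comments and may carry ``key: value`` metadata (patient id,
nominal sampling rate).  Epoch intervals are half-open ``[start_s, end_s)``
in seconds from session start.

Dropped (NaN) pressure samples are removed on read, never imputed: the
analysis operates on raw telemetry and excludes deficient epochs downstream
rather than filling gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Gaze condition codes in clockwise protocol order, starting superior.
GAZE_DIRECTIONS = ("S", "ST", "T", "IT", "I", "IN", "N", "SN")
SPECIAL_LABELS = ("PRIMARY", "CLOSED")
ALL_LABELS = GAZE_DIRECTIONS + SPECIAL_LABELS
GAZE_ECCENTRICITIES = (10.0, 20.0, 25.0)


class TelemetryError(Exception):
    """Base class for iopgaze errors."""


class ParseError(TelemetryError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(TelemetryError):
    """Data violated a structural invariant (ordering, labels, overlap...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class IOPTrace:
    """Timestamped intraocular-pressure samples of one recording session.

    Parameters
    ----------
    patient_id : str
        Opaque identifier of the recorded patient/session.
    time_s : array-like
        Sample times in seconds from session start, strictly increasing.
    iop_mmhg : array-like
        Intraocular pressure in mm Hg, finite.  May contain gaps in time
        (antenna dropout); gaps are never interpolated.
    nominal_rate_hz : float
        Nominal sampling rate of the telemetry link (~9 Hz for the
        sulcus-implanted sensor read through an external antenna).
    """

    patient_id: str
    time_s: np.ndarray
    iop_mmhg: np.ndarray
    nominal_rate_hz: float = 9.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.iop_mmhg = np.asarray(self.iop_mmhg, dtype=float)
        if self.time_s.shape != self.iop_mmhg.shape or self.time_s.ndim != 1:
            raise ValidationError(
                "time_s and iop_mmhg must be 1-d arrays of equal length"
            )
        if self.time_s.size and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError(
                f"trace '{self.patient_id}': sample times are not strictly increasing"
            )
        if not np.all(np.isfinite(self.iop_mmhg)):
            raise ValidationError(
                f"trace '{self.patient_id}': non-finite IOP values present"
            )
        if self.nominal_rate_hz <= 0:
            raise ValidationError("nominal_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.n_samples else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "iop_mmhg": self.iop_mmhg})


@dataclass
class Epoch:
    """One labelled protocol interval, half-open ``[start_s, end_s)``.

    ``label`` is a gaze code (clockwise S..SN), ``PRIMARY`` (straight-ahead
    baseline) or ``CLOSED`` (eyelid closure).  ``eccentricity_deg`` is 0 for
    PRIMARY/CLOSED.  ``is_control`` marks the repeated superior gaze closing
    each eccentricity block (internal control).
    """

    label: str
    eccentricity_deg: float
    start_s: float
    end_s: float
    repetition: int = 1
    ordinal: int = 0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValidationError(
                f"unknown epoch label {self.label!r}; allowed: {', '.join(ALL_LABELS)}"
            )
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"epoch {self.ordinal} ({self.label}): end_s must exceed start_s"
            )
        if self.label in SPECIAL_LABELS and self.eccentricity_deg != 0:
            raise ValidationError(
                f"epoch {self.ordinal}: {self.label} epochs must have eccentricity 0"
            )
        if self.label in GAZE_DIRECTIONS and self.eccentricity_deg not in GAZE_ECCENTRICITIES:
            raise ValidationError(
                f"epoch {self.ordinal} ({self.label}): eccentricity "
                f"{self.eccentricity_deg} not in {GAZE_ECCENTRICITIES}"
            )
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_gaze(self) -> bool:
        return self.label in GAZE_DIRECTIONS


# Expected gaze-label sequence inside one eccentricity block: clockwise from
# superior plus the closing superior internal control.
_BLOCK_SEQUENCE = GAZE_DIRECTIONS + ("S",)


@dataclass
class EpochSchedule:
    """Ordered, non-overlapping protocol epochs of one session."""

    patient_id: str
    epochs: list[Epoch] = field(default_factory=list)
    metadata: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def validate(self) -> None:
        """Check ordering, baseline alternation and clockwise block structure."""
        prev: Epoch | None = None
        for ep in self.epochs:
            if prev is not None:
                if ep.start_s < prev.end_s:
                    raise ValidationError(
                        f"epochs {prev.ordinal} and {ep.ordinal} overlap "
                        f"({prev.end_s} > {ep.start_s})"
                    )
            if ep.label != "PRIMARY":
                if prev is None or prev.label != "PRIMARY":
                    raise ValidationError(
                        f"epoch {ep.ordinal} ({ep.label}) is not immediately "
                        "preceded by a PRIMARY baseline epoch"
                    )
            prev = ep
        self._validate_clockwise()

    def _validate_clockwise(self) -> None:
        # Consecutive gaze epochs sharing (eccentricity, repetition) form a
        # block; each block must follow S, ST, ..., SN (+ closing control S).
        run_labels: list[str] = []
        run_key: tuple[float, int] | None = None

        def check(labels: list[str], key) -> None:
            if labels and list(labels) != list(_BLOCK_SEQUENCE[: len(labels)]):
                raise ValidationError(
                    f"gaze block {key}: sequence {labels} does not follow the "
                    f"clockwise order {_BLOCK_SEQUENCE}"
                )

        for ep in self.epochs:
            if not ep.is_gaze:
                continue
            key = (ep.eccentricity_deg, ep.repetition)
            if key != run_key:
                check(run_labels, run_key)
                run_labels, run_key = [], key
            run_labels.append(ep.label)
            if len(run_labels) > len(_BLOCK_SEQUENCE):
                raise ValidationError(f"gaze block {key}: more than 9 gaze epochs")
        check(run_labels, run_key)

    def mark_controls(self) -> None:
        """Flag the closing S of every complete block as the internal control."""
        run: list[Epoch] = []
        run_key: tuple[float, int] | None = None
        for ep in self.epochs:
            if not ep.is_gaze:
                continue
            key = (ep.eccentricity_deg, ep.repetition)
            if key != run_key:
                run, run_key = [], key
            run.append(ep)
            if len(run) == len(_BLOCK_SEQUENCE):
                run[-1].is_control = True

    def gaze_epochs(self) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.is_gaze]

    def closed_epochs(self) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.label == "CLOSED"]


@dataclass
class TraceReport:
    """Sampling-quality report: effective rate and dropout gaps."""

    n_samples: int
    median_interval_s: float
    effective_rate_hz: float
    gaps: list[tuple[float, float]]
    rate_within_tol: bool


# ---------------------------------------------------------------------------
# file I/O


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _data_line_numbers(path: Path) -> list[int]:
    """1-based file line numbers of the data rows (after header/comments)."""
    numbers = []
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if not seen_header:
                seen_header = True
                continue
            numbers.append(lineno)
    return numbers


def _find_column(columns: Sequence[str], *needles: str) -> str:
    for col in columns:
        low = col.strip().lower()
        if any(n in low for n in needles):
            return col
    raise ParseError(
        f"no column matching {needles} among {list(columns)}"
    )


def _numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna() & ~raw.astype(str).str.strip().str.lower().isin(
        ["", "nan", "na"]
    )
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        lines = _data_line_numbers(path)
        lineno = lines[idx] if idx < len(lines) else "?"
        raise ParseError(
            f"{path}: malformed value {raw.iloc[idx]!r} in column {col!r} "
            f"at line {lineno}"
        )
    return coerced


def read_trace(path: str | Path) -> IOPTrace:
    """Read a telemetry trace CSV; NaN pressures are dropped with a log entry.

    Raises
    ------
    ParseError
        Malformed rows (named with their line number) or missing columns.
    ValidationError
        Non-monotonic sample times.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(
        path, comment="#", skip_blank_lines=True, float_precision="round_trip"
    )
    tcol = _find_column(df.columns, "time")
    pcol = _find_column(df.columns, "iop", "pressure")
    t = _numeric(df, tcol, path)
    p = _numeric(df, pcol, path)
    if t.isna().any():
        lines = _data_line_numbers(path)
        idx = int(np.flatnonzero(t.isna().to_numpy())[0])
        raise ParseError(
            f"{path}: missing timestamp at line {lines[idx] if idx < len(lines) else '?'}"
        )
    keep = p.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d sample(s) with missing IOP", path, n_dropped)
    return IOPTrace(
        patient_id=meta.get("patient_id", path.stem),
        time_s=t[keep].to_numpy(),
        iop_mmhg=p[keep].to_numpy(),
        nominal_rate_hz=float(meta.get("nominal_rate_hz", 9.0)),
    )


def write_trace(trace: IOPTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# patient_id: {trace.patient_id}\n")
        fh.write(f"# nominal_rate_hz: {trace.nominal_rate_hz!r}\n")
        # %.17g guarantees exact float round-trip through text
        trace.to_frame().to_csv(fh, index=False, float_format="%.17g")


_SCHEDULE_COLUMNS = ["label", "eccentricity_deg", "start_s", "end_s", "repetition"]


def read_schedule(path: str | Path) -> EpochSchedule:
    """Read and validate an epoch schedule CSV.

    The optional ``control`` column flags internal-control epochs; when it is
    absent, the closing S of every complete block is marked structurally.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(
        path, comment="#", skip_blank_lines=True, float_precision="round_trip"
    )
    missing = [c for c in _SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: schedule is missing columns {missing}")
    bad = ~df["label"].isin(ALL_LABELS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown label(s) {sorted(df.loc[bad, 'label'].unique())}; "
            f"allowed codes: {', '.join(ALL_LABELS)}"
        )
    has_control = "control" in df.columns
    epochs = [
        Epoch(
            label=row.label,
            eccentricity_deg=float(row.eccentricity_deg),
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            repetition=int(row.repetition),
            ordinal=i,
            is_control=bool(getattr(row, "control", False)) if has_control else False,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    schedule = EpochSchedule(
        patient_id=meta.get("patient_id", path.stem),
        epochs=epochs,
        metadata=meta.get("metadata", ""),
    )
    if not has_control:
        schedule.mark_controls()
    return schedule


def write_schedule(schedule: EpochSchedule, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "label": [ep.label for ep in schedule],
            "eccentricity_deg": [ep.eccentricity_deg for ep in schedule],
            "start_s": [ep.start_s for ep in schedule],
            "end_s": [ep.end_s for ep in schedule],
            "repetition": [ep.repetition for ep in schedule],
            "control": [int(ep.is_control) for ep in schedule],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# patient_id: {schedule.patient_id}\n")
        if schedule.metadata:
            fh.write(f"# metadata: {schedule.metadata}\n")
        df.to_csv(fh, index=False)


def validate_trace(trace: IOPTrace, tol_rate: float = 0.1) -> TraceReport:
    """Report the effective sampling rate and dropout gaps of a trace.

    A gap is an inter-sample interval exceeding 3x the nominal interval.
    """
    if trace.n_samples == 0:
        raise ValidationError("cannot validate an empty trace")
    if trace.n_samples == 1:
        return TraceReport(1, float("nan"), float("nan"), [], False)
    dt = np.diff(trace.time_s)
    median = float(np.median(dt))
    rate = 1.0 / median
    threshold = 3.0 / trace.nominal_rate_hz
    gap_idx = np.flatnonzero(dt > threshold)
    gaps = [(float(trace.time_s[i]), float(trace.time_s[i + 1])) for i in gap_idx]
    within = abs(rate - trace.nominal_rate_hz) <= tol_rate * trace.nominal_rate_hz
    return TraceReport(trace.n_samples, median, rate, gaps, bool(within))
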