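"""Epoch-locked window extraction, QC and baseline-referenced ΔIOP summaries.

The first and last ``trim_s`` seconds of every epoch are excluded from the
analysis interval (default 2 s, leaving an 8-s interval in a 12-s epoch) to
avoid saccadic transients that are not precisely aligned with the allotted
interval.  ΔIOP is the mean IOP of a gaze epoch's analysis interval minus
the mean of the immediately preceding primary-position baseline; negative
values denote an IOP decrease relative to primary gaze.  Time-course
statistics (TW_initial, TW_final, dΔIOP) use the first/last 2 s of the
analysis interval; eyelid-closure responses use the last 2 s of the closure
epoch, skipping the initial lid-squeeze peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GAZE_DIRECTIONS,
    Epoch,
    EpochSchedule,
    IOPTrace,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisWindow",
    "extract_windows",
    "qc_filter",
    "compute_delta_iop",
    "compute_time_windows",
    "compute_eyelid_deltas",
    "aggregate_group",
]


@dataclass
class AnalysisWindow:
    """Samples of one epoch together with its trimmed analysis interval."""

    epoch: Epoch
    window_start_s: float
    window_end_s: float
    time_s: np.ndarray
    iop_mmhg: np.ndarray
    n_expected: int
    qc_pass: bool = True
    artifact_overlap: bool = False

    def interval_mean(self, start_s: float, end_s: float) -> float:
        """Mean IOP over ``[start_s, end_s)``; NaN when no samples fall in it."""
        sel = (self.time_s >= start_s) & (self.time_s < end_s)
        if not sel.any():
            return float("nan")
        return float(self.iop_mmhg[sel].mean())

    @property
    def n_observed(self) -> int:
        sel = (self.time_s >= self.window_start_s) & (self.time_s < self.window_end_s)
        return int(sel.sum())

    @property
    def mean_iop(self) -> float:
        return self.interval_mean(self.window_start_s, self.window_end_s)

    @property
    def valid(self) -> bool:
        return self.n_observed >= 1


def extract_windows(
    trace: IOPTrace, schedule: EpochSchedule, trim_s: float = 2.0
) -> list[AnalysisWindow]:
    """One analysis window per epoch over ``[start + trim, end - trim)``.

    ``n_expected`` is the window length times the nominal rate, rounded
    down.  Raises for epochs too short to trim.
    """
    t = trace.time_s
    windows: list[AnalysisWindow] = []
    for ep in schedule:
        if ep.duration_s <= 2 * trim_s:
            raise ValidationError(
                f"epoch {ep.ordinal} ({ep.label}, {ep.duration_s:g} s) is too "
                f"short for a 2x{trim_s:g} s trim"
            )
        i0, i1 = np.searchsorted(t, [ep.start_s, ep.end_s])
        ws, we = ep.start_s + trim_s, ep.end_s - trim_s
        windows.append(
            AnalysisWindow(
                epoch=ep,
                window_start_s=ws,
                window_end_s=we,
                time_s=t[i0:i1],
                iop_mmhg=trace.iop_mmhg[i0:i1],
                n_expected=int(np.floor((we - ws) * trace.nominal_rate_hz)),
            )
        )
    return windows


def _block_eccentricities(windows: Sequence[AnalysisWindow]) -> np.ndarray:
    """Eccentricity of the gaze block each window belongs to.

    A PRIMARY baseline is assigned to the block of the next gaze epoch; a
    trailing baseline (after the last gaze of the session) to the previous
    one.
    """
    ecc = np.full(len(windows), np.nan)
    current = np.nan
    for i in range(len(windows) - 1, -1, -1):
        ep = windows[i].epoch
        if ep.is_gaze:
            current = ep.eccentricity_deg
        ecc[i] = current
    current = 0.0
    for i in range(len(windows)):
        if np.isnan(ecc[i]):
            ecc[i] = current
        else:
            current = ecc[i]
    return ecc


def qc_filter(
    windows: list[AnalysisWindow],
    min_fraction: float = 0.5,
    artifact_spans: Sequence[tuple[float, float]] = (),
    exclude_whole_repetition: bool = False,
) -> list[AnalysisWindow]:
    """Set ``qc_pass`` flags; returns the same window list.

    A window fails when fewer than ``min_fraction`` of its expected samples
    were observed, or when its analysis interval overlaps a declared
    artifact span (e.g. a cough).  With ``exclude_whole_repetition`` a
    failure removes the whole (eccentricity, repetition) block, mirroring
    the practice of discarding a contaminated repetition outright.
    """
    for w in windows:
        frac = w.n_observed / w.n_expected if w.n_expected else 0.0
        overlap = any(
            w.window_start_s < b and a < w.window_end_s for a, b in artifact_spans
        )
        w.artifact_overlap = overlap
        w.qc_pass = (frac >= min_fraction) and not overlap and w.valid
    if exclude_whole_repetition:
        block_ecc = _block_eccentricities(windows)
        failed = {
            (block_ecc[i], w.epoch.repetition)
            for i, w in enumerate(windows)
            if not w.qc_pass
        }
        for i, w in enumerate(windows):
            if (block_ecc[i], w.epoch.repetition) in failed:
                w.qc_pass = False
    n_failed = sum(not w.qc_pass for w in windows)
    if n_failed:
        logger.info("qc_filter: %d of %d windows excluded", n_failed, len(windows))
    return windows


def compute_delta_iop(
    windows: Sequence[AnalysisWindow], patient_id: str = ""
) -> pd.DataFrame:
    """Baseline-referenced ΔIOP records, one per gaze epoch.

    Each gaze window is paired with the immediately preceding PRIMARY
    baseline window; ``delta_iop = gaze_mean - baseline_mean``.
    """
    rows = []
    prev: AnalysisWindow | None = None
    for w in windows:
        ep = w.epoch
        if ep.is_gaze:
            if prev is None or prev.epoch.label != "PRIMARY":
                raise ValidationError(
                    f"gaze epoch {ep.ordinal} ({ep.label}) has no immediately "
                    "preceding PRIMARY baseline"
                )
            baseline = prev.mean_iop
            gaze = w.mean_iop
            rows.append(
                {
                    "patient_id": patient_id,
                    "direction": ep.label,
                    "eccentricity_deg": ep.eccentricity_deg,
                    "repetition": ep.repetition,
                    "ordinal": ep.ordinal,
                    "baseline_mean": baseline,
                    "gaze_mean": gaze,
                    "delta_iop": gaze - baseline,
                    "qc_pass": bool(w.qc_pass and prev.qc_pass and w.valid and prev.valid),
                    "is_control": ep.is_control,
                }
            )
        prev = w
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "direction", "eccentricity_deg", "repetition", "ordinal",
            "baseline_mean", "gaze_mean", "delta_iop", "qc_pass", "is_control",
        ],
    )


def compute_time_windows(
    windows: Sequence[AnalysisWindow], patient_id: str = "", sub_s: float = 2.0
) -> pd.DataFrame:
    """TW_initial / TW_final / dΔIOP per gaze epoch.

    TW_initial and TW_final are ΔIOP values over the first/last ``sub_s``
    seconds of the analysis interval, both referenced to the same preceding
    baseline; ``d_delta_iop = tw_initial - tw_final`` so that a decline
    while holding gaze is positive.
    """
    rows = []
    prev: AnalysisWindow | None = None
    for w in windows:
        ep = w.epoch
        if ep.is_gaze:
            if prev is None or prev.epoch.label != "PRIMARY":
                raise ValidationError(
                    f"gaze epoch {ep.ordinal} has no preceding PRIMARY baseline"
                )
            if w.window_end_s - w.window_start_s < 2 * sub_s:
                raise ValidationError(
                    f"epoch {ep.ordinal}: analysis interval shorter than 2x{sub_s} s"
                )
            baseline = prev.mean_iop
            first = w.interval_mean(w.window_start_s, w.window_start_s + sub_s)
            last = w.interval_mean(w.window_end_s - sub_s, w.window_end_s)
            tw_i = first - baseline
            tw_f = last - baseline
            rows.append(
                {
                    "patient_id": patient_id,
                    "direction": ep.label,
                    "eccentricity_deg": ep.eccentricity_deg,
                    "repetition": ep.repetition,
                    "ordinal": ep.ordinal,
                    "baseline_mean": baseline,
                    "tw_initial": tw_i,
                    "tw_final": tw_f,
                    "d_delta_iop": tw_i - tw_f,
                    "qc_pass": bool(
                        w.qc_pass
                        and prev.qc_pass
                        and np.isfinite(tw_i)
                        and np.isfinite(tw_f)
                    ),
                    "is_control": ep.is_control,
                }
            )
        prev = w
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "direction", "eccentricity_deg", "repetition", "ordinal",
            "baseline_mean", "tw_initial", "tw_final", "d_delta_iop", "qc_pass",
            "is_control",
        ],
    )


def compute_eyelid_deltas(
    windows: Sequence[AnalysisWindow], patient_id: str = "", sub_s: float = 2.0
) -> pd.DataFrame:
    """Eyelid-closure ΔIOP per CLOSED epoch (last ``sub_s`` seconds of the
    closure epoch minus the preceding PRIMARY baseline mean)."""
    rows = []
    prev: AnalysisWindow | None = None
    for w in windows:
        ep = w.epoch
        if ep.label == "CLOSED":
            if prev is None or prev.epoch.label != "PRIMARY":
                raise ValidationError(
                    f"CLOSED epoch {ep.ordinal} has no preceding PRIMARY baseline"
                )
            baseline = prev.mean_iop
            closure = w.interval_mean(ep.end_s - sub_s, ep.end_s)
            rows.append(
                {
                    "patient_id": patient_id,
                    "repetition": ep.repetition,
                    "ordinal": ep.ordinal,
                    "closure_mean_last2s": closure,
                    "baseline_mean": baseline,
                    "delta_iop": closure - baseline,
                    "qc_pass": bool(
                        w.qc_pass and prev.qc_pass and np.isfinite(closure)
                    ),
                }
            )
        prev = w
    if not rows:
        logger.warning("compute_eyelid_deltas: no CLOSED epochs in schedule")
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "repetition", "ordinal", "closure_mean_last2s",
            "baseline_mean", "delta_iop", "qc_pass",
        ],
    )


def per_patient_condition_means(
    records: pd.DataFrame,
    values: Sequence[str] = ("gaze_mean", "baseline_mean", "delta_iop"),
) -> pd.DataFrame:
    """Mean over qc-passing, non-control repetitions per patient x condition."""
    ok = records[records["qc_pass"] & ~records["is_control"]]
    return (
        ok.groupby(["patient_id", "eccentricity_deg", "direction"], sort=False)[
            list(values)
        ]
        .mean()
        .reset_index()
    )


def aggregate_group(records: pd.DataFrame) -> pd.DataFrame:
    """Group summary per condition (mean, SEM, n) after per-patient averaging.

    Internal-control and qc-failed records are excluded.  Per eccentricity an
    ``Overall`` row averages the eight per-direction group means; its SEM is
    the between-patient SEM of the per-patient overall means.  SEM is NaN
    when only a single patient contributes.
    """
    per_patient = per_patient_condition_means(records)
    out_rows = []
    for ecc, grp in per_patient.groupby("eccentricity_deg", sort=True):
        direction_means = {}
        for direction in GAZE_DIRECTIONS:
            sub = grp[grp["direction"] == direction]
            if sub.empty:
                logger.warning(
                    "aggregate_group: no data for %s at %g deg", direction, ecc
                )
                continue
            n = len(sub)
            row = {"eccentricity_deg": ecc, "direction": direction, "n": n}
            for col, name in [
                ("gaze_mean", "position"),
                ("baseline_mean", "baseline"),
                ("delta_iop", "delta"),
            ]:
                vals = sub[col].to_numpy()
                row[f"{name}_mean"] = float(vals.mean())
                row[f"{name}_sem"] = (
                    float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
                )
            direction_means[direction] = row
            out_rows.append(row)
        if direction_means:
            # Overall: mean of the per-direction group means; SEM across the
            # per-patient overall means.
            overall = {"eccentricity_deg": ecc, "direction": "Overall"}
            for name in ("position", "baseline", "delta"):
                overall[f"{name}_mean"] = float(
                    np.mean([r[f"{name}_mean"] for r in direction_means.values()])
                )
            pp = grp.groupby("patient_id")[["gaze_mean", "baseline_mean", "delta_iop"]].mean()
            n = len(pp)
            overall["n"] = n
            for col, name in [
                ("gaze_mean", "position"),
                ("baseline_mean", "baseline"),
                ("delta_iop", "delta"),
            ]:
                overall[f"{name}_sem"] = (
                    float(pp[col].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
                )
            out_rows.append(overall)
    return pd.DataFrame(
        out_rows,
        columns=[
            "eccentricity_deg", "direction", "n",
            "position_mean", "position_sem",
            "baseline_mean", "baseline_sem",
            "delta_mean", "delta_sem",
        ],
    )
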