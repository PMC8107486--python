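"""Synthetic continuous-IOP telemetry with known ground truth.

The generator composes, sample by sample,

``IOP(t) = IOP0 + delta(epoch) + A * exp(-(t - t_onset)/tau)
          + (OPA/2) * sin(2*pi*f_heart*t) + random-walk drift + white noise``

where ``delta`` is the additive plateau offset of the current epoch (a gaze
direction x eccentricity table, 0 in primary position, a steady-state shift
under eyelid closure), and a transient spike ``A*exp(.)`` is triggered at
every condition change: signed toward the new plateau for gaze saccades,
always positive for eyelid closure (deliberate lid squeeze).  The ocular
pulse is a single sinusoid with configurable peak-to-trough amplitude
coupled to heart rate; slow unexplained variation is a Gaussian random walk.

Default plateau offsets are the group-mean gaze responses reported for the
sulcus-implanted telemetric sensor cohort (11 POAG patients, three
repetitions); the saccadic spike amplitude/decay are free parameters — the
~9 Hz link undersamples the true saccadic transient, so no measured value
exists for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GAZE_DIRECTIONS,
    GAZE_ECCENTRICITIES,
    Epoch,
    EpochSchedule,
    IOPTrace,
    ValidationError,
)

__all__ = [
    "DEFAULT_GAZE_OFFSETS",
    "DEFAULT_OFFSET_DISPERSION",
    "SimulationParams",
    "CohortSpec",
    "PatientSession",
    "build_protocol",
    "simulate_trace",
    "inject_artifacts",
    "draw_patient_params",
    "simulate_cohort",
]

#: Group-mean plateau offsets delta(direction, eccentricity) in mm Hg
#: (gaze-minus-baseline differences of the 11-patient telemetry cohort).
DEFAULT_GAZE_OFFSETS: dict[tuple[str, float], float] = {
    ("S", 10.0): 1.1, ("ST", 10.0): 0.87, ("T", 10.0): 0.60, ("IT", 10.0): 0.33,
    ("I", 10.0): -0.31, ("IN", 10.0): -0.71, ("N", 10.0): -0.18, ("SN", 10.0): 0.66,
    ("S", 20.0): 3.9, ("ST", 20.0): 2.6, ("T", 20.0): 1.1, ("IT", 20.0): 0.47,
    ("I", 20.0): -0.45, ("IN", 20.0): -1.1, ("N", 20.0): -0.71, ("SN", 20.0): 1.9,
    ("S", 25.0): 4.4, ("ST", 25.0): 2.9, ("T", 25.0): 1.2, ("IT", 25.0): 0.14,
    ("I", 25.0): -0.55, ("IN", 25.0): -1.6, ("N", 25.0): -0.51, ("SN", 25.0): 2.9,
}

# Between-patient SEMs of the same differences; dispersion = SEM * sqrt(11).
_OFFSET_SEM: dict[tuple[str, float], float] = {
    ("S", 10.0): 0.61, ("ST", 10.0): 0.28, ("T", 10.0): 0.083, ("IT", 10.0): 0.14,
    ("I", 10.0): 0.17, ("IN", 10.0): 0.16, ("N", 10.0): 0.17, ("SN", 10.0): 0.42,
    ("S", 20.0): 1.38, ("ST", 20.0): 0.70, ("T", 20.0): 0.36, ("IT", 20.0): 0.12,
    ("I", 20.0): 0.23, ("IN", 20.0): 0.18, ("N", 20.0): 0.47, ("SN", 20.0): 0.88,
    ("S", 25.0): 1.48, ("ST", 25.0): 0.94, ("T", 25.0): 0.27, ("IT", 25.0): 0.27,
    ("I", 25.0): 0.31, ("IN", 25.0): 0.23, ("N", 25.0): 0.67, ("SN", 25.0): 1.40,
}

#: Default between-patient SD of each plateau offset (mm Hg).
DEFAULT_OFFSET_DISPERSION: dict[tuple[str, float], float] = {
    key: sem * float(np.sqrt(11.0)) for key, sem in _OFFSET_SEM.items()
}


@dataclass
class SimulationParams:
    """Ground-truth generative parameters of one simulated session.

    Amplitudes are mm Hg, times seconds, rates Hz.  ``pulse_amp`` is ocular
    pulse peak-to-trough; ``spike_amp``/``spike_tau`` shape the saccadic
    transient at gaze changes; ``eyelid_*`` the closure transient and its
    steady-state offset; ``drift_sd`` is the per-sample step SD of the slow
    random walk; ``response_decline_rate`` is the fractional loss of
    gaze-response gain per hour of session time (0 = stable responses, the
    observed situation; > 0 injects a session-long decline detectable by the
    internal-control contrast).
    """

    baseline_iop: float = 16.5
    offset_table: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: dict(DEFAULT_GAZE_OFFSETS)
    )
    pulse_amp: float = 2.0
    heart_rate: float = 1.2
    spike_amp: float = 3.0
    spike_tau: float = 2.5
    eyelid_spike_amp: float = 4.0
    eyelid_offset: float = -2.1
    eyelid_tau: float = 2.0
    noise_sd: float = 0.3
    drift_sd: float = 0.05
    rate_jitter: float = 0.0
    sample_rate_hz: float = 9.0
    response_decline_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pulse_amp", "spike_tau", "eyelid_tau", "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.rate_jitter < 0.9:
            raise ValidationError("rate_jitter must be in [0, 0.9)")
        if self.sample_rate_hz <= 0 or self.heart_rate < 0:
            raise ValidationError("sample_rate_hz must be > 0, heart_rate >= 0")
        missing = [
            (d, e)
            for d in GAZE_DIRECTIONS
            for e in GAZE_ECCENTRICITIES
            if (d, e) not in self.offset_table
        ]
        if missing:
            raise ValidationError(f"offset_table is missing conditions: {missing}")

    def offset(self, label: str, eccentricity_deg: float) -> float:
        """True plateau offset of a condition (0 in primary position)."""
        if label == "PRIMARY":
            return 0.0
        if label == "CLOSED":
            return self.eyelid_offset
        return float(self.offset_table[(label, eccentricity_deg)])

    def replace(self, **changes) -> "SimulationParams":
        return replace(self, **changes)


@dataclass
class CohortSpec:
    """Cohort layout and between-patient dispersion of the generator.

    Between-patient variation of the gaze response has two components,
    mirroring the observation that patients share the direction pattern but
    differ in magnitude (including an occasional negative responder):

    * a per-patient multiplicative response gain ``g ~ N(1,
      response_gain_sd)`` scaling the whole offset table, and
    * an independent additive residual per condition,
      ``N(0, offset_dispersion(d, e))``.

    ``offset_dispersion`` may be a scalar, a per-condition mapping, or None
    for the default residual table, which is derived so that the *marginal*
    between-patient SD of each condition reproduces the reported cohort
    spread (e.g. 4.9 mm Hg at superior/25 deg):
    ``residual^2 = max(0, SD^2 - gain_sd^2 * delta^2)``.
    """

    n_patients: int = 11
    n_repetitions: int = 3
    n_eyelid: int = 9
    eccentricities: Sequence[float] = (10.0, 20.0, 25.0)
    gaze_s: float = 12.0
    baseline_s: float = 12.0
    baseline_sd: float = 4.5
    response_gain_sd: float = 1.0
    offset_dispersion: float | Mapping[tuple[str, float], float] | None = None
    eyelid_offset_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_repetitions < 1:
            raise ValidationError("n_patients and n_repetitions must be >= 1")
        if not 0 <= self.n_eyelid <= self.n_patients:
            raise ValidationError("n_eyelid must be in [0, n_patients]")
        if self.baseline_sd < 0 or self.eyelid_offset_sd < 0 or self.response_gain_sd < 0:
            raise ValidationError("dispersion SDs must be >= 0")

    def dispersion(self, label: str, eccentricity_deg: float) -> float:
        """Residual (additive) between-patient SD of one condition."""
        disp = self.offset_dispersion
        if disp is None:
            total = DEFAULT_OFFSET_DISPERSION[(label, eccentricity_deg)]
            delta = DEFAULT_GAZE_OFFSETS[(label, eccentricity_deg)]
            resid2 = total**2 - (self.response_gain_sd * delta) ** 2
            return float(np.sqrt(max(0.0, resid2)))
        if isinstance(disp, Mapping):
            return float(disp[(label, eccentricity_deg)])
        if disp < 0:
            raise ValidationError("offset dispersion must be >= 0")
        return float(disp)


@dataclass
class PatientSession:
    """One simulated patient: trace, schedule, ground truth, realized params."""

    patient_id: str
    trace: IOPTrace
    schedule: EpochSchedule
    ground_truth: pd.DataFrame
    params: SimulationParams


def build_protocol(
    eccentricities: Sequence[float] = (10.0, 20.0, 25.0),
    gaze_s: float = 12.0,
    baseline_s: float = 12.0,
    n_repetitions: int = 3,
    eyelid: bool = False,
    eyelid_s: float = 10.0,
    n_eyelid_reps: int = 4,
    patient_id: str = "SIM",
) -> EpochSchedule:
    """Construct the fixation-wall protocol schedule.

    Per eccentricity and repetition: an initial PRIMARY baseline, then the
    eight gaze positions clockwise from superior, each preceded by a PRIMARY
    return, and a closing (S, PRIMARY) internal-control pair.  If ``eyelid``,
    a PRIMARY plus ``n_eyelid_reps`` x (CLOSED, PRIMARY) tail is appended.
    """
    for ecc in eccentricities:
        if float(ecc) not in GAZE_ECCENTRICITIES:
            raise ValidationError(
                f"invalid eccentricity {ecc}; allowed: {GAZE_ECCENTRICITIES}"
            )
    if gaze_s <= 4 or baseline_s <= 4 or (eyelid and eyelid_s <= 4):
        raise ValidationError("epoch durations must exceed 4 s")

    epochs: list[Epoch] = []
    t = 0.0

    def add(label: str, ecc: float, dur: float, rep: int, control: bool = False) -> None:
        nonlocal t
        epochs.append(
            Epoch(
                label=label,
                eccentricity_deg=ecc,
                start_s=t,
                end_s=t + dur,
                repetition=rep,
                ordinal=len(epochs),
                is_control=control,
            )
        )
        t += dur

    for ecc in eccentricities:
        ecc = float(ecc)
        for rep in range(1, n_repetitions + 1):
            add("PRIMARY", 0.0, baseline_s, rep)
            for direction in GAZE_DIRECTIONS:
                add(direction, ecc, gaze_s, rep)
                add("PRIMARY", 0.0, baseline_s, rep)
            add("S", ecc, gaze_s, rep, control=True)
            add("PRIMARY", 0.0, baseline_s, rep)
    if eyelid:
        add("PRIMARY", 0.0, baseline_s, 1)
        for rep in range(1, n_eyelid_reps + 1):
            add("CLOSED", 0.0, eyelid_s, rep)
            add("PRIMARY", 0.0, baseline_s, rep)
    return EpochSchedule(patient_id=patient_id, epochs=epochs, metadata="simulated")


def _epoch_terms(
    params: SimulationParams, schedule: EpochSchedule
) -> tuple[np.ndarray, ...]:
    """Per-epoch plateau offsets and spike amplitudes/decay constants."""
    n = len(schedule.epochs)
    delta = np.empty(n)
    amp = np.zeros(n)
    tau = np.full(n, np.inf)
    rate = params.response_decline_rate
    prev_delta = None
    for i, ep in enumerate(schedule.epochs):
        d = params.offset(ep.label, ep.eccentricity_deg)
        if ep.is_gaze and rate:
            d *= max(0.0, 1.0 - rate * ep.start_s / 3600.0)
        delta[i] = d
        if prev_delta is not None:
            if ep.label == "CLOSED":
                if params.eyelid_tau > 0:
                    amp[i] = params.eyelid_spike_amp
                    tau[i] = params.eyelid_tau
            elif params.spike_tau > 0:
                amp[i] = params.spike_amp * np.sign(d - prev_delta)
                tau[i] = params.spike_tau
        prev_delta = d
    return delta, amp, tau


def simulate_trace(
    params: SimulationParams,
    schedule: EpochSchedule,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IOPTrace, pd.DataFrame]:
    """Generate one telemetry trace and its ground-truth event table.

    Deterministic given the seed (or generator).  The ground-truth table has
    one row per epoch with the true plateau offset and spike parameters.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    rate = params.sample_rate_hz
    total = schedule.epochs[-1].end_s
    n = int(np.floor(total * rate))
    t = np.arange(n) / rate
    if params.rate_jitter > 0:
        t = t + rng.uniform(-0.5, 0.5, n) * params.rate_jitter / rate

    starts = np.array([ep.start_s for ep in schedule.epochs])
    ends = np.array([ep.end_s for ep in schedule.epochs])
    delta, amp, tau = _epoch_terms(params, schedule)

    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    inside = (t >= starts[idx]) & (t < ends[idx])

    signal = np.full(n, params.baseline_iop)
    signal += np.where(inside, delta[idx], 0.0)
    with np.errstate(over="ignore"):
        spike = amp[idx] * np.exp(-(t - starts[idx]) / tau[idx])
    signal += np.where(inside, spike, 0.0)
    if params.pulse_amp > 0 and params.heart_rate > 0:
        signal += 0.5 * params.pulse_amp * np.sin(2 * np.pi * params.heart_rate * t)
    if params.drift_sd > 0:
        signal += np.cumsum(rng.normal(0.0, params.drift_sd, n))
    if params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd, n)

    truth = pd.DataFrame(
        {
            "ordinal": [ep.ordinal for ep in schedule.epochs],
            "label": [ep.label for ep in schedule.epochs],
            "eccentricity_deg": [ep.eccentricity_deg for ep in schedule.epochs],
            "repetition": [ep.repetition for ep in schedule.epochs],
            "is_control": [ep.is_control for ep in schedule.epochs],
            "start_s": starts,
            "end_s": ends,
            "true_offset": delta,
            "spike_amp": amp,
            "spike_tau": tau,
        }
    )
    trace = IOPTrace(
        patient_id=schedule.patient_id,
        time_s=t,
        iop_mmhg=signal,
        nominal_rate_hz=rate,
    )
    return trace, truth


def inject_artifacts(
    trace: IOPTrace,
    dropout_spans: Sequence[tuple[float, float]] = (),
    cough_times: Sequence[float] = (),
    cough_amp: float = 10.0,
    cough_width: float = 0.5,
) -> IOPTrace:
    """Apply antenna-dropout spans (samples removed) and cough transients.

    A cough is a short positive half-sine bump of the given width centred at
    each listed time.  Overlapping dropout spans are merged with a warning.
    """
    spans = sorted((float(a), float(b)) for a, b in dropout_spans)
    merged: list[tuple[float, float]] = []
    for a, b in spans:
        if merged and a < merged[-1][1]:
            warnings.warn("overlapping dropout spans merged", stacklevel=2)
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))

    t = trace.time_s
    y = trace.iop_mmhg.copy()
    for t0 in cough_times:
        lo, hi = t0 - cough_width / 2, t0 + cough_width / 2
        sel = (t >= lo) & (t < hi)
        y[sel] += cough_amp * np.sin(np.pi * (t[sel] - lo) / cough_width)

    keep = np.ones(t.size, dtype=bool)
    for a, b in merged:
        keep &= ~((t >= a) & (t < b))
    return IOPTrace(
        patient_id=trace.patient_id,
        time_s=t[keep],
        iop_mmhg=y[keep],
        nominal_rate_hz=trace.nominal_rate_hz,
    )


def draw_patient_params(
    spec: CohortSpec, params: SimulationParams, rng: np.random.Generator
) -> SimulationParams:
    """Realize one patient's parameters around the shared cohort parameters."""
    baseline = rng.normal(params.baseline_iop, spec.baseline_sd)
    gain = rng.normal(1.0, spec.response_gain_sd) if spec.response_gain_sd else 1.0
    offsets = {
        key: gain * value + rng.normal(0.0, spec.dispersion(*key))
        for key, value in params.offset_table.items()
    }
    eyelid = rng.normal(params.eyelid_offset, spec.eyelid_offset_sd)
    return params.replace(
        baseline_iop=baseline, offset_table=offsets, eyelid_offset=eyelid
    )


def simulate_cohort(
    spec: CohortSpec | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> list[PatientSession]:
    """Simulate a cohort; per-patient streams derive from the master seed.

    Child generators use ``SeedSequence(seed, spawn_key=(patient, stream))``,
    a stable hash of (master seed, patient index), so individual patients are
    reproducible independently of cohort size.
    """
    spec = spec or CohortSpec()
    params = params or SimulationParams()
    sessions: list[PatientSession] = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:02d}"
        param_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 0)))
        trace_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 1)))
        realized = draw_patient_params(spec, params, param_rng)
        schedule = build_protocol(
            eccentricities=spec.eccentricities,
            gaze_s=spec.gaze_s,
            baseline_s=spec.baseline_s,
            n_repetitions=spec.n_repetitions,
            eyelid=i < spec.n_eyelid,
            patient_id=pid,
        )
        trace, truth = simulate_trace(realized, schedule, rng=trace_rng)
        sessions.append(PatientSession(pid, trace, schedule, truth, realized))
    return sessions
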