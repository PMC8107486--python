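"""Model/Results objects orchestrating the full telemetry analysis.

``GazeIOPExperiment`` is built from (trace, schedule) session pairs — read
from files, supplied directly, or simulated — and ``fit()`` runs the whole
analysis chain: window extraction and QC, baseline-referenced ΔIOP, group
aggregation, the three-way within-subject RM-ANOVA with Greenhouse–Geisser
correction, Holm-corrected per-direction contrasts, time-course statistics
and their correlation, vertical composites, the individual extreme-direction
contrasts, the internal-control test, and (when closure epochs are present)
the eyelid analyses.  The returned ``GazeIOPResults`` carries the tidy
tables, a ``summary()`` text report and CSV export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import segment, stats
from .io import (
    EpochSchedule,
    IOPTrace,
    ValidationError,
    read_schedule,
    read_trace,
)
from .stats import AnovaResult, CorrelationResult, HolmResult, StatTestResult

logger = logging.getLogger(__name__)

__all__ = ["GazeIOPExperiment", "GazeIOPResults"]


@dataclass
class GazeIOPResults:
    """Fitted results of a gaze/eyelid telemetry experiment.

    Attributes are tidy DataFrames unless noted.  ``delta_records`` has one
    row per patient x direction x eccentricity x repetition; ``anova`` is an
    :class:`~iopgaze.stats.AnovaResult`; ``posthoc`` carries the Holm-
    corrected per-direction one-sample contrasts per eccentricity.
    """

    delta_records: pd.DataFrame
    time_windows: pd.DataFrame
    group_summary: pd.DataFrame
    anova: AnovaResult | None
    posthoc: pd.DataFrame
    composites: pd.DataFrame
    composite_tests: pd.DataFrame
    control: pd.DataFrame
    individual: pd.DataFrame
    timecourse_correlation: CorrelationResult | None
    eyelid_records: pd.DataFrame
    eyelid_per_patient: pd.DataFrame
    eyelid_baseline_test: StatTestResult | None
    eyelid_vs_downgaze: StatTestResult | None
    normality: tuple[float, float] | None
    n_patients: int

    def summary(self) -> str:
        """Plain-text report of the fitted experiment."""
        lines = [
            "Gaze / eyelid IOP telemetry analysis",
            "=" * 52,
            f"patients: {self.n_patients}   "
            f"ΔIOP records: {len(self.delta_records)} "
            f"(qc-passing: {int(self.delta_records['qc_pass'].sum())})",
            "",
            "Group ΔIOP (mm Hg, mean ± SEM over patients):",
        ]
        gs = self.group_summary
        for ecc, grp in gs.groupby("eccentricity_deg"):
            cells = [
                f"{row.direction}: {row.delta_mean:+.2f}±{row.delta_sem:.2f}"
                if np.isfinite(row.delta_sem)
                else f"{row.direction}: {row.delta_mean:+.2f}"
                for row in grp.itertuples()
            ]
            lines.append(f"  {ecc:g} deg  " + "  ".join(cells))
        if self.anova is not None:
            lines += [
                "",
                "Within-subject RM-ANOVA "
                "(GG-corrected where Mauchly rejects sphericity):",
            ]
            for e in self.anova.effects:
                tag = "GG" if e.sphericity_met in (False, None) else "unc"
                lines.append(
                    f"  {e.name:<40s} F({e.df},{e.df_error}) = {e.F:7.3f}  "
                    f"eps = {e.eps:.3f}  p[{tag}] = {e.p:.4g}"
                )
        if not self.posthoc.empty:
            sig = self.posthoc[self.posthoc["reject"]]
            lines += [
                "",
                f"Holm-corrected per-direction contrasts: "
                f"{len(sig)}/{len(self.posthoc)} significant",
            ]
            for row in sig.itertuples():
                lines.append(
                    f"  {row.direction:>3s} @ {row.eccentricity_deg:g} deg: "
                    f"{row.estimate:+.2f}±{row.sem:.2f} mm Hg, "
                    f"p = {row.p:.4g} (alpha = {row.holm_threshold:.3f})"
                )
        if not self.control.empty:
            lines += ["", "Internal control (first vs last upgaze):"]
            for row in self.control.itertuples():
                lines.append(
                    f"  {row.eccentricity_deg:g} deg: {row.estimate:+.2f}±{row.sem:.2f}, "
                    f"p = {row.p:.3f}"
                )
        if self.timecourse_correlation is not None:
            c = self.timecourse_correlation
            lines += [
                "",
                f"TW_initial vs dΔIOP (condition means): R² = {c.r2:.2f}, "
                f"p = {c.p:.4g} (n = {c.n})",
            ]
        if not self.individual.empty:
            n_sig = int(self.individual["significant"].sum())
            lines += [
                "",
                f"Individual extreme-direction contrasts: {n_sig}/"
                f"{len(self.individual)} patients significant at 0.05",
            ]
        if self.eyelid_baseline_test is not None:
            r = self.eyelid_baseline_test
            lines += [
                "",
                f"Eyelid closure vs primary gaze: {r.estimate:+.2f}±{r.sem:.2f} "
                f"mm Hg, t({r.df}) = {r.statistic:.2f}, p = {r.p:.4g} (n = {r.n})",
            ]
        if self.eyelid_vs_downgaze is not None:
            r = self.eyelid_vs_downgaze
            lines.append(
                f"Eyelid closure vs downgaze (INT) at 25 deg: "
                f"{r.estimate:+.2f}±{r.sem:.2f} mm Hg, t({r.df}) = "
                f"{r.statistic:.2f}, p = {r.p:.4g}"
            )
        return "\n".join(lines)

    def to_csv(self, outdir: str | Path) -> list[Path]:
        """Write all result tables as tidy CSVs; returns the written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def write(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            df.to_csv(path, index=False)
            written.append(path)

        write(self.delta_records, "delta_iop.csv")
        write(self.time_windows, "time_windows.csv")
        write(self.group_summary, "group_summary.csv")
        if self.anova is not None:
            write(self.anova.table, "anova.csv")
        write(self.posthoc, "posthoc.csv")
        write(self.composites, "composites.csv")
        write(self.composite_tests, "composite_tests.csv")
        write(self.control, "control.csv")
        write(self.individual, "individual.csv")
        if not self.eyelid_records.empty:
            write(self.eyelid_records, "eyelid.csv")
            tests = []
            if self.eyelid_baseline_test is not None:
                r = self.eyelid_baseline_test
                tests.append(
                    dict(test="closure_vs_baseline", estimate=r.estimate,
                         sem=r.sem, t=r.statistic, df=r.df, p=r.p, n=r.n)
                )
            if self.eyelid_vs_downgaze is not None:
                r = self.eyelid_vs_downgaze
                tests.append(
                    dict(test="closure_vs_downgaze_int25", estimate=r.estimate,
                         sem=r.sem, t=r.statistic, df=r.df, p=r.p, n=r.n)
                )
            write(pd.DataFrame(tests), "eyelid_test.csv")
        return written

    def plot_group(self, ax=None):
        """Group ΔIOP profile per eccentricity (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        from .io import GAZE_DIRECTIONS

        for ecc, grp in self.group_summary.groupby("eccentricity_deg"):
            sub = grp[grp["direction"] != "Overall"].set_index("direction")
            sub = sub.reindex(list(GAZE_DIRECTIONS))
            ax.errorbar(
                range(len(sub)), sub["delta_mean"], yerr=sub["delta_sem"],
                marker="o", capsize=3, label=f"{ecc:g}°",
            )
        ax.axhline(0, color="0.6", lw=0.8)
        ax.set_xticks(range(8), GAZE_DIRECTIONS)
        ax.set_ylabel("ΔIOP (mm Hg)")
        ax.set_xlabel("gaze direction")
        ax.legend(title="eccentricity")
        return ax


class GazeIOPExperiment:
    """Continuous-IOP gaze/eyelid experiment model.

    Parameters
    ----------
    sessions : sequence of (IOPTrace, EpochSchedule)
        One pair per patient; patient identity is taken from the trace.
    trim_s : float
        Seconds trimmed from both ends of every epoch before averaging.
    min_fraction : float
        Minimum observed/expected sample fraction for a window to pass QC.
    artifact_spans : mapping patient_id -> list of (start_s, end_s)
        Declared artifact intervals (e.g. coughs) whose overlapping windows
        are excluded.
    exclude_whole_repetition : bool
        Drop a whole (eccentricity, repetition) block when any of its
        windows fails QC.
    """

    def __init__(
        self,
        sessions: Sequence[tuple[IOPTrace, EpochSchedule]],
        trim_s: float = 2.0,
        min_fraction: float = 0.5,
        artifact_spans: dict[str, Sequence[tuple[float, float]]] | None = None,
        exclude_whole_repetition: bool = False,
        alpha: float = 0.05,
    ) -> None:
        if not sessions:
            raise ValidationError("experiment needs at least one session")
        self.sessions = list(sessions)
        self.trim_s = trim_s
        self.min_fraction = min_fraction
        self.artifact_spans = artifact_spans or {}
        self.exclude_whole_repetition = exclude_whole_repetition
        self.alpha = alpha

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_files(
        cls,
        trace_paths: Sequence[str | Path],
        schedule_paths: Sequence[str | Path],
        **kwargs,
    ) -> "GazeIOPExperiment":
        if len(trace_paths) != len(schedule_paths):
            raise ValidationError("need one schedule per trace")
        sessions = [
            (read_trace(t), read_schedule(s))
            for t, s in zip(sorted(map(str, trace_paths)), sorted(map(str, schedule_paths)))
        ]
        return cls(sessions, **kwargs)

    @classmethod
    def from_simulation(
        cls, spec=None, params=None, seed: int = 0, **kwargs
    ) -> "GazeIOPExperiment":
        from .simulate import simulate_cohort

        cohort = simulate_cohort(spec, params, seed)
        return cls([(s.trace, s.schedule) for s in cohort], **kwargs)

    # -- fitting ----------------------------------------------------------

    def _session_windows(self):
        for trace, schedule in self.sessions:
            windows = segment.extract_windows(trace, schedule, self.trim_s)
            segment.qc_filter(
                windows,
                min_fraction=self.min_fraction,
                artifact_spans=self.artifact_spans.get(trace.patient_id, ()),
                exclude_whole_repetition=self.exclude_whole_repetition,
            )
            yield trace.patient_id, windows

    def fit(self) -> GazeIOPResults:
        """Run the full analysis and return a results object."""
        delta_frames, tw_frames, eyelid_frames = [], [], []
        for pid, windows in self._session_windows():
            delta_frames.append(segment.compute_delta_iop(windows, pid))
            tw_frames.append(segment.compute_time_windows(windows, pid))
            eyelid = segment.compute_eyelid_deltas(windows, pid)
            if not eyelid.empty:
                eyelid_frames.append(eyelid)
        records = pd.concat(delta_frames, ignore_index=True)
        time_windows = pd.concat(tw_frames, ignore_index=True)
        eyelid_records = (
            pd.concat(eyelid_frames, ignore_index=True)
            if eyelid_frames
            else pd.DataFrame(
                columns=[
                    "patient_id", "repetition", "ordinal", "closure_mean_last2s",
                    "baseline_mean", "delta_iop", "qc_pass",
                ]
            )
        )
        n_patients = records["patient_id"].nunique()

        group_summary = segment.aggregate_group(records)
        anova = self._fit_anova(records)
        posthoc = self._fit_posthoc(records)
        control = self._fit_control(records)
        individual = (
            stats.individual_extreme_contrast(records, alpha=self.alpha)
            if (records["eccentricity_deg"] == 25.0).any()
            else pd.DataFrame()
        )
        correlation = self._fit_timecourse_correlation(time_windows)
        normality = self._normality(records)

        composites, composite_tests = self._fit_composites(
            time_windows, eyelid_records
        )
        eyelid_pp, eyelid_base, eyelid_down = self._fit_eyelid(
            eyelid_records, composites
        )

        return GazeIOPResults(
            delta_records=records,
            time_windows=time_windows,
            group_summary=group_summary,
            anova=anova,
            posthoc=posthoc,
            composites=composites,
            composite_tests=composite_tests,
            control=control,
            individual=individual,
            timecourse_correlation=correlation,
            eyelid_records=eyelid_records,
            eyelid_per_patient=eyelid_pp,
            eyelid_baseline_test=eyelid_base,
            eyelid_vs_downgaze=eyelid_down,
            normality=normality,
            n_patients=n_patients,
        )

    # -- pieces -----------------------------------------------------------

    def _fit_anova(self, records: pd.DataFrame) -> AnovaResult | None:
        ok = records[records["qc_pass"] & ~records["is_control"]]
        if (
            ok["patient_id"].nunique() < 2
            or ok["eccentricity_deg"].nunique() < 2
            or ok["repetition"].nunique() < 2
        ):
            logger.info("skipping RM-ANOVA: design not crossed (need >=2 levels)")
            return None
        return stats.rm_anova_within(
            ok,
            dv="delta_iop",
            within=["direction", "eccentricity_deg", "repetition"],
            subject="patient_id",
        )

    def _fit_posthoc(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-direction one-sample contrasts of ΔIOP vs 0, Holm-corrected
        within each eccentricity family of eight tests."""
        per_patient = segment.per_patient_condition_means(records)
        rows = []
        for ecc, grp in per_patient.groupby("eccentricity_deg", sort=True):
            tests: list[tuple[str, StatTestResult]] = []
            for direction, sub in grp.groupby("direction", sort=False):
                vals = sub["delta_iop"].to_numpy()
                if vals.size < 2:
                    continue
                tests.append((direction, stats.one_sample_t(vals)))
            if not tests:
                continue
            holm: HolmResult = stats.holm_adjust(
                [r.p for _, r in tests], alpha=self.alpha
            )
            rank_of = np.empty(len(tests), dtype=int)
            rank_of[holm.order] = np.arange(len(tests))
            for i, (direction, res) in enumerate(tests):
                rows.append(
                    {
                        "eccentricity_deg": ecc,
                        "direction": direction,
                        "n": res.n,
                        "estimate": res.estimate,
                        "sem": res.sem,
                        "t": res.statistic,
                        "df": res.df,
                        "p": res.p,
                        "p_holm": holm.p_adjusted[i],
                        "holm_threshold": holm.thresholds_rounded[rank_of[i]],
                        "holm_threshold_exact": holm.thresholds[rank_of[i]],
                        "reject": bool(holm.reject[i]),
                    }
                )
        return pd.DataFrame(rows)

    def _fit_control(self, records: pd.DataFrame) -> pd.DataFrame:
        if not records["is_control"].any():
            logger.info("no internal-control epochs; skipping control test")
            return pd.DataFrame()
        if records["patient_id"].nunique() < 2:
            return pd.DataFrame()
        return stats.internal_control_test(records)

    def _fit_timecourse_correlation(
        self, time_windows: pd.DataFrame
    ) -> CorrelationResult | None:
        ok = time_windows[time_windows["qc_pass"] & ~time_windows["is_control"]]
        cond = ok.groupby(["direction", "eccentricity_deg"])[
            ["tw_initial", "d_delta_iop"]
        ].mean()
        if len(cond) < 3 or np.ptp(cond["tw_initial"].to_numpy()) == 0:
            return None
        return stats.linear_corr(cond["tw_initial"], cond["d_delta_iop"])

    def _normality(self, records: pd.DataFrame) -> tuple[float, float] | None:
        vals = records.loc[records["qc_pass"], "delta_iop"].to_numpy()
        try:
            return stats.normality_screen(vals)
        except ValidationError:
            return None

    def _fit_composites(
        self, time_windows: pd.DataFrame, eyelid_records: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """SNT/INT composites from last-2-s ΔIOP (TW_final), and the
        one-sample composite battery (6 composites + eyelid, Holm m=7)."""
        ok = time_windows[time_windows["qc_pass"] & ~time_windows["is_control"]]
        per_patient = (
            ok.groupby(["patient_id", "eccentricity_deg", "direction"], sort=False)[
                "tw_final"
            ]
            .mean()
            .reset_index()
        )
        composites = stats.vertical_composites(per_patient, value="tw_final")
        tests: list[dict] = []
        for ecc in sorted(composites["eccentricity_deg"].unique()):
            sub = composites[composites["eccentricity_deg"] == ecc]
            for name in ("snt", "int"):
                vals = sub[name].dropna().to_numpy()
                if vals.size < 2:
                    continue
                res = stats.one_sample_t(vals)
                tests.append(
                    dict(test=f"{ecc:g}{name.upper()}", estimate=res.estimate,
                         sem=res.sem, t=res.statistic, df=res.df, p=res.p,
                         n=res.n)
                )
        if not eyelid_records.empty:
            pp = (
                eyelid_records[eyelid_records["qc_pass"]]
                .groupby("patient_id")["delta_iop"]
                .mean()
            )
            if pp.size >= 2:
                res = stats.one_sample_t(pp.to_numpy())
                tests.append(
                    dict(test="eyelid", estimate=res.estimate, sem=res.sem,
                         t=res.statistic, df=res.df, p=res.p, n=res.n)
                )
        test_df = pd.DataFrame(tests)
        if not test_df.empty:
            holm = stats.holm_adjust(test_df["p"].to_numpy(), alpha=self.alpha)
            rank_of = np.empty(len(test_df), dtype=int)
            rank_of[holm.order] = np.arange(len(test_df))
            test_df["p_holm"] = holm.p_adjusted
            test_df["holm_threshold"] = holm.thresholds_rounded[rank_of]
            test_df["reject"] = holm.reject
        return composites, test_df

    def _fit_eyelid(
        self, eyelid_records: pd.DataFrame, composites: pd.DataFrame
    ) -> tuple[pd.DataFrame, StatTestResult | None, StatTestResult | None]:
        if eyelid_records.empty:
            return pd.DataFrame(), None, None
        pp = (
            eyelid_records[eyelid_records["qc_pass"]]
            .groupby("patient_id", as_index=False)["delta_iop"]
            .mean()
        )
        base_test = (
            stats.one_sample_t(pp["delta_iop"].to_numpy()) if len(pp) >= 2 else None
        )
        down_test = None
        subset = composites[
            composites["patient_id"].isin(pp["patient_id"])
            & (composites["eccentricity_deg"] == 25.0)
        ]
        if len(subset) == len(pp) and len(pp) >= 2:
            down_test = stats.eyelid_vs_downgaze(pp, subset, eccentricity_deg=25.0)
        return pp, base_test, down_test
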