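"""Within-subject inferential toolkit for baseline-referenced ΔIOP.

Implements, from first principles, the statistics of the gaze/eyelid
telemetry analysis:

* paired / one-sample t contrasts (two-sided),
* Bonferroni–Holm step-down familywise error control with the per-rank
  adjusted alpha thresholds ``alpha / (m - k + 1)``,
* a fully within-subjects factorial repeated-measures ANOVA (subjects as the
  random blocking factor, each fixed effect tested against its own
  subject-by-effect interaction) with per-effect Greenhouse–Geisser
  sphericity correction ``eps = tr(C)^2 / (d * tr(C^2))`` computed from the
  covariance of orthonormal within-subject contrasts,
* least-squares correlation, the SNT/INT vertical composites, the
  individual-level extreme-direction contrast, the first-vs-last upgaze
  internal control, the eyelid-vs-downgaze comparison, and a Shapiro–Wilk
  normality screen.

Only distribution tail probabilities (Student t, F) and the Shapiro–Wilk
statistic are delegated to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GAZE_DIRECTIONS, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StatTestResult",
    "HolmResult",
    "AnovaEffect",
    "AnovaResult",
    "CorrelationResult",
    "paired_t",
    "one_sample_t",
    "holm_adjust",
    "gg_epsilon",
    "rm_anova_within",
    "linear_corr",
    "vertical_composites",
    "individual_extreme_contrast",
    "internal_control_test",
    "eyelid_vs_downgaze",
    "normality_screen",
]

SNT_DIRECTIONS = ("SN", "S", "ST")
INT_DIRECTIONS = ("IT", "I", "IN")


@dataclass
class StatTestResult:
    """A t contrast: statistic, df, two-sided p, estimate ± SEM."""

    statistic: float
    df: int
    p: float
    estimate: float
    sem: float
    n: int
    note: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"t({self.df}) = {self.statistic:.3f}, p = {self.p:.4g}, "
            f"estimate = {self.estimate:.3f} ± {self.sem:.3f} (n={self.n})"
        )


@dataclass
class HolmResult:
    """Bonferroni–Holm step-down decisions for one family of p-values."""

    pvals: np.ndarray          # original order
    order: np.ndarray          # indices sorting pvals ascending
    thresholds: np.ndarray     # alpha/(m-k+1) in rank order, exact
    thresholds_rounded: np.ndarray  # same, rounded to 3 decimals (report style)
    reject: np.ndarray         # original order
    p_adjusted: np.ndarray     # original order, monotone step-down adjusted
    alpha: float


@dataclass
class AnovaEffect:
    """One within-subject effect with its subject-interaction error term.

    ``p`` is the operative p-value: Greenhouse–Geisser corrected whenever
    Mauchly's test rejects sphericity for this effect's contrasts, or when
    sphericity is untestable (singular contrast covariance, i.e. the effect
    has more contrast dimensions than subject degrees of freedom — there GG
    is always applied); uncorrected otherwise.  ``p_uncorrected`` and
    ``p_gg`` are always reported alongside.
    """

    name: str
    ss: float
    df: int
    ms: float
    ss_error: float
    df_error: int
    ms_error: float
    F: float
    eps: float
    p_uncorrected: float
    p_gg: float
    mauchly_w: float = float("nan")
    mauchly_p: float = float("nan")
    sphericity_met: bool | None = None
    p: float = float("nan")


@dataclass
class AnovaResult:
    effects: list[AnovaEffect]
    ss_subject: float
    ss_total: float
    n_subjects: int
    n_imputed: int = 0
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# t contrasts


def one_sample_t(x: Sequence[float], mu0: float = 0.0) -> StatTestResult:
    """Two-sided one-sample t-test of ``mean(x) == mu0``.

    Zero variance is flagged: infinite t when the mean differs from ``mu0``,
    t = 0 / p = 1 when it coincides.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("t-test requires n >= 2")
    mean = float(x.mean() - mu0)
    sd = float(x.std(ddof=1))
    df = n - 1
    sem = sd / np.sqrt(n)
    if sd == 0.0:
        if mean == 0.0:
            return StatTestResult(0.0, df, 1.0, mean, 0.0, n, note="zero variance")
        t = float(np.inf) if mean > 0 else float(-np.inf)
        return StatTestResult(t, df, 0.0, mean, 0.0, n, note="zero variance, infinite t")
    t = mean / sem
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return StatTestResult(float(t), df, p, mean, float(sem), n)


def paired_t(diffs: Sequence[float]) -> StatTestResult:
    """Paired t-test on precomputed pair differences (mm Hg)."""
    return one_sample_t(diffs, 0.0)


# ---------------------------------------------------------------------------
# Bonferroni–Holm


def holm_adjust(pvals: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Step-down Holm procedure over one family of m p-values.

    The k-th smallest p-value is compared with ``alpha / (m - k + 1)``; once
    a rank fails, all later ranks fail.  Thresholds are additionally
    reported rounded to three decimals, matching the convention of quoting
    the adjusted alpha in brackets next to each p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("holm_adjust: empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    thresholds = alpha / (m - ranks + 1)
    sorted_p = p[order]
    passing = sorted_p <= thresholds
    # step-down: reject the first r ranks where all of 1..r pass
    fails = np.flatnonzero(~passing)
    n_reject = int(fails[0]) if fails.size else m
    reject_sorted = ranks <= n_reject
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    p_adjusted = np.empty(m)
    p_adjusted[order] = np.minimum(
        1.0, np.maximum.accumulate((m - ranks + 1) * sorted_p)
    )
    return HolmResult(
        pvals=p,
        order=order,
        thresholds=thresholds,
        thresholds_rounded=np.round(thresholds, 3),
        reject=reject,
        p_adjusted=p_adjusted,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def gg_epsilon(contrast_cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a within-subject contrast covariance.

    ``eps = tr(C)^2 / (d * tr(C^2))`` for a symmetric PSD matrix C of size
    d = k - 1, clipped to ``[1/d, 1]``.  Equals 1 under sphericity (all
    eigenvalues equal) and 1/d in the maximally non-spherical case.
    """
    C = np.asarray(contrast_cov, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("contrast covariance must be square")
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, float(np.abs(C).max()))):
        raise ValidationError("contrast covariance must be symmetric")
    d = C.shape[0]
    tr = float(np.trace(C))
    tr2 = float(np.trace(C @ C))
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_test(contrast_cov: np.ndarray, n_subjects: int) -> tuple[float, float]:
    """Mauchly's sphericity test on a within-subject contrast covariance.

    ``W = det(C) / (tr(C)/d)^d`` with the chi-square approximation
    ``-(n-1 - (2d^2 + d + 2)/(6d)) * ln W`` on ``d(d+1)/2 - 1`` degrees of
    freedom.  Returns ``(W, p)``; ``(0, 0)`` when C is singular (sphericity
    untestable and necessarily violated in-sample, e.g. more contrast
    dimensions than subject degrees of freedom).
    """
    C = np.asarray(contrast_cov, dtype=float)
    d = C.shape[0]
    if d < 2:
        return 1.0, 1.0
    tr = float(np.trace(C))
    if tr <= 0:
        return 1.0, 1.0
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0 or d > n_subjects - 1:
        return 0.0, 0.0
    log_w = logdet - d * np.log(tr / d)
    factor = (n_subjects - 1) - (2 * d * d + d + 2) / (6.0 * d)
    chi2 = -factor * log_w
    df = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(np.exp(log_w)), p


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the mean-zero contrast space."""
    if k == 1:
        return np.zeros((0, 1))
    # Helmert-style contrasts, normalized
    M = np.zeros((k - 1, k))
    for i in range(1, k):
        M[i - 1, :i] = 1.0
        M[i - 1, i] = -i
        M[i - 1] /= np.linalg.norm(M[i - 1])
    return M


def _center(a: np.ndarray, axis: int) -> np.ndarray:
    return a - a.mean(axis=axis, keepdims=True)


def _pivot_cells(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list[str], list[list], int]:
    """Cell-mean array Y[subject, f1, ..., fm]; missing cells imputed.

    A missing cell is filled with the subject's mean over the remaining
    levels of the last factor for that combination (e.g. the patient's other
    repetitions of the same condition); cells still missing fall back to the
    across-subject mean of the cell.  The number of imputed cells is
    returned for flagging.
    """
    subjects = list(pd.unique(data[subject]))
    levels = [list(pd.unique(data[f])) for f in within]
    shape = (len(subjects), *[len(l) for l in levels])
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    s_idx = data[subject].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    f_idx = [
        data[f].map({l: i for i, l in enumerate(lv)}).to_numpy()
        for f, lv in zip(within, levels)
    ]
    vals = data[dv].to_numpy(dtype=float)
    np.add.at(sums, (s_idx, *f_idx), vals)
    np.add.at(counts, (s_idx, *f_idx), 1.0)
    with np.errstate(invalid="ignore"):
        Y = sums / counts
    n_missing = int((counts == 0).sum())
    if n_missing:
        # fill along the last factor (within-subject condition mean), then
        # with the across-subject cell mean
        with np.errstate(invalid="ignore"):
            cond_mean = np.nanmean(Y, axis=-1, keepdims=True)
            Y = np.where(np.isnan(Y), np.broadcast_to(cond_mean, Y.shape), Y)
            cell_mean = np.nanmean(Y, axis=0, keepdims=True)
            Y = np.where(np.isnan(Y), np.broadcast_to(cell_mean, Y.shape), Y)
        if np.isnan(Y).any():
            raise ValidationError("table has empty conditions that cannot be imputed")
        logger.warning("rm_anova_within: imputed %d missing cell(s)", n_missing)
    return Y, subjects, levels, n_missing


def rm_anova_within(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str,
) -> AnovaResult:
    """Fully within-subjects factorial repeated-measures ANOVA.

    Subjects are the random blocking factor; every fixed effect E (main
    effects and interactions of the ``within`` factors) is tested with
    ``F = MS_E / MS_{E x subject}``.  A Greenhouse–Geisser epsilon is
    estimated per effect from the covariance of its orthonormal
    within-subject contrasts and used to scale both degrees of freedom for
    ``p_gg`` (for 1-df effects epsilon is identically 1).
    """
    within = list(within)
    Y, subjects, levels, n_imputed = _pivot_cells(data, dv, within, subject)
    n_s = len(subjects)
    if n_s < 2:
        raise ValidationError("repeated-measures ANOVA requires >= 2 subjects")
    k = [len(l) for l in levels]
    m = len(within)
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subject = float(
        np.prod(k) * ((Y.mean(axis=tuple(range(1, m + 1))) - grand) ** 2).sum()
    )

    # flattened per-subject response vectors for the contrast covariances
    Yflat = Y.reshape(n_s, -1)

    effects: list[AnovaEffect] = []
    ss_accounted = ss_subject
    for r in range(1, m + 1):
        for combo in combinations(range(m), r):
            name = " x ".join(within[i] for i in combo)
            axes_in = [i + 1 for i in combo]
            axes_out = [i + 1 for i in range(m) if i not in combo]
            # effect deviations on the subject-averaged cell means
            eff = Y.mean(axis=tuple([0] + axes_out), keepdims=True)
            for ax in axes_in:
                eff = _center(eff, ax)
            mult = n_s * int(np.prod([k[i] for i in range(m) if i not in combo]))
            ss = float(mult * (eff ** 2).sum())
            df = int(np.prod([k[i] - 1 for i in combo]))
            # error: subject x effect interaction
            err = Y.mean(axis=tuple(axes_out), keepdims=True) if axes_out else Y.copy()
            err = _center(err, 0)
            for ax in axes_in:
                err = _center(err, ax)
            mult_e = int(np.prod([k[i] for i in range(m) if i not in combo]))
            ss_err = float(mult_e * (err ** 2).sum())
            df_err = (n_s - 1) * df
            ms = ss / df
            ms_err = ss_err / df_err
            constant = ms_err <= 1e-300
            F = float("nan") if constant else ms / ms_err
            # Greenhouse–Geisser epsilon from orthonormal contrasts
            rows = [
                _orthonormal_contrasts(k[i])
                if i in combo
                else np.full((1, k[i]), 1.0 / k[i])
                for i in range(m)
            ]
            M = rows[0]
            for rmat in rows[1:]:
                M = np.kron(M, rmat)
            Z = Yflat @ M.T  # n_s x df
            if df == 1 or n_s < 3:
                eps, mau_w, mau_p, spherical = 1.0, 1.0, 1.0, True
            else:
                C = np.atleast_2d(np.cov(Z, rowvar=False, ddof=1))
                if np.trace(C @ C) > 0:
                    eps = gg_epsilon(C)
                    mau_w, mau_p = mauchly_test(C, n_s)
                    spherical = None if mau_p == 0.0 and mau_w == 0.0 else mau_p > 0.05
                else:
                    eps, mau_w, mau_p, spherical = 1.0, 1.0, 1.0, True
            p_unc = float("nan") if constant else float(sps.f.sf(F, df, df_err))
            p_gg = (
                float("nan")
                if constant
                else float(sps.f.sf(F, eps * df, eps * df_err))
            )
            p_op = p_unc if spherical else p_gg
            effects.append(
                AnovaEffect(
                    name=name, ss=ss, df=df, ms=ms,
                    ss_error=ss_err, df_error=df_err, ms_error=ms_err,
                    F=F, eps=eps, p_uncorrected=p_unc, p_gg=p_gg,
                    mauchly_w=mau_w, mauchly_p=mau_p, sphericity_met=spherical,
                    p=p_op,
                )
            )
            ss_accounted += ss + ss_err

    table = pd.DataFrame(
        {
            "effect": [e.name for e in effects],
            "SS": [e.ss for e in effects],
            "df": [e.df for e in effects],
            "MS": [e.ms for e in effects],
            "SS_error": [e.ss_error for e in effects],
            "df_error": [e.df_error for e in effects],
            "F": [e.F for e in effects],
            "eps_GG": [e.eps for e in effects],
            "mauchly_W": [e.mauchly_w for e in effects],
            "mauchly_p": [e.mauchly_p for e in effects],
            "p_uncorrected": [e.p_uncorrected for e in effects],
            "p_GG": [e.p_gg for e in effects],
            "p": [e.p for e in effects],
        }
    )
    return AnovaResult(
        effects=effects,
        ss_subject=ss_subject,
        ss_total=ss_total,
        n_subjects=n_s,
        n_imputed=n_imputed,
        table=table,
    )


# ---------------------------------------------------------------------------
# correlation and composites


def linear_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Least-squares linear fit with R² and the slope's two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("linear_corr requires equal-length inputs, n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("linear_corr: x has zero variance")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=int(x.size),
    )


def vertical_composites(records: pd.DataFrame, value: str = "delta_iop") -> pd.DataFrame:
    """SNT / INT vertical composites per patient and eccentricity.

    SNT = mean ΔIOP over SN, S, ST (upgaze); INT = mean over IT, I, IN
    (downgaze).  A missing constituent direction flags the record rather
    than silently dropping it.
    """
    rows = []
    for (pid, ecc), grp in records.groupby(
        ["patient_id", "eccentricity_deg"], sort=True
    ):
        by_dir = grp.set_index("direction")[value]
        row = {"patient_id": pid, "eccentricity_deg": ecc}
        complete = True
        for name, dirs in [("snt", SNT_DIRECTIONS), ("int", INT_DIRECTIONS)]:
            present = [d for d in dirs if d in by_dir.index]
            row[name] = float(by_dir.loc[list(present)].mean()) if present else float("nan")
            if len(present) < len(dirs):
                complete = False
        row["complete"] = complete
        rows.append(row)
    out = pd.DataFrame(rows, columns=["patient_id", "eccentricity_deg", "snt", "int", "complete"])
    if not out.empty and not out["complete"].all():
        logger.warning(
            "vertical_composites: %d record(s) missing constituent directions",
            int((~out["complete"]).sum()),
        )
    return out


def individual_extreme_contrast(
    records: pd.DataFrame,
    eccentricity_deg: float = 25.0,
    directions: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-patient paired t between the extreme gaze directions.

    The two directions default to the group-level maximum-increase and
    maximum-decrease directions at the given eccentricity; pairs are
    repetition-matched ΔIOP values.  Patients with fewer than two matched
    repetitions are skipped with a flag.
    """
    ok = records[
        records["qc_pass"]
        & ~records["is_control"]
        & (records["eccentricity_deg"] == eccentricity_deg)
    ]
    if directions is None:
        group = ok.groupby("direction")["delta_iop"].mean()
        directions = (str(group.idxmax()), str(group.idxmin()))
    hi, lo = directions
    rows = []
    for pid, grp in ok.groupby("patient_id", sort=True):
        a = grp[grp["direction"] == hi].set_index("repetition")["delta_iop"]
        b = grp[grp["direction"] == lo].set_index("repetition")["delta_iop"]
        common = a.index.intersection(b.index)
        row = {
            "patient_id": pid, "direction_hi": hi, "direction_lo": lo,
            "n_pairs": len(common),
        }
        if len(common) < 2:
            row.update(t=np.nan, df=0, p=np.nan, estimate=np.nan,
                       significant=False, skipped=True)
        else:
            res = paired_t((a.loc[common] - b.loc[common]).to_numpy())
            row.update(
                t=res.statistic, df=res.df, p=res.p, estimate=res.estimate,
                significant=bool(res.p < alpha), skipped=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def internal_control_test(records: pd.DataFrame) -> pd.DataFrame:
    """First-vs-last upgaze contrast per eccentricity (sequential effects).

    Per patient and eccentricity the repetition-averaged ΔIOP of the opening
    superior gaze is compared with that of the closing internal-control
    superior gaze; a paired t across patients is reported per eccentricity.
    """
    s_records = records[records["qc_pass"] & (records["direction"] == "S")]
    rows = []
    for ecc, grp in s_records.groupby("eccentricity_deg", sort=True):
        first = grp[~grp["is_control"]].groupby("patient_id")["delta_iop"].mean()
        last = grp[grp["is_control"]].groupby("patient_id")["delta_iop"].mean()
        common = first.index.intersection(last.index)
        if len(common) == 0:
            raise ValidationError(
                f"internal control epoch missing at {ecc} deg"
            )
        res = paired_t((first.loc[common] - last.loc[common]).to_numpy())
        rows.append(
            {
                "eccentricity_deg": ecc, "n": res.n, "estimate": res.estimate,
                "sem": res.sem, "t": res.statistic, "df": res.df, "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def eyelid_vs_downgaze(
    eyelid: pd.DataFrame,
    composites: pd.DataFrame,
    eccentricity_deg: float = 25.0,
    use_composite: bool = True,
    single_direction_records: pd.DataFrame | None = None,
) -> StatTestResult:
    """Paired t of eyelid-closure ΔIOP against downgaze ΔIOP at one
    eccentricity, patient-matched.

    ``eyelid`` holds one row per patient (column ``delta_iop``).  By default
    the downgaze value is the INT composite (mean of IT, I, IN) from
    ``composites``; with ``use_composite=False`` the single inferior
    direction is taken from ``single_direction_records``.
    """
    eyelid_vals = eyelid.set_index("patient_id")["delta_iop"]
    if use_composite:
        sub = composites[composites["eccentricity_deg"] == eccentricity_deg]
        down = sub.set_index("patient_id")["int"]
    else:
        if single_direction_records is None:
            raise ValidationError("single-direction variant needs gaze records")
        sub = single_direction_records[
            (single_direction_records["eccentricity_deg"] == eccentricity_deg)
            & (single_direction_records["direction"] == "I")
        ]
        down = sub.groupby("patient_id")["delta_iop"].mean()
    unmatched = sorted(
        set(eyelid_vals.index).symmetric_difference(set(down.index))
    )
    if unmatched:
        raise ValidationError(
            f"eyelid and gaze patient subsets differ: unmatched {unmatched}"
        )
    common = eyelid_vals.index
    return paired_t((eyelid_vals - down.loc[common]).to_numpy())


def normality_screen(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p (advisory; the pipeline proceeds regardless)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValidationError("Shapiro–Wilk screen requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("normality screen: constant input is degenerate")
    w, p = sps.shapiro(x)
    logger.info("Shapiro–Wilk: W = %.4f, p = %.4g", w, p)
    return float(w), float(p)
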