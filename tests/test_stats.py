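"""Inferential toolkit against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from iopgaze import segment
from iopgaze import stats as igs
from iopgaze.io import ValidationError
from iopgaze.simulate import (
    DEFAULT_GAZE_OFFSETS,
    CohortSpec,
    SimulationParams,
    build_protocol,
    simulate_cohort,
    simulate_trace,
)


class TestTContrasts:
    def test_closed_form_example(self):
        res = igs.one_sample_t([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_all_zero_diffs(self):
        res = igs.paired_t(np.zeros(5))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_zero_variance_nonzero_mean_flagged_infinite(self):
        res = igs.one_sample_t([2.0, 2.0, 2.0])
        assert np.isinf(res.statistic) and res.p == 0.0 and "infinite" in res.note

    def test_paired_equals_one_sample_on_differences(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        pa = igs.paired_t(a - b)
        os = igs.one_sample_t(a - b, 0.0)
        assert pa.statistic == os.statistic and pa.p == os.p

    def test_matches_scipy(self, rng):
        x = rng.normal(0.4, 1.0, size=11)
        res = igs.one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 10  # eleven paired observations -> 10 df

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            igs.one_sample_t([1.0])


class TestHolm:
    def test_single_test_threshold(self):
        res = igs.holm_adjust([0.03])
        assert res.thresholds[0] == pytest.approx(0.05)
        assert res.reject[0]

    def test_step_down_enumeration(self):
        res = igs.holm_adjust([0.001, 0.02, 0.04])
        np.testing.assert_allclose(res.thresholds, [0.05 / 3, 0.025, 0.05])
        assert res.reject.all()

    def test_printed_rounded_thresholds_for_families_of_8_and_7(self):
        assert igs.holm_adjust([0.001] * 8).thresholds_rounded[0] == 0.006
        assert igs.holm_adjust([0.001] * 7).thresholds_rounded[0] == 0.007

    def test_step_down_stops_after_first_failure(self):
        # rank 1 passes, rank 2 fails -> later ranks fail even below threshold
        res = igs.holm_adjust([0.001, 0.04, 0.03])
        assert res.reject[0] and not res.reject[1] and not res.reject[2]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(2, 12))
            mine = igs.holm_adjust(p)
            reject, p_adj, *_ = multipletests(p, alpha=0.05, method="holm")
            np.testing.assert_allclose(mine.p_adjusted, p_adj)
            np.testing.assert_array_equal(mine.reject, reject)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_dominance_ordering(self, pvals, alpha):
        """Bonferroni rejections ⊆ Holm rejections ⊆ unadjusted rejections."""
        res = igs.holm_adjust(pvals, alpha=alpha)
        p = np.asarray(pvals)
        bonf = p <= alpha / p.size
        raw = p <= alpha
        assert np.all(res.reject[bonf])          # Holm ⊇ Bonferroni
        assert np.all(raw[res.reject])           # Holm ⊆ unadjusted
        # thresholds strictly increasing in rank when m > 1
        assert np.all(np.diff(res.thresholds) >= 0)

    def test_empty_family_rejected(self):
        with pytest.raises(ValidationError):
            igs.holm_adjust([])


class TestGGEpsilon:
    def test_one_by_one_is_unity(self):
        assert igs.gg_epsilon(np.array([[2.0]])) == 1.0

    def test_identity_is_spherical(self):
        assert igs.gg_epsilon(np.eye(5)) == 1.0

    def test_rank_one_lower_bound(self):
        assert igs.gg_epsilon(np.diag([1.0, 0.0])) == 0.5

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            igs.gg_epsilon(np.array([[1.0, 0.5], [0.0, 1.0]]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10**6))
    def test_bounds_on_random_psd(self, d, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(d, d + 2))
        C = A @ A.T
        eps = igs.gg_epsilon(C)
        assert 1.0 / d - 1e-12 <= eps <= 1.0 + 1e-12


class TestRMAnova:
    def test_f_equals_t_squared_on_two_level_designs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            table = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), 2),
                    "a": np.tile([0, 1], n),
                    "value": table.ravel(),
                }
            )
            res = igs.rm_anova_within(df, "value", ["a"], "subject")
            tres = igs.paired_t(table[:, 1] - table[:, 0])
            assert res.effects[0].F == pytest.approx(tres.statistic**2, rel=1e-9)
            assert res.effects[0].p_uncorrected == pytest.approx(tres.p, rel=1e-9)

    def test_ss_decomposition_conserves_total(self, rng):
        for _ in range(10):
            rows = [
                dict(subject=s, a=a, b=b, c=c, value=rng.normal())
                for s in range(5)
                for a in range(3)
                for b in range(2)
                for c in range(4)
            ]
            res = igs.rm_anova_within(
                pd.DataFrame(rows), "value", ["a", "b", "c"], "subject"
            )
            accounted = res.ss_subject + sum(e.ss + e.ss_error for e in res.effects)
            assert accounted == pytest.approx(res.ss_total, rel=1e-9)

    def test_three_way_f_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        rows = [
            dict(subject=s, a=a, b=b, c=c,
                 value=rng.normal() + 0.4 * a + 0.2 * a * b)
            for s in range(7)
            for a in range(4)
            for b in range(3)
            for c in range(2)
        ]
        df = pd.DataFrame(rows)
        mine = igs.rm_anova_within(df, "value", ["a", "b", "c"], "subject")
        ref = AnovaRM(df, "value", "subject", within=["a", "b", "c"]).fit().anova_table
        name_map = {
            "a": "a", "b": "b", "c": "c", "a:b": "a x b", "a:c": "a x c",
            "b:c": "b x c", "a:b:c": "a x b x c",
        }
        for ref_name, my_name in name_map.items():
            eff = mine.effect(my_name)
            assert eff.F == pytest.approx(ref.loc[ref_name, "F Value"], rel=1e-9)
            assert eff.df == int(ref.loc[ref_name, "Num DF"])
            assert eff.df_error == int(ref.loc[ref_name, "Den DF"])

    def test_one_way_matches_pingouin_including_gg(self, rng):
        import pingouin as pg

        rows = [
            dict(subject=s, a=a, value=rng.normal() + 0.3 * a + rng.normal() * (a == 2))
            for s in range(12)
            for a in range(5)
        ]
        df = pd.DataFrame(rows)
        mine = igs.rm_anova_within(df, "value", ["a"], "subject").effects[0]
        ref = pg.rm_anova(
            data=df, dv="value", within="a", subject="subject", correction=True
        ).iloc[0]
        assert mine.F == pytest.approx(ref["F"], rel=1e-9)
        assert mine.eps == pytest.approx(ref["eps"], rel=1e-9)
        assert mine.p_gg == pytest.approx(ref["p_GG_corr"], rel=1e-6)
        assert mine.mauchly_w == pytest.approx(ref["W_spher"], rel=1e-9)
        # chi-square approximations differ in order; gate decisions agree
        assert mine.mauchly_p == pytest.approx(ref["p_spher"], rel=0.2)

    def test_compound_symmetry_epsilon_near_unity(self, rng):
        """With many subjects and exchangeable covariance, eps -> 1."""
        n, k = 400, 4
        shared = rng.normal(size=(n, 1))
        y = shared + rng.normal(size=(n, k))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "a": np.tile(np.arange(k), n),
                "value": y.ravel(),
            }
        )
        eff = igs.rm_anova_within(df, "value", ["a"], "subject").effects[0]
        assert eff.eps > 0.95

    def test_constant_response_flagged(self):
        df = pd.DataFrame(
            dict(subject=[0, 0, 1, 1], a=[0, 1, 0, 1], value=[1.0, 1.0, 1.0, 1.0])
        )
        res = igs.rm_anova_within(df, "value", ["a"], "subject")
        assert res.effects[0].ss == 0.0 and np.isnan(res.effects[0].F)

    def test_single_subject_rejected(self):
        df = pd.DataFrame(dict(subject=[0, 0], a=[0, 1], value=[1.0, 2.0]))
        with pytest.raises(ValidationError):
            igs.rm_anova_within(df, "value", ["a"], "subject")

    def test_missing_cell_imputed_and_flagged(self, rng):
        rows = [
            dict(subject=s, a=a, r=r, value=rng.normal())
            for s in range(4)
            for a in range(3)
            for r in range(3)
        ]
        df = pd.DataFrame(rows[:-1])  # drop one repetition cell
        res = igs.rm_anova_within(df, "value", ["a", "r"], "subject")
        assert res.n_imputed == 1


class TestCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = igs.linear_corr(x, 2 * x + 1)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_independent_noise_low_r2(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert igs.linear_corr(x, y).r2 < 0.01

    def test_affine_invariance_of_r2(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        a = igs.linear_corr(x, y).r2
        b = igs.linear_corr(3 * x - 7, -0.5 * y + 2).r2
        assert a == pytest.approx(b)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            igs.linear_corr(np.ones(5), np.arange(5.0))


class TestComposites:
    def _frame(self, values):
        rows = []
        for d, v in values.items():
            rows.append(
                dict(patient_id="p", eccentricity_deg=25.0, direction=d,
                     delta_iop=v)
            )
        return pd.DataFrame(rows)

    def test_equal_inputs_identity(self):
        df = self._frame({d: 1.5 for d in ("SN", "S", "ST", "IT", "I", "IN")})
        out = igs.vertical_composites(df)
        assert out.snt.iloc[0] == 1.5 and out["int"].iloc[0] == 1.5

    def test_simple_arithmetic(self):
        df = self._frame({"SN": 1, "S": 2, "ST": 3, "IT": 1, "I": 2, "IN": 3})
        out = igs.vertical_composites(df)
        assert out.snt.iloc[0] == 2.0 and out["int"].iloc[0] == 2.0

    def test_group_snt_from_reported_differences(self):
        """SNT at 25 deg from the reported cells (2.9, 4.4, 2.9) is 3.4."""
        df = self._frame(
            {d: DEFAULT_GAZE_OFFSETS[(d, 25.0)] for d in ("SN", "S", "ST")}
        )
        out = igs.vertical_composites(df)
        assert out.snt.iloc[0] == pytest.approx(3.4, abs=0.05)

    def test_missing_constituent_flagged_not_dropped(self):
        df = self._frame({"SN": 1, "S": 2, "IT": 1, "I": 2, "IN": 3})
        out = igs.vertical_composites(df)
        assert len(out) == 1 and not out.complete.iloc[0]


class TestIndividualContrast:
    def _records(self, deltas_by_patient, noise_sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for pid, (d_s, d_in) in deltas_by_patient.items():
            for rep in (1, 2, 3):
                for direction, delta in (("S", d_s), ("IN", d_in)):
                    rows.append(
                        dict(patient_id=pid, direction=direction,
                             eccentricity_deg=25.0, repetition=rep,
                             delta_iop=delta + rng.normal(0, noise_sd),
                             qc_pass=True, is_control=False)
                    )
        return pd.DataFrame(rows)

    def test_identical_values_not_significant(self):
        rec = self._records({"p1": (1.0, 1.0)}, noise_sd=1e-6)
        out = igs.individual_extreme_contrast(rec, directions=("S", "IN"))
        assert out.p.iloc[0] > 0.05 and not out.significant.iloc[0]

    def test_separated_offsets_detected(self):
        rec = self._records({"p1": (4.0, -1.6)}, noise_sd=0.02)
        out = igs.individual_extreme_contrast(rec, directions=("S", "IN"))
        assert out.significant.iloc[0]

    def test_mixed_cohort_counts_separated_patients(self):
        deltas = {f"p{i}": (4.0, -1.6) for i in range(8)}
        deltas.update({f"q{i}": (1.0, 1.0) for i in range(3)})
        rec = self._records(deltas, noise_sd=0.05, seed=1)
        out = igs.individual_extreme_contrast(rec, directions=("S", "IN"))
        assert int(out.significant.sum()) == 8

    def test_auto_identifies_extreme_directions(self):
        rec = self._records({"p1": (4.0, -1.6), "p2": (4.2, -1.5)}, noise_sd=0.05)
        out = igs.individual_extreme_contrast(rec)
        assert (out.direction_hi == "S").all() and (out.direction_lo == "IN").all()

    def test_insufficient_repetitions_skipped(self):
        rec = self._records({"p1": (4.0, -1.6)}).query("repetition == 1")
        out = igs.individual_extreme_contrast(rec, directions=("S", "IN"))
        assert out.skipped.iloc[0]


class TestControlAndEyelid:
    def _cohort_records(self, params, n=11, seed=0):
        spec = CohortSpec(
            n_patients=n, n_repetitions=1, eccentricities=(25.0,), n_eyelid=0,
            offset_dispersion=0.0, response_gain_sd=0.0, baseline_sd=0.0,
        )
        frames = []
        for s in simulate_cohort(spec, params, seed):
            w = segment.extract_windows(s.trace, s.schedule)
            segment.qc_filter(w)
            frames.append(segment.compute_delta_iop(w, s.patient_id))
        return pd.concat(frames, ignore_index=True)

    def test_stable_responses_give_null_control(self):
        params = SimulationParams(spike_amp=0.0, drift_sd=0.02)
        rec = self._cohort_records(params)
        out = igs.internal_control_test(rec)
        assert out.df.iloc[0] == 10  # eleven patients
        assert abs(out.estimate.iloc[0]) < 0.3
        assert out.p.iloc[0] > 0.05

    def test_session_long_decline_detected(self):
        params = SimulationParams(spike_amp=0.0, response_decline_rate=3.0)
        rec = self._cohort_records(params)
        out = igs.internal_control_test(rec)
        assert out.estimate.iloc[0] > 0.0 and out.p.iloc[0] < 0.05

    def test_eyelid_equal_to_downgaze_null(self):
        eyelid = pd.DataFrame(
            dict(patient_id=[f"p{i}" for i in range(9)], delta_iop=[-1.0] * 9)
        )
        comp = pd.DataFrame(
            dict(patient_id=[f"p{i}" for i in range(9)],
                 eccentricity_deg=[25.0] * 9, snt=[1.0] * 9, int=[-1.0] * 9)
        )
        res = igs.eyelid_vs_downgaze(eyelid, comp)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_subset_mismatch_lists_patients(self):
        eyelid = pd.DataFrame(dict(patient_id=["p1", "p2"], delta_iop=[-1, -2]))
        comp = pd.DataFrame(
            dict(patient_id=["p1", "p3"], eccentricity_deg=[25.0, 25.0],
                 snt=[1.0, 1.0], int=[-1.0, -1.0])
        )
        with pytest.raises(ValidationError, match="p2.*p3|p3.*p2"):
            igs.eyelid_vs_downgaze(eyelid, comp)


class TestNormalityScreen:
    def test_calibrated_on_normal_draws(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=50)
            _, p = igs.normality_screen(x)
            hits += p > 0.05
        assert hits >= 90

    def test_detects_heavy_skew(self, rng):
        x = rng.exponential(size=200)
        _, p = igs.normality_screen(x)
        assert p < 0.05

    def test_constant_input_degenerate(self):
        with pytest.raises(ValidationError):
            igs.normality_screen(np.ones(20))

    def test_out_of_range_n(self):
        with pytest.raises(ValidationError):
            igs.normality_screen(np.array([1.0, 2.0]))
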