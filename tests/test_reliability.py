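"""ICC, SEM/MDC, LSI, sample-size planning, cohort summaries."""
import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from kneestab.errors import (InvalidConfigError, UndefinedIccError,
                             UndefinedLsiError)
from kneestab.reliability import (average_icc, icc_absolute_agreement,
                                  lower_median, lsi,
                                  sample_size_reliability, sem_mdc,
                                  summarize_cohort)
from kneestab.types import FeatureRecord

MATRIX_4x3 = np.array([[9, 2, 5], [6, 1, 7], [8, 4, 6], [7, 1, 2]],
                      dtype=float)


def icc_oracle(Y):
    """From-first-principles two-way ANOVA and agreement ICC (loops only)."""
    n, k = Y.shape
    grand = sum(Y[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(Y[i]) / k for i in range(n)]
    col_means = [sum(Y[:, j]) / n for j in range(k)]
    msr = k * sum((rm - grand) ** 2 for rm in row_means) / (n - 1)
    msc = n * sum((cm - grand) ** 2 for cm in col_means) / (k - 1)
    sse = sum((Y[i][j] - row_means[i] - col_means[j] + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_identical_columns_gives_one(self):
        Y = np.tile([[1.0], [5.0], [9.0], [3.0]], (1, 3))
        res = icc_absolute_agreement(Y)
        assert res.icc == pytest.approx(1.0)
        assert res.sem == 0.0 and res.mdc == 0.0

    def test_integer_matrix_matches_sums_of_squares_oracle(self):
        res = icc_absolute_agreement(MATRIX_4x3)
        assert res.icc == pytest.approx(icc_oracle(MATRIX_4x3), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pingouin_icc_a1(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(5, 2, (10, 1)) + rng.normal(0, 1, (10, 3))
        res = icc_absolute_agreement(Y)
        df = pd.DataFrame({
            "s": np.repeat(np.arange(10), 3),
            "r": np.tile(np.arange(3), 10),
            "y": Y.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row.ICC, abs=1e-9)
        assert res.p == pytest.approx(row.pval, abs=1e-9)
        lo, hi = row.CI95
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_average_measures_spearman_brown(self):
        single = icc_absolute_agreement(MATRIX_4x3)
        avg = icc_absolute_agreement(MATRIX_4x3, measures="average")
        k = 3
        assert avg.icc == pytest.approx(
            k * single.icc / (1 + (k - 1) * single.icc))

    def test_zero_total_variance_undefined(self):
        with pytest.raises(UndefinedIccError):
            icc_absolute_agreement(np.full((4, 3), 2.0))

    def test_shape_validation(self):
        with pytest.raises(InvalidConfigError):
            icc_absolute_agreement(np.zeros((1, 3)))
        with pytest.raises(InvalidConfigError):
            icc_absolute_agreement(np.zeros((4, 1)))

    @given(st.floats(-50, 50), st.floats(0.01, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_location_scale_invariance(self, shift, scale):
        base = icc_absolute_agreement(MATRIX_4x3).icc
        moved = icc_absolute_agreement(MATRIX_4x3 * scale + shift).icc
        assert moved == pytest.approx(base, abs=1e-9)

    def test_ci_brackets_estimate(self):
        res = icc_absolute_agreement(MATRIX_4x3)
        assert res.ci_low <= res.icc <= res.ci_high <= 1.0


class TestSemMdc:
    def test_perfect_reliability(self):
        assert sem_mdc(10.0, 1.0) == (0.0, 0.0)

    def test_zero_sd(self):
        assert sem_mdc(0.0, 0.3) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        sem, mdc = sem_mdc(10.0, 0.75)
        assert sem == pytest.approx(5.0)
        assert mdc == pytest.approx(13.859, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(InvalidConfigError):
            sem_mdc(-1.0, 0.5)
        with pytest.raises(InvalidConfigError):
            sem_mdc(1.0, 1.5)

    @given(st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mdc_monotone_decreasing_in_icc(self, icc1, icc2):
        lo, hi = sorted([icc1, icc2])
        assert sem_mdc(10.0, hi)[1] <= sem_mdc(10.0, lo)[1]

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mdc_monotone_increasing_in_sd(self, sd1, sd2):
        lo, hi = sorted([sd1, sd2])
        assert sem_mdc(lo, 0.5)[1] <= sem_mdc(hi, 0.5)[1]


class TestLsi:
    def test_equal_limbs(self):
        res = lsi(7.0, 7.0)
        assert res.lsi == 100.0 and res.physiological

    def test_cmj_fmax_group_means(self):
        assert round(lsi(482.0, 520.6).lsi) == 93

    def test_hop_distance_group_means(self):
        assert round(lsi(4.91, 4.94).lsi) == 99

    def test_zero_dominant_undefined(self):
        with pytest.raises(UndefinedLsiError):
            lsi(5.0, 0.0)

    def test_band_edges(self):
        assert lsi(85.0, 100.0).physiological
        assert lsi(115.0, 100.0).physiological
        assert not lsi(84.9, 100.0).physiological

    @given(st.floats(0.1, 1e3), st.floats(0.1, 1e3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_reciprocity(self, a, b):
        assert lsi(a, b).lsi * lsi(b, a).lsi == pytest.approx(1e4, rel=1e-9)


class TestSampleSize:
    def test_protocol_power_analysis(self):
        assert sample_size_reliability(0.3, 0.7, 0.05, 0.8, 3) == 16

    def test_one_sided_variant(self):
        assert sample_size_reliability(0.3, 0.7, 0.05, 0.8, 3,
                                       sided="one") == 13

    def test_wider_gap_needs_fewer_subjects(self):
        n_wide = sample_size_reliability(0.3, 0.9, 0.05, 0.8, 3)
        n_narrow = sample_size_reliability(0.3, 0.7, 0.05, 0.8, 3)
        assert n_wide < n_narrow

    def test_more_trials_need_fewer_subjects(self):
        assert sample_size_reliability(0.3, 0.7, k=2) > \
            sample_size_reliability(0.3, 0.7, k=3)

    def test_domain_error(self):
        with pytest.raises(InvalidConfigError):
            sample_size_reliability(0.7, 0.3)


def _records(task="SLS"):
    recs = []
    rng = np.random.default_rng(0)
    for s in range(6):
        for limb in ("dominant", "non-dominant"):
            base = 10 + s + (0.5 if limb == "dominant" else 0.0)
            for trial in range(3):
                recs.append(FeatureRecord(
                    subject=f"S{s}", limb=limb, task=task, trial=trial,
                    values={"x": base + rng.normal(0, 0.5)}))
    return recs


class TestSummarizeCohort:
    def test_single_trial_median_is_value(self):
        recs = [FeatureRecord(subject="S0", limb="dominant", task="SLS",
                              trial=0, values={"x": 4.2})]
        out = summarize_cohort(recs)
        assert out.medians["median"].iloc[0] == 4.2

    def test_lower_median_even_count(self):
        assert lower_median([4.0, 1.0, 3.0, 2.0]) == 2.0
        assert lower_median([5.0, 1.0, 3.0]) == 3.0

    def test_tables_cover_all_conditions(self):
        out = summarize_cohort(_records())
        assert set(out.reliability.limb) == {"dominant", "non-dominant"}
        assert len(out.lsi) == 6           # one LSI per subject
        assert out.reliability.icc.notna().all()

    def test_average_icc_of_printed_cells(self):
        """Group averages reproduce the published family-level summaries:
        0.46 for acceleration-based and 0.63 for angular-velocity-based
        hop-test parameters."""
        cells = {
            ("RMSa_foot", "dominant"): 0.45,
            ("RMSa_foot", "non-dominant"): 0.42,
            ("RMSa_leg", "dominant"): 0.72,
            ("RMSa_leg", "non-dominant"): 0.25,
            ("RMSw_foot", "dominant"): 0.63,
            ("RMSw_foot", "non-dominant"): 0.66,
            ("RMSw_leg", "dominant"): 0.63,
            ("RMSw_leg", "non-dominant"): 0.50,
            ("wpeak_foot", "dominant"): 0.70,
            ("wpeak_foot", "non-dominant"): 0.65,
            ("wpeak_leg", "dominant"): 0.60,
            ("wpeak_leg", "non-dominant"): 0.66,
        }
        df = pd.DataFrame([{"task": "CHT", "parameter": p, "limb": l,
                            "icc": v} for (p, l), v in cells.items()])
        acc = average_icc(df, ["RMSa_foot", "RMSa_leg"])
        ang = average_icc(df, ["RMSw_foot", "RMSw_leg", "wpeak_foot",
                               "wpeak_leg"])
        assert round(acc, 2) == 0.46
        assert round(ang, 2) == 0.63
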