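import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph3d import (
    classify_population,
    classify_values,
    cumulative_distribution,
    cv_levels,
    distribution_moments,
    percentile_thresholds,
    volume_density,
)


def _metrics_frame(mci_values, vol_values=None, group="control"):
    n = len(mci_values)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i % 4}" for i in range(n)],
            "cell_id": [f"c{i % 2}" for i in range(n)],
            "organelle_id": range(n),
            "group": group,
            "mci": mci_values,
            "volume_um3": vol_values if vol_values is not None else mci_values,
        }
    )


class TestThresholds:
    def test_type7_interpolation_on_1_to_100(self):
        df = _metrics_frame(np.arange(1.0, 101.0))
        thr = percentile_thresholds(df)
        assert thr.q10_mci == pytest.approx(10.9)
        assert thr.q90_mci == pytest.approx(90.1)

    def test_constant_population_is_degenerate(self):
        with pytest.raises(ValueError):
            percentile_thresholds(_metrics_frame(np.full(50, 3.0)))

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            percentile_thresholds(_metrics_frame(np.arange(5.0)))

    def test_thresholds_invariant_to_ordering(self, rng):
        vals = rng.lognormal(0, 1, size=200)
        a = percentile_thresholds(_metrics_frame(vals))
        b = percentile_thresholds(_metrics_frame(np.sort(vals)[::-1]))
        assert a == b


class TestClassification:
    def test_control_pool_classifies_exactly_10pct_simple(self, control_cohort):
        df = control_cohort.metrics
        control = df[df.group == "control"]
        thr = percentile_thresholds(control)
        classified, _, per_group = classify_population(control, thr)
        pooled = per_group.loc[per_group.group == "control"]
        assert pooled["pct_simple"].iloc[0] == pytest.approx(10.0, abs=1e-9)
        assert pooled["pct_complex"].iloc[0] == pytest.approx(10.0, abs=1e-9)

    def test_disease_cohort_recovers_generated_simple_mass(self, control_cohort):
        df = control_cohort.metrics
        thr = percentile_thresholds(df[df.group == "control"])
        _, _, per_group = classify_population(df, thr)
        disease = per_group.loc[per_group.group == "disease"]
        assert disease["pct_simple"].iloc[0] == pytest.approx(46.0, abs=4.0)

    def test_value_at_threshold_is_not_in_a_tail(self):
        out = classify_values([1.0, 5.0, 9.0], q10=1.0, q90=9.0)
        assert list(out) == ["mid", "mid", "mid"]

    def test_simple_and_complex_are_disjoint_and_sum_correctly(self, control_cohort):
        df = control_cohort.metrics
        thr = percentile_thresholds(df[df.group == "control"])
        classified, per_subject, _ = classify_population(df, thr)
        assert not ((classified.mci_class == "simple") & (classified.mci_class == "complex")).any()
        pct_mid = 100.0 - per_subject.pct_simple - per_subject.pct_complex
        assert (pct_mid >= 0).all()
        assert ((per_subject.pct_simple >= 0) & (per_subject.pct_simple <= 100)).all()


class TestCvLevels:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["subject_id", "cell_id", "v"])

    def test_constant_cell_has_zero_within_cv(self):
        df = self._frame(
            [("s1", "c1", 10.0), ("s1", "c1", 10.0), ("s1", "c1", 10.0),
             ("s1", "c2", 5.0), ("s1", "c2", 7.0), ("s2", "c1", 1.0), ("s2", "c1", 2.0)]
        )
        cv = cv_levels(df, "v")
        assert cv.within_cell[("s1", "c1")] == 0.0

    def test_between_cell_cv_hand_example(self):
        # two cells with means 1 and 3: CV = sd/mean of {1, 3} = 70.7%
        df = self._frame(
            [("s1", "c1", 0.5), ("s1", "c1", 1.5), ("s1", "c2", 2.5), ("s1", "c2", 3.5),
             ("s2", "c1", 1.0), ("s2", "c1", 1.0), ("s2", "c2", 1.0), ("s2", "c2", 1.0)]
        )
        cv = cv_levels(df, "v")
        assert cv.between_cell["s1"] == pytest.approx(70.71, abs=0.01)

    def test_singleton_cells_are_excluded_with_warning(self):
        df = self._frame(
            [("s1", "c1", 1.0), ("s1", "c1", 2.0), ("s1", "c2", 9.0),
             ("s2", "c1", 1.0), ("s2", "c1", 3.0), ("s2", "c2", 4.0), ("s2", "c2", 5.0)]
        )
        with pytest.warns(UserWarning, match="single-organelle"):
            cv = cv_levels(df, "v")
        assert ("s1", "c2") not in cv.within_cell.index

    def test_cv_is_scale_invariant(self, rng):
        rows = [
            (f"s{i}", f"c{j}", float(v))
            for i in range(3)
            for j in range(3)
            for v in rng.lognormal(0, 0.5, size=8)
        ]
        df = self._frame(rows)
        base = cv_levels(df, "v")
        scaled = df.assign(v=df.v * 37.5)
        out = cv_levels(scaled, "v")
        assert out.between_person == pytest.approx(base.between_person, rel=1e-9)
        assert np.allclose(out.within_cell, base.within_cell)

    def test_hierarchical_recovery_at_study_scale(self, control_cohort):
        # generator truth: within 0.81, cell 0.14, person 0.28 on the log
        # scale; on the natural scale the within-cell CV of a lognormal with
        # sigma = 0.81 is sqrt(exp(sigma^2) - 1) ~ 97%
        df = control_cohort.metrics
        ctrl = df[df.group == "control"]
        cv = cv_levels(ctrl, "volume_um3")
        expected_within = 100.0 * np.sqrt(np.exp(0.81**2) - 1.0)
        assert cv.within_cell.mean() == pytest.approx(expected_within, rel=0.20)


class TestDensityAndShape:
    def test_printed_control_and_patient_density_examples(self):
        assert volume_density([26.0], 1000.0) == pytest.approx(2.6)
        assert volume_density([20.0, 20.0], 1000.0) == pytest.approx(4.0)
        assert volume_density([], 1000.0) == 0.0

    def test_overfull_fiber_is_a_segmentation_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            volume_density([600.0, 500.0], 1000.0)

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(100_000)
        m = distribution_moments(x)
        assert m["skewness"] == pytest.approx(0.0, abs=0.05)
        assert m["kurtosis"] == pytest.approx(3.0, abs=0.1)
        m_excess = distribution_moments(x, kurtosis_convention="excess")
        assert m_excess["kurtosis"] == pytest.approx(m["kurtosis"] - 3.0, abs=1e-9)

    def test_exponential_sample_skewness_near_2(self, rng):
        x = rng.exponential(size=100_000)
        assert distribution_moments(x)["skewness"] == pytest.approx(2.0, abs=0.1)

    def test_moments_require_4_values(self):
        with pytest.raises(ValueError):
            distribution_moments([1.0, 2.0, 3.0])

    def test_cdf_of_three_values(self):
        cdf = cumulative_distribution([3.0, 1.0, 2.0])
        assert list(cdf.value) == [1.0, 2.0, 3.0]
        assert list(cdf.cumulative_fraction) == pytest.approx([1 / 3, 2 / 3, 1.0])

    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_cdf_is_monotone_and_ends_at_one(self, values):
        cdf = cumulative_distribution(values)
        assert (np.diff(cdf.value) >= 0).all()
        assert cdf.cumulative_fraction.iloc[-1] == pytest.approx(1.0)
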