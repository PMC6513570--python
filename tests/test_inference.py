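from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph3d import (
    chi_square_proportions,
    mann_whitney,
    nested_variance_components,
)
from mitomorph3d.synthetic import CohortSpec, generate_cohort


def brute_force_mw_p(x, y):
    """Independent oracle: exact two-sided p by full enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(sample_x, sample_y):
        return ((sample_x[:, None] > sample_y[None, :]).sum()
                + 0.5 * (sample_x[:, None] == sample_y[None, :]).sum())

    mean_u = n1 * len(y) / 2.0
    obs_dev = abs(u_of(x, y) - mean_u)
    total = extreme = 0
    idx_all = set(range(len(pooled)))
    for chosen in combinations(range(len(pooled)), n1):
        rest = sorted(idx_all - set(chosen))
        u = u_of(pooled[list(chosen)], pooled[rest])
        total += 1
        if abs(u - mean_u) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples_give_p_one(self):
        assert mann_whitney([5, 5, 5], [5, 5, 5]).p_two_sided == 1.0

    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=5),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_brute_force_enumeration(self, x, y):
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_large_shifted_lognormals_are_significant(self, rng):
        x = rng.lognormal(0.0, 0.5, size=80)
        y = rng.lognormal(1.0, 0.5, size=80)
        res = mann_whitney(x, y)
        assert res.method == "normal"
        assert res.p_two_sided < 0.001

    def test_normal_approximation_tracks_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0, 1, size=30)
        y = rng.normal(0.3, 1, size=25)
        ours = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_observed_equal_expected_gives_zero(self):
        out = chi_square_proportions([[10, 10], [10, 10]])
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        out = chi_square_proportions([[10, 20], [20, 10]])
        assert out["statistic"] == pytest.approx(20 / 3)
        assert out["df"] == 1

    def test_invariant_to_row_and_column_permutation(self):
        table = np.array([[12, 30, 8], [25, 14, 11]])
        a = chi_square_proportions(table)
        b = chi_square_proportions(table[::-1, ::-1])
        assert a["statistic"] == pytest.approx(b["statistic"])

    def test_mbi_class_counts_at_printed_proportions_differ(self, rng):
        # human-control vs mouse branching-class mixes
        human = rng.multinomial(973, [0.404, 0.505, 0.091])
        mouse = rng.multinomial(839, [0.547, 0.302, 0.151])
        out = chi_square_proportions(np.vstack([human, mouse]))
        assert out["df"] == 2
        assert out["p"] < 1e-6

    def test_zero_expected_cell_suggests_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            chi_square_proportions([[0, 10], [0, 20]])


class TestNestedVarianceComponents:
    def test_all_equal_values_give_zero_sds(self):
        subj = ["a"] * 6 + ["b"] * 6
        cell = (["c1"] * 3 + ["c2"] * 3) * 2
        fit = nested_variance_components([2.0] * 12, subj, cell)
        assert (fit.sd_person, fit.sd_cell, fit.sd_within) == (0.0, 0.0, 0.0)

    def test_matches_statsmodels_reml_oracle(self):
        import warnings

        import statsmodels.formula.api as smf

        co = generate_cohort(
            CohortSpec(n_control=4, n_disease=0, cells_per_subject=3, mitos_per_cell=12, seed=5)
        )
        d = co.metrics.copy()
        d["y"] = np.log(d.volume_um3)
        fit = nested_variance_components(
            d.volume_um3, d.subject_id, d.cell_id, log_transform=True
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm(
                "y ~ 1", d, groups=d["subject_id"], re_formula="1",
                vc_formula={"cell": "0 + C(cell_id)"},
            ).fit(reml=True)
        assert fit.sd_person**2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=0.02)
        assert fit.sd_cell**2 == pytest.approx(float(ref.vcomp[0]), rel=0.02)
        assert fit.sd_within**2 == pytest.approx(float(ref.scale), rel=0.02)

    def test_recovers_study_scale_simulation_sds(self):
        # volume components reported for healthy muscle: person 0.28,
        # cell 0.14, within 0.81 (natural-log scale), at 8 x 3 x 50
        estimates = []
        for seed in range(5):
            co = generate_cohort(CohortSpec(n_disease=0, seed=100 + seed))
            d = co.metrics
            fit = nested_variance_components(
                d.volume_um3, d.subject_id, d.cell_id, log_transform=True
            )
            estimates.append([fit.sd_person, fit.sd_cell, fit.sd_within])
        mean = np.mean(estimates, axis=0)
        for est, truth in zip(mean, (0.28, 0.14, 0.81)):
            assert est == pytest.approx(truth, rel=0.25)

    def test_doubling_within_noise_doubles_sd_within(self):
        base = generate_cohort(CohortSpec(n_disease=0, seed=3))
        loud = generate_cohort(CohortSpec(n_disease=0, vol_sd_within=1.62, seed=3))
        fits = [
            nested_variance_components(
                c.metrics.volume_um3, c.metrics.subject_id, c.metrics.cell_id, log_transform=True
            )
            for c in (base, loud)
        ]
        assert fits[1].sd_within / fits[0].sd_within == pytest.approx(2.0, rel=0.1)

    def test_single_cell_per_subject_reports_cell_inestimable(self, rng):
        subj = np.repeat([f"s{i}" for i in range(4)], 10)
        cell = np.array([f"{s}_c1" for s in subj])
        y = rng.normal(size=40) + np.repeat(rng.normal(size=4), 10)
        fit = nested_variance_components(y, subj, cell)
        assert np.isnan(fit.sd_cell)
        assert "cell_component_inestimable" in fit.flags
        assert fit.sd_within > 0

    def test_group_fixed_effect_recovers_shift(self, rng):
        subj = np.repeat([f"s{i}" for i in range(6)], 20)
        cell = np.array([f"{s}_c{i % 2}" for i, s in enumerate(subj)])
        group = np.where([int(s[1]) < 3 for s in subj], "control", "disease")
        shift = np.where(group == "disease", 1.5, 0.0)
        y = rng.normal(scale=0.3, size=120) + shift
        fit = nested_variance_components(y, subj, cell, group=group)
        eff = fit.fixed_effects["group[disease-control]"]
        assert eff["estimate"] == pytest.approx(1.5, abs=3 * eff["se"] + 0.2)

    def test_log_transform_requires_positive_values(self):
        with pytest.raises(ValueError, match="positive"):
            nested_variance_components(
                [1.0, -1.0], ["a", "b"], ["c1", "c2"], log_transform=True
            )
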