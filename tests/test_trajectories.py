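"""Adult-deviation, BH correction, mixed-model slopes and quadrant map."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neotraj.trajectories import (
    adult_deviation,
    bh_adjust,
    classify_quadrant,
    fit_longitudinal_slope,
    paired_timepoint_test,
)


def _brute_force_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    stats_all = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n)
    ]
    mean = np.mean(stats_all)
    return np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats_all])


def _brute_force_bh(p):
    """Step-up BH from the definition: q_(i) = min over j>=i of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank_idx in range(m, 0, -1):
        i = order[rank_idx - 1]
        running = min(running, m * p[i] / rank_idx)
        q[i] = min(running, 1.0)
    return q


class TestAdultDeviation:
    def test_identical_distributions_give_zero_fc_and_p_one(self):
        r = adult_deviation([4, 4, 4], [4, 4, 4], epsilon=0.0)
        assert r.log2fc == 0.0
        assert r.ranksum_p == 1.0

    def test_fourfold_elevation_gives_log2fc_two(self):
        r = adult_deviation([8, 8, 8], [2, 2, 2], epsilon=0.0)
        assert r.log2fc == pytest.approx(2.0)

    def test_p_matches_exact_enumeration(self):
        infants, adults = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        r = adult_deviation(infants, adults)
        assert r.ranksum_p == pytest.approx(
            _brute_force_ranksum_p(infants, adults)
        )  # 2/20 over all C(6,3) assignments

    def test_epsilon_defaults_to_half_smallest_positive(self):
        # infants all zero: log2((0+eps)/(2+eps)) finite with eps = 0.5
        r = adult_deviation([0.0, 0.0, 0.0], [2.0, 2.0, 1.0])
        assert np.isfinite(r.log2fc)
        assert r.log2fc == pytest.approx(np.log2(0.5 / 2.5))

    def test_all_zero_with_zero_epsilon_rejected(self):
        with pytest.raises(ValueError, match="zero denominator"):
            adult_deviation([0.0, 0.0], [0.0, 0.0], epsilon=0.0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        # ranks 1..4: 4*.01/1, 4*.02/2, 4*.03/3, 4*.04/4 -> step-up = all .04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force_and_is_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.allclose(q, _brute_force_bh(ps))
        assert np.all(q >= np.asarray(ps) - 1e-12)  # q >= p always
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


class TestLongitudinalSlope:
    @staticmethod
    def _cohort(slope, intercept_sd, noise_sd, n_subjects, n_samples, seed):
        rng = np.random.default_rng(seed)
        vals, ages, sids = [], [], []
        for i in range(n_subjects):
            t = np.arange(n_samples) * 7.0 + rng.integers(1, 8)
            y = rng.normal(0, intercept_sd) + slope * t
            y = y + rng.normal(0, noise_sd, n_samples)
            vals += list(y)
            ages += list(t)
            sids += [f"s{i}"] * n_samples
        return np.array(vals), np.array(ages), np.array(sids)

    def test_exact_line_recovered_in_any_model(self):
        vals, ages, sids = self._cohort(2.0, 0.0, 0.0, 4, 3, 0)
        for model in ("mixed", "per_subject"):
            fit = fit_longitudinal_slope(vals, ages, sids, model=model)
            assert fit.slope == pytest.approx(2.0, abs=1e-8)

    def test_per_subject_constants_give_zero_slope(self):
        vals = np.array([1.0, 1, 1, 5, 5, 5])
        ages = np.array([0.0, 7, 14, 0, 7, 14])
        sids = np.array(["a"] * 3 + ["b"] * 3)
        fit = fit_longitudinal_slope(vals, ages, sids)
        assert fit.slope == pytest.approx(0.0, abs=1e-3)

    def test_recovers_generating_slope_within_three_se(self):
        vals, ages, sids = self._cohort(0.5, 1.0, 0.5, 20, 8, 1)
        fit = fit_longitudinal_slope(vals, ages, sids)
        assert abs(fit.slope - 0.5) < 3 * fit.slope_se

    def test_ols_limit_with_zero_random_effects(self):
        # no subject heterogeneity: mixed estimate equals pooled OLS slope
        vals, ages, sids = self._cohort(0.3, 0.0, 0.4, 10, 6, 2)
        fit = fit_longitudinal_slope(vals, ages, sids)
        ols = np.polyfit(ages, vals, 1)[0]
        assert fit.slope == pytest.approx(ols, abs=5e-3)

    def test_all_ages_equal_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_longitudinal_slope([1, 2, 3, 4], [5, 5, 5, 5],
                                   ["a", "a", "b", "b"])

    def test_wald_interval_coverage_near_nominal(self):
        # 200 small cohorts: the 95% Wald interval for the fixed slope
        # should cover the generating value close to 95% of the time
        hits = 0
        for rep in range(200):
            vals, ages, sids = self._cohort(0.2, 0.8, 0.5, 12, 6, 100 + rep)
            fit = fit_longitudinal_slope(vals, ages, sids)
            hits += abs(fit.slope - 0.2) <= 1.96 * fit.slope_se
        assert 0.91 <= hits / 200 <= 0.99


class TestQuadrantMap:
    def test_four_sign_combinations(self):
        from neotraj.trajectories import AdultDeviation, SlopeFit

        cases = [
            (1.0, -0.1, "start_high_decreasing"),
            (1.0, 0.1, "start_high_increasing"),
            (-1.0, 0.1, "start_low_increasing"),
            (-1.0, -0.1, "start_low_decreasing"),
            (0.0, 0.1, "start_low_increasing"),  # tie rule: zero fc -> low
        ]
        for fc, slope, expected in cases:
            dev = AdultDeviation("p", fc, 0.5)
            fit = SlopeFit("p", slope, 0.01, 0.2, "mixed", 5, 20)
            assert classify_quadrant(dev, fit).quadrant == expected

    def test_significance_reflects_slope_p(self):
        from neotraj.trajectories import AdultDeviation, SlopeFit

        dev = AdultDeviation("p", 1.0, 0.5)
        assert classify_quadrant(
            dev, SlopeFit("p", 1.0, 0.1, 0.01, "mixed", 5, 20), alpha=0.05
        ).significant
        assert not classify_quadrant(
            dev, SlopeFit("p", 1.0, 0.1, 0.2, "mixed", 5, 20), alpha=0.05
        ).significant

    def test_invariant_to_positive_rescaling(self):
        # scaling a parameter by c > 0 shifts log2fc by 0 (ratio) and
        # scales the slope positively: the quadrant cannot change
        infants, adults = [8.0, 9, 10], [2.0, 2.5, 3]
        ages = np.array([1.0, 8, 15, 1, 8, 15])
        sids = np.array(["a"] * 3 + ["b"] * 3)
        vals = np.array([8.0, 7, 6, 9, 8, 7])
        for c in (1.0, 3.7, 0.2):
            dev = adult_deviation(np.array(infants) * c, np.array(adults) * c)
            fit = fit_longitudinal_slope(vals * c, ages, sids)
            assert classify_quadrant(dev, fit).quadrant == "start_high_decreasing"


class TestPairedTest:
    def test_identical_vectors_give_p_one(self):
        assert paired_timepoint_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_p_for_five_positive_shifts(self):
        # all five differences positive: 2 of 2^5 sign patterns as extreme
        p = paired_timepoint_test([1, 1, 1, 1, 1], [2, 3, 4, 5, 6])
        assert p == pytest.approx(0.0625)

    def test_swap_symmetry(self):
        a = [1.0, 4, 2, 8, 5, 7]
        b = [2.0, 3, 5, 6, 9, 4]
        assert paired_timepoint_test(a, b) == paired_timepoint_test(b, a)


def test_mfi_parameters_fit_on_log10_scale():
    # an MFI series growing tenfold per 10 days is linear in log10 with
    # slope 0.1/day; frequencies are fit on the raw scale
    import pandas as pd

    from neotraj.io import ClinicalRecord, CohortBundle, ImmuneMatrix
    from neotraj.trajectories import run_slope_stage

    keys, rows = [], []
    for s in ("a", "b", "c"):
        for day in (0.0, 10.0, 20.0):
            keys.append((s, day))
            rows.append([100.0 * 10 ** (day / 10.0), 5.0 + 0.2 * day])
    idx = pd.MultiIndex.from_tuples(
        keys, names=["subject_id", "postnatal_age_days"]
    )
    immune = ImmuneMatrix(
        data=pd.DataFrame(rows, index=idx, columns=["marker", "subset"]),
        kinds={"marker": "mfi", "subset": "frequency_percent"},
    )
    clinical = {
        s: ClinicalRecord(s, 200.0, "stable") for s in ("a", "b", "c")
    }
    bundle = CohortBundle(immune=immune, clinical=clinical)
    slopes, _ = run_slope_stage(bundle)
    by_param = slopes.set_index("parameter")["slope_per_day"]
    assert by_param["marker"] == pytest.approx(0.1, abs=1e-6)
    assert by_param["subset"] == pytest.approx(0.2, abs=1e-6)
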