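"""5-day bin alignment and the all-subjects consistency criterion."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neotraj.link import (
    aggregate_threshold,
    bin_align,
    consistency_criterion,
    intra_individual_correlation,
    run_link_stage,
)


def _immune(rows):
    return pd.DataFrame(rows, columns=["subject_id", "postnatal_age_days", "x"])


def _taxa(rows):
    return pd.DataFrame(rows, columns=["subject_id", "postnatal_age_days", "y"])


class TestBinAlign:
    def test_same_bin_pairs_up(self):
        out = bin_align(_immune([("a", 3.0, 1.0)]), _taxa([("a", 4.0, 2.0)]),
                        "x", "y")
        assert len(out) == 1
        assert out.loc[0, "bin_index"] == 0

    def test_half_open_bins_separate_day4_and_day5(self):
        out = bin_align(_immune([("a", 4.0, 1.0)]), _taxa([("a", 5.0, 2.0)]),
                        "x", "y")
        assert len(out) == 0

    def test_multiple_samples_in_bin_averaged(self):
        out = bin_align(
            _immune([("a", 1.0, 2.0), ("a", 3.0, 4.0)]),
            _taxa([("a", 2.0, 0.5)]),
            "x", "y",
        )
        assert out.loc[0, "immune_value"] == pytest.approx(3.0)

    def test_subjects_never_mix(self):
        out = bin_align(_immune([("a", 3.0, 1.0)]), _taxa([("b", 3.0, 2.0)]),
                        "x", "y")
        assert len(out) == 0

    def test_idempotent_rebinning(self):
        imm = _immune([("a", 1.0, 2.0), ("a", 3.0, 4.0), ("a", 11.0, 6.0)])
        tax = _taxa([("a", 2.0, 0.1), ("a", 12.0, 0.3)])
        once = bin_align(imm, tax, "x", "y")
        again = bin_align(
            once.assign(postnatal_age_days=once["bin_index"] * 5.0),
            once.assign(postnatal_age_days=once["bin_index"] * 5.0),
            "immune_value", "taxa_value",
        )
        assert np.allclose(once["immune_value"], again["immune_value"])
        assert np.allclose(once["taxa_value"], again["taxa_value"])
        assert list(once["bin_index"]) == list(again["bin_index"])


class TestIntraIndividualCorrelation:
    @staticmethod
    def _pairs(sid, values):
        return pd.DataFrame(
            {
                "subject_id": sid,
                "bin_index": range(len(values)),
                "immune_value": [v[0] for v in values],
                "taxa_value": [v[1] for v in values],
            }
        )

    def test_monotone_subject_gives_rho_one(self):
        res = intra_individual_correlation(
            self._pairs("a", [(1, 2), (2, 4), (3, 5), (4, 9)])
        )
        assert res[0][1] == pytest.approx(1.0)

    def test_four_bins_match_enumeration_oracle(self):
        vals = [(1.0, 3.0), (2.0, 1.0), (3.0, 4.0), (4.0, 2.0)]
        res = intra_individual_correlation(self._pairs("a", vals))
        _, rho, p, n = res[0]
        x = np.array([v[0] for v in vals])
        y = np.array([v[1] for v in vals])
        rho_ref = stats.spearmanr(x, y).statistic
        ry = stats.rankdata(y)
        rhos = [
            stats.pearsonr(stats.rankdata(x), np.array(perm)).statistic
            for perm in itertools.permutations(ry)
        ]
        p_ref = np.mean([abs(r) >= abs(rho_ref) - 1e-12 for r in rhos])
        assert rho == pytest.approx(rho_ref)
        assert p == pytest.approx(p_ref)

    def test_bin_order_irrelevant(self):
        vals = [(1.0, 3.0), (2.0, 1.0), (3.0, 4.0), (4.0, 2.0)]
        r1 = intra_individual_correlation(self._pairs("a", vals))
        r2 = intra_individual_correlation(self._pairs("a", vals[::-1]))
        assert r1[0][1] == pytest.approx(r2[0][1])

    def test_below_min_bins_excluded(self):
        res = intra_individual_correlation(
            self._pairs("a", [(1, 2), (2, 4), (3, 5)]), min_bins=4
        )
        assert res == []

    def test_constant_series_excluded(self):
        res = intra_individual_correlation(
            self._pairs("a", [(1, 2), (1, 4), (1, 5), (1, 9)])
        )
        assert res == []


class TestConsistencyCriterion:
    def test_all_subjects_below_alpha_flags(self):
        res = consistency_criterion(
            [("a", 0.5, 0.1, 5), ("b", 0.6, 0.15, 5), ("c", 0.4, 0.19, 5)]
        )
        assert res.significant
        assert res.mean_rho == pytest.approx(0.5)
        assert res.aggregate_alpha == pytest.approx(0.008)

    def test_one_subject_above_alpha_blocks(self):
        res = consistency_criterion([("a", 0.5, 0.1, 5), ("b", 0.6, 0.25, 5)])
        assert not res.significant

    @pytest.mark.parametrize(
        "alpha, k, expected",
        [(0.2, 3, 0.008), (0.2, 1, 0.2), (0.5, 0, 1.0), (0.1, 2, 0.01)],
    )
    def test_aggregate_threshold_is_alpha_to_the_k(self, alpha, k, expected):
        assert math.isclose(aggregate_threshold(alpha, k), expected,
                            rel_tol=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            aggregate_threshold(1.5, 3)


class TestRecovery:
    @staticmethod
    def _cohort(n_subjects, n_bins, rho, seed):
        """Subjects with a planted within-subject correlation between one
        immune parameter and one family; a second, independent pair."""
        rng = np.random.default_rng(seed)
        imm_rows, tax_rows = [], []
        r_lat = 2 * np.sin(np.pi * rho / 6)
        chol = np.linalg.cholesky([[1.0, r_lat], [r_lat, 1.0]])
        for i in range(n_subjects):
            sid = f"s{i}"
            for b in range(n_bins):
                z = chol @ rng.normal(size=2)
                day = b * 5.0 + 1.0
                imm_rows.append((sid, day, 50 + 5 * z[0], rng.normal()))
                tax_rows.append((sid, day, 0.5 + 0.1 * z[1], rng.normal()))
        imm = pd.DataFrame(imm_rows, columns=["subject_id", "postnatal_age_days",
                                              "linked", "free"])
        tax = pd.DataFrame(tax_rows, columns=["subject_id", "postnatal_age_days",
                                              "Staphylococcaceae", "other"])
        return imm, tax

    def test_planted_pair_flagged_and_decoys_not(self):
        # the every-subject gate is deliberately strict: with 10 included
        # subjects the planted correlation must be strong (rho 0.9, 12
        # matched bins each) before the pair is reliably flagged
        flagged_planted, flagged_decoy = 0, 0
        reps = 10
        for rep in range(reps):
            imm, tax = self._cohort(10, 12, rho=0.9, seed=50 + rep)
            pairs, _ = run_link_stage(
                imm, tax, ["linked", "free"], ["Staphylococcaceae", "other"]
            )
            pairs = pairs.set_index(["immune_parameter", "taxa_family"])
            if pairs.loc[("linked", "Staphylococcaceae"), "significant"]:
                flagged_planted += 1
            others = pairs.drop(index=("linked", "Staphylococcaceae"))
            flagged_decoy += int(others["significant"].sum())
        assert flagged_planted >= 9  # planted association recovered
        assert flagged_decoy == 0  # independent pairs stay silent

    def test_global_null_false_flag_rate_bounded(self):
        # no associations anywhere: flag rate over many pairs must stay
        # below alpha^k plus Monte-Carlo slack
        rng = np.random.default_rng(99)
        n_subjects, n_bins, n_pairs = 3, 8, 200
        flags = 0
        for _ in range(n_pairs):
            rows = []
            for i in range(n_subjects):
                for b in range(n_bins):
                    rows.append((f"s{i}", b * 5.0 + 1, rng.normal(), rng.normal()))
            imm = pd.DataFrame(rows, columns=["subject_id", "postnatal_age_days",
                                              "x", "drop1"])
            tax = pd.DataFrame(rows, columns=["subject_id", "postnatal_age_days",
                                              "drop2", "y"])
            binned = bin_align(imm, tax, "x", "y")
            per = intra_individual_correlation(binned)
            flags += consistency_criterion(per).significant
        bound = aggregate_threshold(0.2, n_subjects)
        mc_sd = math.sqrt(bound * (1 - bound) / n_pairs)
        assert flags / n_pairs <= bound + 3 * mc_sd
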