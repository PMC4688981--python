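"""Experiment driver and statistics: arms, summaries, tests, sample size."""

import math

import numpy as np
import pytest

from morphatlas import (
    ExperimentConfig,
    FusionConfig,
    GroupSummary,
    PropagationCache,
    SyntheticConfig,
    enumerate_random_combinations,
    equivalence_ladder,
    equivalence_test,
    generate_database,
    independent_t_test,
    pick_reference_k,
    run_full_experiment,
    run_random_arm,
    run_selected_arm,
    sample_size_two_means,
    summarize,
)


class TestCombinationEnumeration:
    def test_all_pairs_of_eleven(self):
        ids = [f"a{i:02d}" for i in range(11)]
        combos = enumerate_random_combinations(ids, 2, limit="all")
        assert len(combos) == 55  # C(11, 2)
        assert len(set(combos)) == 55

    def test_k_equals_n_gives_single_subset(self):
        ids = ["a", "b", "c"]
        assert enumerate_random_combinations(ids, 3) == [frozenset(ids)]

    def test_seeded_sampling_is_repeatable_and_distinct(self):
        ids = [f"a{i:02d}" for i in range(11)]
        first = enumerate_random_combinations(ids, 3, limit=10, seed=42)
        second = enumerate_random_combinations(ids, 3, limit=10, seed=42)
        assert first == second
        assert len(set(first)) == 10

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            enumerate_random_combinations(["a", "b"], 3)


@pytest.fixture(scope="module")
def tiny_db():
    cfg = SyntheticConfig(
        n_atlases=5, grid_shape=(32, 32, 32),
        protraction_range_mm=(20.0, 42.0), seed=7,
    )
    return cfg, generate_database(cfg)


class TestArms:
    def test_selected_arm_record_count_and_shape(self, tiny_db):
        cfg, db = tiny_db
        records = run_selected_arm(db, k_values=(2,), synthetic_config=cfg)
        assert len(records) == 5  # one per patient
        for r in records:
            assert r.strategy == "selected"
            assert len(r.combination) == 2
            assert r.patient_id not in r.combination

    def test_zero_error_registration_gives_perfect_dsc(self):
        cfg = SyntheticConfig(
            n_atlases=4, grid_shape=(32, 32, 32),
            protraction_range_mm=(20.0, 42.0), seed=3,
            error_base_mm=0.0, error_slope=0.0,
        )
        db = generate_database(cfg)
        records = run_selected_arm(db, k_values=(2, 3), synthetic_config=cfg)
        assert all(r.scores.dsc == 1.0 for r in records)

    def test_random_arm_full_enumeration_count(self, tiny_db):
        cfg, db = tiny_db
        records = run_random_arm(
            db, k_values=(2,), limit="all", synthetic_config=cfg
        )
        assert len(records) == 5 * math.comb(4, 2)  # 30

    def test_random_arm_seeded_repeatability(self, tiny_db):
        cfg, db = tiny_db
        a = run_random_arm(db, k_values=(2,), limit=3, seed=5, synthetic_config=cfg)
        b = run_random_arm(db, k_values=(2,), limit=3, seed=5, synthetic_config=cfg)
        assert [(r.patient_id, r.combination, r.scores) for r in a] == [
            (r.patient_id, r.combination, r.scores) for r in b
        ]

    def test_too_small_database_rejected(self, tiny_db):
        cfg, db = tiny_db
        with pytest.raises(ValueError):
            run_selected_arm(db, k_values=(5,), synthetic_config=cfg)

    def test_arms_coincide_at_k_equals_n_minus_one(self, tiny_db):
        """With k = n-1 both arms use the unique remaining combination."""
        cfg, db = tiny_db
        registration_seed = 3
        selected = run_selected_arm(
            db, k_values=(4,), synthetic_config=cfg, seed=registration_seed
        )
        random = run_random_arm(
            db, k_values=(4,), limit="all", synthetic_config=cfg,
            seed=registration_seed,
        )
        sel = {r.patient_id: r.scores for r in selected}
        ran = {r.patient_id: r.scores for r in random}
        assert sel == ran


class TestSummarize:
    def _record(self, dsc, patient="p", k=2, strategy="selected"):
        from morphatlas import RunRecord, SimilarityScores

        return RunRecord(
            patient_id=patient, k=k, strategy=strategy,
            combination=frozenset(("a", "b")),
            scores=SimilarityScores(dsc=dsc, ji=dsc / 2, ini=dsc),
        )

    def test_hand_computed_mean_and_sd(self):
        values = [0.5, 0.6, 0.7, 0.8]
        records = [self._record(v) for v in values]
        (summary,) = summarize(records)
        mean = sum(values) / 4
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 3)
        assert summary.dsc_mean == pytest.approx(mean)
        assert summary.dsc_sd == pytest.approx(sd)
        assert summary.n_runs == 4

    def test_single_record_flags_undefined_sd(self):
        (summary,) = summarize([self._record(0.42)])
        assert summary.dsc_mean == pytest.approx(0.42)
        assert summary.dsc_sd == 0.0
        assert not summary.sd_defined

    def test_equal_scores_give_zero_sd(self):
        (summary,) = summarize([self._record(0.5), self._record(0.5)])
        assert summary.dsc_sd == 0.0
        assert summary.sd_defined


class TestTTest:
    def test_welch_against_hand_formula(self):
        a = [0.9, 0.8, 0.85]
        b = [0.5, 0.55, 0.45]
        t, p, diff = independent_t_test(a, b)
        ma, mb = np.mean(a), np.mean(b)
        se = math.sqrt(np.var(a, ddof=1) / 3 + np.var(b, ddof=1) / 3)
        assert t == pytest.approx((ma - mb) / se, rel=1e-12)
        assert diff == pytest.approx(ma - mb)
        assert p < 0.05

    def test_identical_degenerate_groups(self):
        t, p, diff = independent_t_test([0.5, 0.5], [0.5, 0.5])
        assert (t, p, diff) == (0.0, 1.0, 0.0)

    def test_swapping_groups_flips_signs_only(self):
        a, b = [0.9, 0.7, 0.82], [0.6, 0.64, 0.5]
        t1, p1, d1 = independent_t_test(a, b)
        t2, p2, d2 = independent_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            independent_t_test([0.5], [0.4, 0.6])


class TestEquivalence:
    def test_identical_groups_equivalent_when_ci_fits(self):
        group = [0.60, 0.58, 0.62, 0.61, 0.59, 0.60]
        result = equivalence_test(group, list(group), margin_mode="relative")
        assert result.mean_difference == 0.0
        assert result.ci_low == pytest.approx(-result.ci_high)
        assert result.margin == pytest.approx(0.06, rel=1e-6)
        assert result.equivalent

    def test_relative_margin_is_fraction_of_reference_mean(self):
        ref = [0.598] * 5
        comp = [0.58, 0.60, 0.59, 0.61, 0.60]
        result = equivalence_test(ref, comp, margin_mode="relative", margin_value=0.10)
        assert result.margin == pytest.approx(0.0598)

    def test_shift_of_twice_margin_not_equivalent(self):
        ref = [0.6000, 0.6001, 0.5999, 0.6000]
        comp = [v - 0.12 for v in ref]  # 2x the 10%-relative margin
        result = equivalence_test(ref, comp)
        assert not result.equivalent
        assert result.ci_low > result.margin

    def test_absolute_margin_mode(self):
        ref = [0.6, 0.61, 0.59]
        comp = [0.55, 0.56, 0.54]
        result = equivalence_test(
            ref, comp, margin_mode="absolute", margin_value=0.2
        )
        assert result.margin == 0.2
        assert result.equivalent

    def test_ci_brackets_the_mean_difference(self):
        result = equivalence_test([0.7, 0.6, 0.65], [0.5, 0.52, 0.48])
        assert result.ci_low <= result.mean_difference <= result.ci_high


class TestReferenceK:
    def _summary(self, k, dsc, strategy="selected"):
        return GroupSummary(
            strategy=strategy, k=k, n_runs=12,
            dsc_mean=dsc, dsc_sd=0.1, ji_mean=0.0, ji_sd=0.0,
            ini_mean=0.0, ini_sd=0.0,
        )

    def test_highest_mean_dsc_wins(self):
        summaries = [
            self._summary(k, m)
            for k, m in [(2, 0.44), (5, 0.57), (6, 0.598), (7, 0.593)]
        ]
        assert pick_reference_k(summaries) == 6

    def test_random_arm_ignored(self):
        summaries = [
            self._summary(6, 0.5),
            self._summary(3, 0.9, strategy="random"),
        ]
        assert pick_reference_k(summaries) == 6

    def test_tie_prefers_fewer_atlases(self):
        summaries = [self._summary(5, 0.6), self._summary(6, 0.6)]
        assert pick_reference_k(summaries) == 5

    def test_single_k(self):
        assert pick_reference_k([self._summary(4, 0.5)]) == 4


class TestSampleSize:
    def test_unit_case_closed_form(self):
        # 2 * (z_0.95 + z_0.80)^2 = 2 * (1.6449 + 0.8416)^2 = 12.37 -> 13
        assert sample_size_two_means(sd=1.0, delta=1.0) == 13

    def test_doubling_delta_quarters_n(self):
        n1 = sample_size_two_means(sd=0.2, delta=0.05)
        n2 = sample_size_two_means(sd=0.2, delta=0.10)
        assert n1 / n2 == pytest.approx(4.0, rel=0.15)

    def test_monotone_decreasing_in_delta(self):
        sizes = [
            sample_size_two_means(sd=0.15, delta=d)
            for d in (0.02, 0.05, 0.1, 0.2)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_means(sd=1.0, delta=0.0)
        with pytest.raises(ValueError):
            sample_size_two_means(sd=0.0, delta=1.0)


def test_full_experiment_consistency(tiny_db):
    """End-to-end on a small database: counts, shared cache, ladder shape."""
    cfg, db = tiny_db
    result = run_full_experiment(
        db,
        synthetic_config=cfg,
        experiment_config=ExperimentConfig(
            k_values=(2, 3), random_limit=2, seed=9
        ),
    )
    assert len(result.selected) == 5 * 2
    assert len(result.random) == 5 * 2 * 2
    ks = sorted({s.k for s in result.summaries})
    assert ks == [2, 3]
    assert result.reference_k in (2, 3)
    assert set(result.t_tests) == {"dsc", "ji", "ini"}
    comparison_ks = [e.comparison_k for e in result.equivalence]
    assert comparison_ks == [k for k in (2, 3) if k != result.reference_k]
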