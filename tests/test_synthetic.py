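"""Generators: doping statistics, selection survival, time courses, fixtures."""

import numpy as np
import pytest
from scipy import stats

from clickselex import (
    ActivityModel,
    LibrarySpec,
    SelectionSchedule,
    TimeCourse,
    generate_doped_pool,
    generate_gel_fixture,
    generate_time_course,
    original_schedule,
    reselection_schedule,
    simulate_selection,
    simulate_selection_round,
)
from clickselex.pools import Pool, sequence_matrix
from clickselex.quantification import circ_metrics, lig_percent

NINE_TIMEPOINTS = [4, 8, 12, 18, 24, 36, 48, 60, 72]


class TestLibrarySpec:
    def test_default_layout(self, spec):
        assert len(spec.reference_sequence) == 82
        assert spec.doped_length == 40
        assert spec.doped_interval == (21, 61)
        assert spec.mutation_rate == 0.45

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"doped_interval": (10, 50)},  # overlaps 5' PBS
            {"doped_interval": (21, 82)},  # overlaps 3' PBS
            {"mutation_rate": 1.5},
            {"reference_sequence": "ACGU" * 20 + "AC"},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LibrarySpec(**kwargs)


class TestDopedPool:
    def test_zero_rate_reproduces_reference(self, spec):
        zero = LibrarySpec(mutation_rate=0.0)
        pool = generate_doped_pool(zero, 50, seed=0)
        assert all(r.sequence == zero.reference_sequence for r in pool)

    def test_flanks_never_mutated(self, spec):
        pool = generate_doped_pool(spec, 500, seed=1)
        ref = spec.reference_sequence
        for rec in pool:
            assert rec.sequence[:21] == ref[:21]
            assert rec.sequence[61:] == ref[61:]

    def test_per_position_mutation_rate(self, spec):
        """Every doped position mutates at ~45% (binomial CI, n=20000)."""
        n = 20000
        pool = generate_doped_pool(spec, n, seed=2)
        matrix = sequence_matrix(pool.sequences())
        ref = np.frombuffer(spec.reference_sequence.encode(), np.uint8)
        start, end = spec.doped_interval
        mismatch = (matrix[:, start:end] != ref[start:end]).mean(axis=0)
        # ~4.5 sigma two-sided bound per position, 40 positions
        half_width = 4.5 * np.sqrt(0.45 * 0.55 / n)
        assert np.all(np.abs(mismatch - 0.45) < half_width)
        # and the pool-wide mean within 3 Monte-Carlo SEs of the mean
        se_mean = np.sqrt(0.45 * 0.55 / (n * spec.doped_length))
        assert abs(mismatch.mean() - 0.45) < 3 * se_mean

    def test_replacement_bases_uniform(self, spec):
        """Non-reference replacements are uniform over the 3 alternatives."""
        pool = generate_doped_pool(spec, 20000, seed=3)
        matrix = sequence_matrix(pool.sequences())
        ref = np.frombuffer(spec.reference_sequence.encode(), np.uint8)
        start, end = spec.doped_interval
        worst_p = 1.0
        for j in range(start, end):
            col = matrix[:, j]
            alternatives = [b for b in b"ACGT" if b != ref[j]]
            observed = [(col == b).sum() for b in alternatives]
            _, p = stats.chisquare(observed)
            worst_p = min(worst_p, p)
        # Bonferroni-ish: no column wildly non-uniform
        assert worst_p > 0.001 / 40

    def test_fully_wildtype_sequence_essentially_never(self, spec):
        """P(no mutation) = 0.55^40 ~ 4e-11, so none in 1e5 draws."""
        pool = generate_doped_pool(spec, 100_000, seed=4)
        assert 0.55**40 < 1e-10
        assert spec.reference_sequence not in set(pool.sequences())

    def test_seed_reproducibility(self, spec):
        a = generate_doped_pool(spec, 200, seed=7)
        b = generate_doped_pool(spec, 200, seed=7)
        assert a.sequences() == b.sequences()

    def test_invalid_n_rejected(self, spec):
        with pytest.raises(ValueError):
            generate_doped_pool(spec, 0, seed=0)


class TestSelectionRound:
    def test_halflife_survival(self, spec):
        """Homogeneous pool at kt = ln 2 survives at ~50% (closed form)."""
        k = 0.5
        t = np.log(2) / k
        pool = Pool.from_sequences([spec.reference_sequence] * 20000)
        model = ActivityModel(required_bases={}, k_max=k)
        _, frac = simulate_selection_round(pool, model, t, seed=0)
        se = np.sqrt(0.25 / 20000)
        assert abs(frac - 0.5) < 4 * se

    def test_penalty_free_uniform_survival(self, spec):
        """mismatch_penalty=1 makes survival independent of sequence."""
        pool = generate_doped_pool(spec, 20000, seed=1)
        model = ActivityModel.from_reference(spec, [24, 30, 40], k_max=0.2,
                                             mismatch_penalty=1.0)
        survivors, frac = simulate_selection_round(pool, model, 5.0, seed=2)
        expected = 1 - np.exp(-0.2 * 5.0)
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / 20000)
        # survivor mismatch rate unchanged at constrained positions
        matrix = sequence_matrix(survivors.sequences())
        ref = np.frombuffer(spec.reference_sequence.encode(), np.uint8)
        rate = (matrix[:, 23] != ref[23]).mean()
        assert abs(rate - 0.45) < 0.02

    def test_vanishing_time_vanishing_ligation(self, spec):
        pool = Pool.from_sequences([spec.reference_sequence] * 5000)
        model = ActivityModel(required_bases={}, k_max=0.5)
        _, frac = simulate_selection_round(pool, model, 1e-6, seed=0)
        assert frac < 0.001

    def test_errors(self, spec):
        model = ActivityModel(required_bases={}, k_max=0.5)
        with pytest.raises(ValueError):
            simulate_selection_round(Pool([]), model, 1.0, seed=0)
        pool = Pool.from_sequences([spec.reference_sequence])
        with pytest.raises(ValueError):
            simulate_selection_round(pool, model, 0.0, seed=0)


class TestSelectionTrajectory:
    def test_schedules_match_stringency_pattern(self):
        assert [r.reaction_time for r in reselection_schedule().rounds] == [
            8.0, 8.0, 8.0, 8.0, 6.0, 3.0, 1.5,
        ]
        assert [r.reaction_time for r in original_schedule().rounds] == [
            8.0] * 6 + [4.0] * 2 + [2.0] * 3

    def test_penalty_free_trajectory_flat(self, spec):
        model = ActivityModel(required_bases={}, k_max=0.3, mismatch_penalty=1.0)
        schedule = SelectionSchedule.from_times([2.0] * 4, pool_size=20000)
        result = simulate_selection(spec, model, schedule, seed=3)
        expected = 1 - np.exp(-0.3 * 2.0)
        for frac in result.trajectory:
            assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / 20000)

    def test_enrichment_mean_rate_nondecreasing(self, spec):
        """Selection enriches activity; first-round survival matches the
        brute-force expectation E[1 - exp(-r_i t)] on a small pool."""
        model = ActivityModel.from_reference(spec, [24, 28, 33, 38],
                                             k_max=0.5, mismatch_penalty=0.2)
        schedule = SelectionSchedule.from_times([8.0] * 5, pool_size=2000)
        result = simulate_selection(spec, model, schedule, seed=11)
        assert result.status == "completed"
        assert result.trajectory == sorted(result.trajectory)

        small = generate_doped_pool(spec, 100, seed=12)
        expected = np.mean(
            [1 - np.exp(-model.rate(s) * 8.0) for s in small.sequences()]
        )
        fracs = [
            simulate_selection_round(small, model, 8.0, seed=s)[1]
            for s in range(200)
        ]
        assert abs(np.mean(fracs) - expected) < 0.01

    def test_extinct_pool_truncates(self, spec):
        model = ActivityModel(required_bases={}, k_max=1e-6)
        schedule = SelectionSchedule.from_times([0.001] * 5, pool_size=50)
        result = simulate_selection(spec, model, schedule, seed=0)
        assert result.status == "pool extinct"
        assert len(result.trajectory) < 5
        assert len(result.final_pool) == 0


class TestTimeCourse:
    def test_noiseless_asymptote_and_halflife(self):
        k, ymax = 0.1, 80.0
        tc = generate_time_course(k, ymax, [np.log(2) / k, 500.0], 0.0, seed=0)
        assert tc.ligation_percent[0] == pytest.approx(ymax / 2)
        assert tc.ligation_percent[1] == pytest.approx(ymax, abs=1e-6)

    def test_printed_parameter_evaluation(self):
        """76 * (1 - exp(-0.027*72)) ~ 65.1 at the last timepoint."""
        tc = generate_time_course(0.027, 76.0, NINE_TIMEPOINTS, 0.0, seed=0)
        assert tc.ligation_percent[-1] == pytest.approx(65.1221, abs=1e-3)

    def test_noise_clipped_and_seeded(self):
        a = generate_time_course(0.027, 76.0, NINE_TIMEPOINTS, 1.5, seed=9)
        b = generate_time_course(0.027, 76.0, NINE_TIMEPOINTS, 1.5, seed=9)
        assert a == b
        assert all(0 <= y <= 100 for y in a.ligation_percent)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_time_course(0.0, 76.0, [1, 2, 3], 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_time_course(0.1, 76.0, [1, 1, 3], 0.0, seed=0)
        with pytest.raises(ValueError):
            TimeCourse((1.0, 2.0), (10.0,))


class TestGelFixture:
    def test_two_band_symmetry(self):
        bands = generate_gel_fixture("two-band", {"lig_percent": 50.0}, seed=0)
        assert bands["lig"] == pytest.approx(bands["unlig"])
        assert lig_percent(bands["lig"], bands["unlig"]) == pytest.approx(50.0)

    def test_three_band_back_solve(self):
        """Targets Y=33, S=97 back-solve to CP=33, LLP~1.02, unlig~65.98."""
        bands = generate_gel_fixture("three-band", {"Y": 33.0, "S": 97.0}, seed=1)
        total = sum(bands.values())
        assert bands["CP"] / total * 100 == pytest.approx(33.0, abs=0.1)
        assert bands["LLP"] / total * 100 == pytest.approx(1.0206, abs=0.01)
        assert bands["unlig"] / total * 100 == pytest.approx(65.979, abs=0.01)
        y, s = circ_metrics(bands["unlig"], bands["CP"], bands["LLP"])
        assert y == pytest.approx(33.0, abs=0.1)
        assert s == pytest.approx(97.0, abs=0.1)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            generate_gel_fixture("three-band", {"Y": 97.0, "S": 33.0}, seed=0)
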