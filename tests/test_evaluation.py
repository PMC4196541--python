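"""Accuracy summaries, chance bounds, sweep and greedy selection."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from adaptbci.engine import AdaptiveConfig, TrialRecord, run_session
from adaptbci.evaluation import (
    AccuracyTimecourse,
    SweepResult,
    accuracy_timecourse,
    chance_level,
    median_accuracy,
    peak_accuracy,
    run_channel_sweep,
    select_channels,
    select_classes,
    separability_map,
)
from adaptbci.features import DEFAULT_BANDS
from adaptbci.montage import ElectrodeGrid, derivations_overlap, make_derivation, parse_derivation
from adaptbci.preprocessing import TrialTiming
from adaptbci.synthetic import generate_session

from conftest import small_spec


def _result_from_table(correct_rows, pair=("A", "B")):
    """Build a minimal AdaptiveSessionResult-like object from a correctness
    table (trials x timepoints)."""
    from adaptbci.engine import AdaptiveSessionResult

    records = []
    for i, row in enumerate(correct_rows):
        rec = TrialRecord(i, pair[1], in_scope=True)
        rec.pair = pair
        rec.pred01 = np.asarray(row, dtype=np.int8)  # true label = pair[1] -> 1
        records.append(rec)
    return AdaptiveSessionResult(
        records=records,
        models=[],
        selected_pair=pair,
        timing=TrialTiming(),
        first_valid_sample=255,
    )


class TestAccuracyTimecourse:
    def test_all_correct_is_flat_one(self):
        res = _result_from_table(np.ones((3, 100)))
        tc = accuracy_timecourse(res)
        assert np.all(tc.accuracy == 1.0) and tc.n_trials == 3

    def test_half_correct_is_flat_half(self):
        res = _result_from_table(np.vstack([np.ones(50), np.zeros(50)]))
        tc = accuracy_timecourse(res)
        assert np.all(tc.accuracy == 0.5)

    def test_hand_built_three_trial_table(self):
        rows = np.array([[1, 1, 0, 0], [1, 0, 0, 1], [1, 1, 1, 1]])
        tc = accuracy_timecourse(_result_from_table(rows))
        np.testing.assert_allclose(tc.accuracy, [1.0, 2 / 3, 1 / 3, 2 / 3])

    def test_zero_evaluated_trials_is_an_error(self):
        with pytest.raises(ValueError, match="no evaluated"):
            accuracy_timecourse(_result_from_table(np.empty((0, 4))))


class TestWindowSummaries:
    def _tc(self, acc):
        times = 4.0 + np.arange(len(acc)) / 256.0
        return AccuracyTimecourse(times, np.asarray(acc), n_trials=10)

    def test_constant_curve(self):
        tc = self._tc([0.8] * 1024)
        assert median_accuracy(tc) == 0.8
        assert peak_accuracy(tc) == 0.8

    def test_linear_ramp_peak_is_last_value(self):
        ramp = np.linspace(0.5, 1.0, 1024)
        tc = self._tc(ramp)
        assert peak_accuracy(tc) == ramp[-1]
        assert median_accuracy(tc) == pytest.approx(0.75, abs=1e-3)

    def test_peak_never_below_median_on_random_curves(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tc = self._tc(rng.random(64))
            assert peak_accuracy(tc) >= median_accuracy(tc)

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            median_accuracy(self._tc([0.5] * 10), window=(9.0, 10.0))


class TestChanceLevel:
    def test_sixty_trials_binary_is_two_thirds(self):
        assert chance_level(60, 2, 0.01) == pytest.approx(40 / 60)

    def test_alpha_near_one_approaches_prior(self):
        # the bound converges to 1/n_classes from below at rate ~sqrt(p q / n)
        assert chance_level(20000, 2, 0.999) == pytest.approx(0.5, abs=0.02)
        assert chance_level(20001, 3, 0.999) == pytest.approx(1 / 3, abs=0.02)

    @pytest.mark.parametrize("n", [20, 60, 100])
    def test_matches_exact_tail_summation_oracle(self, n):
        # oracle: exact rational binomial tail, no scipy
        def tail(k):
            return sum(
                Fraction(math.comb(n, j), 2**n) for j in range(k, n + 1)
            )

        expected = next(k for k in range(n + 1) if tail(k) <= Fraction(1, 100)) / n
        assert chance_level(n, 2, 0.01) == pytest.approx(expected)

    def test_monotone_in_trials_and_alpha(self):
        grid = [10, 20, 40, 80, 160]
        bounds = [chance_level(n, 2, 0.01) for n in grid]
        assert all(a >= b for a, b in zip(bounds, bounds[1:]))
        alphas = [0.2, 0.05, 0.01, 0.001]
        bounds_a = [chance_level(60, 2, a) for a in alphas]
        assert all(a <= b for a, b in zip(bounds_a, bounds_a[1:]))


@pytest.fixture(scope="module")
def toy_sweep_inputs(small_grid):
    """A 28-trial session on the 4-electrode grid, two derivations."""
    session, _ = generate_session(small_spec(seed=60))
    derivs = [
        parse_derivation(small_grid, "FCz-CPz"),
        parse_derivation(small_grid, "P1-P2"),
    ]
    return session, derivs


class TestSweep:
    def test_cells_match_standalone_engine_runs(self, toy_sweep_inputs):
        session, derivs = toy_sweep_inputs
        sweep = run_channel_sweep(session, derivs, [("Hand", "Word")])
        assert len(sweep.cells) == 2
        for d in derivs:
            cfg = AdaptiveConfig(mode="mini", derivations=(d,), classes=("Hand", "Word"))
            res = run_session(session, cfg)
            expected = median_accuracy(accuracy_timecourse(res))
            assert sweep.cell(d.name, ("Hand", "Word")) == pytest.approx(expected)

    def test_five_classes_give_ten_pairs_per_derivation(self, small_grid):
        session, _ = generate_session(
            small_spec(seed=61, classes=("A", "B", "C", "D", "E"),
                       effect_matrix={}, runs=1, trials_per_class_per_run=4)
        )
        derivs = [parse_derivation(small_grid, "FCz-CPz")]
        sweep = run_channel_sweep(session, derivs)
        assert len(sweep.cells) == 10

    def test_erd_derivation_tops_ranking(self, toy_sweep_inputs):
        # Hand's ERD lives at FCz: FCz-CPz must outrank P1-P2... both carry
        # effects here, so use a spec with one silent derivation instead
        session, _ = generate_session(
            small_spec(seed=62, effect_matrix={("Hand", "FCz", 1): -0.8})
        )
        _, derivs = toy_sweep_inputs
        sweep = run_channel_sweep(session, derivs, [("Hand", "Word")])
        scores = sweep.derivation_scores()
        assert scores["FCz-CPz"] > scores["P1-P2"]


def _fake_sweep(grid, rows):
    derivs = {}
    for name, _, _ in rows:
        if name not in derivs:
            derivs[name] = parse_derivation(grid, name)
    cells = pd.DataFrame(
        [{"derivation": n, "pair": p, "median_accuracy": a} for n, p, a in rows]
    )
    return SweepResult(cells=cells, derivations=derivs)


class TestSelectChannels:
    def test_non_overlapping_top_k(self, grid30):
        sweep = _fake_sweep(grid30, [
            ("C3-CP3", "A|B", 0.9),
            ("P1-P2", "A|B", 0.8),
            ("FCz-CPz", "A|B", 0.7),
        ])
        chosen = select_channels(sweep, k=3)
        assert [d.name for d in chosen] == ["C3-CP3", "P1-P2", "FCz-CPz"]

    def test_overlapping_runner_up_skipped(self, grid30):
        # FCz-CPz covers Cz's position; Cz-CPz overlaps it and must be skipped
        sweep = _fake_sweep(grid30, [
            ("FCz-CPz", "A|B", 0.9),
            ("Cz-CPz", "A|B", 0.85),
            ("P1-P2", "A|B", 0.8),
        ])
        chosen = select_channels(sweep, k=2)
        assert [d.name for d in chosen] == ["FCz-CPz", "P1-P2"]
        trace = {t["derivation"]: t["kept"] for t in sweep.selection_trace}
        assert trace["Cz-CPz"] is False

    def test_result_is_mutually_non_overlapping(self, grid30):
        from adaptbci.montage import enumerate_bipolar_derivations

        rng = np.random.default_rng(4)
        ders = enumerate_bipolar_derivations(grid30, max_gap=1)
        rows = [(d.name, "A|B", float(rng.random())) for d in ders]
        sweep = _fake_sweep(grid30, rows)
        chosen = select_channels(sweep, k=5)
        for i, d1 in enumerate(chosen):
            for d2 in chosen[i + 1 :]:
                assert not derivations_overlap(d1, d2)

    def test_k_larger_than_available_returns_all_kept(self, grid30):
        sweep = _fake_sweep(grid30, [("FCz-CPz", "A|B", 0.9), ("Cz-CPz", "A|B", 0.8)])
        chosen = select_channels(sweep, k=5)
        assert [d.name for d in chosen] == ["FCz-CPz"]


class TestSelectClasses:
    def test_chance_class_excluded(self, grid30):
        rows = []
        for pair, acc in [("A|B", 0.9), ("A|C", 0.9), ("B|C", 0.9),
                          ("A|Z", 0.5), ("B|Z", 0.5), ("C|Z", 0.5)]:
            rows.append(("FCz-CPz", pair, acc))
        sweep = _fake_sweep(grid30, rows)
        d = [sweep.derivations["FCz-CPz"]]
        assert "Z" not in select_classes(sweep, d, m=3)

    def test_all_identical_breaks_ties_lexicographically(self, grid30):
        rows = [("FCz-CPz", p, 0.7) for p in ["A|B", "A|C", "A|D", "B|C", "B|D", "C|D"]]
        sweep = _fake_sweep(grid30, rows)
        d = [sweep.derivations["FCz-CPz"]]
        assert select_classes(sweep, d, m=3) == ["A", "B", "C"]

    def test_five_classes_m4_drops_exactly_one(self, grid30):
        import itertools

        rng = np.random.default_rng(1)
        rows = [
            ("FCz-CPz", "|".join(p), float(rng.random()))
            for p in itertools.combinations("ABCDE", 2)
        ]
        sweep = _fake_sweep(grid30, rows)
        d = [sweep.derivations["FCz-CPz"]]
        assert len(select_classes(sweep, d, m=4)) == 4


class TestSeparabilityMap:
    def test_injected_cell_is_map_maximum(self, small_grid, small_derivs):
        session, _ = generate_session(small_spec(seed=63))
        table = separability_map(session, list(small_derivs), DEFAULT_BANDS,
                                 class_filter="all")
        # Hand ERD at FCz 10-13 Hz; Word ERD at P1 16-24 Hz
        top = table.stack().idxmax()
        assert top in {("FCz-CPz", "10-13Hz"), ("P1-P2", "16-24Hz")}
        assert (table.values >= 0).all()

    def test_null_session_near_zero(self, small_grid, small_derivs):
        session, _ = generate_session(small_spec(seed=64, effect_matrix={}))
        table = separability_map(session, list(small_derivs), DEFAULT_BANDS)
        assert table.values.max() < 0.5

    def test_filters_partition_pairs(self, small_grid, small_derivs):
        session, _ = generate_session(
            small_spec(seed=65, classes=("Feet", "Hand", "Word"),
                       effect_matrix={("Hand", "FCz", 1): -0.5})
        )
        mt = separability_map(session, list(small_derivs), DEFAULT_BANDS, "mt_vs_mt")
        nm = separability_map(session, list(small_derivs), DEFAULT_BANDS, "mt_vs_nm")
        assert mt.shape == nm.shape
        with pytest.raises(ValueError, match="filter"):
            separability_map(session, list(small_derivs), DEFAULT_BANDS, "nm_vs_nm")
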