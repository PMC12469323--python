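"""Search-engine behaviour: interruption, bracketing, termination, replay."""

import numpy as np
import pytest

from varstep import (
    Bracket,
    EvaluationCache,
    EvaluationError,
    SchedulePolicy,
    SearchPolicy,
    SyntheticObjectiveSpec,
    exhaustive_grid_size,
    initial_candidates,
    make_synthetic,
    make_tabulated,
    refine_candidates,
    run_round,
    run_search,
    select_bracket,
    should_terminate,
)

KM = SchedulePolicy(km=0.005)


def brute_force_grid_best(objective, km=0.005, bound=1.0):
    """Independent oracle: argmax over the km-spaced grid, ties to smaller lr."""
    best_lr, best_acc = None, -1.0
    for i in range(1, int(round(bound / km)) + 1):
        lr = round(i * km, 10)
        acc = objective(lr)
        if acc > best_acc:
            best_lr, best_acc = lr, acc
    return best_lr, best_acc


class TestRunRound:
    def test_interruption_after_three_consecutive_failures(self, fixtures_error):
        cache = EvaluationCache()
        rec = run_round(initial_candidates(KM), fixtures_error["resnet18"],
                        cache, SearchPolicy())
        assert [r.lr for r in rec.evaluated] == [1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.2, 0.3]
        assert rec.interrupted
        # the last three fresh accuracies are all below the threshold
        assert all(r.accuracy < 0.80 for r in rec.evaluated[-3:])

    def test_counter_resets_on_success(self, fixtures_error):
        # one accuracy of 80.04% inside a failing stretch must reset the count
        cache = EvaluationCache()
        rec = run_round(initial_candidates(KM), fixtures_error["shufflenet"],
                        cache, SearchPolicy())
        assert len(rec.evaluated) == 12
        assert rec.evaluated[-1].lr == 0.8
        assert rec.interrupted

    def test_cached_candidates_skipped_and_counter_unaffected(self):
        # three cached sub-threshold values must not trigger interruption
        obj = make_tabulated([(0.1, 0.5), (0.2, 0.5), (0.3, 0.5), (0.4, 0.9)])
        cache = EvaluationCache()
        for lr in (0.1, 0.2, 0.3):
            cache.add(lr, 0.5)
        rec = run_round([0.1, 0.2, 0.3, 0.4], obj, cache, SearchPolicy())
        assert [r.lr for r in rec.evaluated] == [0.4]
        assert [r.lr for r in rec.cache_hits] == [0.1, 0.2, 0.3]
        assert not rec.interrupted

    def test_all_cached_means_no_new_evaluations(self):
        obj = make_tabulated([(0.1, 0.5)])
        cache = EvaluationCache()
        cache.add(0.1, 0.5)
        rec = run_round([0.1], obj, cache, SearchPolicy())
        assert rec.evaluated == [] and not rec.interrupted

    def test_objective_failure_names_the_learning_rate(self):
        obj = make_tabulated([(0.1, 0.5)], missing_policy="error")
        with pytest.raises(EvaluationError, match="0.2"):
            run_round([0.2], obj, EvaluationCache(), SearchPolicy())

    def test_interruption_disabled_runs_full_round(self, fixtures_nearest):
        cache = EvaluationCache()
        rec = run_round(initial_candidates(KM), fixtures_nearest["resnet18"], cache,
                        SearchPolicy(interruption_enabled=False))
        assert len(rec.evaluated) == 14 and not rec.interrupted


class TestSelectBracket:
    def test_brackets_best_between_neighbours(self):
        cache = EvaluationCache()
        for lr, acc in [(1e-5, 0.47), (1e-4, 0.86), (0.001, 0.93),
                        (0.01, 0.96), (0.1, 0.70), (0.2, 0.56), (0.3, 0.60)]:
            cache.add(lr, acc)
        assert select_bracket(cache, KM) == Bracket(0.001, 0.01, 0.1)

    def test_boundary_fallback(self):
        cache = EvaluationCache()
        cache.add(0.01, 0.9)
        b = select_bracket(cache, KM)
        assert b == Bracket(KM.lower_bound, 0.01, KM.k2)

    def test_tie_breaks_toward_smaller_lr(self):
        cache = EvaluationCache()
        cache.add(0.2, 0.9)
        cache.add(0.1, 0.9)
        assert select_bracket(cache, KM).lrb == 0.1


class TestShouldTerminate:
    def _cache(self, *pairs):
        cache = EvaluationCache()
        for lr, acc in pairs:
            cache.add(lr, acc)
        return cache

    def test_accuracy_target_wins_regardless_of_interval(self):
        cache = self._cache((0.01, 0.995), (0.1, 0.5))
        b = Bracket(0.001, 0.01, 0.1)
        assert should_terminate(cache, b, [0.05], KM, SearchPolicy(), 1) == "accuracy_target"

    def test_exhausted_when_all_candidates_cached(self):
        cache = self._cache((0.006, 0.96), (0.01, 0.963), (0.015, 0.957))
        b = Bracket(0.006, 0.01, 0.015)
        assert should_terminate(cache, b, [0.015], KM, SearchPolicy(), 2) == "exhausted"

    def test_interval_at_precision(self):
        cache = self._cache((0.01, 0.9), (0.015, 0.89))
        b = Bracket(0.01, 0.015, 0.02)
        assert (
            should_terminate(cache, b, [0.02], KM, SearchPolicy(), 1) == "interval_le_km"
        )

    def test_continues_otherwise(self):
        cache = self._cache((0.01, 0.9), (0.1, 0.5))
        b = Bracket(0.001, 0.01, 0.1)
        assert should_terminate(cache, b, [0.05], KM, SearchPolicy(), 1) is None


class TestRunSearchReplay:
    def test_resnet18_trajectory(self, fixtures_error):
        out = run_search(fixtures_error["resnet18"], KM)
        assert out.best_lr == 0.01
        assert out.best_accuracy == 0.9633
        assert out.total_new_evaluations == 14
        assert out.new_lrs_per_round() == [
            [1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.2, 0.3],
            [0.006, 0.02, 0.03, 0.04, 0.05, 0.06],
            [0.015],
        ]

    def test_shufflenet_trajectory(self, fixtures_error):
        out = run_search(fixtures_error["shufflenet"], KM)
        assert out.best_lr == 0.015
        assert out.best_accuracy == 0.9674
        assert out.total_new_evaluations == 22
        assert out.new_lrs_per_round() == [
            [1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
            [0.006, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09],
            [0.015],
        ]

    def test_round2_brackets_match_recorded_intervals(self, fixtures_error):
        out = run_search(fixtures_error["resnet18"], KM)
        assert out.rounds[1].bracket_used == Bracket(0.001, 0.01, 0.1)
        assert out.rounds[2].bracket_used == Bracket(0.006, 0.01, 0.02)

    def test_constant_objective_hand_trace(self):
        out = run_search(lambda lr: 0.85, KM)
        assert out.total_new_evaluations == 14
        assert out.best_lr == 1e-5          # tie toward the smallest lr
        assert out.best_accuracy == 0.85
        assert len(out.rounds) == 1
        assert not out.rounds[0].interrupted
        assert out.termination_reason == "exhausted"

    def test_trace_consistency(self, fixtures_error):
        out = run_search(fixtures_error["shufflenet"], KM)
        records = [r for rnd in out.rounds for r in rnd.evaluated]
        assert out.best_accuracy == max(r.accuracy for r in records)
        assert out.total_new_evaluations == sum(len(r.evaluated) for r in out.rounds)

    def test_trace_export_roundtrip(self, fixtures_error, tmp_path):
        out = run_search(fixtures_error["resnet18"], KM)
        df = out.trace_dataframe()
        assert list(df.columns) == ["round", "lr", "accuracy", "from_cache",
                                    "interrupted_round"]
        # fresh rows reproduce the cache contents exactly
        fresh = df[~df.from_cache]
        assert len(fresh) == 14
        path = tmp_path / "trace.csv"
        out.to_trace_csv(path)
        import pandas as pd

        again = pd.read_csv(path)
        assert len(again) == len(df)
        assert out.to_json()  # serializable


class TestEngineProperties:
    def _random_specs(self, n, seed, noise=True):
        rng = np.random.default_rng(seed)
        for i in range(n):
            yield SyntheticObjectiveSpec(
                peak_lr=float(10 ** rng.uniform(-4, -0.3)),
                peak_acc=float(rng.uniform(0.88, 0.99)),
                floor_acc=float(rng.uniform(0.2, 0.7)),
                log_width=float(rng.uniform(0.3, 1.5)),
                noise_sd=float(rng.uniform(0, 0.05)) if noise else 0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )

    def test_no_duplicate_evaluations_and_grid_bound(self):
        limit = exhaustive_grid_size(1.0, 0.005)
        for spec in self._random_specs(40, seed=42):
            out = run_search(make_synthetic(spec), KM)
            lrs = [r.lr for rnd in out.rounds for r in rnd.evaluated]
            assert len(lrs) == len(set(lrs))
            assert out.total_new_evaluations <= limit

    def test_peak_recovery_against_grid_oracle(self):
        # noiseless unimodal surfaces with km-aligned peaks: the search must
        # return exactly the peak the exhaustive km grid would find
        rng = np.random.default_rng(7)
        peaks = [round(0.005 * k, 10) for k in range(2, 19)]  # 0.01 .. 0.09
        for _ in range(12):
            peak = float(rng.choice(peaks))
            spec = SyntheticObjectiveSpec(
                peak_lr=peak,
                peak_acc=float(rng.uniform(0.9, 0.98)),
                floor_acc=float(rng.uniform(0.80, 0.85)),
                log_width=float(rng.uniform(0.3, 1.0)),
            )
            obj = make_synthetic(spec)
            oracle_lr, _ = brute_force_grid_best(obj)
            assert oracle_lr == peak
            assert run_search(obj, KM).best_lr == peak

    def test_interrupted_round_is_prefix_of_uninterrupted_round(self):
        # within a round, interruption only truncates: the evaluations of an
        # interruption-enabled round are a prefix of the disabled round's
        cands = initial_candidates(KM)
        for spec in self._random_specs(15, seed=11):
            obj = make_synthetic(spec)
            with_int = run_round(cands, obj, EvaluationCache(), SearchPolicy())
            without = run_round(cands, obj, EvaluationCache(),
                                SearchPolicy(interruption_enabled=False))
            n = len(with_int.evaluated)
            assert with_int.evaluated == without.evaluated[:n]
            if not with_int.interrupted:
                assert n == len(without.evaluated)

    def test_disabling_interruption_never_hurts_on_replay_fixtures(self, fixtures_nearest):
        for obj in fixtures_nearest.values():
            with_int = run_search(obj, KM, SearchPolicy())
            without = run_search(obj, KM, SearchPolicy(interruption_enabled=False))
            assert without.best_accuracy >= with_int.best_accuracy

    def test_max_rounds_exit_is_flagged(self):
        obj = make_synthetic(SyntheticObjectiveSpec(peak_lr=0.03, floor_acc=0.82))
        out = run_search(obj, KM, SearchPolicy(max_rounds=1))
        assert out.termination_reason == "max_rounds"

    def test_accuracy_target_stops_early(self):
        out = run_search(lambda lr: 0.999, KM)
        assert out.termination_reason == "accuracy_target"
        assert out.total_new_evaluations <= 14
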