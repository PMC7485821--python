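"""The BO loop: bootstrap, stopping rules, reporting, trace persistence."""

import numpy as np
import pandas as pd
import pytest

from pipeopt.optimise import (
    BayesianPipelineOptimiser,
    IterationRecord,
    OptimisationAborted,
    OptimiserSettings,
    iteration_report,
    load_evaluations,
    persist_trace,
    reference_space,
    run_search,
)
from pipeopt.segmentation import run_pipeline
from pipeopt.space import ParameterSpec, SearchSpace
from pipeopt.synth import SceneSpec, SimulatedRater, generate_sample

SMALL_SPACE = SearchSpace(
    [
        ParameterSpec("a", "float", 0.0, 1.0, 0.1),
        ParameterSpec("b", "float", 0.0, 1.0, 0.1),
    ]
)


class DummyResult:
    """Stands in for a pipeline result when the evaluator only needs x."""

    def __init__(self, config):
        self.config = config


def dummy_pipeline(config):
    return DummyResult(config)


def quadratic_evaluator(result):
    """Smooth deterministic score peaking at (0.7, 0.3); range ~[1, 10]."""
    a, b = result.config["a"], result.config["b"]
    return float(max(1.0, 10.0 - 18.0 * ((a - 0.7) ** 2 + (b - 0.3) ** 2)))


def settings(**kw):
    kw.setdefault("target_qs", 9.0)
    kw.setdefault("max_iterations", 15)
    kw.setdefault("seed", 0)
    return OptimiserSettings(**kw)


class TestStoppingRules:
    def test_achievable_target_terminates_with_zero_gap(self):
        res = run_search(SMALL_SPACE, dummy_pipeline, quadratic_evaluator, settings())
        assert res.terminated_reason == "target_met"
        assert res.records[-1].gap == 0.0
        assert res.best_qs >= 9.0

    def test_unachievable_target_exhausts_exact_budget(self):
        res = run_search(
            SMALL_SPACE,
            dummy_pipeline,
            lambda r: 5.0,
            settings(target_qs=10.0, max_iterations=5),
        )
        assert res.terminated_reason == "budget_exhausted"
        assert len(res.records) == 2 + 5  # bootstrap + post-bootstrap budget

    def test_stops_during_bootstrap_if_target_already_met(self):
        res = run_search(
            SMALL_SPACE, dummy_pipeline, lambda r: 9.5, settings(target_qs=9.0)
        )
        assert res.terminated_reason == "target_met"
        assert len(res.records) == 1
        assert res.records[0].phase == "bootstrap"

    def test_two_bootstrap_evaluations_before_first_gp_fit(self):
        res = run_search(
            SMALL_SPACE,
            dummy_pipeline,
            lambda r: 5.0,
            settings(target_qs=10.0, max_iterations=3),
        )
        phases = [r.phase for r in res.records]
        assert phases[:2] == ["bootstrap", "bootstrap"]
        assert all(p == "bo" for p in phases[2:])
        assert res.records[0].theta is None and res.records[1].theta is None
        assert res.records[2].theta is not None

    def test_bootstrap_count_below_two_rejected(self):
        with pytest.raises(ValueError, match="bootstrap"):
            OptimiserSettings(bootstrap_count=1)


class TestRobustness:
    def test_crashing_configuration_scored_worst_and_flagged(self):
        def crashy(config):
            if config["a"] < 0.5:
                raise RuntimeError("boom")
            return DummyResult(config)

        res = run_search(
            SMALL_SPACE,
            crashy,
            quadratic_evaluator,
            settings(target_qs=10.0, max_iterations=8, seed=2),
        )
        flagged = [r for r in res.records if r.flagged]
        assert flagged, "expected at least one crashing configuration"
        assert all(r.qs == 1.0 for r in flagged)
        assert res.terminated_reason in ("target_met", "budget_exhausted")

    def test_evaluator_failure_aborts_with_partial_trace(self):
        calls = []

        def failing(result):
            calls.append(1)
            if len(calls) >= 3:
                raise RuntimeError("rater left")
            return 5.0

        with pytest.raises(OptimisationAborted) as excinfo:
            run_search(
                SMALL_SPACE,
                dummy_pipeline,
                failing,
                settings(target_qs=10.0, max_iterations=5),
            )
        assert len(excinfo.value.records) == 2


@pytest.fixture(scope="module")
def result():
    return run_search(
        SMALL_SPACE,
        dummy_pipeline,
        quadratic_evaluator,
        settings(target_qs=10.0, max_iterations=12, seed=5),
    )


class TestTraceInvariants:

    def test_best_so_far_monotone(self, result):
        best = [r.best_qs for r in result.records]
        assert np.all(np.diff(best) >= 0)

    def test_best_gap_monotone_non_increasing(self, result):
        gaps = np.minimum.accumulate([r.gap for r in result.records])
        assert np.all(np.diff(gaps) <= 0)

    def test_bit_reproducible_given_seed(self):
        kw = dict(target_qs=10.0, max_iterations=6, seed=7)
        r1 = run_search(SMALL_SPACE, dummy_pipeline, quadratic_evaluator, settings(**kw))
        r2 = run_search(SMALL_SPACE, dummy_pipeline, quadratic_evaluator, settings(**kw))
        pd.testing.assert_frame_equal(r1.trace, r2.trace)

    def test_executed_configs_lie_on_grid(self, result):
        from pipeopt.space import grid_values

        grids = {s.name: set(np.round(grid_values(s), 9)) for s in SMALL_SPACE.specs}
        for r in result.records:
            for name, value in r.config.items():
                assert round(value, 9) in grids[name]


class TestIterationReport:
    def test_published_example_rows(self):
        space = SearchSpace(
            [
                ParameterSpec("Size of adaptive window", "integer", 10, 400, 1),
                ParameterSpec("Typical artifact diameter", "float", 1.0, 20.0, 1.0),
            ]
        )
        record = IterationRecord(
            index=5,
            phase="bo",
            proposal={"Size of adaptive window": 295.7, "Typical artifact diameter": 9.0},
            config={"Size of adaptive window": 296.0, "Typical artifact diameter": 9.0},
            previous_config={
                "Size of adaptive window": 240.0,
                "Typical artifact diameter": 3.0,
            },
            qs=7.0,
            gap=1.0,
            best_qs=7.5,
            best_config={
                "Size of adaptive window": 348.0,
                "Typical artifact diameter": 9.0,
            },
            theta=None,
        )
        rows = iteration_report(record, space)
        assert rows[0] == ("Size of adaptive window", 348.0, 240.0, 295.7)
        assert rows[1] == ("Typical artifact diameter", 9.0, 3.0, 9.0)

    def test_first_bo_iteration_old_value_is_last_bootstrap(self):
        res = run_search(
            SMALL_SPACE,
            dummy_pipeline,
            lambda r: 5.0,
            settings(target_qs=10.0, max_iterations=2),
        )
        first_bo = res.records[2]
        rows = iteration_report(first_bo, SMALL_SPACE)
        for (name, _, old, _) in rows:
            assert old == res.records[1].config[name]

    def test_first_evaluation_has_no_old_value(self):
        res = run_search(
            SMALL_SPACE, dummy_pipeline, lambda r: 5.0, settings(max_iterations=1)
        )
        rows = iteration_report(res.records[0], SMALL_SPACE)
        assert all(old is None for _, _, old, _ in rows)


@pytest.fixture(scope="module")
def persisted(tmp_path_factory):
    res = run_search(
        SMALL_SPACE,
        dummy_pipeline,
        quadratic_evaluator,
        settings(target_qs=10.0, max_iterations=6, seed=3),
    )
    out = tmp_path_factory.mktemp("trace")
    paths = persist_trace(res, str(out))
    return res, paths


class TestPersistence:

    def test_all_artifacts_written(self, persisted):
        _, paths = persisted
        import os

        for p in paths.values():
            assert os.path.exists(p)

    def test_one_line_per_evaluation(self, persisted):
        res, paths = persisted
        with open(paths["txt"]) as fh:
            lines = fh.read().strip().splitlines()
        assert len(lines) == len(res.records) + 1  # header + evaluations

    def test_roundtrip_restores_training_set(self, persisted):
        res, paths = persisted
        configs, scores = load_evaluations(paths["txt"], SMALL_SPACE)
        assert configs == [r.config for r in res.records]
        assert np.array_equal(scores, np.array([r.qs for r in res.records]))

    def test_gap_column_non_negative(self, persisted):
        _, paths = persisted
        df = pd.read_csv(paths["txt"], sep="\t")
        assert (df["gap"] >= 0).all()


class TestEstimatorFrontEnd:
    def test_fit_on_synthetic_scene_sets_attributes(self):
        sample = generate_sample(SceneSpec(seed=11))
        opt = BayesianPipelineOptimiser(
            target_qs=6.0, max_iterations=10, random_state=1
        ).fit(sample.image, sample.ground_truth["nucleus"])
        assert hasattr(opt, "best_config_") and hasattr(opt, "trace_")
        assert opt.terminated_reason_ in ("target_met", "budget_exhausted")
        predicted = opt.predict(sample.image)
        assert predicted.primary.shape == sample.image.shape

    def test_sklearn_param_interface(self):
        opt = BayesianPipelineOptimiser(target_qs=7.0)
        params = opt.get_params()
        assert params["target_qs"] == 7.0
        opt.set_params(max_iterations=3)
        assert opt.max_iterations == 3

    def test_requires_truth_or_evaluator(self):
        with pytest.raises(ValueError, match="ground-truth"):
            BayesianPipelineOptimiser().fit(np.zeros((120, 120)))
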