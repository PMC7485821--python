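"""The interactive Bayesian-optimisation loop.

The loop follows the two-step scheme of the original toolchain: it is
initialised with two randomly generated configurations (the bootstrap),
then repeatedly (i) fits the GP surrogate on all evaluated configurations
and their quality scores, re-estimating the hyperparameters by marginal
likelihood, and (ii) selects the next configuration by Expected
Improvement.  The run stops as soon as the current QS meets or exceeds the
target QS (quality gap zero) or when the post-bootstrap iteration budget is
exhausted.  Every evaluation is recorded; traces are persisted as a
plain-text evaluations file, a CSV, and a quality-gap-versus-iteration plot.

A random-search baseline shares the identical loop, stopping rules, seeding
and persistence, but proposes each configuration by an independent uniform
draw from the interval grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .acquisition import AcquisitionSettings, candidate_points, propose_next
from .evaluation import quality_gap
from .gp import DEFAULT_BOUNDS, GPHyperparams, GPSurrogate
from .segmentation import PipelineResult, run_pipeline
from .space import (
    Configuration,
    ParameterSpec,
    SearchSpace,
    decode,
    decode_continuous,
    encode,
    sample_random,
    validate_space,
)
from .synth import SimulatedRater

__all__ = [
    "OptimiserSettings",
    "IterationRecord",
    "BOResult",
    "OptimisationAborted",
    "run_bo",
    "run_random_search",
    "run_search",
    "iteration_report",
    "persist_trace",
    "load_evaluations",
    "reference_space",
    "BayesianPipelineOptimiser",
    "RandomSearchOptimiser",
]

_CRASH_QS = 1.0


def reference_space(max_window: int = 99) -> SearchSpace:
    """The four-setting search space of the reference pipeline.

    Ranges are sized for the synthetic scenes (the adaptive window must fit
    inside the image).
    """
    return SearchSpace(
        [
            ParameterSpec("Size of adaptive window", "integer", 11, max_window, 2),
            ParameterSpec("Threshold correction factor I", "float", 0.6, 2.0, 0.05),
            ParameterSpec("Typical artifact diameter", "float", 0.0, 12.0, 1.0),
            ParameterSpec("Threshold correction factor II", "float", 0.3, 1.5, 0.05),
        ]
    )


@dataclass(frozen=True)
class OptimiserSettings:
    """Controls of one optimisation run.

    target_qs : the user's minimum acceptable quality score (1-10).
    max_iterations : post-bootstrap evaluation budget (>= 1).
    bootstrap_count : random configurations evaluated before the first GP
        fit; at least 2 (hyperparameter estimation needs two points).
    acquisition : Expected-Improvement settings (xi, candidate count).
    sigma_n, sigma_f, sigma_l : initial GP hyperparameters.
    gp_bounds : hyperparameter search bounds for marginal-likelihood
        optimisation (None = defaults).
    gp_restarts : random restarts of the hyperparameter optimiser.
    seed : master seed; with a deterministic evaluator the whole trace is
        reproducible from it.
    """

    target_qs: float = 8.0
    max_iterations: int = 30
    bootstrap_count: int = 2
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    sigma_n: float = 0.1
    sigma_f: float = 1.0
    sigma_l: float = 1.0
    gp_bounds: Optional[dict] = None
    gp_restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.bootstrap_count < 2:
            raise ValueError("bootstrap_count must be >= 2")
        if not 1.0 <= self.target_qs <= 10.0:
            raise ValueError("target_qs must lie in [1, 10]")


@dataclass
class IterationRecord:
    """One evaluation: proposal, executed configuration, QS and bookkeeping."""

    index: int
    phase: str  # "bootstrap" | "bo" | "random"
    proposal: Configuration  # continuous (un-snapped) proposal
    config: Configuration  # grid-snapped configuration actually executed
    previous_config: Optional[Configuration]
    qs: float
    gap: float
    best_qs: float
    best_config: Configuration
    theta: Optional[GPHyperparams]
    flagged: bool = False


@dataclass
class BOResult:
    """Full outcome of one optimisation run."""

    records: List[IterationRecord]
    best_config: Configuration
    best_qs: float
    terminated_reason: str  # "target_met" | "budget_exhausted"
    final_result: Optional[PipelineResult]
    space: SearchSpace

    @property
    def trace(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"iteration": r.index, "phase": r.phase}
            row.update({name: r.config[name] for name in self.space.names})
            row.update(
                {
                    "qs": r.qs,
                    "gap": r.gap,
                    "best_qs": r.best_qs,
                    "flagged": r.flagged,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def iterations_to_gap(self, gap_level: float) -> Optional[int]:
        """1-based evaluation count at which the best-so-far quality gap
        first reaches ``gap_level``; None if it never does.

        best_qs is non-decreasing, so the best-so-far gap is the running
        minimum of the per-evaluation gaps.
        """
        best_gap = np.inf
        for r in self.records:
            best_gap = min(best_gap, r.gap)
            if best_gap <= gap_level:
                return r.index + 1
        return None


class OptimisationAborted(RuntimeError):
    """Raised when the evaluator fails; carries the partial trace."""

    def __init__(self, message: str, records: List[IterationRecord]):
        super().__init__(message)
        self.records = records


def run_search(
    space: SearchSpace,
    pipeline: Callable[[Configuration], PipelineResult],
    evaluator: Callable[[PipelineResult], float],
    settings: OptimiserSettings,
    strategy: str = "bo",
) -> BOResult:
    """Shared driver for BO and the random-search baseline."""
    if strategy not in ("bo", "random"):
        raise ValueError("strategy must be 'bo' or 'random'")
    validate_space(space)
    ss = np.random.SeedSequence(settings.seed)
    boot_ss, prop_ss, gp_ss = ss.spawn(3)
    boot_seed = int(boot_ss.generate_state(1)[0] % (2**31))
    gp_seed = int(gp_ss.generate_state(1)[0] % (2**31))
    prop_rng = np.random.default_rng(prop_ss)

    records: List[IterationRecord] = []
    best_qs = -np.inf
    best_config: Optional[Configuration] = None

    def evaluate(config: Configuration, proposal: Configuration, phase: str,
                 theta: Optional[GPHyperparams]) -> IterationRecord:
        nonlocal best_qs, best_config
        flagged = False
        try:
            result = pipeline(config)
        except Exception:
            # crashing configurations are scored worst, not fatal, so the
            # surrogate can learn away from invalid corners of the space
            result = None
            flagged = True
        if result is not None:
            try:
                qs = float(evaluator(result))
            except Exception as exc:
                raise OptimisationAborted(
                    f"evaluator failed at iteration {len(records)}: {exc}", records
                ) from exc
        else:
            qs = _CRASH_QS
        gap = quality_gap(settings.target_qs, qs)
        if qs > best_qs:
            best_qs, best_config = qs, dict(config)
        prev = records[-1].config if records else None
        rec = IterationRecord(
            index=len(records),
            phase=phase,
            proposal=dict(proposal),
            config=dict(config),
            previous_config=prev,
            qs=qs,
            gap=gap,
            best_qs=best_qs,
            best_config=dict(best_config),
            theta=theta,
            flagged=flagged,
        )
        records.append(rec)
        return rec

    # --- bootstrap: randomly generated configurations ------------------
    reason = None
    for config in sample_random(space, settings.bootstrap_count, boot_seed):
        rec = evaluate(config, config, "bootstrap", None)
        if rec.gap == 0.0:
            reason = "target_met"
            break

    # --- BO / random loop ----------------------------------------------
    if reason is None:
        for _ in range(settings.max_iterations):
            theta = None
            if strategy == "bo":
                X = np.array([encode(r.config, space) for r in records])
                y = np.array([r.qs for r in records])
                gp = GPSurrogate(
                    sigma_n=settings.sigma_n,
                    sigma_f=settings.sigma_f,
                    sigma_l=settings.sigma_l,
                    bounds=settings.gp_bounds,
                    n_restarts=settings.gp_restarts,
                    random_state=gp_seed,
                ).fit(X, y)
                theta = gp.theta_
                cand_seed = int(prop_rng.integers(2**31))
                cands = candidate_points(
                    space, [r.config for r in records], settings.acquisition, cand_seed
                )
                x_next = propose_next(gp, cands, best_qs, settings.acquisition)
                proposal = decode_continuous(x_next, space)
                config = decode(x_next, space)
                phase = "bo"
            else:
                config = sample_random(space, 1, prop_rng)[0]
                proposal = dict(config)
                phase = "random"
            rec = evaluate(config, proposal, phase, theta)
            if rec.gap == 0.0:
                reason = "target_met"
                break
        else:
            reason = "budget_exhausted"

    try:
        final_result = pipeline(best_config)
    except Exception:
        final_result = None
    return BOResult(
        records=records,
        best_config=best_config,
        best_qs=best_qs,
        terminated_reason=reason,
        final_result=final_result,
        space=space,
    )


def run_bo(space, pipeline, evaluator, settings: OptimiserSettings) -> BOResult:
    """Bayesian-optimisation run (bootstrap, GP + EI loop, stopping rule)."""
    return run_search(space, pipeline, evaluator, settings, strategy="bo")


def run_random_search(space, pipeline, evaluator, settings: OptimiserSettings) -> BOResult:
    """Random-selection baseline: identical loop, uniform grid proposals."""
    return run_search(space, pipeline, evaluator, settings, strategy="random")


def iteration_report(
    record: IterationRecord, space: SearchSpace
) -> List[Tuple[str, float, Optional[float], float]]:
    """Per-setting report rows: (name, best-so-far, old value, new value).

    'Old value' is the previously evaluated configuration (None on the very
    first evaluation); 'new value' is the continuous proposal of the current
    iteration, which may sit off the interval grid.
    """
    rows = []
    for name in space.names:
        old = record.previous_config[name] if record.previous_config else None
        rows.append(
            (name, record.best_config[name], old, record.proposal[name])
        )
    return rows


def persist_trace(result: BOResult, directory: str) -> Dict[str, str]:
    """Write the run trace: evaluations.txt (TSV), trace.csv, best_config.json
    and a quality-gap-versus-iteration plot."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    names = result.space.names

    txt = out / "evaluations.txt"
    with open(txt, "w") as fh:
        fh.write("\t".join(["iteration"] + names + ["qs", "gap"]) + "\n")
        for r in result.records:
            vals = [repr(float(r.config[n])) for n in names]
            fh.write(
                "\t".join([str(r.index)] + vals + [repr(float(r.qs)), repr(float(r.gap))])
                + "\n"
            )

    csv = out / "trace.csv"
    result.trace.to_csv(csv, index=False)

    cfg = out / "best_config.json"
    with open(cfg, "w") as fh:
        json.dump(
            {
                "best_config": result.best_config,
                "best_qs": result.best_qs,
                "terminated_reason": result.terminated_reason,
            },
            fh,
            indent=2,
        )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    it = [r.index for r in result.records]
    ax.scatter(it, [r.gap for r in result.records], label="current", s=18)
    ax.plot(
        it,
        np.minimum.accumulate([r.gap for r in result.records]),
        drawstyle="steps-post",
        color="C1",
        label="best so far",
    )
    ax.set_xlabel("iteration")
    ax.set_ylabel("quality gap")
    ax.legend(frameon=False)
    fig.tight_layout()
    png = out / "quality_gap.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)

    return {"txt": str(txt), "csv": str(csv), "json": str(cfg), "png": str(png)}


def load_evaluations(path: str, space: SearchSpace) -> Tuple[List[Configuration], np.ndarray]:
    """Round-trip parse of evaluations.txt back to (configurations, scores)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    configs = [
        {name: float(row[name]) for name in space.names} for _, row in df.iterrows()
    ]
    return configs, df["qs"].to_numpy(dtype=float)


# ----------------------------------------------------------------------
# sklearn-style front ends


class BayesianPipelineOptimiser(BaseEstimator):
    """Fit-shaped front end: optimise the segmentation pipeline on one image.

    ``fit(image, truth)`` runs the full BO loop with the simulated rater
    scoring the ``object_class`` mask against ``truth``; alternatively pass
    a custom ``evaluator`` callable (PipelineResult -> QS).

    Attributes (after fit): ``result_``, ``best_config_``, ``best_qs_``,
    ``trace_``, ``terminated_reason_``.
    """

    _strategy = "bo"

    def __init__(
        self,
        space: Optional[SearchSpace] = None,
        target_qs: float = 8.0,
        max_iterations: int = 30,
        bootstrap_count: int = 2,
        xi: float = 0.3,
        candidate_count: int = 2048,
        sigma_n: float = 0.1,
        sigma_f: float = 1.0,
        sigma_l: float = 1.0,
        gp_bounds: Optional[dict] = None,
        gp_restarts: int = 5,
        object_class: str = "nucleus",
        rating_noise_p: float = 0.0,
        smoothing_sigma: float = 1.0,
        random_state: int = 0,
    ):
        self.space = space
        self.target_qs = target_qs
        self.max_iterations = max_iterations
        self.bootstrap_count = bootstrap_count
        self.xi = xi
        self.candidate_count = candidate_count
        self.sigma_n = sigma_n
        self.sigma_f = sigma_f
        self.sigma_l = sigma_l
        self.gp_bounds = gp_bounds
        self.gp_restarts = gp_restarts
        self.object_class = object_class
        self.rating_noise_p = rating_noise_p
        self.smoothing_sigma = smoothing_sigma
        self.random_state = random_state

    def _settings(self) -> OptimiserSettings:
        return OptimiserSettings(
            target_qs=self.target_qs,
            max_iterations=self.max_iterations,
            bootstrap_count=self.bootstrap_count,
            acquisition=AcquisitionSettings(
                xi=self.xi, candidate_count=self.candidate_count
            ),
            sigma_n=self.sigma_n,
            sigma_f=self.sigma_f,
            sigma_l=self.sigma_l,
            gp_bounds=self.gp_bounds,
            gp_restarts=self.gp_restarts,
            seed=self.random_state,
        )

    def fit(
        self,
        image: np.ndarray,
        truth: Optional[np.ndarray] = None,
        evaluator: Optional[Callable[[PipelineResult], float]] = None,
    ) -> "BayesianPipelineOptimiser":
        space = self.space if self.space is not None else reference_space(
            max_window=min(np.asarray(image).shape) - 1
            if min(np.asarray(image).shape) <= 99
            else 99
        )
        if evaluator is None:
            if truth is None:
                raise ValueError("provide either a ground-truth mask or an evaluator")
            evaluator = SimulatedRater(
                truth,
                object_class=self.object_class,
                noise_p=self.rating_noise_p,
                seed=self.random_state,
            )

        def pipeline(config: Configuration) -> PipelineResult:
            return run_pipeline(image, config, smoothing_sigma=self.smoothing_sigma)

        self.result_ = run_search(
            space, pipeline, evaluator, self._settings(), strategy=self._strategy
        )
        self.space_ = space
        self.best_config_ = self.result_.best_config
        self.best_qs_ = self.result_.best_qs
        self.trace_ = self.result_.trace
        self.terminated_reason_ = self.result_.terminated_reason
        return self

    def predict(self, image: np.ndarray) -> PipelineResult:
        """Run the pipeline at the optimised configuration on a new image."""
        if not hasattr(self, "best_config_"):
            raise RuntimeError("optimiser is not fitted")
        return run_pipeline(
            image, self.best_config_, smoothing_sigma=self.smoothing_sigma
        )


class RandomSearchOptimiser(BayesianPipelineOptimiser):
    """Random-selection baseline with the identical interface and stopping rules."""

    _strategy = "random"
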