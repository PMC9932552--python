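"""Experiment protocols and the random parameter search.

Experiment 1 is the heading-switch protocol: 3 preswitch headings (0, ±6°)
crossed with 6 switch angles (±3, ±6, ±12°), 34-frame trials with the
switch at frame 30, read out at frames 32 and 34 (the shorter and longer
postswitch-viewing analogues).  Experiment 2 crosses the same 18 heading
conditions with four blackout conditions on a 32-frame protocol and reads
out at frame 32 (frame 33 for the lengthened midblackout trials).

Each switch condition is paired with a no-switch condition at the same
postswitch heading, trial length and dot placement; heading bias is the
differential error between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import analysis
from .flow import (
    EXP2_SCHEDULE,
    FlowSample,
    SceneConfig,
    TrialSpec,
    make_condition_grid,
    render_sequence,
)
from .model import ModelParams, TemplateBank, build_templates, run_trial

__all__ = [
    "ExperimentPlan",
    "ResultsBundle",
    "SearchSpace",
    "run_experiment",
    "parameter_search",
    "BiasTargetObjective",
    "qualitative_objective",
    "calibrate_drive_scale",
]


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to reproduce one simulated experiment."""

    experiment: int = 1
    n_reps: int = 10
    base_seed: int = 0
    readout_frames: tuple[int, ...] | None = None
    params: ModelParams = field(default_factory=ModelParams)
    scene: SceneConfig = field(default_factory=SceneConfig)

    def readouts_for(self, spec: TrialSpec) -> tuple[int, ...]:
        if self.readout_frames is not None:
            return self.readout_frames
        if self.experiment == 1:
            return (32, 34)
        # Exp 2: read out after frame 32; the midblackout trial is one
        # frame longer, so its readout shifts with it
        return (33,) if spec.n_frames == 33 else (32,)


@dataclass
class ResultsBundle:
    """Per-trial results plus the derived bias and precision tables."""

    trials: pd.DataFrame
    bias_trials: pd.DataFrame
    bias_table: pd.DataFrame
    precision_table: pd.DataFrame


def _trial_rows(spec: TrialSpec, result) -> list[dict]:
    rows = []
    for est in result.estimates:
        rows.append(
            {
                "preswitch_heading": spec.preswitch_heading,
                "switch_angle": spec.switch_angle,
                "postswitch_heading": spec.postswitch_heading,
                "condition_label": spec.condition_label,
                "repetition": spec.repetition,
                "seed": spec.seed,
                "n_frames": spec.n_frames,
                "readout_frame": est.frame,
                "judged": est.value,
                "true_heading": spec.postswitch_heading,
                "error": est.value - spec.postswitch_heading,
            }
        )
    return rows


def run_trials(
    specs: Sequence[TrialSpec],
    params: ModelParams,
    scene: SceneConfig,
    readouts: Callable[[TrialSpec], Sequence[int]],
    bank: TemplateBank | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> pd.DataFrame:
    """Render and run a list of trial specs; one row per (trial, readout)."""
    bank = bank or build_templates(scene.resolution, scene)
    rows: list[dict] = []
    for i, spec in enumerate(specs):
        sample = render_sequence(spec, scene)
        result = run_trial(sample, params, readout_frames=readouts(spec), bank=bank)
        rows.extend(_trial_rows(spec, result))
        if progress is not None:
            progress(i + 1, len(specs))
    return pd.DataFrame(rows)


def run_experiment(plan: ExperimentPlan, bank: TemplateBank | None = None,
                   progress: Callable[[int, int], None] | None = None) -> ResultsBundle:
    """Run the full condition grid of an experiment and derive all tables.

    Fully reproducible from the plan: the grid, per-trial seeds, model
    parameters and readouts are all functions of the plan fields.
    """
    specs = make_condition_grid(plan.experiment, plan.n_reps, plan.base_seed)
    trials = run_trials(
        specs, plan.params, plan.scene, plan.readouts_for, bank=bank, progress=progress
    )
    switch = trials[trials["condition_label"] != "noswitch"]
    noswitch = trials[trials["condition_label"] == "noswitch"]
    bias_trials = analysis.heading_bias(switch, noswitch)
    bias_table = analysis.aggregate_bias(bias_trials)
    if plan.n_reps >= 2:
        precision_table = analysis.precision(switch)
    else:  # precision undefined from a single repetition
        precision_table = pd.DataFrame(
            columns=["preswitch_heading", "switch_angle", "condition_label",
                     "readout_frame", "precision", "n"]
        )
    return ResultsBundle(
        trials=trials,
        bias_trials=bias_trials,
        bias_table=bias_table,
        precision_table=precision_table,
    )


# ---------------------------------------------------------------------------
# random parameter search

#: Search intervals; radii and filter SDs are sampled in degrees of visual
#: angle and converted to pixels with the scene's linear mapping.
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "r_mt_deg": (2.0, 12.5),
    "r_mst_deg": (7.5, 22.0),
    "a_decay": (0.1, 1.0),
    "c_avg": (0.2, 0.8),
    "sigma_mt_deg": (0.1, 28.0),
    "sigma_mst_deg": (0.1, 35.0),
    "b_ceiling": (1.0, 150.0),
}


@dataclass(frozen=True)
class SearchSpace:
    """Uniform sampling intervals for the random parameter search."""

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEARCH_SPACE)
    )

    def sample(self, rng: np.random.Generator, scene: SceneConfig) -> ModelParams:
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in self.intervals.items()}
        px = 1.0 / scene.deg_per_px
        kwargs = {}
        for key, value in draw.items():
            if key.endswith("_deg"):
                kwargs[key[:-4]] = value * px
            else:
                kwargs[key] = value
        return ModelParams(**kwargs)


def qualitative_objective(bias_table: pd.DataFrame) -> float:
    """Score a bias table against the qualitative target pattern.

    Soft-constraint penalties (lower is better, 0 is a perfect match):
    every switch angle shows positive mean bias at the earlier readout;
    collapsed |bias| is non-decreasing in |switch angle|; and bias does not
    grow from the earlier to the later readout.  Mirrors parameter
    selection "by visual inspection" against the attraction pattern.
    """
    penalty = 0.0
    early = bias_table["readout_frame"].min()
    late = bias_table["readout_frame"].max()
    tab_e = bias_table[bias_table["readout_frame"] == early]
    for _, row in tab_e.iterrows():
        penalty += max(0.0, -row["bias"]) ** 2
    by_abs = (
        tab_e.assign(abs_switch=tab_e["switch_angle"].abs())
        .groupby("abs_switch")["bias"]
        .mean()
        .sort_index()
    )
    diffs = np.diff(by_abs.to_numpy())
    penalty += float(np.sum(np.maximum(0.0, -diffs) ** 2))
    if late != early:
        mean_e = tab_e["bias"].abs().mean()
        mean_l = bias_table[bias_table["readout_frame"] == late]["bias"].abs().mean()
        penalty += max(0.0, mean_l - mean_e) ** 2
    return penalty


class BiasTargetObjective:
    """Weighted squared distance to a target bias table.

    The candidate and target tables are aligned on their condition keys; a
    candidate equal to the target scores exactly zero.
    """

    def __init__(self, target: pd.DataFrame, weight_col: str | None = None):
        self.keys = ["preswitch_heading", "switch_angle", "readout_frame"]
        self.target = target.set_index(self.keys)["bias"]
        self.weights = (
            target.set_index(self.keys)[weight_col] if weight_col else None
        )

    def __call__(self, bias_table: pd.DataFrame) -> float:
        cand = bias_table.set_index(self.keys)["bias"]
        joined = pd.concat([cand, self.target], axis=1, join="inner")
        diff = joined.iloc[:, 0] - joined.iloc[:, 1]
        w = self.weights.loc[joined.index] if self.weights is not None else 1.0
        return float((w * diff**2).sum())


def parameter_search(
    space: SearchSpace,
    n_iter: int,
    seed: int,
    objective: Callable[[pd.DataFrame], float] = qualitative_objective,
    n_reps: int = 2,
    scene: SceneConfig | None = None,
    base_plan: ExperimentPlan | None = None,
) -> pd.DataFrame:
    """Random search over model parameters, scored on the Experiment-1 bias.

    Each iteration samples one value per parameter uniformly from its
    interval, runs a (reduced, ``n_reps``-repetition) Experiment-1 grid and
    scores the resulting bias table.  Candidates whose dynamics diverge are
    scored ``inf`` and kept in the ranking rather than aborting the search.
    Returns one row per candidate sorted by ascending score.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    scene = scene or SceneConfig()
    rng = np.random.default_rng(seed)
    bank = build_templates(scene.resolution, scene)
    rows = []
    for it in range(n_iter):
        params = space.sample(rng, scene)
        plan = replace(
            base_plan or ExperimentPlan(experiment=1, base_seed=seed),
            n_reps=n_reps,
            params=params,
            scene=scene,
        )
        try:
            bundle = run_experiment(plan, bank=bank)
            score = objective(bundle.bias_table)
        except (FloatingPointError, ValueError, RuntimeError):
            score = float("inf")
        rows.append({"iteration": it, "score": score, **params.to_dict()})
    return pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)


def calibrate_drive_scale(
    scales: Sequence[float] = (500, 1000, 2000, 4000, 8000),
    n_reps: int = 2,
    base_seed: int = 0,
    scene: SceneConfig | None = None,
    objective: Callable[[pd.DataFrame], float] = qualitative_objective,
) -> pd.DataFrame:
    """Score candidate drive scales on a reduced Experiment-1 grid.

    The drive scale is the one global input-normalization constant of the
    model; it is fixed once from this calibration and then never treated as
    a free parameter.  Returns one row per candidate sorted by score.
    """
    scene = scene or SceneConfig()
    bank = build_templates(scene.resolution, scene)
    rows = []
    for s in scales:
        plan = ExperimentPlan(
            experiment=1,
            n_reps=n_reps,
            base_seed=base_seed,
            params=ModelParams(drive_scale=float(s)),
            scene=scene,
        )
        bundle = run_experiment(plan, bank=bank)
        prec = bundle.precision_table["precision"].mean()
        rows.append(
            {
                "drive_scale": float(s),
                "score": objective(bundle.bias_table),
                "mean_bias": bundle.bias_table["bias"].mean(),
                "mean_precision": prec,
            }
        )
    return pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)
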