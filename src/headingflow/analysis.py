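"""Heading-error, heading-bias and precision statistics.

Conventions: the heading error on a trial is ``E = judged - true``, where
the true heading is the postswitch heading (or the constant heading on
no-switch trials).  The heading bias of a switch trial is its error minus
the mean error of matched no-switch trials at the same postswitch heading
and readout condition; bias values from positive switch angles are then
negated, so positive bias always means attraction toward the preswitch
heading.

All functions operate on tidy :class:`pandas.DataFrame` tables with one row
per (trial, readout).  The expected columns are those produced by
:func:`headingflow.experiment.run_experiment`:

``preswitch_heading, switch_angle, postswitch_heading, condition_label,
repetition, seed, readout_frame, judged, true_heading, error``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "heading_error",
    "heading_bias",
    "aggregate_bias",
    "precision",
    "collapse_by_sign",
    "PairingError",
    "InsufficientRepetitionsError",
]


class PairingError(ValueError):
    """A switch condition has no matched no-switch trials."""


class InsufficientRepetitionsError(ValueError):
    """Precision requested for a group with fewer than two repetitions."""


def heading_error(judged, true_heading):
    """Signed heading error in degrees, ``judged - true_heading``."""
    return np.asarray(judged, float) - np.asarray(true_heading, float)


#: Columns that identify a matched no-switch reference group.
PAIR_KEYS = ["true_heading", "readout_frame", "n_frames"]


def heading_bias(
    switch_results: pd.DataFrame,
    noswitch_results: pd.DataFrame,
    pair_keys: list[str] | None = None,
) -> pd.DataFrame:
    """Per-trial heading bias with the attraction sign convention.

    Each switch trial's error is referenced to the mean no-switch error at
    the same postswitch heading (and readout condition, per ``pair_keys``),
    then the bias of positive-switch-angle trials is negated so that
    positive values denote attraction toward the preswitch heading.
    Returns a copy of ``switch_results`` with ``raw_bias`` and ``bias``
    columns.
    """
    keys = [k for k in (pair_keys or PAIR_KEYS) if k in switch_results.columns]
    ref = (
        noswitch_results.groupby(keys)["error"].mean().rename("noswitch_error")
    )
    out = switch_results.merge(ref, how="left", left_on=keys, right_index=True)
    if out["noswitch_error"].isna().any():
        missing = out.loc[out["noswitch_error"].isna(), keys].drop_duplicates()
        raise PairingError(
            f"no matched no-switch trials for conditions:\n{missing}"
        )
    out["raw_bias"] = out["error"] - out["noswitch_error"]
    out["bias"] = np.where(out["switch_angle"] > 0, -out["raw_bias"], out["raw_bias"])
    return out


def aggregate_bias(
    per_trial: pd.DataFrame,
    group_keys: list[str] = ("preswitch_heading", "switch_angle", "condition_label", "readout_frame"),
) -> pd.DataFrame:
    """Condition-level bias table: mean, 95% CI halfwidth and n per group.

    CIs are normal-approximation intervals over repetitions; they are
    descriptive only.
    """
    g = per_trial.groupby(list(group_keys))["bias"]
    table = g.agg(["mean", "std", "count"]).reset_index()
    table = table.rename(columns={"mean": "bias", "count": "n"})
    table["ci95"] = 1.96 * table["std"] / np.sqrt(table["n"])
    return table.drop(columns="std")


def precision(
    results: pd.DataFrame,
    group_keys: list[str] = ("preswitch_heading", "switch_angle", "condition_label", "readout_frame"),
) -> pd.DataFrame:
    """Across-repetition standard deviation of the judged heading per group.

    Sample standard deviation (ddof 1) across the repetitions of each
    condition; every group must contain at least two repetitions.
    """
    g = results.groupby(list(group_keys))["judged"]
    counts = g.count()
    if (counts < 2).any():
        bad = counts[counts < 2]
        raise InsufficientRepetitionsError(
            f"groups with fewer than 2 repetitions:\n{bad}"
        )
    table = g.agg(["std", "count"]).reset_index()
    return table.rename(columns={"std": "precision", "count": "n"})


def collapse_by_sign(
    table: pd.DataFrame,
    value_col: str,
    sign_cols: tuple[str, ...] = ("switch_angle",),
) -> pd.DataFrame:
    """Merge condition entries that differ only in the sign of angles.

    Replaces each column in ``sign_cols`` by its absolute value and
    averages ``value_col`` (weighted by ``n`` when present) over the merged
    entries.  Bias tables are already sign-normalized by the attraction
    convention, so plain averaging is the correct pooling.  Raises
    :class:`PairingError` if the grid is asymmetric (an entry lacks its
    mirror).
    """
    work = table.copy()
    for col in sign_cols:
        signed = set(np.round(work[col][work[col] != 0], 9))
        if {-s for s in signed} != signed:
            raise PairingError(f"asymmetric grid in column {col!r}")
        work[col] = work[col].abs()
    other = [c for c in work.columns if c not in (value_col, "n", "ci95")]
    if "n" in work.columns:
        work["_w"] = work["n"]
    else:
        work["_w"] = 1.0
    work["_wv"] = work[value_col] * work["_w"]
    agg = work.groupby(other)[["_wv", "_w"]].sum().reset_index()
    agg[value_col] = agg["_wv"] / agg["_w"]
    agg["n"] = agg["_w"]
    return agg.drop(columns=["_wv", "_w"])
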