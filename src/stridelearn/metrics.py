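"""Stride-level outcome, exploration, and memory measures.

Every measure is built on the per-stride percent change in left step length
from baseline,

    dLSL(s) = (LSL(s) - LSL_baseline) / LSL_baseline * 100,

with LSL_baseline the mean over the final 50 baseline strides. Outcome
measures are epoch means of dLSL, of the absolute error to the target
centre, and of the binary success rate. Exploration measures are
baseline-normalised standard deviations: sigma_dlsl (SD of dLSL over an
epoch divided by the baseline-reference SD) and sigma_trial_to_trial (SD of
consecutive-stride dLSL changes conditioned on the preceding stride's
success, divided by the unconditional baseline change SD) — the win-stay/
lose-shift signature is a larger SD after failures than after successes.
Memory measures express post-learning behaviour as a percentage of each
subject's own learned change (aftereffects, retention) or as the absolute
error to the late-learning level (retention accuracy).

Sample (n-1) standard deviations are used throughout. Conditional sets with
fewer than two differences yield a missing value with a logged warning,
never a zero.
"""
from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .protocol import (
    PHASE_LEARNING,
    EpochSpec,
    PhaseLayout,
    default_epochs,
    epoch_slice,
    plateau_start_stride,
)
from .synthetic_walkers import SubjectSeries

__all__ = [
    "delta_lsl",
    "dlsl_series",
    "epoch_dlsl",
    "epoch_mean_dlsl",
    "target_error",
    "epoch_target_error",
    "percent_success",
    "epoch_percent_success",
    "sigma_dlsl",
    "sigma_trial_to_trial",
    "percent_of_learned",
    "absolute_retention_error",
    "total_sd_plateau",
    "learning_rate_proxy",
    "match_by_total_variability",
    "compute_metric_table",
    "METRIC_TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_TABLE_COLUMNS = ["subject", "group", "measure", "epoch", "value"]

#: Minimum |late-learning dLSL| (percentage points) below which
#: percent-of-learned values are flagged unreliable.
MIN_LEARNED_PCT = 0.5

#: Baseline SDs (percentage points) at or below this are degenerate: far
#: beneath any physiological stride-to-stride variability, attributable only
#: to float round-off of constant series.
DEGENERATE_SD_PCT = 1e-9


def delta_lsl(lsl_m, lsl_baseline_m: float):
    """Percent left step length change from baseline. Accepts scalars or arrays."""
    if lsl_baseline_m <= 0:
        raise ValueError(f"baseline step length must be > 0, got {lsl_baseline_m}")
    return (np.asarray(lsl_m) - lsl_baseline_m) / lsl_baseline_m * 100.0


def dlsl_series(series: SubjectSeries, phase: str) -> np.ndarray:
    """dLSL for every stride of a phase, in stride order."""
    return delta_lsl(series.phase_values(phase), series.baseline_mean_m)


def epoch_dlsl(series: SubjectSeries, spec: EpochSpec) -> np.ndarray:
    """dLSL over an epoch."""
    return delta_lsl(epoch_slice(series, spec), series.baseline_mean_m)


def epoch_mean_dlsl(series: SubjectSeries, spec: EpochSpec) -> float:
    """Arithmetic mean of dLSL over an epoch."""
    values = epoch_dlsl(series, spec)
    if len(values) == 0:
        raise ValueError(f"epoch {spec.name!r} is empty")
    return float(np.mean(values))


def target_error(dlsl_pct, target_center_pct):
    """Absolute difference between dLSL and the target centre (percentage points)."""
    return np.abs(np.asarray(dlsl_pct) - np.asarray(target_center_pct))


def epoch_target_error(series: SubjectSeries, spec: EpochSpec) -> float:
    """Mean per-stride |dLSL - target centre| over a learning epoch."""
    dlsl = epoch_dlsl(series, spec)
    centers = epoch_slice(series, spec, column="target_center_pct")
    return float(np.mean(target_error(dlsl, centers)))


def percent_success(flags) -> float:
    """Share of strides whose step landed inside the reward window, in percent."""
    flags = np.asarray(flags, dtype=float)
    if len(flags) == 0:
        raise ValueError("cannot compute percent success of an empty epoch")
    return float(100.0 * np.mean(flags))


def epoch_percent_success(series: SubjectSeries, spec: EpochSpec) -> float:
    return percent_success(epoch_slice(series, spec, column="success"))


def _baseline_ref_spec(series: SubjectSeries, epochs) -> EpochSpec:
    return epochs["baseline_ref"]


def sigma_dlsl(series: SubjectSeries, learning_epoch: EpochSpec,
               baseline_ref: EpochSpec) -> float:
    """Exploration: SD of dLSL over an epoch, normalised by the baseline SD.

    A ratio of 1 means baseline-level motor variability; larger values mean
    variability above baseline noise, the motor-learning signature of
    exploration. Scale-free: multiplying every step length by a constant
    leaves it unchanged.
    """
    num = np.std(epoch_dlsl(series, learning_epoch), ddof=1)
    den = np.std(epoch_dlsl(series, baseline_ref), ddof=1)
    if not den > DEGENERATE_SD_PCT:
        raise ValueError(
            f"subject {series.subject_id}: baseline-reference dLSL SD is zero; "
            "sigma_dlsl is undefined"
        )
    return float(num / den)


def sigma_trial_to_trial(
    series: SubjectSeries,
    baseline_ref: EpochSpec,
    scope_start: int = 51,
) -> tuple[float, float]:
    """Win-stay/lose-shift variability: conditional SDs of stride-to-stride changes.

    Over learning strides ``scope_start``.. end (default: everything after the
    initial 50-stride target hold), each change d(s) = dLSL(s+1) - dLSL(s) is
    assigned to the success or failure set according to the outcome of stride
    s — the stride that was or was not rewarded. Returns (sigma_after_success,
    sigma_after_failure), each normalised by the SD of unconditional
    consecutive dLSL changes over the baseline reference epoch. A conditional
    set with fewer than two changes yields NaN with a logged warning.
    """
    learn = series.table[series.table["phase"] == PHASE_LEARNING].sort_values("stride")
    dlsl = delta_lsl(learn["lsl_m"].to_numpy(), series.baseline_mean_m)
    flags = learn["success"].to_numpy(dtype=float)
    i0 = scope_start - 1
    if len(dlsl) - i0 < 2:
        raise ValueError("not enough learning strides beyond the scope start")
    d = np.diff(dlsl[i0:])
    cond = flags[i0:-1] > 0.5

    base_d = np.diff(epoch_dlsl(series, baseline_ref))
    den = np.std(base_d, ddof=1)
    if not den > DEGENERATE_SD_PCT:
        raise ValueError(
            f"subject {series.subject_id}: baseline trial-to-trial SD is zero"
        )

    out = []
    for label, sel in (("success", cond), ("failure", ~cond)):
        if np.sum(sel) < 2:
            logger.warning(
                "subject %s: fewer than 2 trial-to-trial changes after %s; "
                "reporting missing", series.subject_id, label,
            )
            out.append(float("nan"))
        else:
            out.append(float(np.std(d[sel], ddof=1) / den))
    return out[0], out[1]


def _dlsl_late_mean(series: SubjectSeries, epochs) -> float:
    return epoch_mean_dlsl(series, epochs["late_learning"])


def percent_of_learned(
    series: SubjectSeries,
    spec: EpochSpec,
    epochs,
    per_stride: bool = True,
) -> float:
    """Post-learning dLSL as a percentage of the subject's learned change.

    100 means the epoch reproduces the late-learning pattern exactly. By
    default the ratio is computed per stride and averaged over the epoch; the
    ratio-of-epoch-means variant is available via ``per_stride=False``.
    Values from subjects with a near-zero learned change (|late dLSL| <
    0.5 points) are flagged unreliable via a logged warning.
    """
    late = _dlsl_late_mean(series, epochs)
    if late == 0:
        raise ValueError(f"subject {series.subject_id}: late-learning dLSL is exactly zero")
    if abs(late) < MIN_LEARNED_PCT:
        logger.warning(
            "subject %s: |late-learning dLSL| = %.3f < %.1f points; "
            "percent-of-learned is unreliable", series.subject_id, abs(late), MIN_LEARNED_PCT,
        )
    values = epoch_dlsl(series, spec)
    if per_stride:
        return float(np.mean(100.0 * values / late))
    return float(100.0 * np.mean(values) / late)


def absolute_retention_error(series: SubjectSeries, spec: EpochSpec, epochs) -> float:
    """|mean dLSL over a retention epoch - late-learning mean dLSL| (points).

    The accuracy measure for explicit retention: it penalises over- and
    understepping alike.
    """
    return float(abs(epoch_mean_dlsl(series, spec) - _dlsl_late_mean(series, epochs)))


def total_sd_plateau(series: SubjectSeries, plateau_start: int | None = None) -> float:
    """Raw (non-normalised) SD of dLSL across all plateau learning strides."""
    plateau_start = plateau_start or plateau_start_stride()
    dlsl = dlsl_series(series, PHASE_LEARNING)
    if len(dlsl) < plateau_start + 1:
        raise ValueError("learning phase ends before the target plateau")
    return float(np.std(dlsl[plateau_start - 1:], ddof=1))


def learning_rate_proxy(series: SubjectSeries, plateau_start: int | None = None) -> float:
    """Per-100-stride decline of the per-stride target error over the plateau.

    A proxy for learning rate: the negative OLS slope of |dLSL - target| on
    stride index across the plateau, scaled to percentage points per 100
    strides. Positive values mean error shrinks as learning proceeds. This is
    an operationalisation choice, not a measure defined by the protocol.
    """
    plateau_start = plateau_start or plateau_start_stride()
    learn = series.table[series.table["phase"] == PHASE_LEARNING].sort_values("stride")
    dlsl = delta_lsl(learn["lsl_m"].to_numpy(), series.baseline_mean_m)
    centers = learn["target_center_pct"].to_numpy(dtype=float)
    err = target_error(dlsl, centers)[plateau_start - 1:]
    strides = np.arange(len(err))
    slope = np.polyfit(strides, err, 1)[0]
    return float(-slope * 100.0)


def match_by_total_variability(
    cohort: Sequence[SubjectSeries],
    n_pairs: int,
    plateau_start: int | None = None,
) -> list[tuple[str, str]]:
    """Match subjects across groups on raw plateau motor variability.

    Greedy pairing: all cross-group pairs are ranked by the absolute
    difference in total plateau dLSL SD and selected smallest-first, never
    reusing a subject, keeping the ``n_pairs`` closest pairs. Deterministic;
    tie-breaks use the sorted subject-id pair, so the result is invariant
    under swapping the group labels.

    Returns pairs as (RPE subject id, TE subject id).
    """
    groups = sorted({s.group for s in cohort})
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    ga, gb = ("RPE", "TE") if set(groups) == {"RPE", "TE"} else tuple(groups)
    sd = {s.subject_id: total_sd_plateau(s, plateau_start) for s in cohort}
    ids_a = [s.subject_id for s in cohort if s.group == ga]
    ids_b = [s.subject_id for s in cohort if s.group == gb]
    if len(ids_a) < n_pairs or len(ids_b) < n_pairs:
        raise ValueError(
            f"need >= {n_pairs} subjects per group, have {len(ids_a)} ({ga}) "
            f"and {len(ids_b)} ({gb})"
        )
    candidates = sorted(
        ((abs(sd[a] - sd[b]), tuple(sorted((a, b))), a, b)
         for a, b in itertools.product(ids_a, ids_b)),
    )
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _, _, a, b in candidates:
        if len(pairs) == n_pairs:
            break
        if a in used or b in used:
            continue
        pairs.append((a, b))
        used.update((a, b))
    return pairs


def compute_metric_table(
    cohort: Sequence[SubjectSeries],
    layout: PhaseLayout | None = None,
    epochs: dict[str, EpochSpec] | None = None,
    plateau_start: int | None = None,
) -> pd.DataFrame:
    """Long-format metric table: one row per subject x measure x epoch.

    Emits learning measures for every subject and the post-phase measures
    that the layout's post phases support (aftereffects for washout,
    retention and retention-accuracy for the retention tests).
    """
    layout = layout or PhaseLayout()
    epochs = epochs or default_epochs(layout)
    plateau_start = plateau_start or plateau_start_stride()
    rows = []

    def add(series, measure, epoch, value):
        rows.append((series.subject_id, series.group, measure, epoch, value))

    for s in cohort:
        early, late = epochs["early_learning"], epochs["late_learning"]
        add(s, "dlsl_early", early.name, epoch_mean_dlsl(s, early))
        add(s, "dlsl_late", late.name, epoch_mean_dlsl(s, late))
        for spec in (early, late):
            add(s, "error", spec.name, epoch_target_error(s, spec))
            add(s, "pct_success", spec.name, epoch_percent_success(s, spec))
            add(s, "sigma_dlsl", spec.name, sigma_dlsl(s, spec, epochs["baseline_ref"]))
        t2t_s, t2t_f = sigma_trial_to_trial(s, epochs["baseline_ref"])
        add(s, "sigma_t2t_success", "learning_scope", t2t_s)
        add(s, "sigma_t2t_fail", "learning_scope", t2t_f)
        add(s, "total_sd_plateau", "plateau", total_sd_plateau(s, plateau_start))
        add(s, "learning_rate", "plateau", learning_rate_proxy(s, plateau_start))

        for post in layout.posts:
            if post.kind == "washout":
                if "immediate_washout" in epochs:
                    add(s, "aftereffect_immediate", "immediate_washout",
                        percent_of_learned(s, epochs["immediate_washout"], epochs))
                if "early_washout" in epochs:
                    add(s, "aftereffect_early", "early_washout",
                        percent_of_learned(s, epochs["early_washout"], epochs))
            elif post.kind == "immediate_retention":
                spec = epochs["immediate_retention"]
                add(s, "retention_immediate", spec.name, percent_of_learned(s, spec, epochs))
                add(s, "abs_retention_error_immediate", spec.name,
                    absolute_retention_error(s, spec, epochs))
            elif post.kind == "retention_24h":
                spec = epochs["retention_24h"]
                add(s, "retention_24h", spec.name, percent_of_learned(s, spec, epochs))
                add(s, "abs_retention_error_24h", spec.name,
                    absolute_retention_error(s, spec, epochs))

    return pd.DataFrame(rows, columns=METRIC_TABLE_COLUMNS)
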