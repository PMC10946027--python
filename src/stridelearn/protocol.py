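"""Experimental protocol: phase layout, adaptive target schedule, reward window, epochs.

The task studied here is a treadmill stepping protocol in which participants
gradually learn to walk with a left step length (LSL) 10% longer than their
own baseline. A session consists of a baseline phase (walk normally), a
learning phase driven by visual feedback, and one or more post-learning
phases probing motor memory: a washout (implicit aftereffects) or explicit
retention tests immediately after learning and 24 h later.

During learning the target is adaptive: it sits on the participant's
baseline LSL for an initial hold, then ramps up in small percent steps every
few strides until it plateaus at its final offset, where it stays for the
remainder of the phase. Reward/success is binary: a stride counts as
successful when the executed LSL lands inside an absolute window of fixed
half-width (±2 cm by default) centred on the current target. The window
width is the same for everyone — only the centre scales with baseline — so
task difficulty does not depend on body size.

Everything downstream (metrics, inference) slices stride series by named
epochs defined here, e.g. "early learning" = the first 50 strides after the
target reaches its plateau, "late learning" = the last 50 strides of the
learning phase.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolConfigError",
    "PostPhase",
    "PhaseLayout",
    "EpochSpec",
    "build_target_schedule",
    "classify_success",
    "epoch_slice",
    "default_epochs",
    "plateau_start_stride",
    "write_schedule",
    "read_schedule",
    "PHASE_BASELINE",
    "PHASE_LEARNING",
    "POST_KINDS",
]

PHASE_BASELINE = "baseline"
PHASE_LEARNING = "learning"

#: Recognised post-learning phase kinds and their default stride counts.
POST_KINDS = ("washout", "immediate_retention", "retention_24h")
_DEFAULT_POST_N = {"washout": 900, "immediate_retention": 25, "retention_24h": 250}

SCHEDULE_COLUMNS = ["stride", "center_pct", "center_m", "lower_m", "upper_m"]


class ProtocolConfigError(ValueError):
    """Raised for invalid protocol parameters (non-positive counts, bad phases...)."""


@dataclass(frozen=True)
class PostPhase:
    """One post-learning phase: its kind and stride count."""

    kind: str
    n: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in POST_KINDS:
            raise ProtocolConfigError(
                f"unknown post phase kind {self.kind!r}; valid kinds: {POST_KINDS}"
            )
        if self.n is None:
            object.__setattr__(self, "n", _DEFAULT_POST_N[self.kind])
        if self.n <= 0:
            raise ProtocolConfigError(f"post phase {self.kind!r} needs n > 0, got {self.n}")


@dataclass(frozen=True)
class PhaseLayout:
    """Stride counts for every phase of a session.

    Defaults follow the study protocol: 250 baseline strides and 900 learning
    strides. Post phases default to a single 900-stride washout; the
    retention variant carries the immediate (25-stride) and 24 h (250-stride)
    explicit retention tests.
    """

    baseline_n: int = 250
    learning_n: int = 900
    posts: tuple[PostPhase, ...] = (PostPhase("washout"),)

    def __post_init__(self) -> None:
        if self.baseline_n <= 0 or self.learning_n <= 0:
            raise ProtocolConfigError(
                f"phase counts must be > 0 (baseline_n={self.baseline_n}, "
                f"learning_n={self.learning_n})"
            )
        posts = tuple(
            p if isinstance(p, PostPhase) else PostPhase(**p) if isinstance(p, Mapping) else PostPhase(*p)
            for p in self.posts
        )
        kinds = [p.kind for p in posts]
        if len(set(kinds)) != len(kinds):
            raise ProtocolConfigError(f"duplicate post phase kinds: {kinds}")
        object.__setattr__(self, "posts", posts)

    @classmethod
    def washout(cls, baseline_n: int = 250, learning_n: int = 900, post_n: int = 900) -> "PhaseLayout":
        """Experiment-1 shape: implicit aftereffects probed by a washout phase."""
        return cls(baseline_n, learning_n, (PostPhase("washout", post_n),))

    @classmethod
    def retention(cls, baseline_n: int = 250, learning_n: int = 900) -> "PhaseLayout":
        """Experiment-2 shape: immediate and 24 h explicit retention tests."""
        return cls(
            baseline_n,
            learning_n,
            (PostPhase("immediate_retention"), PostPhase("retention_24h")),
        )

    @property
    def phase_names(self) -> tuple[str, ...]:
        return (PHASE_BASELINE, PHASE_LEARNING) + tuple(p.kind for p in self.posts)

    def length(self, phase: str) -> int:
        if phase == PHASE_BASELINE:
            return self.baseline_n
        if phase == PHASE_LEARNING:
            return self.learning_n
        for p in self.posts:
            if p.kind == phase:
                return p.n
        raise ProtocolConfigError(
            f"unknown phase {phase!r}; valid phases: {self.phase_names}"
        )

    @property
    def total_strides(self) -> int:
        return self.baseline_n + self.learning_n + sum(p.n for p in self.posts)


@dataclass(frozen=True)
class EpochSpec:
    """A named contiguous slice of one phase, 1-based inclusive indices."""

    name: str
    phase: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.stop):
            raise ProtocolConfigError(
                f"epoch {self.name!r}: need 1 <= start <= stop, got [{self.start}, {self.stop}]"
            )

    @property
    def n(self) -> int:
        return self.stop - self.start + 1


def plateau_start_stride(
    ramp_hold: int = 50,
    step_pct: float = 1.0,
    strides_per_step: int = 10,
    final_pct: float = 10.0,
) -> int:
    """First learning stride at which the target sits at its final offset.

    With the default ramp (hold 50, +1% every 10 strides up to 10%) this is
    stride 141: the plateau spans strides 141-900 of a 900-stride phase.
    """
    n_steps = int(math.ceil(final_pct / step_pct))
    return ramp_hold + strides_per_step * (n_steps - 1) + 1


def default_epochs(
    layout: PhaseLayout | None = None,
    ramp_hold: int = 50,
    step_pct: float = 1.0,
    strides_per_step: int = 10,
    final_pct: float = 10.0,
    epoch_len: int = 50,
) -> dict[str, EpochSpec]:
    """The analysis epochs, adapted to a layout.

    baseline_ref is the final 50 strides of baseline (the ΔLSL reference),
    early_learning the first 50 strides after the target plateau,
    late_learning the last 50 strides of learning; washout splits into the
    first 5 strides (immediate) and the next 25 (early); each retention test
    uses its first 25 strides.
    """
    layout = layout or PhaseLayout()
    plateau = plateau_start_stride(ramp_hold, step_pct, strides_per_step, final_pct)
    epochs = {
        "baseline_ref": EpochSpec(
            "baseline_ref", PHASE_BASELINE,
            max(1, layout.baseline_n - epoch_len + 1), layout.baseline_n,
        ),
        "early_learning": EpochSpec(
            "early_learning", PHASE_LEARNING,
            plateau, min(layout.learning_n, plateau + epoch_len - 1),
        ),
        "late_learning": EpochSpec(
            "late_learning", PHASE_LEARNING,
            max(1, layout.learning_n - epoch_len + 1), layout.learning_n,
        ),
    }
    for post in layout.posts:
        if post.kind == "washout":
            epochs["immediate_washout"] = EpochSpec("immediate_washout", "washout", 1, min(5, post.n))
            if post.n >= 6:
                epochs["early_washout"] = EpochSpec("early_washout", "washout", 6, min(30, post.n))
        else:
            epochs[post.kind] = EpochSpec(post.kind, post.kind, 1, min(25, post.n))
    return epochs


def build_target_schedule(
    baseline_lsl_m: float,
    learning_n: int = 900,
    ramp_hold: int = 50,
    step_pct: float = 1.0,
    strides_per_step: int = 10,
    final_pct: float = 10.0,
    half_width_m: float = 0.02,
) -> pd.DataFrame:
    """Per-stride target centres and reward-window bounds for the learning phase.

    The target centre is ``baseline_lsl_m * (1 + center_pct/100)`` where
    ``center_pct`` holds at 0 for the first ``ramp_hold`` strides, then rises
    by ``step_pct`` every ``strides_per_step`` strides (the first stride of
    each block carries the new level) until it reaches ``final_pct``, where it
    stays. The window is the centre ± ``half_width_m`` in metres — relative
    centre, absolute width.

    Returns a DataFrame with columns stride (1-based), center_pct, center_m,
    lower_m, upper_m; one row per learning stride.
    """
    if baseline_lsl_m <= 0:
        raise ProtocolConfigError(f"baseline_lsl_m must be > 0, got {baseline_lsl_m}")
    if min(learning_n, ramp_hold, strides_per_step) <= 0 or step_pct <= 0 or final_pct <= 0:
        raise ProtocolConfigError(
            "learning_n, ramp_hold, strides_per_step, step_pct and final_pct must be > 0"
        )
    if half_width_m <= 0:
        raise ProtocolConfigError(f"half_width_m must be > 0, got {half_width_m}")

    stride = np.arange(1, learning_n + 1)
    ramp_level = step_pct * np.ceil((stride - ramp_hold) / strides_per_step)
    center_pct = np.clip(ramp_level, 0.0, final_pct)
    center_m = baseline_lsl_m * (1.0 + center_pct / 100.0)
    return pd.DataFrame(
        {
            "stride": stride,
            "center_pct": center_pct,
            "center_m": center_m,
            "lower_m": center_m - half_width_m,
            "upper_m": center_m + half_width_m,
        }
    )


def classify_success(lsl_m, lower_m, upper_m):
    """Binary reward rule: success iff the step length falls inside the window.

    Bounds are inclusive on both sides (a physical ±2 cm tolerance). Accepts
    scalars or aligned arrays.
    """
    lsl_m = np.asarray(lsl_m)
    out = (np.asarray(lower_m) <= lsl_m) & (lsl_m <= np.asarray(upper_m))
    return bool(out) if out.ndim == 0 else out


def _phase_frame(series, phase: str) -> pd.DataFrame:
    table = series.table if hasattr(series, "table") else series
    sub = table[table["phase"] == phase]
    if sub.empty:
        raise IndexError(f"phase {phase!r} not present in series")
    return sub


def epoch_slice(series, spec: EpochSpec, column: str = "lsl_m") -> np.ndarray:
    """Values of ``column`` over an epoch, in stride order.

    ``series`` is a SubjectSeries or a stride-table DataFrame with ``phase``
    and ``stride`` columns. Raises IndexError (naming the phase) when the
    epoch extends beyond the phase.
    """
    sub = _phase_frame(series, spec.phase).sort_values("stride")
    n_phase = int(sub["stride"].max())
    if spec.stop > n_phase:
        raise IndexError(
            f"epoch {spec.name!r} [{spec.start}, {spec.stop}] exceeds the "
            f"{spec.phase!r} phase (length {n_phase})"
        )
    mask = (sub["stride"] >= spec.start) & (sub["stride"] <= spec.stop)
    values = sub.loc[mask, column].to_numpy()
    if len(values) != spec.n:
        raise IndexError(
            f"epoch {spec.name!r} expected {spec.n} strides in phase "
            f"{spec.phase!r} but found {len(values)}"
        )
    return values


def write_schedule(schedule: pd.DataFrame, path) -> None:
    """Write a target schedule as TSV (stride, center_pct, center_m, lower_m, upper_m)."""
    schedule[SCHEDULE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_schedule(path) -> pd.DataFrame:
    sched = pd.read_csv(path, sep="\t")
    missing = set(SCHEDULE_COLUMNS) - set(sched.columns)
    if missing:
        raise ProtocolConfigError(f"schedule file {path} missing columns {sorted(missing)}")
    return sched[SCHEDULE_COLUMNS]
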