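"""Synthetic walkers: agents that learn the stepping task, and trace synthesis.

No raw participant data accompanies the study this analysis targets, so the
pipeline is exercised end-to-end on simulated subjects whose behaviour
carries the statistical structure the analysis assumes:

* A **TE agent** (target-error group) sees its step length and the target,
  and corrects a fraction of each target error: aim(s+1) = aim(s) +
  gain * (target_centre(s) - executed(s)). It tracks the ramping target
  tightly with near-baseline variability.
* An **RPE agent** (reward-prediction-error group) receives only the binary
  reward and follows a win-stay/lose-shift policy: after a rewarded stride
  the aim is retained (optionally with a small exploitation jitter) and the
  exploration scale decays multiplicatively toward its floor of 1; after an
  unrewarded stride the next aim is perturbed by Gaussian exploration noise
  whose SD is the current scale times the baseline motor noise. Reward is
  judged against the (invisible) target window. This is the minimal policy
  that produces elevated early-learning variability which decays as the
  reward landscape is learned — the exploration/exploitation trade-off.
* **Post-learning memory**: washout expresses a retained fraction of the
  learned change decaying per stride (implicit aftereffect); retention
  reproduces the late-learning pattern plus a signed recall bias
  (negative = understep, the RPE signature; positive = overstep, the TE
  signature), at both the immediate and the 24 h test.

Both agents execute every aim with additive Gaussian motor noise whose SD
defaults to 1.5% of baseline step length, which keeps the ±2 cm reward
window comfortably inside baseline variability. All randomness derives from
a single per-subject seed (separate streams per phase), so a subject,
cohort, or trace is bit-reproducible from its seed.

``synthesize_traces`` converts a subject's stride series into heel-marker
and force-plate time series with heel strikes planted at known samples and
marker separations equal to the planted step lengths, for round-trip testing
of the event detector.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gait_events import GaitTimeSeries, STRIDE_TABLE_COLUMNS, REFRACTORY_S
from .protocol import (
    PHASE_BASELINE,
    PHASE_LEARNING,
    PhaseLayout,
    build_target_schedule,
    classify_success,
    default_epochs,
)

__all__ = [
    "AgentParams",
    "SubjectSeries",
    "CohortHyper",
    "simulate_te_agent",
    "simulate_rpe_agent",
    "simulate_post_phase",
    "simulate_subject",
    "simulate_cohort",
    "synthesize_traces",
    "GROUP_RPE",
    "GROUP_TE",
]

GROUP_RPE = "RPE"
GROUP_TE = "TE"

#: Group-specific defaults for fields left as None in AgentParams.
_GROUP_DEFAULTS = {
    GROUP_RPE: {"washout_retain": 0.45, "recall_bias_pct": -1.5},
    GROUP_TE: {"washout_retain": 0.55, "recall_bias_pct": 2.5},
}

#: Baseline motor noise as a fraction of baseline step length.
DEFAULT_NOISE_FRAC = 0.015


@dataclass
class AgentParams:
    """Parameters of one simulated subject.

    ``correction_gain`` drives the TE agent; ``explore_*`` and
    ``exploit_shift_sd_scale`` drive the RPE agent; the ``washout_*`` and
    ``recall_bias_pct`` fields shape post-learning memory for either group.
    """

    group: str
    baseline_lsl_m: float = 0.6
    baseline_sd_m: float | None = None
    correction_gain: float = 0.3
    explore_sd_scale: float = 2.5
    explore_decay: float = 0.995
    exploit_shift_sd_scale: float = 0.0
    washout_retain: float | None = None
    washout_decay: float = 0.995
    recall_bias_pct: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in (GROUP_RPE, GROUP_TE):
            raise ValueError(f"group must be {GROUP_RPE!r} or {GROUP_TE!r}, got {self.group!r}")
        if self.baseline_lsl_m <= 0:
            raise ValueError(f"baseline_lsl_m must be > 0, got {self.baseline_lsl_m}")
        if self.baseline_sd_m is None:
            self.baseline_sd_m = DEFAULT_NOISE_FRAC * self.baseline_lsl_m
        if self.baseline_sd_m < 0:
            raise ValueError("baseline_sd_m must be >= 0")
        if not 0.0 <= self.correction_gain <= 1.0:
            raise ValueError(f"correction_gain must be in [0, 1], got {self.correction_gain}")
        if self.explore_sd_scale < 1.0:
            raise ValueError(f"explore_sd_scale must be >= 1, got {self.explore_sd_scale}")
        if not 0.0 < self.explore_decay <= 1.0:
            raise ValueError(f"explore_decay must be in (0, 1], got {self.explore_decay}")
        if self.exploit_shift_sd_scale < 0:
            raise ValueError("exploit_shift_sd_scale must be >= 0")
        defaults = _GROUP_DEFAULTS[self.group]
        if self.washout_retain is None:
            self.washout_retain = defaults["washout_retain"]
        if self.recall_bias_pct is None:
            self.recall_bias_pct = defaults["recall_bias_pct"]
        if not 0.0 <= self.washout_retain <= 1.0:
            raise ValueError(f"washout_retain must be in [0, 1], got {self.washout_retain}")
        if not 0.0 < self.washout_decay <= 1.0:
            raise ValueError(f"washout_decay must be in (0, 1], got {self.washout_decay}")


@dataclass
class SubjectSeries:
    """A subject's full protocol as an ordered stride table plus baseline summaries.

    ``table`` follows the canonical stride-table schema (subject, group,
    phase, stride, lsl_m, target_center_pct, success); success flags exist
    only during learning.
    """

    subject_id: str
    group: str
    table: pd.DataFrame
    params: AgentParams | None = None

    def phase_values(self, phase: str) -> np.ndarray:
        sub = self.table[self.table["phase"] == phase].sort_values("stride")
        return sub["lsl_m"].to_numpy()

    def _baseline_ref_values(self, n_ref: int = 50) -> np.ndarray:
        base = self.phase_values(PHASE_BASELINE)
        if len(base) == 0:
            raise ValueError(f"subject {self.subject_id}: no baseline phase")
        return base[-min(n_ref, len(base)):]

    @property
    def baseline_mean_m(self) -> float:
        """Mean LSL over the baseline reference epoch (final 50 baseline strides)."""
        return float(np.mean(self._baseline_ref_values()))

    @property
    def baseline_sd_m(self) -> float:
        """Sample SD of LSL over the baseline reference epoch."""
        return float(np.std(self._baseline_ref_values(), ddof=1))


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-phase random streams derived from one subject seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("baseline", "learning", "post", "traces")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _assemble(subject_id, group, phase_rows) -> pd.DataFrame:
    return pd.DataFrame(phase_rows, columns=STRIDE_TABLE_COLUMNS)


def _baseline_rows(params: AgentParams, layout: PhaseLayout, rng, subject_id) -> list:
    noise = rng.normal(0.0, params.baseline_sd_m, layout.baseline_n)
    return [
        (subject_id, params.group, PHASE_BASELINE, s + 1,
         params.baseline_lsl_m + noise[s], np.nan, np.nan)
        for s in range(layout.baseline_n)
    ]


def _check_schedule(schedule: pd.DataFrame, layout: PhaseLayout) -> None:
    if len(schedule) < layout.learning_n:
        raise ValueError(
            f"schedule has {len(schedule)} entries but the layout's learning "
            f"phase has {layout.learning_n} strides"
        )


def simulate_te_agent(
    params: AgentParams,
    schedule: pd.DataFrame,
    layout: PhaseLayout | None = None,
    subject_id: str = "TE01",
) -> SubjectSeries:
    """Simulate baseline + learning for a target-error corrector.

    The aim starts at baseline and moves by ``correction_gain`` times the
    visible target error after every stride; each executed step adds baseline
    motor noise. Success flags come from the reward window even though the TE
    group is driven by the error, not the reward.
    """
    if params.group != GROUP_TE:
        raise ValueError(f"simulate_te_agent requires group TE, got {params.group!r}")
    layout = layout or PhaseLayout()
    _check_schedule(schedule, layout)
    rngs = _rngs(params.seed)
    rows = _baseline_rows(params, layout, rngs["baseline"], subject_id)

    rng = rngs["learning"]
    center = schedule["center_m"].to_numpy()
    lower = schedule["lower_m"].to_numpy()
    upper = schedule["upper_m"].to_numpy()
    center_pct = schedule["center_pct"].to_numpy()
    aim = params.baseline_lsl_m
    for s in range(layout.learning_n):
        x = aim + rng.normal(0.0, params.baseline_sd_m)
        success = classify_success(x, lower[s], upper[s])
        rows.append((subject_id, params.group, PHASE_LEARNING, s + 1,
                     x, float(center_pct[s]), float(success)))
        aim = aim + params.correction_gain * (center[s] - x)
    return SubjectSeries(subject_id, params.group, _assemble(subject_id, params.group, rows), params)


def simulate_rpe_agent(
    params: AgentParams,
    schedule: pd.DataFrame,
    layout: PhaseLayout | None = None,
    subject_id: str = "RPE01",
) -> SubjectSeries:
    """Simulate baseline + learning for a win-stay/lose-shift reward learner.

    After a rewarded stride the aim is kept (plus optional exploitation
    jitter) and the exploration scale decays by ``explore_decay`` (floored at
    1). After an unrewarded stride the next aim is a Gaussian perturbation of
    SD ``current_scale * baseline_sd_m`` around the last *rewarded* aim — the
    win-stay anchor — so exploration searches outward from the best known
    action; before any reward has been earned there is no anchor and the
    perturbation is centred on the current aim, so an agent that is never
    rewarded performs an unanchored random walk. The target window is
    invisible to the agent — only the binary outcome feeds back.
    """
    if params.group != GROUP_RPE:
        raise ValueError(f"simulate_rpe_agent requires group RPE, got {params.group!r}")
    layout = layout or PhaseLayout()
    _check_schedule(schedule, layout)
    rngs = _rngs(params.seed)
    rows = _baseline_rows(params, layout, rngs["baseline"], subject_id)

    rng = rngs["learning"]
    lower = schedule["lower_m"].to_numpy()
    upper = schedule["upper_m"].to_numpy()
    center_pct = schedule["center_pct"].to_numpy()
    aim = params.baseline_lsl_m
    anchor: float | None = None  # last rewarded aim
    scale = params.explore_sd_scale
    sd = params.baseline_sd_m
    for s in range(layout.learning_n):
        x = aim + rng.normal(0.0, sd)
        success = classify_success(x, lower[s], upper[s])
        rows.append((subject_id, params.group, PHASE_LEARNING, s + 1,
                     x, float(center_pct[s]), float(success)))
        if success:
            anchor = aim
            if params.exploit_shift_sd_scale > 0:
                aim = aim + rng.normal(0.0, params.exploit_shift_sd_scale * sd)
            scale = max(1.0, scale * params.explore_decay)
        else:
            base = aim if anchor is None else anchor
            aim = base + rng.normal(0.0, scale * sd)
            # failure signals unlearned values: exploration recovers toward its cap
            scale = min(params.explore_sd_scale, scale / params.explore_decay)
    return SubjectSeries(subject_id, params.group, _assemble(subject_id, params.group, rows), params)


def simulate_post_phase(series: SubjectSeries, layout: PhaseLayout | None = None) -> SubjectSeries:
    """Fill the layout's post-learning phases of a simulated subject in place.

    Washout expresses ``washout_retain`` of the late-learning change, decaying
    by ``washout_decay`` per stride; each retention test reproduces the
    late-learning change plus ``recall_bias_pct``. Per-stride motor noise is
    the subject's baseline noise expressed in ΔLSL percentage points. Refuses
    to overwrite post phases that are already present.
    """
    if series.params is None:
        raise ValueError("simulate_post_phase needs the subject's AgentParams")
    layout = layout or PhaseLayout()
    params = series.params
    present = set(series.table["phase"].unique())
    post_kinds = [p.kind for p in layout.posts]
    clash = present.intersection(post_kinds)
    if clash:
        raise ValueError(f"post phase(s) {sorted(clash)} already present; refusing to overwrite")
    learn = series.phase_values(PHASE_LEARNING)
    if len(learn) < layout.learning_n:
        raise ValueError("learning phase incomplete; simulate it before the post phase")

    base_mean = series.baseline_mean_m
    late = learn[-min(50, len(learn)):]
    dlsl_late = (np.mean(late) - base_mean) / base_mean * 100.0
    noise_pct = params.baseline_sd_m / base_mean * 100.0

    rng = _rngs(params.seed)["post"]
    rows = []
    for post in layout.posts:
        strides = np.arange(1, post.n + 1)
        if post.kind == "washout":
            det = params.washout_retain * dlsl_late * params.washout_decay ** (strides - 1)
        else:
            det = np.full(post.n, dlsl_late + params.recall_bias_pct)
        dlsl = det + rng.normal(0.0, noise_pct, post.n)
        lsl = base_mean * (1.0 + dlsl / 100.0)
        for s, v in zip(strides, lsl):
            rows.append((series.subject_id, series.group, post.kind, int(s), v, np.nan, np.nan))
    post_df = pd.DataFrame(rows, columns=STRIDE_TABLE_COLUMNS).astype(
        series.table.dtypes.to_dict()
    )
    series.table = pd.concat([series.table, post_df], ignore_index=True)
    return series


def simulate_subject(
    params: AgentParams,
    schedule: pd.DataFrame | None = None,
    layout: PhaseLayout | None = None,
    subject_id: str | None = None,
) -> SubjectSeries:
    """Simulate one subject end to end (baseline, learning, post phases).

    When no schedule is given, the default ramp schedule is built on the
    subject's own baseline step length, as in the study protocol.
    """
    layout = layout or PhaseLayout()
    if schedule is None:
        schedule = build_target_schedule(params.baseline_lsl_m, learning_n=layout.learning_n)
    subject_id = subject_id or f"{params.group}01"
    sim = simulate_rpe_agent if params.group == GROUP_RPE else simulate_te_agent
    series = sim(params, schedule, layout, subject_id)
    return simulate_post_phase(series, layout)


@dataclass
class CohortHyper:
    """Per-group hyper-distributions for subject parameters.

    Baseline step length is drawn uniformly from ``baseline_range`` (metres).
    ``group_fields`` maps group -> field -> either a fixed value or a
    ``("lognormal", median, sigma)`` triple; unlisted fields keep the
    AgentParams defaults. Distributions with negative support are rejected at
    draw time by AgentParams validation.
    """

    baseline_range: tuple[float, float] = (0.5, 0.7)
    group_fields: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.baseline_range
        if not 0 < lo <= hi:
            raise ValueError(f"baseline_range must satisfy 0 < lo <= hi, got {self.baseline_range}")

    def draw(self, group: str, rng: np.random.Generator, seed: int) -> AgentParams:
        kwargs: dict[str, object] = {}
        for fname, spec in self.group_fields.get(group, {}).items():
            if isinstance(spec, (tuple, list)):
                kind, median, sigma = spec
                if kind != "lognormal":
                    raise ValueError(f"unknown distribution {kind!r} for field {fname!r}")
                if median <= 0:
                    raise ValueError(f"lognormal median for {fname!r} must be > 0")
                kwargs[fname] = float(median * math.exp(sigma * rng.standard_normal()))
            else:
                kwargs[fname] = spec
        baseline = rng.uniform(*self.baseline_range)
        return AgentParams(group=group, baseline_lsl_m=float(baseline), seed=seed, **kwargs)


def simulate_cohort(
    n_per_group: tuple[int, int] = (15, 15),
    layout: PhaseLayout | None = None,
    hyper: CohortHyper | None = None,
    seed: int = 0,
    schedule_kwargs: Mapping[str, object] | None = None,
) -> list[SubjectSeries]:
    """Simulate a two-group cohort (n_RPE, n_TE subjects).

    Each subject's parameters are drawn from ``hyper`` and their target
    schedule is built on their own baseline step length. Subject seeds derive
    deterministically from the master seed, so the cohort's stride tables are
    bit-identical across runs with the same seed.
    """
    n_rpe, n_te = n_per_group
    if n_rpe < 0 or n_te < 0 or n_rpe + n_te < 1:
        raise ValueError(f"need at least one subject, got n_per_group={n_per_group}")
    layout = layout or PhaseLayout()
    hyper = hyper or CohortHyper()
    schedule_kwargs = dict(schedule_kwargs or {})
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cohort: list[SubjectSeries] = []
    for group, n in ((GROUP_RPE, n_rpe), (GROUP_TE, n_te)):
        for i in range(n):
            sub_seed = int(rng.integers(0, 2**31))
            params = hyper.draw(group, rng, sub_seed)
            schedule = build_target_schedule(
                params.baseline_lsl_m, learning_n=layout.learning_n, **schedule_kwargs
            )
            cohort.append(
                simulate_subject(params, schedule, layout, subject_id=f"{group}{i + 1:02d}")
            )
    return cohort


def synthesize_traces(
    series: SubjectSeries,
    cadence_s: float = 1.1,
    trace_noise_m: float = 0.0,
    seed: int = 0,
    kin_rate: float = 100.0,
    grf_rate: float = 1000.0,
    swing_amplitude_m: float = 0.3,
    stance_frac: float = 0.6,
    stance_force_n: float = 700.0,
) -> GaitTimeSeries:
    """Marker and force traces with heel strikes planted at known samples.

    Heel trajectories are antiphase sinusoids riding on a slowly re-anchored
    offset, arranged so the left heel's AP velocity crosses from positive to
    negative half a kinematic sample before stride k's planted time k*T
    (T = ``cadence_s`` snapped to the kinematic grid); the detector then
    fires exactly at sample k*T, where the left-right marker separation
    equals the planted step length before trace noise. Left-belt force is a
    square wave, on for ``stance_frac`` of each cycle starting at the planted
    strike. Offset re-anchoring between strides happens mid-swing, where the
    force gate is off, so it can never spawn events.
    """
    dt = 1.0 / kin_rate
    T = round(cadence_s * kin_rate) / kin_rate
    if T <= REFRACTORY_S:
        raise ValueError(
            f"cadence_s={cadence_s} is too short for the {REFRACTORY_S} s "
            "detection refractory period"
        )
    lengths = series.table["lsl_m"].to_numpy()  # table rows are already in protocol order
    n = len(lengths)
    if n == 0:
        raise ValueError("series has no strides to synthesize")

    omega = 2.0 * math.pi / T
    eps = dt / 2.0  # peak leads the planted sample by half a kinematic sample
    t_end = n * T + 0.5 * T
    kin_time = np.arange(0.0, t_end + dt / 2, dt)
    grf_time = np.arange(0.0, t_end + 0.5 / grf_rate, 1.0 / grf_rate)

    A = swing_amplitude_m
    c_vals = lengths - 2.0 * A * math.cos(omega * eps)
    k = np.arange(1, n + 1)
    knots_t = np.column_stack([k * T - 0.3 * T, k * T + 0.6 * T]).ravel()
    knots_c = np.repeat(c_vals, 2)
    offset = np.interp(kin_time, knots_t, knots_c)

    carrier = np.cos(omega * (kin_time + eps))
    left = offset + A * carrier
    right = -A * carrier

    if trace_noise_m > 0:
        rng = np.random.default_rng(seed)
        left = left + rng.normal(0.0, trace_noise_m, left.shape)
        right = right + rng.normal(0.0, trace_noise_m, right.shape)

    # Stance starts 2 ms before the planted strike so float jitter in the
    # phase computation can never leave the strike sample unloaded.
    guard = 0.002
    u = np.mod(grf_time + guard, T)
    left_grf = np.where(u < stance_frac * T, stance_force_n, 0.0)
    # right belt loads in antiphase (not used by left-event detection)
    u_r = np.mod(grf_time + guard + 0.5 * T, T)
    right_grf = np.where(u_r < stance_frac * T, stance_force_n, 0.0)

    return GaitTimeSeries(
        kin_time=kin_time,
        left_heel_ap=left,
        right_heel_ap=right,
        grf_time=grf_time,
        left_grf_z=left_grf,
        right_grf_z=right_grf,
        kin_rate=kin_rate,
        grf_rate=grf_rate,
    )
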