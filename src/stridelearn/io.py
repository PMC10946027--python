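"""Readers, writers, run configuration, and the end-to-end pipeline.

Canonical on-disk formats are TSV ('.' decimal, no thousands separators) for
tables and JSON for structured reports; both are diffable and language
neutral. A pipeline run writes per-stage subdirectories (01_simulate,
02_metrics, 03_infer), each with a manifest recording the package version,
the config hash, the master seed and row counts, so stages can be rerun and
audited independently. A run's config plus seed reproduces its stride and
metric tables bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (
    MCMCConfig,
    PosteriorContrast,
    fit_cell_model,
    group_difference,
    slope_difference,
    summarize_contrast,
)
from .gait_events import STRIDE_TABLE_COLUMNS
from .metrics import METRIC_TABLE_COLUMNS, compute_metric_table
from .protocol import PHASE_BASELINE, PHASE_LEARNING, POST_KINDS, PhaseLayout, default_epochs
from .synthetic_walkers import CohortHyper, SubjectSeries, simulate_cohort

__all__ = [
    "RunConfig",
    "read_stride_table",
    "write_stride_table",
    "read_metric_table",
    "write_metric_table",
    "write_contrasts",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

VALID_PHASES = (PHASE_BASELINE, PHASE_LEARNING) + POST_KINDS


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    experiment: str = "washout"  # "washout" (aftereffects) or "retention"
    n_rpe: int = 15
    n_te: int = 15
    baseline_n: int = 250
    learning_n: int = 900
    baseline_range: tuple[float, float] = (0.5, 0.7)
    group_fields: dict = field(default_factory=dict)  # CohortHyper.group_fields
    schedule: dict = field(default_factory=dict)      # build_target_schedule overrides
    draws: int = 10_000
    chains: int = 4
    tune: int = 1_000
    seed: int = 0
    out_dir: str = "stridelearn_run"

    def __post_init__(self) -> None:
        self.baseline_range = tuple(self.baseline_range)
        if self.experiment not in ("washout", "retention"):
            raise ValueError(
                f"experiment must be 'washout' or 'retention', got {self.experiment!r}"
            )

    @property
    def layout(self) -> PhaseLayout:
        maker = PhaseLayout.washout if self.experiment == "washout" else PhaseLayout.retention
        return maker(baseline_n=self.baseline_n, learning_n=self.learning_n)

    @property
    def hyper(self) -> CohortHyper:
        return CohortHyper(baseline_range=tuple(self.baseline_range),
                           group_fields=self.group_fields)

    @property
    def mcmc(self) -> MCMCConfig:
        return MCMCConfig(draws=self.draws, chains=self.chains, tune=self.tune)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(known)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Stride / metric table I/O
# ---------------------------------------------------------------------------

def write_stride_table(cohort: Sequence[SubjectSeries] | pd.DataFrame, path) -> None:
    if isinstance(cohort, pd.DataFrame):
        table = cohort
    else:
        table = pd.concat([s.table for s in cohort], ignore_index=True)
    table[STRIDE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_stride_table(path) -> list[SubjectSeries]:
    """Read a stride-table TSV and group it into SubjectSeries.

    Validates the schema, phase labels, duplicate keys and per-phase stride
    monotonicity; an empty (header-only) file yields an empty collection with
    a logged warning.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(STRIDE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stride table {path} missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("stride table %s contains a header but no rows", path)
        return []
    bad_phase = set(df["phase"].unique()) - set(VALID_PHASES)
    if bad_phase:
        raise ValueError(
            f"stride table {path}: unknown phase labels {sorted(bad_phase)}; "
            f"valid labels: {VALID_PHASES}"
        )
    dup = df.duplicated(subset=["subject", "phase", "stride"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"stride table {path}: duplicated key (subject={row['subject']!r}, "
            f"phase={row['phase']!r}, stride={row['stride']})"
        )
    if not np.issubdtype(df["lsl_m"].dtype, np.number):
        bad = df[pd.to_numeric(df["lsl_m"], errors="coerce").isna()].index[0]
        raise ValueError(f"stride table {path}: non-numeric lsl_m at row {bad + 2}")

    out = []
    for subject, sub in df.groupby("subject", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {subject!r} appears with multiple groups: {groups}")
        for phase, ph in sub.groupby("phase", sort=False):
            strides = ph["stride"].to_numpy()
            if not np.array_equal(np.sort(strides), np.arange(1, len(strides) + 1)):
                raise ValueError(
                    f"subject {subject!r}, phase {phase!r}: stride indices must be "
                    f"1..{len(strides)} without gaps"
                )
        out.append(SubjectSeries(str(subject), str(groups[0]), sub.reset_index(drop=True)))
    return out


def write_metric_table(table: pd.DataFrame, path) -> None:
    table[METRIC_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(METRIC_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metric table {path} missing columns {sorted(missing)}")
    return df


def write_contrasts(contrasts: Mapping[str, PosteriorContrast], path,
                    diagnostics: Mapping[str, dict] | None = None) -> None:
    payload = {k: c.to_dict() for k, c in contrasts.items()}
    if diagnostics:
        for k, d in diagnostics.items():
            if k in payload:
                payload[k]["diagnostics"] = d
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _measure_slice(metrics: pd.DataFrame, measures: Mapping[str, str]) -> pd.DataFrame:
    """Stack measure rows into a (group, epoch, value) slice.

    ``measures`` maps measure name -> label to use as the model's timepoint.
    """
    parts = []
    for measure, label in measures.items():
        sub = metrics[metrics["measure"] == measure][["subject", "group", "value"]].copy()
        sub["epoch"] = label
        parts.append(sub)
    return pd.concat(parts, ignore_index=True).dropna(subset=["value"])


def _infer_contrasts(metrics: pd.DataFrame, mcmc: MCMCConfig, seed: int,
                     experiment: str) -> dict[str, PosteriorContrast]:
    """All posterior contrasts of one experiment's metric table."""
    seeds = iter(np.random.SeedSequence(seed).generate_state(32))
    contrasts: dict[str, PosteriorContrast] = {}
    have = set(metrics["measure"].unique())

    def fit(measures: Mapping[str, str]):
        return fit_cell_model(_measure_slice(metrics, measures), mcmc=mcmc,
                              seed=int(next(seeds)) % (2**31))

    # learning level: did the RPE group learn, and the late group difference
    d = fit({"dlsl_early": "early", "dlsl_late": "late"})
    contrasts["rpe_dlsl_late"] = summarize_contrast(
        d.flat("mu[RPE,late]"), "rpe_dlsl_late", diagnostics=d.diagnostics)
    contrasts["dlsl_group_difference_late"] = group_difference(d, "late")

    # error / success / exploration: early group difference + slope difference
    for measure in ("error", "pct_success", "sigma_dlsl"):
        d = fit_cell_model(
            metrics[metrics["measure"] == measure],
            mcmc=mcmc, seed=int(next(seeds)) % (2**31),
            time_order=("early_learning", "late_learning"),
        )
        contrasts[f"{measure}_group_difference_early"] = group_difference(d, "early_learning")
        contrasts[f"{measure}_slope_difference"] = slope_difference(d)

    # win-stay/lose-shift variability: success/failure as the within factor
    if {"sigma_t2t_success", "sigma_t2t_fail"} <= have:
        d = fit({"sigma_t2t_success": "after_success", "sigma_t2t_fail": "after_failure"})
        contrasts["sigma_t2t_group_difference_fail"] = group_difference(d, "after_failure")
        contrasts["sigma_t2t_slope_difference"] = slope_difference(d)

    if experiment == "washout":
        for measure in ("aftereffect_immediate", "aftereffect_early"):
            if measure in have:
                d = fit({measure: measure})
                contrasts[f"{measure}_group_difference"] = group_difference(d, measure)
    else:
        for measure in ("retention_immediate", "retention_24h",
                        "abs_retention_error_immediate", "abs_retention_error_24h"):
            if measure in have:
                d = fit({measure: measure})
                contrasts[f"{measure}_group_difference"] = group_difference(d, measure)
    return contrasts


def _manifest(stage_dir: Path, config: RunConfig, **extra) -> None:
    payload = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        **extra,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, compute metrics, and estimate all posterior contrasts.

    Writes 01_simulate/strides.tsv, 02_metrics/metrics.tsv and
    03_infer/{contrasts.json, report.txt} under ``config.out_dir`` with a
    manifest per stage; any stage error aborts with the stage name while
    earlier stages' outputs stay on disk for debugging.
    """
    out = Path(config.out_dir)
    layout = config.layout
    stage = "01_simulate"
    try:
        d = out / stage
        d.mkdir(parents=True, exist_ok=True)
        cohort = simulate_cohort(
            n_per_group=(config.n_rpe, config.n_te),
            layout=layout,
            hyper=config.hyper,
            seed=config.seed,
            schedule_kwargs=config.schedule,
        )
        write_stride_table(cohort, d / "strides.tsv")
        config.to_yaml(d / "config.yaml")
        n_rows = sum(len(s.table) for s in cohort)
        _manifest(d, config, stage=stage, n_subjects=len(cohort), n_rows=n_rows)
        logger.info("%s: %d subjects, %d stride rows (seed %d)",
                    stage, len(cohort), n_rows, config.seed)

        stage = "02_metrics"
        d = out / stage
        d.mkdir(parents=True, exist_ok=True)
        epochs = default_epochs(layout, **{
            k: v for k, v in config.schedule.items()
            if k in ("ramp_hold", "step_pct", "strides_per_step", "final_pct")
        })
        metrics = compute_metric_table(cohort, layout, epochs)
        write_metric_table(metrics, d / "metrics.tsv")
        _manifest(d, config, stage=stage, n_rows=len(metrics))
        logger.info("%s: %d metric rows", stage, len(metrics))

        stage = "03_infer"
        d = out / stage
        d.mkdir(parents=True, exist_ok=True)
        contrasts = _infer_contrasts(metrics, config.mcmc, config.seed, config.experiment)
        write_contrasts(contrasts, d / "contrasts.json")
        report = "\n".join(c.summary() for c in contrasts.values()) + "\n"
        (d / "report.txt").write_text(report)
        _manifest(d, config, stage=stage, n_contrasts=len(contrasts))
        logger.info("%s: %d contrasts", stage, len(contrasts))
    except Exception:
        logger.error("pipeline failed in stage %s (partial outputs kept in %s)", stage, out)
        raise

    return {"cohort": cohort, "metrics": metrics, "contrasts": contrasts, "out_dir": str(out)}
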