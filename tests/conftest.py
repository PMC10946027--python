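"""Shared fixtures: small layouts, schedules, and simulated subjects."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stridelearn import (
    AgentParams,
    PhaseLayout,
    build_target_schedule,
    default_epochs,
    simulate_rpe_agent,
    simulate_subject,
    simulate_te_agent,
)
from stridelearn.bayes import MCMCConfig
from stridelearn.gait_events import STRIDE_TABLE_COLUMNS
from stridelearn.protocol import PostPhase
from stridelearn.synthetic_walkers import SubjectSeries


@pytest.fixture(scope="session")
def schedule_05():
    """Default ramp schedule on a 0.5 m baseline."""
    return build_target_schedule(0.5)


@pytest.fixture(scope="session")
def epochs():
    return default_epochs()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Small but converging sampler settings for tests."""
    return MCMCConfig(draws=1000, chains=4, tune=600, thin=6, walkers=32)


@pytest.fixture(scope="session")
def rpe_subject():
    """One fully simulated RPE subject under default study conditions."""
    return simulate_subject(AgentParams(group="RPE", baseline_lsl_m=0.6, seed=11))


@pytest.fixture(scope="session")
def te_subject():
    return simulate_subject(AgentParams(group="TE", baseline_lsl_m=0.6, seed=12))


def make_series(
    subject_id: str,
    group: str,
    phases: dict[str, np.ndarray],
    success: dict[str, np.ndarray] | None = None,
    centers: dict[str, np.ndarray] | None = None,
) -> SubjectSeries:
    """Hand-build a SubjectSeries from per-phase step-length arrays (metres)."""
    rows = []
    for phase, values in phases.items():
        suc = (success or {}).get(phase)
        cen = (centers or {}).get(phase)
        for i, v in enumerate(values):
            rows.append(
                (
                    subject_id,
                    group,
                    phase,
                    i + 1,
                    float(v),
                    float(cen[i]) if cen is not None else np.nan,
                    float(suc[i]) if suc is not None else np.nan,
                )
            )
    return SubjectSeries(subject_id, group, pd.DataFrame(rows, columns=STRIDE_TABLE_COLUMNS))


@pytest.fixture()
def toy_layout():
    """Tiny layout for plumbing tests: 4 baseline, 4 learning, 2 washout strides."""
    return PhaseLayout(baseline_n=4, learning_n=4, posts=(PostPhase("washout", 2),))
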