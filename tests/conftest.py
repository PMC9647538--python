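"""Shared fixtures.

The expensive 5-seed simulate-and-fit protocol (326 subjects, 4-class
quadratic random-effects fit, 50 starts) is session-scoped and shared by the
acceptance tests and the parameter-recovery invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from psytraj.cohort import aggregate_cohort
from psytraj.synth import GeneratorConfig, SimulatedCohort, simulate_cohort
from psytraj.gmm import GrowthMixtureFit, GrowthMixtureSpec, fit_gmm
from psytraj.selection import label_classes

PROTOCOL_SEEDS = (1, 2, 3, 4, 5)


@dataclass
class ProtocolRun:
    seed: int
    sim: SimulatedCohort
    fit: GrowthMixtureFit
    label_map: dict[int, str]

    @property
    def modal_labels(self) -> pd.Series:
        return pd.Series(
            {
                sid: self.label_map[int(k)]
                for sid, k in zip(self.fit.subject_ids, self.fit.modal_class)
            }
        )

    @property
    def shares_pct(self) -> dict[str, float]:
        return {
            self.label_map[k]: float(100.0 * self.fit.pi[k])
            for k in range(self.fit.n_classes)
        }


def run_protocol(seed: int, n_starts: int = 50) -> ProtocolRun:
    """One arm of the reference protocol: default generator at n=326, 4-class
    quadratic random-effects fit."""
    sim = simulate_cohort(GeneratorConfig(seed=seed))
    series = aggregate_cohort(sim.cohort)
    spec = GrowthMixtureSpec(
        n_classes=4,
        degree=2,
        random_effects="intercept_slope",
        n_starts=n_starts,
        seed=100 + seed,
    )
    fit = fit_gmm(series, spec)
    return ProtocolRun(seed=seed, sim=sim, fit=fit, label_map=label_classes(fit))


@pytest.fixture(scope="session")
def protocol_runs() -> list[ProtocolRun]:
    return [run_protocol(seed) for seed in PROTOCOL_SEEDS]


@pytest.fixture(scope="session")
def default_sim() -> SimulatedCohort:
    return simulate_cohort(GeneratorConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
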