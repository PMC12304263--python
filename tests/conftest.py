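"""Shared fixtures: small toy datasets and session-scoped study simulations.

The multi-seed study simulations are expensive, so they are computed once per
session and shared between the property tests and the acceptance tests that
consume them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import plasmavib as pv
from plasmavib.study import prepare_study_datasets

N_STUDY_SEEDS = 10
WET_KEYS = ("ftir_wet", "raman_wet", "fused")


@pytest.fixture
def toy_dataset() -> pv.SpectralDataset:
    """3 samples × 5 wavenumbers, one patient per group."""
    grid = np.array([900.0, 1000.0, 1100.0, 1200.0, 1300.0])
    matrix = np.array(
        [
            [1.0, 2.0, 3.0, 2.0, 1.0],
            [0.5, 1.5, 2.5, 1.5, 0.5],
            [2.0, 2.0, 2.0, 2.0, 2.0],
        ]
    )
    samples = [
        pv.SampleRecord("P1", "cancer", "ATR-FTIR", "wet", 1),
        pv.SampleRecord("P2", "healthy", "ATR-FTIR", "wet", 1),
        pv.SampleRecord("P3", "pcos", "ATR-FTIR", "wet", 1),
    ]
    return pv.SpectralDataset(grid=grid, matrix=matrix, samples=samples)


@pytest.fixture
def small_config() -> pv.SyntheticConfig:
    """Reduced cohort for fast end-to-end unit tests."""
    return pv.SyntheticConfig(
        n_cancer=6, n_pcos=4, n_healthy=4, replicates_dry=3, seed=7
    )


@dataclass
class StudyRun:
    """One seeded end-to-end run kept for reuse across tests."""

    seed: int
    datasets: dict
    result: pv.StudyResult


def _run_study(seed: int, effect_scale: float, keys=WET_KEYS) -> StudyRun:
    cfg = pv.SyntheticConfig(seed=seed, effect_scale=effect_scale)
    raw = pv.synth_study(cfg)
    datasets = prepare_study_datasets(raw, include=keys)
    eval_cfg = pv.EvalConfig(master_seed=seed, run_cv=False)
    result = pv.run_supervised_study(datasets, eval_cfg)
    return StudyRun(seed=seed, datasets=datasets, result=result)


@pytest.fixture(scope="session")
def default_study_runs() -> list[StudyRun]:
    """Ten seeded default-condition studies on the wet + fused datasets."""
    return [_run_study(seed, effect_scale=1.0) for seed in range(N_STUDY_SEEDS)]


@pytest.fixture(scope="session")
def null_study_runs() -> list[StudyRun]:
    """Ten seeded no-effect (effect_scale = 0) studies."""
    return [_run_study(seed, effect_scale=0.0) for seed in range(N_STUDY_SEEDS)]


@pytest.fixture(scope="session")
def biomarker_runs():
    """Per-seed biomarker panels/regions on default wet ATR-FTIR data."""
    out = []
    for seed in range(N_STUDY_SEEDS):
        cfg = pv.SyntheticConfig(seed=seed)
        raw = pv.synth_study(cfg)
        pre = prepare_study_datasets(raw, include=("ftir_wet",))["ftir_wet"]
        plan = pv.make_split_plan(pre.samples, pv.EvalConfig(master_seed=seed))
        panels, regions = pv.run_biomarker_study(
            pre, plan, pv.RankingConfig(seed=seed)
        )
        out.append((panels, regions))
    return out


def majority_test_rate(run: StudyRun, dataset: str) -> float:
    """Mean majority-class fraction over the iterations' test rows."""
    ds = run.datasets[dataset]
    fracs = []
    for _, test_pids in run.result.plan:
        rows = ds.rows_for_patients(test_pids)
        labels = ds.class_labels[rows]
        _, counts = np.unique(labels, return_counts=True)
        fracs.append(counts.max() / counts.sum())
    return float(np.mean(fracs))
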