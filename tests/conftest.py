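"""Shared fixtures: small ground-truthed batches and processed stores."""

from __future__ import annotations

import numpy as np
import pytest

from lcmsqc import (NamingPattern, PipelineConfig, QCStore, TrackedCompound,
                    WarningRule, process_source)
from lcmsqc.compound_tracking import EIC, TrackingParams
from lcmsqc.synthetic_data import BatchConfig, ContaminantSpec, generate_batch

PATTERN = "{project}_{date}_{instrument}_{mode}_{sample_id}"


def make_eic(rt, intensity, mz_lo=99.998, mz_hi=100.002, mz_per_scan=None):
    rt = np.asarray(rt, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz_per_scan is None:
        mz_per_scan = np.where(intensity > 0, 100.0, np.nan)
    return EIC(rt=rt, intensity=intensity, mz_lo=mz_lo, mz_hi=mz_hi,
               mz_per_scan=np.asarray(mz_per_scan, dtype=float))


def drift_config(n_runs=6, seed=11, **kw):
    rng = np.random.default_rng(seed)
    defaults = dict(
        n_runs=n_runs, scans_per_run=50, seed=seed,
        ppm_offsets=rng.uniform(-30, 30, n_runs).round(2).tolist(),
        rt_shifts=rng.uniform(-0.2, 0.2, n_runs).round(3).tolist(),
        contaminants=[
            ContaminantSpec("peg_like", 415.2538, "constant", 800.0),
            ContaminantSpec("nylon_like", 114.0913, "peak", 5000.0),
        ],
        noise_baseline=20.0, noise_centroids_per_scan=5,
    )
    defaults.update(kw)
    return BatchConfig(**defaults)


def tracked_from(config: BatchConfig) -> list[TrackedCompound]:
    return [TrackedCompound(c.name, c.mz, c.rt) for c in config.compounds]


def pipeline_config(config: BatchConfig, tol_ppm=50.0,
                    rules=()) -> PipelineConfig:
    from lcmsqc import load_contaminant_list
    return PipelineConfig(
        pattern=NamingPattern(PATTERN),
        compounds=tracked_from(config),
        contaminants=load_contaminant_list(),
        rules=list(rules),
        tracking=TrackingParams(tol_ppm=tol_ppm),
    )


@pytest.fixture(scope="session")
def batch(tmp_path_factory):
    """A 6-run drifted batch with contaminants, on disk with its manifest."""
    config = drift_config()
    out = tmp_path_factory.mktemp("batch")
    paths, manifest = generate_batch(config, out)
    return {"config": config, "dir": out, "paths": paths, "manifest": manifest}


@pytest.fixture()
def processed(batch):
    """An in-memory store with the session batch fully processed."""
    store = QCStore()
    pc = pipeline_config(batch["config"],
                         rules=[WarningRule("mz_dev_ppm", "abs_gt", 20.0)])
    result = process_source(store, batch["dir"], pc)
    yield {"store": store, "pipeline": pc, "result": result, **batch}
    store.close()
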