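"""Shared fixtures.

The expensive end-to-end benchmark (desk-scale cohort, bb_loss and
full_scale trained on an identical split) is computed once per session and
shared by the acceptance tests for learnability and saliency.
"""

from __future__ import annotations

import numpy as np
import pytest

from meniscus3d.evaluate import evaluate_checkpoint
from meniscus3d.phantom import generate_cohort
from meniscus3d.train import TrainConfig, train_model

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def small_cohort():
    """16 small phantoms for fast pipeline tests."""
    samples, manifest = generate_cohort(16, 0.5, seed=5, grid_shape=(16, 32, 32))
    return samples, manifest


@pytest.fixture(scope="session")
def desk_benchmark():
    """Desk-scale paired comparison: 64 phantoms at 32x64x64, quarter-width
    encoders, bb_loss and full_scale trained on the identical split."""
    samples, manifest = generate_cohort(64, 0.4, BENCHMARK_SEED,
                                        grid_shape=(32, 64, 64))
    by_id = {s.sample_id: s for s in samples}
    out = {"samples": samples, "manifest": manifest}
    for approach in ("bb_loss", "full_scale"):
        cfg = TrainConfig(approach=approach, max_epochs=80, seed=BENCHMARK_SEED)
        ckpt = train_model(cfg, samples, manifest)
        test = [by_id[sid] for sid in ckpt["split"]["test"]]
        out[approach] = {
            "checkpoint": ckpt,
            "report": evaluate_checkpoint(ckpt, test),
            "test_samples": test,
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
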