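"""Shared fixtures: skeletons, gait clips, and one session-scoped trained
manifold model reused by the enhancement and acceptance tests."""

from dataclasses import replace

import pytest

import motionmend as mm
from motionmend.experiment import (BenchmarkConfig, run_benchmark, train_model)


@pytest.fixture(scope="session")
def skel():
    return mm.cmu21_skeleton()


@pytest.fixture(scope="session")
def gait_clip(skel):
    """One clean 240-frame walking clip with its commanded angle traces."""
    return mm.generate_motion(skel, 240, 60.0, mm.GaitParams(seed=11))


@pytest.fixture(scope="session")
def bench_cfg():
    """Desk-scale benchmark settings shared across enhancement tests."""
    return BenchmarkConfig(preset="awgn10", n_train_clips=50, n_test_clips=3,
                           epochs=80, n_filters=64, seed=7)


@pytest.fixture(scope="session")
def trained(bench_cfg):
    """Session-trained manifold model (one training run for the whole suite)."""
    params, losses = train_model(bench_cfg)
    return params, losses


@pytest.fixture(scope="session")
def benchmark_reports(bench_cfg, trained):
    """End-to-end benchmark reports for all four corruption presets."""
    params, _ = trained
    reports = {}
    for preset in ("awgn7", "awgn10", "dropout25", "dropout50"):
        cfg = replace(bench_cfg, preset=preset)
        reports[preset] = run_benchmark(cfg, params)
    return reports
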