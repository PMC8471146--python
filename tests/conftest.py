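import numpy as np
import pytest

import prvkit as pk


@pytest.fixture(scope="session")
def default_dual():
    """One paired contact/camera recording at the default study conditions."""
    cfg = pk.SimulationConfig(seed=1)
    contact, camera, truth = pk.simulate_dual_recording(cfg)
    return cfg, contact, camera, truth


@pytest.fixture(scope="session")
def clean_dual():
    """Artifact-free, noise-free paired recording (pure timing ground truth)."""
    cfg = pk.SimulationConfig(seed=1, artifact_rate_per_min=0.0, channel_noise_sd=0.0)
    contact, camera, truth = pk.simulate_dual_recording(cfg)
    return cfg, contact, camera, truth


@pytest.fixture(scope="session")
def clean_pipeline_results(clean_dual):
    _, contact, camera, truth = clean_dual
    return (
        pk.run_ppi_pipeline(contact),
        pk.run_ppi_pipeline(camera),
        truth,
    )


@pytest.fixture(scope="session")
def short_constant_beats():
    """60 s of exactly periodic 1 Hz beats (for video-frame tests)."""
    cfg = pk.SimulationConfig(
        duration_s=660, mean_rate_bpm=60, lf_depth=0.0, hf_depth=0.0,
        artifact_rate_per_min=0.0,
    )
    truth = pk.simulate_beats(cfg)
    keep = truth.beat_times_ms <= 60_000
    return pk.GroundTruth(truth.beat_times_ms[keep], np.diff(truth.beat_times_ms[keep]))
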