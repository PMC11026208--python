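import numpy as np
import pytest

from neoms.preprocess import preprocess_epoch
from neoms.synthetic import (
    GroundTruthConfig,
    generate_maps,
    sample_label_sequence,
    synthesize_epoch,
)


@pytest.fixture(scope="session")
def true_maps():
    """Four well-separated ground-truth topographies on 9 channels."""
    return generate_maps(4, 9, seed=1)


@pytest.fixture(scope="session")
def default_cfg():
    return GroundTruthConfig(mean_duration_ms=200.0, fs=250.0, epoch_s=60.0)


@pytest.fixture(scope="session")
def synth(true_maps, default_cfg):
    """One default-snr synthetic epoch with its ground truth, preprocessed."""
    labels = sample_label_sequence(default_cfg, default_cfg.n_samples, seed=2)
    epoch = synthesize_epoch(true_maps, labels, default_cfg, seed=3)
    return {
        "labels": labels,
        "epoch": epoch,
        "prepped": preprocess_epoch(epoch),
        "cfg": default_cfg,
        "maps": true_maps,
    }


@pytest.fixture(scope="session")
def noiseless(true_maps):
    """The same epoch with the noise turned off (snr = inf)."""
    cfg = GroundTruthConfig(
        mean_duration_ms=200.0, fs=250.0, epoch_s=60.0, snr=np.inf
    )
    labels = sample_label_sequence(cfg, cfg.n_samples, seed=2)
    epoch = synthesize_epoch(true_maps, labels, cfg, seed=3)
    return {
        "labels": labels,
        "epoch": epoch,
        "prepped": preprocess_epoch(epoch),
        "cfg": cfg,
        "maps": true_maps,
    }
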