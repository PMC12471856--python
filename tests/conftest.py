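"""Shared fixtures: synthetic data, tiny models, and one overfit training run."""

from __future__ import annotations

import numpy as np
import pytest

import hirdnet as hn

SMOKE_INPUT = 48  # tiny-model input side used by the training smoke tests
SMOKE_WIDTH = 0.25


@pytest.fixture(scope="session")
def disk_image() -> hn.RawFundusImage:
    """200×200 black frame with a filled white disk of radius 50 at (100, 100)."""
    a = np.zeros((200, 200, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0:200, 0:200]
    a[(yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2] = 255
    return hn.RawFundusImage(a, source_id="disk")


@pytest.fixture(scope="session")
def synth_enhanced_40() -> hn.LabeledImageSet:
    """40 synthetic fundus images (8 per grade) enhanced to the smoke size."""
    spec = hn.SynthSpec(image_size=64, counts={g: 8 for g in range(5)}, seed=0)
    ds, _ = hn.generate_dataset(spec)
    cfg = hn.EnhancementConfig(output_size=SMOKE_INPUT)
    return hn.LabeledImageSet([(hn.enhance_pipeline(im, cfg), g) for im, g in ds.items])


@pytest.fixture(scope="session")
def tiny_model() -> hn.HIRDNet:
    """Untrained quarter-width model with the full topology."""
    return hn.HIRDNet(hn.HIRDNetConfig(input_size=SMOKE_INPUT,
                                       width_multiplier=SMOKE_WIDTH, seed=0))


@pytest.fixture(scope="session")
def smoke_run(synth_enhanced_40):
    """The overfit smoke training: tiny model, 40 images, at most 200 steps.

    Returns (model, log, train_set); the model carries the best-validation
    checkpoint.
    """
    model = hn.HIRDNet(hn.HIRDNetConfig(input_size=SMOKE_INPUT,
                                        width_multiplier=SMOKE_WIDTH, seed=0))
    cfg = hn.TrainConfig(batch_size=8, epochs=40, max_steps=200, seed=0)
    _, log = hn.train(model, synth_enhanced_40, synth_enhanced_40, cfg)
    return model, log, synth_enhanced_40


@pytest.fixture(scope="session")
def full_model_summary():
    """Shape ledger, descriptor width and parameter count of the full-size
    network (one ~15 s construction+forward shared by every consumer)."""
    model = hn.build_hirdnet(hn.HIRDNetConfig())
    ledger = model.shape_ledger()
    rng = np.random.default_rng(1)
    probs = model(rng.random((2, 3, 224, 224), dtype=np.float32))
    return {
        "ledger": ledger,
        "descriptor_width": model.descriptor_width,
        "parameters": hn.count_parameters(model),
        "probs": probs.data,
    }
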