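"""Shared fixtures.

The expensive artifacts (the synthetic study dataset, the trained
desk-scale detector and the ablation table) are session-scoped so the
end-to-end checks share one computation.  A ``timing`` dict records the
wall-clock cost of each stage for the runtime assertions.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from pathospeech.datasets import images_from_clips
from pathospeech.experiments import run_ablation, train_holdout
from pathospeech.model import NetConfig
from pathospeech.synth import generate_clips, subject_ids
from pathospeech.training import TrainConfig

# Desk-scale study conditions: quarter-width network, 240 clips of the
# default generator classes, 10 training epochs, subject-disjoint split.
STUDY_SEED = 0
N_PER_CLASS = 120
CLIP_DURATION_S = 5.0
WIDTH_SCALE = 0.25
TRAIN_EPOCHS = 10
ABLATION_EPOCHS = 2


@pytest.fixture(scope="session")
def timing() -> dict:
    return {}


@pytest.fixture(scope="session")
def small_clips():
    """A tiny balanced clip set for unit tests (3 per class, 3 s)."""
    return generate_clips(3, duration_s=3.0, seed=11)


@pytest.fixture(scope="session")
def study_clips(timing):
    t0 = time.monotonic()
    clips = generate_clips(N_PER_CLASS, duration_s=CLIP_DURATION_S, seed=STUDY_SEED)
    timing["synthesis_s"] = time.monotonic() - t0
    return clips


@pytest.fixture(scope="session")
def study_data(study_clips, timing):
    t0 = time.monotonic()
    images = images_from_clips(study_clips)
    timing["spectrograms_s"] = time.monotonic() - t0
    labels = np.array([c.label for c in study_clips])
    subjects = subject_ids(study_clips)
    return {"images": images, "labels": labels, "subjects": subjects}


@pytest.fixture(scope="session")
def holdout_run(study_data, timing):
    """The trained quarter-width detector on a subject-disjoint split."""
    net = NetConfig(width_scale=WIDTH_SCALE, seed=STUDY_SEED)
    tc = TrainConfig(epochs=TRAIN_EPOCHS, seed=STUDY_SEED)
    t0 = time.monotonic()
    run = train_holdout(study_data["images"], study_data["labels"],
                        study_data["subjects"], net, tc)
    timing["training_s"] = time.monotonic() - t0
    return run


@pytest.fixture(scope="session")
def ablation_table(study_data, timing):
    """All four variants trained under one (short) shared protocol."""
    net = NetConfig(width_scale=WIDTH_SCALE, seed=STUDY_SEED)
    tc = TrainConfig(epochs=ABLATION_EPOCHS, seed=STUDY_SEED)
    t0 = time.monotonic()
    table = run_ablation(study_data["images"], study_data["labels"],
                         study_data["subjects"], net, tc)
    timing["ablation_s"] = time.monotonic() - t0
    return table
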