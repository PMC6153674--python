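"""Shared fixtures: a desk-scale synthetic study and trained classifiers.

The study (5 procedures, 110 frames each, 160-px frames) mirrors the
clinical variability pattern — two bright sequences plus one turbid, one
dim, and one weak-laser-spot procedure.  The heavy leave-one-out training
run is session-scoped so every test that needs trained folds shares one
computation.  All seeds are pinned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import fetseg as fs
from fetseg.backbone import BackboneConfig, TrainConfig, build_model, train
from fetseg.data import balanced_subsample, load_dataset, make_loocv_splits
from fetseg.evaluation import cross_validate_cnn

STUDY_SEED = 1
STUDY_SIZE = 160
FRAMES_PER_PROC = 110


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("study")
    fs.generate_study(
        root,
        n_procedures=5,
        seed=STUDY_SEED,
        image_size=STUDY_SIZE,
        frames_per_procedure=FRAMES_PER_PROC,
        overwrite=True,
    )
    return root


@pytest.fixture(scope="session")
def study_ds(study_dir):
    return load_dataset(study_dir)


@pytest.fixture(scope="session")
def study_splits(study_ds):
    return make_loocv_splits(study_ds)


@pytest.fixture(scope="session")
def loocv_folds(study_ds, study_splits):
    """Full leave-one-procedure-out run of the small CNN (pinned seeds)."""
    return cross_validate_cnn(study_ds, study_splits, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def quick_model(study_ds):
    """A small CNN trained briefly (with rotation augmentation) on the four
    non-weak-spot procedures; enough to separate the synthetic classes."""
    train_ds = balanced_subsample(
        study_ds.subset(["proc_00", "proc_01", "proc_02", "proc_03"]), seed=0
    )
    model = build_model(BackboneConfig("small_cnn"), init_seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train(model, train_ds, TrainConfig(iterations=300, seed=0))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
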