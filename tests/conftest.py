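"""Shared fixtures: synthetic studies and trained models, built once per session.

The heavy objects (two ten-patient paired studies, a five-fold
cross-validation run, a second stain-specific model) are session-scoped so
the parameter-recovery, heatmap and saliency-agreement tests all reuse
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from virtualstain.dataset import gather_tiles
from virtualstain.fixtures import FixtureSpec, generate_section_pair
from virtualstain.study import StudyData, build_study, desk_train_config
from virtualstain.training import cross_validate, train


@pytest.fixture(scope="session")
def mel_study() -> StudyData:
    """Default synthetic study, cytoplasmic (MelanA-like) IHC."""
    return build_study(ihc_mode="cytoplasmic", seed=1, n_patients=10)


@pytest.fixture(scope="session")
def sox_study() -> StudyData:
    """Nuclear (SOX10-like) study on independent fixtures."""
    return build_study(ihc_mode="nuclear", seed=7, n_patients=10)


@pytest.fixture(scope="session")
def mel_cv(mel_study):
    return cross_validate(mel_study.manifest, mel_study.pairs, mel_study.negatives, desk_train_config(seed=1))


@pytest.fixture(scope="session")
def mel_model(mel_cv):
    """Fold-0 cytoplasmic-label model."""
    return mel_cv.models[0]


@pytest.fixture(scope="session")
def sox_model(sox_study):
    """Fold-0 nuclear-label model."""
    x_tr, y_tr = gather_tiles(sox_study.manifest, sox_study.pairs, sox_study.negatives, 0, "train")
    x_va, y_va = gather_tiles(sox_study.manifest, sox_study.pairs, sox_study.negatives, 0, "val")
    return train(x_tr, y_tr, x_va, y_va, desk_train_config(seed=7))


@pytest.fixture(scope="session")
def positive_tiles(mel_study):
    """Melanocyte-positive H&E tiles from the default study (fold 0 train)."""
    x, y = gather_tiles(mel_study.manifest, mel_study.pairs, mel_study.negatives, 0, "train")
    return x[y == 1]


@pytest.fixture(scope="session")
def small_pair():
    """One small section pair with the default planted misalignment."""
    spec = FixtureSpec(section_height_px=448, section_width_px=448, n_melanocytes=12, n_keratinocytes=70, seed=3)
    he, ihc, truth = generate_section_pair(spec)
    return spec, he, ihc, truth
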