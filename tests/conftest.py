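"""Shared fixtures: synthetic slides, segmentations and labelled features.

The expensive imaging fixtures are session-scoped so that segmentation,
classification and acceptance tests reuse the same rendered slides.
"""
from __future__ import annotations

import numpy as np
import pytest

import tilquant as tq
from tilquant.classify import extract_features
from tilquant.segmentation import match_to_ground_truth

MPP = 0.5  # microns per pixel of the rendered fixtures

# Hard-core separation comfortably above two maximal cancer radii, so every
# rendered nucleus is isolated and detectable by construction.
NONOVERLAP = dict(
    lymphocyte_intensity=300.0,
    cancer_intensity=300.0,
    stromal_intensity=300.0,
    min_separation_um=18.0,
)


@pytest.fixture(scope="session")
def nonoverlap_config():
    return tq.SyntheticConfig(field_width_um=500.0, field_height_um=500.0,
                              seed=5, **NONOVERLAP)


@pytest.fixture(scope="session")
def nonoverlap_slide(nonoverlap_config):
    slide = tq.simulate_point_pattern(nonoverlap_config)
    slide.image = tq.render_slide(slide, nonoverlap_config)
    return slide


@pytest.fixture(scope="session")
def seg_params():
    return tq.SegmentationParams(microns_per_pixel=MPP)


@pytest.fixture(scope="session")
def segmented_nonoverlap(nonoverlap_slide, seg_params):
    """(objects, haematoxylin channel) for the non-overlapping fixture."""
    objects, h = tq.segment_image(nonoverlap_slide.image, seg_params)
    return objects, h


def _labelled_features(seed: int):
    cfg = tq.SyntheticConfig(field_width_um=700.0, field_height_um=700.0,
                             seed=seed, **NONOVERLAP)
    slide = tq.simulate_point_pattern(cfg)
    image = tq.render_slide(slide, cfg)
    objects, h = tq.segment_image(image, tq.SegmentationParams(microns_per_pixel=MPP))
    truth_xy = slide.cells[["x_um", "y_um"]].to_numpy()
    assigned, _, _ = match_to_ground_truth(objects, truth_xy,
                                           slide.cells["radius_um"].to_numpy())
    keep = assigned >= 0
    feats = [extract_features(o, h, MPP) for o, k in zip(objects, keep) if k]
    labels = slide.cells["class"].to_numpy()[assigned[keep]]
    return feats, list(labels)


@pytest.fixture(scope="session")
def train_set():
    return _labelled_features(seed=11)


@pytest.fixture(scope="session")
def test_set():
    return _labelled_features(seed=12)


@pytest.fixture(scope="session")
def trained_classifier(train_set):
    feats, labels = train_set
    return tq.train_classifier(feats, labels, seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    return tq.simulate_cohort(tq.CohortConfig(n_patients=20_000, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
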