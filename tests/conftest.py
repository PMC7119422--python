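"""Shared fixtures: scaled-down synthetic datasets, cached per session."""

from __future__ import annotations

import dataclasses

import pytest

import spheropol as sp


@pytest.fixture(scope="session")
def scaled_params() -> sp.SyntheticParams:
    """Fast geometry: 96 px frames, 5 z-planes, proportional structures."""
    return sp.SCALED_PARAMS


@pytest.fixture(scope="session")
def noiseless_params(scaled_params) -> sp.SyntheticParams:
    return scaled_params.noiseless()


@pytest.fixture(scope="session")
def flat_params(scaled_params) -> sp.SyntheticParams:
    """Single-plane geometry for 2D-only tests (cheap to generate)."""
    return dataclasses.replace(scaled_params, z_planes=1)


@pytest.fixture(scope="session")
def small_dataset(flat_params) -> sp.LabelledDataset:
    """24 spheroids, 6 per fine class, default noise."""
    counts = {label: 6 for label in sp.FINE_LABELS}
    return sp.generate_dataset(counts, flat_params, seed=42)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    feats = sp.extract_features_batch(small_dataset.stacks, n_slices=1)
    coarse = [l.coarse_label for l in small_dataset.labels]
    return feats, coarse


@pytest.fixture(scope="session")
def training_features(flat_params):
    """120-spheroid training set (40 per coarse class) plus labels."""
    counts = {
        "1_regular": 40,
        "2_inverse": 40,
        "3a_aggregate": 20,
        "3b_multilumen": 20,
    }
    ds = sp.generate_dataset(counts, flat_params, seed=7)
    feats = sp.extract_features_batch(ds.stacks, n_slices=1)
    coarse = [l.coarse_label for l in ds.labels]
    return feats, coarse


def make_rgb_set(params, counts, seed):
    """Labelled RGB images rendered from freshly generated stacks."""
    ds = sp.generate_dataset(counts, params, seed=seed)
    images = []
    for stack, label in zip(ds.stacks, ds.labels):
        eq = sp.equatorial_projection(stack, n_slices=1)
        img = sp.to_rgb(eq)
        img.label = label
        images.append(img)
    return images, ds.labels
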