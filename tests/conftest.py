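"""Shared fixtures: toy datasets, a tiny architecture, and cheap trained models."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from antsemble.datamodel import (
    VIEWS,
    ImageSample,
    MultiViewDataset,
    SpecimenRecord,
    View,
    split_dataset,
)
from antsemble.netspec import ArchitectureDescriptor, LayerSpec
from antsemble.synthgen import SynthConfig, generate_dataset
from antsemble.training import Hyperparams, train_general, train_specific, train_transfer

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_sample(sid: str, view: View, value: float = 0.5, size: int = 8) -> ImageSample:
    return ImageSample(sid, view, np.full((size, size), value, dtype=np.float32))


def make_specimen(sid: str, genus: int,
                  n_per_view: dict[View, int] | int = 1) -> SpecimenRecord:
    if isinstance(n_per_view, int):
        n_per_view = {v: n_per_view for v in VIEWS}
    images = {
        v: [make_sample(sid, v) for _ in range(n_per_view.get(v, 0))]
        for v in VIEWS
    }
    return SpecimenRecord(sid, genus, images)


@pytest.fixture
def toy_dataset() -> MultiViewDataset:
    """3 specimens, 2 genera; s3 is missing its dorsal picture."""
    return MultiViewDataset([
        make_specimen("s1", 1),
        make_specimen("s2", 1, {View.HEAD: 1, View.DORSUM: 1, View.PROFILE: 2}),
        make_specimen("s3", 2, {View.HEAD: 1, View.DORSUM: 0, View.PROFILE: 1}),
    ])


def tiny_architecture(n_labels: int, input_size: int = 32) -> ArchitectureDescriptor:
    """A small conv net for fast unit tests (not the reference pattern)."""
    layers = [
        LayerSpec("input"),
        LayerSpec("convolution", k=5, stride=2, padding=2, out_channels=8),
        LayerSpec("relu"),
        LayerSpec("pooling", k=3, stride=2),
        LayerSpec("normalization"),
        LayerSpec("convolution", k=3, stride=1, padding=1, out_channels=8),
        LayerSpec("relu"),
        LayerSpec("pooling", k=3, stride=2),
        LayerSpec("fully_connected", out_channels=32),
        LayerSpec("relu"),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("fully_connected", out_channels=16),
        LayerSpec("relu"),
        LayerSpec("fully_connected", out_channels=n_labels),
        LayerSpec("softmax"),
        LayerSpec("loss"),
    ]
    return ArchitectureDescriptor(layers, input_size=input_size,
                                  input_channels=1, n_labels=n_labels)


@pytest.fixture(scope="session")
def small_synth():
    """A small 3-genus multi-view dataset at 32x32 with its archetypes."""
    cfg = SynthConfig(n_genera=3, specimens_per_genus=10, image_size=32,
                      noise_sd=0.05, extra_picture_prob=0.15, seed=42)
    ds, archetypes = generate_dataset(cfg)
    return cfg, ds, archetypes


@pytest.fixture(scope="session")
def small_split(small_synth):
    _, ds, _ = small_synth
    return split_dataset(ds, (0.6, 0.2, 0.2), seed=42)


@pytest.fixture(scope="session")
def trained_models(small_split):
    """General + head-specific + head-transfer models on the small dataset."""
    arch = tiny_architecture(n_labels=3, input_size=32)
    hp = Hyperparams(iterations=200, validation_interval=50, seed=7)
    general, ghist = train_general(small_split, arch, hp)
    specific, shist = train_specific(small_split, View.HEAD, arch, hp)
    transfer, thist = train_transfer(
        general, small_split, View.HEAD,
        Hyperparams(iterations=120, validation_interval=40,
                    learning_rate=0.004, seed=7),
    )
    return {
        "general": (general, ghist),
        "specific": (specific, shist),
        "transfer": (transfer, thist),
        "arch": arch,
    }
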