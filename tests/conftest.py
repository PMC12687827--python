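"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from voljepa.jepa import VolJEPA, prepare_volume
from voljepa.phantom import PhantomSpec, make_phantom_volume
from voljepa.tokenizer import PATCH_SHAPE, TokenGrid


def make_full_grid(dims, modality: str = "MRI", seed: int = 0,
                   patch_shape=PATCH_SHAPE) -> TokenGrid:
    """Fully-foreground token grid with random patch values."""
    rng = np.random.default_rng(seed)
    coords = np.indices(dims).reshape(3, -1).T
    values = rng.normal(size=(len(coords), int(np.prod(patch_shape))))
    return TokenGrid(token_coords=coords, patch_values=values,
                     grid_dims=tuple(dims), patch_shape=patch_shape,
                     modality=modality)


@pytest.fixture(scope="session")
def mri_phantom():
    spec = PhantomSpec(seed=7, lesion_menu=(("hemorrhage", None, None),))
    return make_phantom_volume(spec)


@pytest.fixture(scope="session")
def ct_phantom():
    spec = PhantomSpec(seed=7, modality="CT",
                       lesion_menu=(("hemorrhage", None, None),))
    return make_phantom_volume(spec)


@pytest.fixture(scope="session")
def mri_processed(mri_phantom):
    return prepare_volume(mri_phantom[0])["none"]


@pytest.fixture(scope="session")
def ct_processed(ct_phantom):
    return prepare_volume(ct_phantom[0])


@pytest.fixture(scope="session")
def smoke_result():
    """The canonical 200-step smoke pretraining + probe benchmark (shared:
    it is the most expensive fixture in the suite)."""
    from voljepa.benchmarks import lesion_probe_benchmark

    return lesion_probe_benchmark(seed=0)


@pytest.fixture(scope="session")
def tiny_model():
    """A briefly pretrained very small model, shared by downstream tests."""
    vols = []
    for i in range(8):
        menu = (("tumor", (5, 7), 120.0),) if i % 2 else ()
        vol, _ = make_phantom_volume(PhantomSpec(seed=300 + i, lesion_menu=menu))
        vols.append(prepare_volume(vol))
    model = VolJEPA(embed_dim=32, depth=2, heads=4, predictor_dim=16,
                    predictor_depth=1, predictor_heads=2, steps=15,
                    batch_size=4, lr=3e-3, ema_start=0.9, random_state=0)
    model.fit(vols)
    return model
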