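"""Shared fixtures: noiseless configs, toy fluorophores, the seeded
default library, and a CNN trained on it (session-scoped, built once)."""

from __future__ import annotations

import numpy as np
import pytest

from hsfkit.dataset import (
    ClassEntry,
    ClassRegistry,
    balance_oversample,
    default_registry,
    examples_to_arrays,
    generate_library,
    shuffle_split,
)
from hsfkit.device import DeviceConfig, FluorophoreSpec, SampleSpec
from hsfkit.models import build_cnn, evaluate, train_cnn

MASTER_SEED = 17


@pytest.fixture(scope="session")
def config() -> DeviceConfig:
    return DeviceConfig()


@pytest.fixture(scope="session")
def noiseless_config() -> DeviceConfig:
    return DeviceConfig(noise_floor=0.0, shot_noise_scale=0.0)


def grid_aligned_leds(config: DeviceConfig) -> tuple[float, ...]:
    """12 strictly increasing LED centers that coincide with axis pixels."""
    axis = config.emission_axis
    usable = axis[(axis >= 255.0) & (axis <= 400.0)]
    picks = np.linspace(0, len(usable) - 1, 12).astype(int)
    return tuple(float(usable[i]) for i in picks)


@pytest.fixture(scope="session")
def aligned_noiseless_config(noiseless_config) -> DeviceConfig:
    """Noiseless device whose LED centers sit exactly on axis pixels."""
    from dataclasses import replace

    return replace(noiseless_config, led_wavelengths=grid_aligned_leds(noiseless_config))


@pytest.fixture(scope="session")
def simple_fluor() -> FluorophoreSpec:
    """One absorber at 280 nm, one emission band at 360 nm."""
    return FluorophoreSpec(
        name="probe-a",
        absorption_bands=((280.0, 30.0, 3.0),),
        emission_bands=((360.0, 45.0, 1.0),),
        quantum_yield=0.3,
    )


@pytest.fixture(scope="session")
def red_fluor() -> FluorophoreSpec:
    """Second absorber at 330 nm emitting at 470 nm (no spectral overlap at 360)."""
    return FluorophoreSpec(
        name="probe-b",
        absorption_bands=((330.0, 25.0, 2.0),),
        emission_bands=((470.0, 50.0, 1.0),),
        quantum_yield=0.4,
    )


@pytest.fixture(scope="session")
def simple_sample(simple_fluor) -> SampleSpec:
    return SampleSpec(components=((simple_fluor, 0.5),))


def mini_registry(counts=(4, 4, 4)) -> ClassRegistry:
    """Three-class registry (two pures + their mixture) for fast pipeline tests."""
    entries = (
        ClassEntry("bromazolam:low", "bromazolam", "standard", "low",
                   (("bromazolam", 0.2),), counts[0]),
        ClassEntry("metonitazene", "metonitazene", "standard", "n/a",
                   (("metonitazene", 0.5),), counts[1]),
        ClassEntry("bromazolam+metonitazene", "bromazolam+metonitazene", "mixture", "n/a",
                   (("bromazolam", 0.2), ("metonitazene", 0.5)), counts[2]),
    )
    return ClassRegistry(entries)


def blob_dataset(n_per_class: int = 10, n_classes: int = 3, seed: int = 0,
                 noise: float = 0.02):
    """Linearly separable toy fingerprints: one bright blob per class."""
    rng = np.random.default_rng(seed)
    centers = [(15, 15), (15, 50), (50, 32), (50, 55), (30, 10)][:n_classes]
    yy, xx = np.mgrid[0:66, 0:66]
    xs, ys = [], []
    for k, (cy, cx) in enumerate(centers):
        base = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 6.0 ** 2))
        for _ in range(n_per_class):
            img = np.clip(base + noise * rng.standard_normal((66, 66)), 0.0, 1.0)
            xs.append(img[:, :, None])
            ys.append(k)
    x = np.asarray(xs, dtype=np.float32)
    y = np.asarray(ys, dtype=np.int64)
    order = rng.permutation(len(x))
    return x[order], y[order]


@pytest.fixture(scope="session")
def default_run():
    """Default 86-class library, balanced and split at the master seed."""
    registry = default_registry()
    library = generate_library(registry, seed=MASTER_SEED)
    balanced = balance_oversample(library, per_class=20, seed=MASTER_SEED)
    split = shuffle_split(balanced, seed=MASTER_SEED)
    x, y, classes = examples_to_arrays(balanced, classes=sorted(registry.class_ids))
    return {
        "registry": registry,
        "library": library,
        "balanced": balanced,
        "split": split,
        "x": x,
        "y": y,
        "classes": classes,
    }


@pytest.fixture(scope="session")
def trained_cnn(default_run):
    """Default CNN trained on the 80% split; returns model + test report."""
    x, y = default_run["x"], default_run["y"]
    split = default_run["split"]
    tr, te = list(split.train_ids), list(split.test_ids)
    spec = build_cnn(len(default_run["classes"]), seed=MASTER_SEED)
    model, trace = train_cnn(spec, x[tr], y[tr])
    report = evaluate(model, x[te], y[te], classes=default_run["classes"])
    return {"model": model, "trace": trace, "report": report,
            "test_ids": te, "train_ids": tr}
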