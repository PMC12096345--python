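"""Labeled synthetic library: class registry, generation, balancing, split.

The default registry holds 86 drug-variant-concentration classes whose
named entries (alprazolam/etizolam/lorazepam dose series, the key
mixtures, cutting agents, nondrug controls) carry their documented
concentrations; the remainder is filled from the packaged compound pool
at low/medium/high bands. Raw example counts sum to 1470; oversampling
with replacement balances every class to 20, giving 1720 examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hsfkit import compounds
from hsfkit.device import DeviceConfig, SampleSpec, acquire_scan
from hsfkit.preprocess import HSFMatrix, PreprocessParams, preprocess_scan

BANDS = ("low", "medium", "high", "n/a")
DEFAULT_PER_CLASS = 20
N_DEFAULT_CLASSES = 86
DEFAULT_RAW_TOTAL = 1470


@dataclass(frozen=True)
class ClassEntry:
    class_id: str
    drug: str
    variant: str
    concentration_band: str
    components: tuple[tuple[str, float], ...]
    raw_example_count: int

    def __post_init__(self) -> None:
        if self.concentration_band not in BANDS:
            raise ValueError(f"{self.class_id}: unknown band {self.concentration_band!r}")
        if self.raw_example_count < 1:
            raise ValueError(f"{self.class_id}: raw_example_count must be >= 1")
        object.__setattr__(self, "components",
                           tuple((str(n), float(c)) for n, c in self.components))


@dataclass(frozen=True)
class ClassRegistry:
    entries: tuple[ClassEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.class_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate class_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, class_id: str) -> ClassEntry:
        for e in self.entries:
            if e.class_id == class_id:
                return e
        raise KeyError(class_id)

    @property
    def class_ids(self) -> tuple[str, ...]:
        return tuple(e.class_id for e in self.entries)

    @property
    def raw_total(self) -> int:
        return sum(e.raw_example_count for e in self.entries)


@dataclass(frozen=True)
class LabeledExample:
    fingerprint: HSFMatrix
    class_id: str
    seed: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed", tuple(self.seed))


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    seed: int | None

    def __post_init__(self) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train/test indices overlap")


_POOL_COMPOUNDS = (
    "clonazepam", "nitrazepam", "flubromazolam", "flunitrazolam", "temazepam",
    "oxazepam", "chlordiazepoxide", "midazolam", "triazolam", "phenazepam",
    "deschloroetizolam", "pyrazolam", "flualprazolam", "clonazolam", "norflurazepam",
)
_POOL_BAND_CONC = {"low": 0.25, "medium": 0.75, "high": 1.5}


def default_registry() -> ClassRegistry:
    """The packaged 86-class registry; raw counts sum to 1470.

    61 classes carry 20 raw examples; the 7 mixture classes plus 18 of
    the pool classes carry 10 each, giving the 250-example deficit that
    oversampling to 20-per-class repairs (1470 -> 1720).
    """
    e: list[ClassEntry] = []

    def add(cid, drug, variant, band, comps, count=20):
        e.append(ClassEntry(cid, drug, variant, band, tuple(comps), count))

    for band, conc in (("low", 0.1), ("medium", 0.2), ("high", 0.6)):
        add(f"alprazolam:{band}", "alprazolam", "standard", band, [("alprazolam", conc)])
    for band, conc in (("low", 0.3), ("medium", 0.6), ("high", 1.2)):
        add(f"etizolam:{band}", "etizolam", "standard", band, [("etizolam", conc)])
    for band, conc in (("low", 0.2), ("medium", 0.8), ("high", 1.6)):
        add(f"lorazepam:{band}", "lorazepam", "standard", band, [("lorazepam", conc)])
    add("diazepam:low", "diazepam", "standard", "low", [("diazepam", 0.5)])
    add("bromazolam:low", "bromazolam", "standard", "low", [("bromazolam", 0.2)])
    add("metonitazene", "metonitazene", "standard", "n/a", [("metonitazene", 0.5)])
    add("etonitazene", "etonitazene", "standard", "n/a", [("etonitazene", 0.5)])
    add("heroin", "heroin", "street", "n/a", [("heroin", 1.0), ("noscapine", 0.3)])
    add("fentanyl", "fentanyl", "standard", "n/a", [("fentanyl", 1.0)])
    add("xylazine", "xylazine", "standard", "n/a", [("xylazine", 0.33)])
    add("bromazolam+metonitazene", "bromazolam+metonitazene", "mixture", "n/a",
        [("bromazolam", 0.2), ("metonitazene", 0.5)], 10)
    add("heroin+etonitazene", "heroin+etonitazene", "mixture", "n/a",
        [("heroin", 1.0), ("noscapine", 0.3), ("etonitazene", 0.5)], 10)
    add("fentanyl+xylazine", "fentanyl+xylazine", "mixture", "n/a",
        [("fentanyl", 1.0), ("xylazine", 0.33)], 10)
    add("caffeine", "caffeine", "cutting-agent", "n/a", [("caffeine", 0.25)])
    add("paracetamol", "paracetamol", "cutting-agent", "n/a", [("paracetamol", 20.0)])
    add("ibuprofen", "ibuprofen", "cutting-agent", "n/a", [("ibuprofen", 20.0)])
    add("clobazam", "clobazam", "tablet-extract", "n/a", [("clobazam", 1.0)])
    add("diazepam+caffeine", "diazepam+caffeine", "mixture", "n/a",
        [("diazepam", 1.0), ("caffeine", 0.25)], 10)
    add("diazepam+paracetamol", "diazepam+paracetamol", "mixture", "n/a",
        [("diazepam", 1.0), ("paracetamol", 20.0)], 10)
    add("diazepam+ibuprofen", "diazepam+ibuprofen", "mixture", "n/a",
        [("diazepam", 1.0), ("ibuprofen", 20.0)], 10)
    add("diazepam+clobazam", "diazepam+clobazam", "mixture", "n/a",
        [("diazepam", 1.0), ("clobazam", 1.0)], 10)
    add("tramadol", "tramadol", "tablet-extract", "n/a", [("tramadol", 20.0)])
    add("oxycodone", "oxycodone", "tablet-extract", "n/a", [("oxycodone", 4.0)])
    add("buprenorphine", "buprenorphine", "tablet-extract", "n/a", [("buprenorphine", 0.8)])
    add("dihydrocodeine", "dihydrocodeine", "tablet-extract", "n/a", [("dihydrocodeine", 12.0)])
    add("cocaine", "cocaine", "standard", "n/a", [("cocaine", 2.0)])
    add("ketamine:sample-1", "ketamine", "sample-1", "n/a", [("ketamine", 2.0)])
    add("ketamine:sample-2", "ketamine", "sample-2", "n/a", [("ketamine", 1.8)])
    add("mdma", "mdma", "standard", "n/a", [("mdma", 2.0)])
    add("mephedrone", "mephedrone", "standard", "n/a", [("mephedrone", 2.0)])
    add("2c-b", "2c-b", "standard", "n/a", [("2c-b", 2.0)])
    add("white-paper", "white paper", "nondrug", "n/a", [("white_paper", 1.0)])
    add("blank", "blank solvent", "nondrug", "n/a", [])
    add("noscapine", "noscapine", "standard", "n/a", [("noscapine", 1.0)])
    add("zopiclone", "zopiclone", "tablet-extract", "n/a", [("zopiclone", 1.0)])

    # fill to 86 with the pool at three bands; the first 18 pool classes
    # carry 10 raw examples so totals land on 1470
    short = 0
    for name in _POOL_COMPOUNDS:
        for band, conc in _POOL_BAND_CONC.items():
            count = 10 if short < 18 else 20
            short += 1
            add(f"{name}:{band}", name, "pool", band, [(name, conc)], count)

    registry = ClassRegistry(tuple(e))
    assert len(registry) == N_DEFAULT_CLASSES, len(registry)
    assert registry.raw_total == DEFAULT_RAW_TOTAL, registry.raw_total
    return registry


def sample_for_entry(entry: ClassEntry) -> SampleSpec:
    comps = tuple((compounds.get_fluorophore(name), conc) for name, conc in entry.components)
    return SampleSpec(components=comps)


def generate_library(
    registry: ClassRegistry,
    config: DeviceConfig | None = None,
    seed: int = 0,
    params: PreprocessParams | None = None,
) -> list[LabeledExample]:
    """Simulate and preprocess every registry entry's raw examples.

    Per-example seeds are ``SeedSequence([seed, entry_index, replicate])``
    so classes and replicates draw independent streams, and the whole
    library is byte-identical for a given master seed.
    """
    config = config or DeviceConfig()
    params = params or PreprocessParams()
    out: list[LabeledExample] = []
    for i, entry in enumerate(registry.entries):
        sample = sample_for_entry(entry)
        for j in range(entry.raw_example_count):
            scan = acquire_scan(sample, config, seed=[seed, i, j],
                                sample_id=f"{entry.class_id}#{j}")
            fp = preprocess_scan(scan, params)
            out.append(LabeledExample(fingerprint=fp, class_id=entry.class_id,
                                      seed=(seed, i, j)))
    return out


def balance_oversample(examples: list[LabeledExample], per_class: int = DEFAULT_PER_CLASS,
                       seed=None) -> list[LabeledExample]:
    """Resample every class to exactly ``per_class`` examples.

    Deficient classes are oversampled with replacement; classes already
    at the target pass through untouched; over-represented classes are
    randomly subsampled without replacement (extension beyond the
    under-sampling case).
    """
    if not examples:
        raise ValueError("no examples to balance")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    groups: dict[str, list[LabeledExample]] = {}
    order: list[str] = []
    for ex in examples:
        if ex.class_id not in groups:
            groups[ex.class_id] = []
            order.append(ex.class_id)
        groups[ex.class_id].append(ex)
    rng = np.random.default_rng(seed)
    out: list[LabeledExample] = []
    for cid in order:
        g = groups[cid]
        if len(g) == per_class:
            out.extend(g)
        elif len(g) < per_class:
            extra = rng.choice(len(g), size=per_class - len(g), replace=True)
            out.extend(g)
            out.extend(g[k] for k in extra)
        else:
            keep = rng.choice(len(g), size=per_class, replace=False)
            out.extend(g[k] for k in sorted(keep))
    return out


def shuffle_split(examples: list[LabeledExample], train_fraction: float = 0.8,
                  seed=None) -> DatasetSplit:
    """Uniform seeded shuffle; first floor(train_fraction * N) to train."""
    n = len(examples)
    if n < 2:
        raise ValueError(f"need at least 2 examples to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.floor(train_fraction * n)
    return DatasetSplit(train_ids=tuple(int(i) for i in perm[:n_train]),
                        test_ids=tuple(int(i) for i in perm[n_train:]),
                        seed=seed)


def examples_to_arrays(examples: list[LabeledExample],
                       classes: list[str] | None = None):
    """Stack fingerprints into (N, 66, 66, 1) float32 plus integer labels."""
    if classes is None:
        classes = sorted({ex.class_id for ex in examples})
    index = {c: k for k, c in enumerate(classes)}
    unknown = sorted({ex.class_id for ex in examples} - set(index))
    if unknown:
        raise ValueError(f"examples carry classes outside the class list: {unknown}")
    x = np.stack([ex.fingerprint.values for ex in examples]).astype(np.float32)
    y = np.array([index[ex.class_id] for ex in examples], dtype=np.int64)
    return x, y, list(classes)


def write_registry(registry: ClassRegistry, path) -> None:
    data = {"classes": [
        {
            "class_id": e.class_id,
            "drug": e.drug,
            "variant": e.variant,
            "concentration_band": e.concentration_band,
            "components": [{"compound": n, "mg_per_ml": c} for n, c in e.components],
            "raw_example_count": e.raw_example_count,
        }
        for e in registry.entries
    ]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def read_registry(path) -> ClassRegistry:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict) or "classes" not in data:
        raise ValueError(f"{path}: expected a top-level 'classes' list")
    entries = []
    for item in data["classes"]:
        entries.append(ClassEntry(
            class_id=item["class_id"],
            drug=item.get("drug", item["class_id"]),
            variant=item.get("variant", "standard"),
            concentration_band=item.get("concentration_band", "n/a"),
            components=tuple((c["compound"], float(c["mg_per_ml"]))
                             for c in item.get("components", [])),
            raw_example_count=int(item.get("raw_example_count", DEFAULT_PER_CLASS)),
        ))
    return ClassRegistry(tuple(entries))
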