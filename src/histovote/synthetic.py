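"""Synthetic fixtures: labeled texture images and model prediction matrices.

Two generator families make every pipeline testable without the real
histopathology archive:

* :func:`generate_images` renders tiny labeled RGB textures (colored
  noise plus geometric primitives) into the directory layout the data
  pipeline indexes, with per-class counts defaulting to the imbalanced
  census of the BreakHis archive scaled down.  The textures make no
  attempt at H&E realism — they exist so that indexing, splitting,
  weighting, and baseline classifiers have something learnable to chew
  on (each class has a distinct base color, so even a nearest-centroid
  color rule beats chance).

* :func:`generate_predictions` emits per-model class-probability
  matrices with prescribed per-class accuracy and confidence profiles,
  emulating how fitted classifiers differ class by class.  Ensemble
  fusion and weight search are exercised against these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

from .data import CATEGORIES, DatasetIndex, ImageRecord, round_half_away
from .ensemble import PredictionMatrix

__all__ = [
    "BREAKHIS_CLASS_TOTALS",
    "BREAKHIS_TEST_PROPORTIONS",
    "ImageScenario",
    "ModelProfile",
    "generate_images",
    "generate_predictions",
    "scenario_presets",
]

#: Published per-class image totals of the BreakHis archive, in the
#: fixed category order (A, DC, F, LC, MC, PC, PT, TA); 7909 in all.
BREAKHIS_CLASS_TOTALS: tuple[int, ...] = (444, 3451, 1014, 626, 792, 560, 453, 569)

#: Class proportions of the 20% test partition (1582 images).
BREAKHIS_TEST_PROPORTIONS: np.ndarray = np.array(
    (89, 690, 203, 125, 158, 112, 91, 114), dtype=float
) / 1582.0

# distinct base colors per class so mean-color classification beats chance
_BASE_COLORS = (
    (200, 120, 160), (150, 60, 120), (220, 170, 190), (120, 90, 170),
    (180, 130, 90), (90, 150, 170), (210, 200, 140), (130, 180, 120),
)


@dataclass(frozen=True)
class ImageScenario:
    """Recipe for one synthetic labeled image collection."""

    categories: tuple[str, ...] = CATEGORIES
    counts: tuple[int, ...] = tuple(
        round_half_away(0.02 * n) for n in BREAKHIS_CLASS_TOTALS
    )
    image_size: int = 64
    blob_density: float = 6.0
    stripe_frequency: float = 4.0
    noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.categories):
            raise ValueError("one count per category required")
        if any(c < 1 for c in self.counts):
            raise ValueError("every category needs at least one image")
        if self.image_size < 32:
            raise ValueError("image_size below 32 px cannot carry the textures")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImageScenario":
        d = dict(d)
        for key in ("categories", "counts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ModelProfile:
    """Accuracy and confidence signature of one emulated classifier.

    ``accuracy[k]`` is the probability the model's emitted label equals
    the truth for class-k samples; otherwise the emitted label is
    uniform over the wrong classes.  ``confidence`` controls how much
    probability mass lands on the emitted label: it may be a scalar or
    one value per *emitted* class, which lets a profile be confident on
    its specialty classes and diffuse elsewhere (or overconfident
    everywhere, as poorly calibrated models are).
    """

    accuracy: tuple[float, ...]
    confidence: float | tuple[float, ...] = 20.0
    name: str = "model"

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.accuracy):
            raise ValueError("per-class accuracies must lie in [0, 1]")
        conf = self.confidence if isinstance(self.confidence, tuple) else (self.confidence,)
        if any(c <= 0 for c in conf):
            raise ValueError("confidence concentration must be positive")
        if isinstance(self.confidence, tuple) and len(self.confidence) != len(self.accuracy):
            raise ValueError("per-class confidence needs one value per class")

    def confidence_vector(self) -> np.ndarray:
        k = len(self.accuracy)
        if isinstance(self.confidence, tuple):
            return np.asarray(self.confidence, float)
        return np.full(k, float(self.confidence))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelProfile":
        d = dict(d)
        d["accuracy"] = tuple(d["accuracy"])
        if isinstance(d.get("confidence"), (list, tuple)):
            d["confidence"] = tuple(d["confidence"])
        return cls(**d)


def _render_texture(rng: np.random.Generator, scenario: ImageScenario,
                    class_idx: int) -> np.ndarray:
    s = scenario.image_size
    base = np.array(_BASE_COLORS[class_idx % len(_BASE_COLORS)], float)
    img = np.tile(base, (s, s, 1))
    # class-specific stripe orientation and frequency
    yy, xx = np.mgrid[0:s, 0:s] / s
    phase = rng.uniform(0, 2 * np.pi)
    freq = scenario.stripe_frequency * (1 + 0.25 * class_idx)
    angle = np.pi * class_idx / len(scenario.categories)
    coord = xx * np.cos(angle) + yy * np.sin(angle)
    img += 18.0 * np.sin(2 * np.pi * freq * coord + phase)[..., None]
    # nuclei-like dark blobs, density varying with class
    n_blobs = rng.poisson(scenario.blob_density * (1 + 0.3 * class_idx))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, s, 2)
        r = rng.uniform(s / 32, s / 12)
        mask = (yy * s - cy) ** 2 + (xx * s - cx) ** 2 < r**2
        img[mask] *= 0.6
    img += rng.normal(0, scenario.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_images(scenario: ImageScenario, out_dir: str | Path) -> DatasetIndex:
    """Render the scenario into ``out_dir/<category>/*.png`` and index it.

    Deterministic under the scenario seed: the same scenario renders
    byte-identical files.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(scenario.seed)
    records: list[ImageRecord] = []
    for idx, (cat, count) in enumerate(zip(scenario.categories, scenario.counts)):
        cat_dir = out_dir / cat
        cat_dir.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            arr = _render_texture(rng, scenario, idx)
            path = cat_dir / f"{cat.lower()}_{i:04d}.png"
            Image.fromarray(arr).save(path)
            records.append(ImageRecord(path, cat))
    return DatasetIndex(records, tuple(scenario.categories))


def generate_predictions(
    n_samples: int,
    profiles: Sequence[ModelProfile],
    seed: int = 0,
    class_probs: Sequence[float] | None = None,
) -> tuple[list[PredictionMatrix], np.ndarray]:
    """Emit per-model probability matrices plus the ground-truth labels.

    Truth labels are drawn from ``class_probs`` (default: the imbalanced
    test-partition proportions of the BreakHis archive).  For each model
    and sample the emitted label is correct with the profile's per-class
    probability, else uniform over the wrong labels.  The probability
    row places a Beta-distributed share of mass (sharpness set by the
    profile's confidence for the emitted class, support (1/K, 1)) on the
    emitted label and spreads the rest with a flat Dirichlet draw,
    rescaled if needed so the emitted label stays the row argmax.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if len(profiles) < 1:
        raise ValueError("at least one model profile required")
    k = len(profiles[0].accuracy)
    if any(len(p.accuracy) != k for p in profiles):
        raise ValueError("all profiles must cover the same class count")
    if class_probs is None:
        class_probs = BREAKHIS_TEST_PROPORTIONS[:k]
    probs = np.asarray(class_probs, float)
    if probs.shape != (k,) or np.any(probs < 0):
        raise ValueError("class_probs must be a non-negative length-K vector")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    truth = rng.choice(k, size=n_samples, p=probs)
    matrices: list[PredictionMatrix] = []
    for profile in profiles:
        acc = np.asarray(profile.accuracy, float)
        conf = profile.confidence_vector()
        correct = rng.uniform(size=n_samples) < acc[truth]
        # wrong emissions: uniform over the K-1 other labels
        offsets = rng.integers(1, k, size=n_samples)
        emitted = np.where(correct, truth, (truth + offsets) % k)
        rows = np.empty((n_samples, k))
        mass = 1.0 / k + (1.0 - 1.0 / k) * rng.beta(conf[emitted], 2.0)
        rest = rng.dirichlet(np.ones(k - 1), size=n_samples) * (1.0 - mass)[:, None]
        # cap off-label mass so the emitted label stays the argmax
        cap = np.maximum(rest.max(axis=1), 1e-12)
        scale = np.minimum(1.0, 0.95 * mass / cap)
        rest *= scale[:, None]
        for i in range(n_samples):
            row = np.empty(k)
            others = np.delete(np.arange(k), emitted[i])
            row[others] = rest[i]
            row[emitted[i]] = 1.0 - rest[i].sum()
            rows[i] = row
        matrices.append(PredictionMatrix(rows, model_name=profile.name))
    return matrices, truth


def scenario_presets() -> dict[str, ImageScenario | tuple[ModelProfile, ...]]:
    """Named fixture bundles used throughout the test and demo paths.

    * ``balanced_tiny`` — 8 classes x 10 images at 64 px, balanced.
    * ``breakhis_imbalanced`` — per-class counts at the archive's
      imbalanced proportions, scaled by 0.02.
    * ``complementary_trio`` — three emulated classifiers with disjoint
      class-wise strengths: a well-calibrated specialist covering the
      five most frequent classes (diffuse when off its specialty) and
      two overconfident models that are only reliable on the remaining
      classes.  No fixed weighting serves all classes equally well, so
      weight search has something real to find.
    * ``planted_dominant`` — one near-perfect model beside two
      label-noise models; the optimal weights are near-degenerate on
      the dominant model.
    """
    strong, weak = 0.95, 0.45
    trio = (
        ModelProfile(
            accuracy=(strong, strong, strong, strong, strong, 0.15, 0.15, 0.15),
            confidence=(25.0, 25.0, 25.0, 25.0, 25.0, 1.0, 1.0, 1.0),
            name="specialist_calibrated",
        ),
        ModelProfile(
            accuracy=(weak, weak, weak, weak, weak, strong, strong, weak),
            confidence=20.0,
            name="overconfident_a",
        ),
        ModelProfile(
            accuracy=(weak, weak, weak, weak, weak, weak, weak, 0.90),
            confidence=20.0,
            name="overconfident_b",
        ),
    )
    planted = (
        ModelProfile(accuracy=(0.99,) * 8, confidence=25.0, name="dominant"),
        ModelProfile(accuracy=(0.125,) * 8, confidence=5.0, name="noise_a"),
        ModelProfile(accuracy=(0.125,) * 8, confidence=5.0, name="noise_b"),
    )
    return {
        "balanced_tiny": ImageScenario(counts=(10,) * 8),
        "breakhis_imbalanced": ImageScenario(),
        "complementary_trio": trio,
        "planted_dominant": planted,
    }


def save_preset(name: str, path: str | Path) -> None:
    """Serialize one preset bundle to a YAML file."""
    preset = scenario_presets()[name]
    if isinstance(preset, ImageScenario):
        payload = {"kind": "image_scenario", "scenario": preset.to_dict()}
    else:
        payload = {"kind": "model_profiles", "profiles": [p.to_dict() for p in preset]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_preset(path: str | Path) -> ImageScenario | tuple[ModelProfile, ...]:
    payload = yaml.safe_load(Path(path).read_text())
    if payload["kind"] == "image_scenario":
        return ImageScenario.from_dict(payload["scenario"])
    return tuple(ModelProfile.from_dict(p) for p in payload["profiles"])
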