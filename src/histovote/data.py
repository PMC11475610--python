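"""Dataset indexing, stratified splitting, class weights, and metrics.

Targets labeled RGB image collections in the layout of the BreakHis
breast-tumor archive: eight categories (four benign, four malignant)
photographed at four optical magnifications, pooled here into a single
magnification-independent experiment.  Splitting is per-class at the
image level, imbalance is countered by inverse-frequency class weights,
and evaluation reports accuracy plus macro-averaged precision, recall
and F1 alongside the confusion matrix.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "CATEGORY_FULL_NAMES",
    "ImageRecord",
    "DatasetIndex",
    "SplitResult",
    "index_dataset",
    "round_half_away",
    "stratified_split",
    "validation_carveout",
    "class_weights",
    "augment",
    "standardize",
    "EvalReport",
    "evaluate",
]

#: Fixed category order: adenosis, ductal/lobular/mucinous/papillary
#: carcinoma, fibroadenoma, phyllodes tumor, tubular adenoma.
CATEGORIES: tuple[str, ...] = ("A", "DC", "F", "LC", "MC", "PC", "PT", "TA")

CATEGORY_FULL_NAMES: dict[str, str] = {
    "A": "adenosis",
    "DC": "ductal_carcinoma",
    "F": "fibroadenoma",
    "LC": "lobular_carcinoma",
    "MC": "mucinous_carcinoma",
    "PC": "papillary_carcinoma",
    "PT": "phyllodes_tumor",
    "TA": "tubular_adenoma",
}

MAGNIFICATIONS: tuple[str, ...] = ("40X", "100X", "200X", "400X")

_MAG_RE = re.compile(r"^(40|100|200|400)\s*[xX]$")
_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    category: str
    magnification: str | None = None
    patient_id: str | None = None


@dataclass
class DatasetIndex:
    """Labeled image records over a fixed ordered category list."""

    records: list[ImageRecord]
    categories: tuple[str, ...] = CATEGORIES

    def __len__(self) -> int:
        return len(self.records)

    def per_class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.categories}
        for r in self.records:
            counts[r.category] += 1
        return counts

    def by_class(self) -> dict[str, list[ImageRecord]]:
        groups: dict[str, list[ImageRecord]] = {c: [] for c in self.categories}
        for r in self.records:
            groups[r.category].append(r)
        return groups


def _match_category(name: str, categories: Sequence[str]) -> str | None:
    norm = name.strip().lower().replace("-", "_").replace(" ", "_")
    for cat in categories:
        if norm == cat.lower() or norm == CATEGORY_FULL_NAMES.get(cat, "").lower():
            return cat
    return None


def index_dataset(
    root: str | Path, categories: Sequence[str] = CATEGORIES
) -> DatasetIndex:
    """Index an image tree whose top-level directories name the classes.

    Directory names may be the short codes (``DC``) or the full tumor
    names (``ductal_carcinoma``).  Deeper nesting is allowed — the
    BreakHis convention ``<class>/<patient>/<magnification>/<file>`` is
    parsed, tagging each record with its patient directory and any path
    component that looks like a magnification (``40X`` ... ``400X``).
    Unreadable image files are logged and skipped; an unknown top-level
    directory or an empty category is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[ImageRecord] = []
    for child in sorted(p for p in root.iterdir() if p.is_dir()):
        cat = _match_category(child.name, categories)
        if cat is None:
            raise ValueError(
                f"unknown category directory {child}: expected one of "
                f"{list(categories)} or their full names"
            )
        n_before = len(records)
        for f in sorted(child.rglob("*")):
            if not (f.is_file() and f.suffix.lower() in _IMAGE_SUFFIXES):
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError):
                logger.warning("skipping unreadable image %s", f)
                continue
            rel = f.relative_to(child).parts
            mag = next(
                (p.upper().replace(" ", "") for p in rel if _MAG_RE.match(p)), None
            )
            patient = rel[0] if len(rel) > 2 else None
            records.append(ImageRecord(f, cat, mag, patient))
        if len(records) == n_before:
            raise ValueError(f"category {cat} under {root} holds no readable images")
    return DatasetIndex(records, tuple(categories))


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SplitResult:
    """Disjoint train/validation/test record sets with a per-class census."""

    train: list[ImageRecord]
    validation: list[ImageRecord]
    test: list[ImageRecord]
    categories: tuple[str, ...] = CATEGORIES

    @property
    def per_class_counts(self) -> pd.DataFrame:
        rows = []
        for cat in self.categories:
            rows.append(
                {
                    "category": cat,
                    "train": sum(r.category == cat for r in self.train),
                    "validation": sum(r.category == cat for r in self.validation),
                    "test": sum(r.category == cat for r in self.test),
                }
            )
        df = pd.DataFrame(rows).set_index("category")
        df["total"] = df.sum(axis=1)
        return df

    def to_manifest(self) -> pd.DataFrame:
        rows = []
        for subset, recs in (
            ("train", self.train),
            ("validation", self.validation),
            ("test", self.test),
        ):
            for r in recs:
                rows.append(
                    {
                        "path": str(r.path),
                        "category": r.category,
                        "magnification": r.magnification or "",
                        "subset": subset,
                    }
                )
        return pd.DataFrame(rows, columns=["path", "category", "magnification", "subset"])


def stratified_split(
    index: DatasetIndex, train_fraction: float = 0.8, seed: int = 0
) -> SplitResult:
    """Per-class random split into train and test sets.

    Within each category, exactly ``round_half_away(train_fraction * N)``
    records are drawn uniformly at random (under ``seed``) into the
    training set; the remainder form the test set.  All magnifications
    are pooled.  The validation set is empty here; carve it out of the
    training records with :func:`validation_carveout`.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[ImageRecord] = []
    test: list[ImageRecord] = []
    for cat, recs in index.by_class().items():
        n_train = round_half_away(train_fraction * len(recs))
        if n_train == 0 or n_train == len(recs):
            logger.warning(
                "category %s: train/test share is empty at fraction %.2f",
                cat,
                train_fraction,
            )
        order = rng.permutation(len(recs))
        train.extend(recs[i] for i in sorted(order[:n_train]))
        test.extend(recs[i] for i in sorted(order[n_train:]))
    return SplitResult(train=train, validation=[], test=test, categories=index.categories)


def validation_carveout(
    train: Sequence[ImageRecord],
    fraction: float = 0.1,
    seed: int = 0,
    categories: Sequence[str] = CATEGORIES,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Move a stratified fraction of training records into a validation set.

    Per category, ``round_half_away(fraction * class train count)``
    records are selected uniformly at random under ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("validation fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    remaining: list[ImageRecord] = []
    validation: list[ImageRecord] = []
    groups: dict[str, list[ImageRecord]] = {c: [] for c in categories}
    for r in train:
        groups[r.category].append(r)
    for recs in groups.values():
        n_val = round_half_away(fraction * len(recs))
        order = rng.permutation(len(recs))
        validation.extend(recs[i] for i in sorted(order[:n_val]))
        remaining.extend(recs[i] for i in sorted(order[n_val:]))
    return remaining, validation


def class_weights(per_class_counts: Mapping[str, int] | Sequence[int]) -> dict[str, float]:
    """Inverse-frequency class weights.

    For class i with N_i examples out of n classes,

        weight_i = (sum_k N_k) / (n * N_i)

    so a balanced dataset yields weight 1 everywhere and the weighted
    mean of the weights under the class frequencies is exactly 1.
    Computed exactly; round only for display.
    """
    if not isinstance(per_class_counts, Mapping):
        per_class_counts = dict(zip(CATEGORIES, per_class_counts))
    n = len(per_class_counts)
    total = sum(per_class_counts.values())
    weights = {}
    for cat, count in per_class_counts.items():
        if count <= 0:
            raise ZeroDivisionError(f"category {cat} has no training examples")
        weights[cat] = total / (n * count)
    return weights


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent 50% horizontal and 50% vertical flips (training only)."""
    out = np.asarray(image)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    return out


def standardize(image: np.ndarray | Image.Image, size: int = 224) -> np.ndarray:
    """Bilinear-resize to ``size`` x ``size`` and scale intensities to [0, 1]."""
    if isinstance(image, np.ndarray):
        image = Image.fromarray(np.asarray(image, dtype=np.uint8))
    elif not isinstance(image, Image.Image):
        raise TypeError("standardize expects a decoded image or pixel array")
    resized = image.convert("RGB").resize((size, size), Image.BILINEAR)
    return np.asarray(resized, dtype=np.float32) / 255.0


@dataclass
class EvalReport:
    """Accuracy, macro precision/recall/F1, and the confusion matrix.

    Confusion-matrix orientation: rows are true classes, columns are
    predicted classes.
    """

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion_matrix: np.ndarray
    categories: tuple[str, ...] = CATEGORIES
    per_class: pd.DataFrame = field(default_factory=pd.DataFrame)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion_matrix,
            index=list(self.categories),
            columns=list(self.categories),
        )

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "macro_precision", "macro_recall", "macro_f1"],
                "value": [
                    self.accuracy,
                    self.macro_precision,
                    self.macro_recall,
                    self.macro_f1,
                ],
            }
        )


def evaluate(
    predicted: Sequence[int],
    truth: Sequence[int],
    categories: Sequence[str] = CATEGORIES,
) -> EvalReport:
    """Score predicted labels against ground truth.

    Precision and recall are computed per class with the 0/0 case
    defined as 0 (a class never predicted contributes precision 0, not
    an error) and macro-averaged so rare tumor classes count equally;
    F1 is the harmonic mean per class before averaging.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth label vectors differ in length")
    k = len(categories)
    all_labels = np.arange(k)
    cm = _sk_confusion(truth, predicted, labels=all_labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predicted, labels=all_labels, average=None, zero_division=0
    )
    per_class = pd.DataFrame(
        {"category": list(categories), "precision": prec, "recall": rec, "f1": f1}
    ).set_index("category")
    return EvalReport(
        accuracy=float(np.trace(cm) / len(truth)),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion_matrix=cm,
        categories=tuple(categories),
        per_class=per_class,
    )
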