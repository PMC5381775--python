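"""Three-class pixel classifier on RGB features.

Each pixel of a stained micrograph is classified independently from its
own (R, G, B) triple into adipogenic / osteogenic / stain-negative, using
a support vector machine with a radial-basis kernel trained on small
labeled reference crops. Channels are divided by 255 so features lie in
[0, 1]^3; the kernel width follows the inverse-feature-count-times-variance
("scale") heuristic.

The SVM is fitted with scikit-learn, but the fitted decision rule — the
support vectors, dual coefficients, intercepts and resolved kernel width —
is extracted into :class:`ClassifierModel`, which performs prediction
itself by one-vs-one voting. Vote ties are broken by the summed
decision-function margin, then by the lowest class code. This makes
prediction an explicit, portable function of plain arrays: a model
serialized to JSON and reloaded in another process predicts bit-identically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .classes import CLASS_CODES, CLASS_NAMES, DEFAULT_PALETTE, StainClass
from .errors import ConfigurationError, ContractError, InputError
from . import image_io

logger = logging.getLogger(__name__)

MODEL_FORMAT = "stainmap-svm"
MODEL_VERSION = 1

#: Ordered class pairs of the one-vs-one decomposition for three classes.
_OVO_PAIRS = ((0, 1), (0, 2), (1, 2))


# ---------------------------------------------------------------------------
# Training data


@dataclass
class TrainingSet:
    """Flat table of per-pixel RGB features with class labels.

    Attributes
    ----------
    features : (N, 3) int array, channels in [0, 255]
    labels : (N,) int array of class codes
    provenance : identifiers of the source crops, in assembly order
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.int64).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ContractError("features and labels differ in length")
        if not np.isin(self.labels, CLASS_CODES).all():
            raise ConfigurationError(f"labels must be class codes {CLASS_CODES}")
        if self.features.size and (self.features.min() < 0 or self.features.max() > 255):
            raise InputError("feature channels must lie in [0, 255]")

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])

    @property
    def per_class_counts(self) -> dict[StainClass, int]:
        return {cls: int(np.sum(self.labels == cls)) for cls in StainClass}


def training_set_from_crops(
    crops: list[tuple[np.ndarray, StainClass]],
    provenance: list[str] | None = None,
    require_all_classes: bool = True,
) -> TrainingSet:
    """Assemble a TrainingSet from in-memory (image, class) crops.

    Every pixel of every crop becomes one feature row carrying the crop's
    class label; rows are ordered crop by crop, row-major within a crop,
    so assembly (and hence training) is reproducible.
    """
    if not crops:
        raise ConfigurationError("no training crops given")
    feats, labs = [], []
    for image, cls in crops:
        image = image_io.validate_rgb_image(image)
        feats.append(image.reshape(-1, 3))
        labs.append(np.full(image.shape[0] * image.shape[1], int(cls), dtype=np.int64))
    present = {int(c) for _, c in crops}
    if require_all_classes and present != set(CLASS_CODES):
        missing = [StainClass(c).name for c in set(CLASS_CODES) - present]
        raise ConfigurationError(f"no training crops for class(es): {', '.join(missing)}")
    prov = provenance if provenance is not None else [f"crop[{i}]" for i in range(len(crops))]
    return TrainingSet(np.concatenate(feats), np.concatenate(labs), list(prov))


def load_training_crops(crop_sources: list[tuple[str | Path, StainClass]]) -> TrainingSet:
    """Load labeled reference crops from image files into a TrainingSet.

    Parameters
    ----------
    crop_sources : list of (path, StainClass)
        Reference micrograph crops (typically ~100x100 px) whose area is
        dominated by a single stain class.
    """
    crops = [(image_io.load_rgb_image(path), cls) for path, cls in crop_sources]
    provenance = [str(path) for path, _ in crop_sources]
    ts = training_set_from_crops(crops, provenance=provenance)
    logger.info(
        "assembled training set: %d pixels (%s)",
        ts.n_samples,
        ", ".join(f"{c.name.lower()}={n}" for c, n in ts.per_class_counts.items()),
    )
    return ts


# ---------------------------------------------------------------------------
# Model


@dataclass
class ClassifierModel:
    """Trained three-class RBF-SVM decision rule over RGB space.

    Holds the support-vector expansion as plain arrays and predicts by
    one-vs-one voting (ties: summed margin, then lowest class code).
    ``feature_scale`` is the divisor applied to raw channels before the
    kernel is evaluated.
    """

    support_vectors: np.ndarray  # (S, 3), already scaled
    dual_coef: np.ndarray  # (n_classes - 1, S)
    intercept: np.ndarray  # (n_pairs,)
    n_support: np.ndarray  # (n_classes,)
    classes: np.ndarray  # (n_classes,) ascending class codes
    gamma: float  # resolved numeric kernel width
    feature_scale: float = 255.0
    hyperparameters: dict = field(default_factory=dict)
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.dual_coef = np.asarray(self.dual_coef, dtype=np.float64)
        self.intercept = np.asarray(self.intercept, dtype=np.float64)
        self.n_support = np.asarray(self.n_support, dtype=np.int64)
        self.classes = np.asarray(self.classes, dtype=np.int64)

    # -- prediction --------------------------------------------------------

    def decision_function(self, rgb: np.ndarray) -> np.ndarray:
        """One-vs-one decision values, shape (N, n_pairs).

        Positive values vote for the first class of the pair (ascending
        class-code order, pairs (0,1), (0,2), (1,2)).
        """
        X = np.asarray(rgb, dtype=np.float64).reshape(-1, 3) / self.feature_scale
        sq = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        starts = np.concatenate([[0], np.cumsum(self.n_support)])
        dec = np.empty((X.shape[0], len(_OVO_PAIRS)))
        for p, (i, j) in enumerate(_OVO_PAIRS):
            si = slice(starts[i], starts[i + 1])
            sj = slice(starts[j], starts[j + 1])
            dec[:, p] = (
                K[:, si] @ self.dual_coef[j - 1, si]
                + K[:, sj] @ self.dual_coef[i, sj]
                + self.intercept[p]
            )
        return dec

    def predict(self, rgb: np.ndarray, chunk_size: int = 1 << 16) -> np.ndarray:
        """Predict class codes for an (N, 3) array of RGB triples."""
        rgb = np.asarray(rgb).reshape(-1, 3)
        out = np.empty(rgb.shape[0], dtype=np.int64)
        for lo in range(0, rgb.shape[0], chunk_size):
            out[lo : lo + chunk_size] = self._predict_block(rgb[lo : lo + chunk_size])
        return out

    def _predict_block(self, rgb: np.ndarray) -> np.ndarray:
        dec = self.decision_function(rgb)
        n = dec.shape[0]
        k = len(self.classes)
        votes = np.zeros((n, k), dtype=np.int64)
        margins = np.zeros((n, k))
        for p, (i, j) in enumerate(_OVO_PAIRS):
            d = dec[:, p]
            win_i = d > 0
            votes[win_i, i] += 1
            votes[~win_i, j] += 1
            margins[:, i] += d
            margins[:, j] -= d
        best = np.argmax(votes, axis=1)
        tied = votes == votes.max(axis=1, keepdims=True)
        multi = tied.sum(axis=1) > 1
        if multi.any():
            # argmax picks the lowest index (lowest class code) on exact ties
            masked = np.where(tied[multi], margins[multi], -np.inf)
            best[multi] = np.argmax(masked, axis=1)
        return self.classes[best]

    def classify(self, image: np.ndarray) -> np.ndarray:
        """Label every pixel of an (H, W, 3) image; returns (H, W) codes.

        Pixels are classified independently from their own color, so the
        result is invariant to any spatial permutation of the input.
        """
        image = image_io.validate_rgb_image(image)
        h, w = image.shape[:2]
        return self.predict(image.reshape(-1, 3)).reshape(h, w)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "feature_scale": self.feature_scale,
            "gamma": self.gamma,
            "classes": self.classes.tolist(),
            "n_support": self.n_support.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept.tolist(),
            "hyperparameters": self.hyperparameters,
            "training_summary": self.training_summary,
        }

    def save(self, path: str | Path) -> None:
        """Write the model as a portable JSON document."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, doc: dict) -> "ClassifierModel":
        if doc.get("format") != MODEL_FORMAT:
            raise InputError(f"not a {MODEL_FORMAT} model document")
        if "version" not in doc:
            raise InputError("model document lacks a version field")
        return cls(
            support_vectors=np.array(doc["support_vectors"]),
            dual_coef=np.array(doc["dual_coef"]),
            intercept=np.array(doc["intercept"]),
            n_support=np.array(doc["n_support"]),
            classes=np.array(doc["classes"]),
            gamma=float(doc["gamma"]),
            feature_scale=float(doc["feature_scale"]),
            hyperparameters=dict(doc.get("hyperparameters", {})),
            training_summary=dict(doc.get("training_summary", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        try:
            doc = json.loads(Path(path).read_text())
        except FileNotFoundError:
            raise InputError(f"{path}: file not found") from None
        except json.JSONDecodeError as exc:
            raise InputError(f"{path}: not a valid model document ({exc})") from exc
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# Training and evaluation


def train(training_set: TrainingSet, C: float = 1.0, gamma: str | float = "scale") -> ClassifierModel:
    """Fit the RBF-SVM pixel classifier on a TrainingSet.

    Training is deterministic: same samples in the same order with the
    same hyperparameters yield an identical decision rule. A degenerate
    set in which two classes present identical color sets trains anyway
    but logs a warning.
    """
    counts = training_set.per_class_counts
    missing = [c.name for c, n in counts.items() if n == 0]
    if missing:
        raise ConfigurationError(f"training set lacks samples for class(es): {', '.join(missing)}")
    _warn_if_degenerate(training_set)

    X = training_set.features.astype(np.float64) / 255.0
    y = training_set.labels
    clf = SVC(C=C, kernel="rbf", gamma=gamma, decision_function_shape="ovo")
    clf.fit(X, y)

    model = ClassifierModel(
        support_vectors=clf.support_vectors_,
        dual_coef=clf.dual_coef_,
        intercept=clf.intercept_,
        n_support=clf.n_support_,
        classes=clf.classes_,
        gamma=float(clf._gamma),
        feature_scale=255.0,
        hyperparameters={"kernel": "rbf", "C": float(C), "gamma": gamma},
    )
    summary = evaluate_training_accuracy(model, training_set)
    model.training_summary = {
        "n_samples": training_set.n_samples,
        "per_class_counts": {name: counts[cls] for name, cls in zip(CLASS_NAMES, StainClass)},
        "training_accuracy": summary.accuracy,
        "error_pixels": summary.error_pixels,
    }
    logger.info(
        "trained on %d pixels, %d support vectors, training accuracy %.4f",
        training_set.n_samples,
        model.support_vectors.shape[0],
        summary.accuracy,
    )
    return model


def _warn_if_degenerate(ts: TrainingSet) -> None:
    uniq = {
        cls: {tuple(row) for row in np.unique(ts.features[ts.labels == cls], axis=0)}
        for cls in StainClass
    }
    pairs = [(a, b) for i, a in enumerate(StainClass) for b in list(StainClass)[i + 1 :]]
    for a, b in pairs:
        if uniq[a] and uniq[a] == uniq[b]:
            msg = f"classes {a.name} and {b.name} have identical feature sets; training proceeds"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=3)


@dataclass
class ConfusionSummary:
    """3x3 confusion counts (rows: true class, columns: predicted)."""

    counts: np.ndarray
    class_codes: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.class_codes),) * 2:
            raise ContractError(f"confusion counts must be {len(self.class_codes)}x{len(self.class_codes)}")

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def error_pixels(self) -> int:
        return self.total_pixels - int(np.trace(self.counts))

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error_pixels / self.total_pixels

    def to_csv(self, path: str | Path) -> None:
        """Write tidy counts plus a summary line."""
        lines = ["true_class,predicted_class,count"]
        for i, ti in enumerate(self.class_codes):
            for j, pj in enumerate(self.class_codes):
                lines.append(f"{StainClass(ti).name.lower()},{StainClass(pj).name.lower()},{self.counts[i, j]}")
        lines.append(f"# accuracy={self.accuracy:.6f} error_pixels={self.error_pixels} total_pixels={self.total_pixels}")
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate_training_accuracy(model: ClassifierModel, training_set: TrainingSet) -> ConfusionSummary:
    """Tabulate model predictions against the training labels."""
    if tuple(model.classes.tolist()) != CLASS_CODES:
        raise ContractError(f"model classes {model.classes.tolist()} do not match {CLASS_CODES}")
    pred = model.predict(training_set.features)
    counts = np.zeros((3, 3), dtype=np.int64)
    for i, ti in enumerate(CLASS_CODES):
        mask = training_set.labels == ti
        for j, pj in enumerate(CLASS_CODES):
            counts[i, j] = np.sum(pred[mask] == pj)
    return ConfusionSummary(counts)


# ---------------------------------------------------------------------------
# Label-map utilities


def render_overlay(label_map: np.ndarray, palette: dict[StainClass, tuple[int, int, int]] | None = None) -> np.ndarray:
    """Render a label map as an RGB image (red/blue/white by default)."""
    if palette is None:
        palette = DEFAULT_PALETTE
    missing = [c.name for c in StainClass if c not in palette]
    if missing:
        raise ConfigurationError(f"palette missing class(es): {', '.join(missing)}")
    label_map = np.asarray(label_map)
    if not np.isin(label_map, CLASS_CODES).all():
        raise InputError(f"label map contains codes outside {CLASS_CODES}")
    lut = np.zeros((max(CLASS_CODES) + 1, 3), dtype=np.uint8)
    for cls, rgb in palette.items():
        lut[int(cls)] = rgb
    return lut[label_map]


def filter_small_components(
    label_map: np.ndarray,
    min_area: int,
    target_class: StainClass = StainClass.ADIPOGENIC,
) -> np.ndarray:
    """Optional spatial post-filter (off by default in the pipeline).

    Connected components of ``target_class`` smaller than ``min_area``
    pixels — e.g. isolated red speckles misread as lipid droplets — are
    reassigned to the stain-negative class.
    """
    from scipy import ndimage

    label_map = np.asarray(label_map).copy()
    mask = label_map == int(target_class)
    comp, n = ndimage.label(mask)
    if n == 0 or min_area <= 1:
        return label_map
    areas = np.bincount(comp.ravel())
    small = np.isin(comp, np.nonzero(areas < min_area)[0]) & mask
    label_map[small] = int(StainClass.NEGATIVE)
    return label_map


__all__ = [
    "TrainingSet",
    "training_set_from_crops",
    "load_training_crops",
    "ClassifierModel",
    "train",
    "ConfusionSummary",
    "evaluate_training_accuracy",
    "render_overlay",
    "filter_small_components",
]
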