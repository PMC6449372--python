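"""Bag-of-features tern-vs-foam chip classifier.

Pipeline: dense gradient-orientation-histogram descriptors on a cell grid ->
k-means visual vocabulary -> hard-assignment occurrence histograms (L1
normalised) -> linear maximum-margin classifier.  Terns render as compact
smooth blobs (strong, radially organised gradients), foam as fractal texture
(isotropic, high-frequency gradients), so their local-descriptor statistics
separate well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.svm import LinearSVC

__all__ = [
    "DescriptorSpec",
    "Vocabulary",
    "EncodedChip",
    "ClassifierModel",
    "ValidationReport",
    "compute_descriptors",
    "build_vocabulary",
    "encode",
    "train_classifier",
    "evaluate",
]

TERN, FOAM = 1, 0
LABEL_NAMES = {TERN: "tern", FOAM: "foam"}


@dataclass(frozen=True)
class DescriptorSpec:
    """Dense descriptor layout: square cells, signed-orientation bins.

    Each cell yields an L2-normalised signed-orientation histogram plus one
    gradient-energy channel (log-compressed total gradient magnitude).  The
    orientation part captures local structure; the energy part captures local
    contrast, which separates a smooth bright blob (a plunging tern seen from
    above) from high-frequency foam texture.
    """

    cell_px: int = 4
    n_orientations: int = 8
    energy_channel: bool = True
    energy_gain: float = 20.0

    @property
    def n_dims(self) -> int:
        return self.n_orientations + (1 if self.energy_channel else 0)

    def grid_shape(self, chip_side: int) -> Tuple[int, int]:
        return chip_side // self.cell_px, chip_side // self.cell_px


@dataclass
class Vocabulary:
    centroids: np.ndarray       # (k, d)
    k: int
    descriptor_spec: DescriptorSpec
    seed: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("vocabulary needs k >= 2")


@dataclass
class EncodedChip:
    histogram: np.ndarray       # (k,), sums to 1
    label: int = -1             # TERN / FOAM / -1 unknown
    degenerate: bool = False    # True when the chip had no usable gradients


@dataclass
class ClassifierModel:
    vocabulary: Vocabulary
    svm: LinearSVC
    training_meta: dict = field(default_factory=dict)

    def predict(self, histograms: np.ndarray) -> np.ndarray:
        return self.svm.predict(np.atleast_2d(histograms))


@dataclass
class ValidationReport:
    n_validation: int
    per_class_accuracy: dict            # label name -> %
    average_accuracy: float             # macro mean, %
    confusion: np.ndarray               # (2, 2), rows = truth (foam, tern)


def compute_descriptors(chip: np.ndarray, spec: DescriptorSpec = DescriptorSpec()):
    """Per-cell gradient-orientation histograms, each L2-normalised.

    The chip is divided into non-overlapping ``cell_px`` squares; within each
    cell, central-difference gradients vote their magnitude into
    ``n_orientations`` signed-orientation bins (0..2pi, so a half-turn of the
    chip permutes bins by n/2 while leaving the energy channel unchanged).
    Cells with no gradient energy yield zero vectors; a fully degenerate
    (constant) chip returns an all-zero descriptor set, which callers should
    flag.
    """
    chip = np.asarray(chip, dtype=float)
    side = chip.shape[0]
    if side < spec.cell_px:
        raise ValueError("chip side smaller than descriptor cell span")
    gy, gx = np.gradient(chip)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    bins = np.floor(ang / (2 * np.pi) * spec.n_orientations).astype(int)
    bins = np.clip(bins, 0, spec.n_orientations - 1)

    n_cells = side // spec.cell_px
    descs = np.zeros((n_cells * n_cells, spec.n_dims))
    idx = 0
    for i in range(n_cells):
        for j in range(n_cells):
            sl = (slice(i * spec.cell_px, (i + 1) * spec.cell_px),
                  slice(j * spec.cell_px, (j + 1) * spec.cell_px))
            hist = np.bincount(bins[sl].ravel(), weights=mag[sl].ravel(),
                               minlength=spec.n_orientations)
            energy = hist.sum()
            norm = np.linalg.norm(hist)
            if norm > 1e-12:
                hist = hist / norm
            else:
                hist = np.zeros_like(hist)
            if spec.energy_channel:
                descs[idx] = np.r_[hist, np.log1p(spec.energy_gain * energy)]
            else:
                descs[idx] = hist
            idx += 1
    return descs


def build_vocabulary(
    descriptor_sets: Sequence[np.ndarray],
    k: int = 200,
    seed: int = 0,
    spec: DescriptorSpec = DescriptorSpec(),
    max_iter: int = 100,
) -> Vocabulary:
    """k-means (k-means++ init, single run, fixed seed) visual vocabulary."""
    all_desc = np.vstack([np.atleast_2d(d) for d in descriptor_sets])
    if all_desc.shape[0] < k:
        raise ValueError(
            f"only {all_desc.shape[0]} descriptors for k={k}; use a smaller k")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    km.fit(all_desc)
    return Vocabulary(centroids=km.cluster_centers_, k=k,
                      descriptor_spec=spec, seed=seed)


def encode(descriptors: np.ndarray, vocab: Vocabulary,
           spec: Optional[DescriptorSpec] = None) -> EncodedChip:
    """Hard-assignment histogram over nearest centroids, L1-normalised.

    A chip with no usable descriptors (all-zero gradient energy) encodes to
    the uniform histogram and is flagged degenerate.
    """
    if spec is not None and spec != vocab.descriptor_spec:
        raise ValueError("descriptor spec does not match the vocabulary's")
    descriptors = np.atleast_2d(np.asarray(descriptors, dtype=float))
    live = descriptors[np.linalg.norm(descriptors, axis=1) > 1e-12]
    k = vocab.k
    if live.shape[0] == 0:
        return EncodedChip(histogram=np.full(k, 1.0 / k), degenerate=True)
    nearest = np.argmin(cdist(live, vocab.centroids), axis=1)
    hist = np.bincount(nearest, minlength=k).astype(float)
    return EncodedChip(histogram=hist / hist.sum())


def train_classifier(
    encoded: Sequence[EncodedChip],
    labels: Sequence[int],
    vocabulary: Vocabulary,
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierModel:
    """L2-regularised linear max-margin classifier on BoF histograms."""
    X = np.vstack([e.histogram for e in encoded])
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    svm = LinearSVC(C=C, loss="squared_hinge", dual=False, tol=1e-6,
                    max_iter=20000, random_state=seed)
    svm.fit(X, y)
    counts = {LABEL_NAMES[c]: int(np.sum(y == c)) for c in np.unique(y)}
    return ClassifierModel(
        vocabulary=vocabulary, svm=svm,
        training_meta={"n_per_class": counts, "C": C, "seed": seed,
                       "solver": "liblinear squared-hinge, dual=False"},
    )


def classify_chips(model: ClassifierModel, chips: Sequence[np.ndarray]) -> np.ndarray:
    """End-to-end: descriptors -> encode -> predict for raw chip arrays."""
    spec = model.vocabulary.descriptor_spec
    hists = np.vstack([
        encode(compute_descriptors(c, spec), model.vocabulary).histogram
        for c in chips
    ])
    return model.predict(hists)


def evaluate(model: ClassifierModel, encoded: Sequence[EncodedChip],
             labels: Sequence[int]) -> ValidationReport:
    """Confusion matrix, per-class and macro-average accuracy (percent)."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("validation set is empty")
    X = np.vstack([e.histogram for e in encoded])
    pred = model.predict(X)
    confusion = np.zeros((2, 2), dtype=int)  # rows truth, cols prediction
    for cls_true in (FOAM, TERN):
        for cls_pred in (FOAM, TERN):
            confusion[cls_true, cls_pred] = int(
                np.sum((y == cls_true) & (pred == cls_pred)))
    per_class = {}
    for cls in (FOAM, TERN):
        n_cls = confusion[cls].sum()
        per_class[LABEL_NAMES[cls]] = (
            100.0 * confusion[cls, cls] / n_cls if n_cls else float("nan"))
    avg = float(np.nanmean(list(per_class.values())))
    return ValidationReport(
        n_validation=int(y.size),
        per_class_accuracy=per_class,
        average_accuracy=avg,
        confusion=confusion,
    )


def encode_chips(chips: np.ndarray, vocab: Vocabulary) -> List[EncodedChip]:
    """Vectorised convenience: encode a stack of raw chips."""
    spec = vocab.descriptor_spec
    return [encode(compute_descriptors(c, spec), vocab) for c in chips]


MODEL_SCHEMA_VERSION = 1


def save_model(model: ClassifierModel, path) -> None:
    """Persist vocabulary + linear weights + spec + seeds as one archive."""
    spec = model.vocabulary.descriptor_spec
    np.savez(
        path,
        schema_version=MODEL_SCHEMA_VERSION,
        centroids=model.vocabulary.centroids,
        vocab_seed=model.vocabulary.seed,
        cell_px=spec.cell_px,
        n_orientations=spec.n_orientations,
        energy_channel=int(spec.energy_channel),
        energy_gain=spec.energy_gain,
        svm_coef=model.svm.coef_,
        svm_intercept=model.svm.intercept_,
        svm_classes=model.svm.classes_,
        training_meta=np.array([repr(model.training_meta)]),
    )


def load_model(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as d:
        if int(d["schema_version"]) != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d['schema_version']}")
        spec = DescriptorSpec(cell_px=int(d["cell_px"]),
                              n_orientations=int(d["n_orientations"]),
                              energy_channel=bool(int(d["energy_channel"])),
                              energy_gain=float(d["energy_gain"]))
        vocab = Vocabulary(centroids=d["centroids"],
                           k=d["centroids"].shape[0],
                           descriptor_spec=spec, seed=int(d["vocab_seed"]))
        svm = LinearSVC()
        svm.coef_ = d["svm_coef"]
        svm.intercept_ = d["svm_intercept"]
        svm.classes_ = d["svm_classes"]
        return ClassifierModel(vocabulary=vocab, svm=svm,
                               training_meta={"restored": str(d["training_meta"][0])})
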