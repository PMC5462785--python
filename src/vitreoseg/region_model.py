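"""Voxelwise 5-class region prediction with a random forest.

Surfaces induce a labelling of every voxel into one of five anatomical
regions (vitreous, vitreous cortex, cortex–ILM gap, retina, sub-RPE space).
A random forest trained on these labels predicts, for unseen voxels, the
probability of belonging to each region; the probability maps drive the
graph-based surface extraction downstream.

Training follows the annotation protocol for the posterior vitreous
boundary: only the exterior cortex surface is trusted, the cortex band is
assumed at least 3 voxels thick, and a 20-voxel zone immediately exterior
to the annotated boundary is excluded from training because its labels are
uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .types import (
    ABOVE_VITREOUS,
    VMI,
    VMI_ILM,
    ILM_RPE,
    BELOW_RPE,
    REGION_NAMES,
    SurfaceSet,
)

__all__ = [
    "N_CLASSES",
    "RegionModelConfig",
    "RegionProbabilityMap",
    "labels_from_surfaces",
    "training_mask_from_surfaces",
    "build_training_set",
    "train_region_classifier",
    "predict_probabilities",
]

N_CLASSES = 5

_EXCLUSION_VOXELS = 20
_MIN_CORTEX = 3


@dataclass(frozen=True)
class RegionModelConfig:
    """Random-forest hyperparameters and sampling caps.

    The forest size and per-class cap are tunable; training is deterministic
    for a fixed seed.
    """

    n_trees: int = 100
    max_depth: Optional[int] = None
    per_class_cap: int = 20_000
    exclusion_voxels: int = _EXCLUSION_VOXELS


@dataclass
class RegionProbabilityMap:
    """Per-voxel probabilities over the 5 region classes.

    ``probs`` has shape ``(n_bscans, n_ascans, n_axial, 5)`` with class order
    ``(above_vitreous, VMI, VMI_ILM, ILM_RPE, below_RPE)``; every voxel's
    vector is non-negative and sums to 1.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 4 or self.probs.shape[-1] != N_CLASSES:
            raise ValueError("probability map must be (bscan, ascan, axial, 5)")

    @property
    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.probs, axis=-1).astype(np.uint8)


def labels_from_surfaces(surfaces: SurfaceSet, grid_shape: Sequence[int]) -> np.ndarray:
    """Per-voxel region labels induced by the boundary surfaces.

    Axial bands per A-scan: ``[0, vit_top)`` vitreous, ``[vit_top,
    vit_bottom)`` cortex, ``[vit_bottom, ILM)`` gap (empty when attached),
    ``[ILM, RPE)`` retina, ``[RPE, end)`` sub-RPE. A-scans with the vitreous
    out of range are vitreous down to the ILM.
    """
    nb, na, nz = (int(g) for g in grid_shape)
    if surfaces.grid_shape != (nb, na):
        raise ValueError("surface grid does not match the volume grid")
    surfaces.validate_ordering(min_cortex=0)

    z = np.arange(nz)[None, None, :]
    defined = surfaces.vitreous_defined
    vt = np.where(defined, surfaces.vit_top, surfaces.ilm)[..., None]
    vb = np.where(defined, surfaces.vit_bottom, surfaces.ilm)[..., None]
    ilm = surfaces.ilm[..., None]
    rpe = surfaces.rpe[..., None]

    labels = np.full((nb, na, nz), ABOVE_VITREOUS, dtype=np.uint8)
    labels[(z >= vt) & (z < vb)] = VMI
    labels[(z >= vb) & (z < ilm)] = VMI_ILM
    labels[(z >= ilm) & (z < rpe)] = ILM_RPE
    labels[z >= rpe] = BELOW_RPE
    return labels


def training_mask_from_surfaces(
    surfaces: SurfaceSet,
    grid_shape: Sequence[int],
    exclusion_voxels: int = _EXCLUSION_VOXELS,
) -> np.ndarray:
    """Boolean include-mask for training voxels.

    The ``exclusion_voxels`` voxels immediately exterior (smaller axial
    index) to the annotated vitreous boundary are excluded: the annotation
    gives only the exterior cortex surface, so labels just above it are the
    least reliable. A-scans without an in-range vitreous boundary have their
    whole supra-ILM range excluded — whether those voxels are vitreous gel
    or retrohyaloid space is exactly what the missing annotation cannot say.
    """
    nb, na, nz = (int(g) for g in grid_shape)
    z = np.arange(nz)[None, None, :]
    include = np.ones((nb, na, nz), dtype=bool)
    defined = surfaces.vitreous_defined
    vt = np.where(defined, surfaces.vit_top, -1.0)[..., None]
    include[(z >= vt - exclusion_voxels) & (z < vt)] = False
    undefined_above = (~defined)[..., None] & (z < surfaces.ilm[..., None])
    include[undefined_above] = False
    return include


def build_training_set(
    feature_stacks: Sequence,
    label_maps: Sequence[np.ndarray],
    training_masks: Optional[Sequence[np.ndarray]] = None,
    per_class_cap: int = 20_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a balanced voxel sample across volumes.

    Voxels in excluded zones are dropped, each class is subsampled to at
    most ``per_class_cap`` voxels (without replacement, deterministic for a
    fixed seed), and the rows are shuffled. Raises if any region class has
    no eligible voxels, naming the missing classes.
    """
    if len(feature_stacks) != len(label_maps):
        raise ValueError("feature stacks and label maps must align")
    rng = np.random.default_rng(seed)
    feats, labs = [], []
    for i, (stack, lmap) in enumerate(zip(feature_stacks, label_maps)):
        values = stack.values if hasattr(stack, "values") else np.asarray(stack)
        if values.shape[:3] != lmap.shape:
            raise ValueError(f"stack/labels shape mismatch for volume {i}")
        mask = (
            np.ones(lmap.shape, dtype=bool)
            if training_masks is None
            else np.asarray(training_masks[i], dtype=bool)
        )
        feats.append(values[mask])
        labs.append(lmap[mask])
    X = np.concatenate(feats)
    y = np.concatenate(labs).astype(np.int64)

    missing = [REGION_NAMES[c] for c in range(N_CLASSES) if not np.any(y == c)]
    if missing:
        raise ValueError(f"no eligible training voxels for classes: {', '.join(missing)}")

    keep = []
    for c in range(N_CLASSES):
        idx = np.flatnonzero(y == c)
        if len(idx) > per_class_cap:
            idx = rng.choice(idx, size=per_class_cap, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    rng.shuffle(keep)
    return X[keep], y[keep]


def train_region_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: RegionModelConfig = RegionModelConfig(),
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> RandomForestClassifier:
    """Fit the voxel classifier (an ensemble of decision trees).

    The returned handle is picklable; the feature layout used in training is
    recorded on it so prediction can verify compatibility.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(features) != len(labels):
        raise ValueError("feature matrix and label vector lengths differ")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(features, labels)
    clf.vitreoseg_feature_names_ = (
        list(feature_names) if feature_names is not None else None
    )
    return clf


def predict_probabilities(feature_stack, classifier) -> RegionProbabilityMap:
    """Per-voxel 5-class probabilities for a whole volume.

    The classifier's training feature layout (when recorded) must match the
    stack; classes absent from training receive probability 0.
    """
    values = feature_stack.values if hasattr(feature_stack, "values") else np.asarray(feature_stack)
    names = getattr(feature_stack, "names", None)
    trained_names = getattr(classifier, "vitreoseg_feature_names_", None)
    if trained_names is not None and names is not None and list(names) != list(trained_names):
        missing = [n for n in trained_names if n not in names]
        extra = [n for n in names if n not in trained_names]
        raise ValueError(
            f"feature layout mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    nb, na, nz, nf = values.shape
    if nf != classifier.n_features_in_:
        raise ValueError(
            f"classifier expects {classifier.n_features_in_} features, stack has {nf}"
        )
    flat = values.reshape(-1, nf)
    raw = classifier.predict_proba(flat)
    probs = np.zeros((flat.shape[0], N_CLASSES), dtype=np.float64)
    probs[:, classifier.classes_.astype(int)] = raw
    probs /= probs.sum(axis=1, keepdims=True)
    return RegionProbabilityMap(probs.reshape(nb, na, nz, N_CLASSES))
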