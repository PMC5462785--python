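"""Auto-context refinement and segmentation accuracy evaluation.

The base classifier sees only image features and produces probability maps
with occasional gross errors. Auto-context feeds the spatial output of each
classifier back as features for the next one: for every voxel, the signed
axial distance to each currently extracted surface, and raw probability
samples of selected classes at fixed axial offsets ("what is the probability
that the voxel 2 above me is retina?"). A fresh classifier is trained on the
image features merged with these context features; applying the chain for a
small number of iterations removes most large segmentation errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureStack, FilterBank, extract_features
from .region_model import (
    RegionModelConfig,
    RegionProbabilityMap,
    build_training_set,
    labels_from_surfaces,
    predict_probabilities,
    train_region_classifier,
    training_mask_from_surfaces,
)
from .surface_graph import SurfaceConfig, extract_surfaces
from .types import REGION_NAMES, VMI, ILM_RPE, SURFACE_NAMES, OCTVolume, SurfaceSet

__all__ = [
    "AutoContextConfig",
    "context_features",
    "CascadeModel",
    "train_autocontext",
    "IterationTrace",
    "run_autocontext",
    "ErrorSummary",
    "evaluate_against_reference",
]


@dataclass(frozen=True)
class AutoContextConfig:
    """Context feature layout and iteration count.

    ``offsets`` are axial voxel offsets at which class probabilities are
    sampled (clamped at the volume border); ``sampled_classes`` are the
    region classes sampled (cortex and retina by default — the classes whose
    local context disambiguates the boundary). Surface distances use
    ``missing_sentinel`` times the axial size for out-of-range surfaces.
    """

    n_iterations: int = 2
    offsets: tuple[int, ...] = (-10, -5, -2, 2, 5, 10)
    sampled_classes: tuple[int, ...] = (VMI, ILM_RPE)
    missing_sentinel: float = 10.0


def context_features(
    prob_map: RegionProbabilityMap,
    surfaces: SurfaceSet,
    config: AutoContextConfig = AutoContextConfig(),
) -> FeatureStack:
    """Distance-to-surface and neighbourhood-probability features.

    Distances are signed, ``z_voxel - z_surface`` (positive below the
    surface). Missing vitreous surfaces yield a constant sentinel of
    ``missing_sentinel * n_axial`` voxels.
    """
    probs = prob_map.probs if hasattr(prob_map, "probs") else np.asarray(prob_map)
    nb, na, nz, _ = probs.shape
    z = np.arange(nz, dtype=np.float32)[None, None, :]
    sentinel = np.float32(config.missing_sentinel * nz)

    blocks, names = [], []
    for name, surf in surfaces.surfaces().items():
        d = z - surf[..., None].astype(np.float32)
        d = np.where(np.isnan(d), sentinel, d)
        blocks.append(d[..., None])
        names.append(f"dist_{name}")
    for cls in config.sampled_classes:
        for off in config.offsets:
            idx = np.clip(np.arange(nz) + off, 0, nz - 1)
            blocks.append(probs[:, :, idx, cls][..., None].astype(np.float32))
            names.append(f"p_{REGION_NAMES[cls]}_off{off:+d}")
    return FeatureStack(np.concatenate(blocks, axis=-1), names)


@dataclass
class CascadeModel:
    """Classifier chain produced by auto-context training.

    ``classifiers[0]`` consumes image features only; ``classifiers[k]``
    (k >= 1) consumes image features merged with context features derived
    from the output of ``classifiers[k - 1]``.
    """

    classifiers: list
    autocontext: AutoContextConfig
    surface_config: SurfaceConfig
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.classifiers) - 1


@dataclass
class IterationTrace:
    """Per-iteration segmentation state for one volume.

    Entry ``k`` holds the surfaces and probability map after iteration ``k``
    (entry 0 is the base segmentation); length is ``n_iterations + 1``.
    """

    surfaces: list
    prob_maps: list
    seeds: dict

    def __len__(self) -> int:
        return len(self.surfaces)

    @property
    def final_surfaces(self) -> SurfaceSet:
        return self.surfaces[-1]


def train_autocontext(
    training_volumes: Sequence[tuple[OCTVolume, SurfaceSet]],
    bank: FilterBank,
    n_iterations: int = 2,
    model_config: RegionModelConfig = RegionModelConfig(),
    autocontext_config: AutoContextConfig = AutoContextConfig(),
    surface_config: SurfaceConfig = SurfaceConfig(),
    seed: int = 0,
) -> CascadeModel:
    """Train the base classifier and ``n_iterations`` context classifiers.

    Each iteration re-draws the same balanced voxel sample (same seed), so
    accuracy changes across iterations are attributable to the context
    features rather than to resampling. Deterministic for fixed seeds.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    base_stacks, label_maps, masks = [], [], []
    for volume, truth_surfaces in training_volumes:
        base_stacks.append(extract_features(volume, bank))
        grid = volume.data.shape
        label_maps.append(labels_from_surfaces(truth_surfaces, grid))
        masks.append(
            training_mask_from_surfaces(truth_surfaces, grid, model_config.exclusion_voxels)
        )

    X, y = build_training_set(base_stacks, label_maps, masks, model_config.per_class_cap, seed)
    base_clf = train_region_classifier(X, y, model_config, seed, base_stacks[0].names)
    classifiers = [base_clf]

    stacks = base_stacks
    for k in range(1, n_iterations + 1):
        aug_stacks = []
        for stack, base in zip(stacks, base_stacks):
            probs = predict_probabilities(stack, classifiers[-1])
            surfaces = extract_surfaces(probs, surface_config)
            ctx = context_features(probs, surfaces, autocontext_config)
            aug_stacks.append(base.concat(ctx))
        X, y = build_training_set(aug_stacks, label_maps, masks, model_config.per_class_cap, seed)
        clf = train_region_classifier(
            X, y, model_config, seed + k, aug_stacks[0].names
        )
        classifiers.append(clf)
        stacks = aug_stacks
    return CascadeModel(classifiers, autocontext_config, surface_config, seed)


def run_autocontext(
    volume: OCTVolume,
    bank: FilterBank,
    model: CascadeModel,
    n_iterations: Optional[int] = None,
) -> IterationTrace:
    """Apply the trained cascade to one volume.

    Returns the trace of surfaces/probability maps after each iteration
    (``n_iterations + 1`` entries; iteration 0 is the base segmentation).
    """
    if n_iterations is None:
        n_iterations = model.n_iterations
    if n_iterations > model.n_iterations:
        raise ValueError(
            f"cascade was trained for {model.n_iterations} iterations; "
            f"requested {n_iterations}"
        )
    base = extract_features(volume, bank)
    traces_s, traces_p = [], []
    stack = base
    for k in range(n_iterations + 1):
        probs = predict_probabilities(stack, model.classifiers[k])
        surfaces = extract_surfaces(probs, model.surface_config)
        traces_p.append(probs)
        traces_s.append(surfaces)
        if k < n_iterations:
            ctx = context_features(probs, surfaces, model.autocontext)
            stack = base.concat(ctx)
    return IterationTrace(traces_s, traces_p, seeds={"train_seed": model.seed})


# ---------------------------------------------------------------------------
# Validation against reference surfaces
# ---------------------------------------------------------------------------


@dataclass
class ErrorSummary:
    """Per-A-scan ILM–vitreous distance error of automatic vs reference.

    Signed errors are automatic minus reference, reported in pixels and µm
    (µm = pixels x axial spacing, exactly). A-scans where the vitreous is
    missing in either input are excluded from the statistics and counted.
    ``surface_mae`` holds the mean unsigned surface position error (voxels)
    for each of the four surfaces over the A-scans defined in both inputs.
    """

    signed_px: np.ndarray
    signed_um: np.ndarray
    median_px: float
    quartiles_px: tuple[float, float]
    mean_abs_px: float
    n_evaluated: int
    n_excluded: int
    histogram: tuple[np.ndarray, np.ndarray]
    surface_mae: dict


def evaluate_against_reference(
    auto: SurfaceSet, reference: SurfaceSet, axial_spacing_um: float
) -> ErrorSummary:
    """Compare automatic and reference segmentations per A-scan."""
    if auto.grid_shape != reference.grid_shape:
        raise ValueError(
            f"grid mismatch: {auto.grid_shape} vs {reference.grid_shape}"
        )
    both = auto.vitreous_defined & reference.vitreous_defined
    dist_auto = auto.ilm - auto.vit_bottom
    dist_ref = reference.ilm - reference.vit_bottom
    signed_px = (dist_auto - dist_ref)[both]
    signed_um = signed_px * float(axial_spacing_um)
    n_excluded = int(both.size - both.sum())

    if signed_px.size:
        median = float(np.median(signed_px))
        q1, q3 = (float(q) for q in np.percentile(signed_px, [25, 75]))
        mean_abs = float(np.mean(np.abs(signed_px)))
        hist = np.histogram(signed_px, bins=21)
    else:
        median, q1, q3, mean_abs = np.nan, np.nan, np.nan, np.nan
        hist = (np.zeros(21, dtype=int), np.linspace(-1, 1, 22))

    surface_mae = {}
    for name in SURFACE_NAMES:
        a, r = getattr(auto, name), getattr(reference, name)
        ok = ~np.isnan(a) & ~np.isnan(r)
        surface_mae[name] = float(np.mean(np.abs(a[ok] - r[ok]))) if ok.any() else np.nan

    return ErrorSummary(
        signed_px=signed_px,
        signed_um=signed_um,
        median_px=median,
        quartiles_px=(q1, q3),
        mean_abs_px=mean_abs,
        n_evaluated=int(signed_px.size),
        n_excluded=n_excluded,
        histogram=hist,
        surface_mae=surface_mae,
    )
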