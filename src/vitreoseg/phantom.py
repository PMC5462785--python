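"""Synthetic OCT phantoms with known posterior-vitreous geometry.

The generator renders layered macular volumes — a bright retina bounded by the
ILM and the RPE, and a thin, faint posterior vitreous cortex whose separation
from the ILM follows one of four vitreomacular configurations:

``attached``
    the cortex rests on the ILM everywhere (ILM–vitreous distance 0);
``shallow_vma`` / ``steep_vma``
    a residual attachment zone around the fovea with separation increasing
    monotonically with radial distance outside it; the steep class has a
    strictly larger separation gradient (and typically larger peak separation);
``complete_pvd``
    the detached cortex lies above the axial scanning range, so the vitreous
    surfaces are unknown (explicit NaN sentinel, distinct from distance 0).

Ground truth (surfaces, per-voxel region labels, en-face distance map) is
returned alongside the rendered intensities so that every downstream stage of
the segmentation pipeline can be validated without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import OCTVolume, SurfaceSet, EyeRecord
from .region_model import labels_from_surfaces

__all__ = [
    "VMA_CLASSES",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_EFFECT_SPEC",
]

VMA_CLASSES = ("attached", "shallow_vma", "steep_vma", "complete_pvd")

#: Default peak ILM–vitreous separation (µm) per class. The shallow/steep
#: values bracket the per-cluster mean distances reported for clinical VMA
#: phenotypes (a few µm up to several tens of µm mean, with peak separations
#: of one to a few hundred µm at the scan edge).
_DEFAULT_MAX_SEPARATION = {
    "attached": 0.0,
    "shallow_vma": 80.0,
    "steep_vma": 200.0,
    "complete_pvd": 0.0,  # unused: the boundary is out of range
}

#: Fraction of the adhesion-to-edge radial span over which the steep class
#: reaches its peak separation (the shallow class ramps over the full span).
#: Combined with the larger peak separation this gives the steep class a
#: roughly 3x larger separation gradient while keeping most of its boundary
#: inside the default axial field of view (~372 µm deep).
_STEEP_RAMP_FRACTION = 0.8

_CORTEX_THICKNESS = 3  # voxels, inclusive band [vit_top, vit_bottom]

# Rendering intensities (arbitrary units in [0, 1]); the cortex band contrast
# is ~30% of the retinal band contrast, echoing its faint appearance. The
# vitreous gel scatters weakly whereas the retrohyaloid space between a
# detached cortex and the ILM is optically empty, so the gel renders a bit
# brighter than the gap below the cortex.
_I_VITREOUS_GEL = 0.12
_I_GAP = 0.05
_I_RETINA = 0.45
_I_CORTEX = _I_GAP + 0.3 * (_I_RETINA - _I_GAP)
_I_ILM_LINE = 0.85
_I_RPE_LINE = 0.95
_I_BELOW_RPE = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic macular volume.

    ``grid_shape`` is ``(n_bscans, n_ascans, n_axial)``. When
    ``voxel_spacing`` is None, the lateral and inter-B-scan spacings are set
    so the field of view is 6 x 6 mm regardless of grid size (mirroring a
    20° x 20° macular cube) with an axial spacing of 3.87 µm.
    ``adhesion_radius`` is the radius (µm) of the residual attachment zone;
    ``max_separation`` the peak ILM–vitreous distance (µm) reached towards
    the volume edge (class-specific default when None). ``noise_level`` is
    the multiplicative speckle contrast (std/mean) in [0, 1).
    """

    grid_shape: tuple[int, int, int] = (16, 48, 96)
    voxel_spacing: Optional[tuple[float, float, float]] = None
    vma_class: str = "attached"
    adhesion_radius: float = 750.0
    max_separation: Optional[float] = None
    noise_level: float = 0.3
    seed: int = 0
    ilm_depth_fraction: float = 0.55
    retina_thickness_fraction: float = 0.25

    def resolved_spacing(self) -> tuple[float, float, float]:
        if self.voxel_spacing is not None:
            return tuple(float(s) for s in self.voxel_spacing)
        nb, na, _ = self.grid_shape
        return (3.87, 6000.0 / na, 6000.0 / nb)

    def resolved_max_separation(self) -> float:
        if self.max_separation is not None:
            return float(self.max_separation)
        return _DEFAULT_MAX_SEPARATION[self.vma_class]

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 8 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be three sizes all >= 8; got {self.grid_shape}")
        if any(s <= 0 for s in self.resolved_spacing()):
            raise ValueError("voxel spacing must be positive")
        if self.vma_class not in VMA_CLASSES:
            raise ValueError(f"unknown vma_class {self.vma_class!r}; expected one of {VMA_CLASSES}")
        if not (0.0 <= self.noise_level < 1.0):
            raise ValueError("noise_level must be in [0, 1)")
        if self.adhesion_radius < 0:
            raise ValueError("adhesion_radius must be non-negative")
        n_axial = self.grid_shape[2]
        ilm_base = self.ilm_depth_fraction * n_axial
        # the cortex band and the retina must fit inside the axial range
        if ilm_base - _CORTEX_THICKNESS < 1 or ilm_base + 12 > n_axial - 1:
            raise ValueError(
                "grid too small to honour the cortex thickness and retina bands; "
                f"n_axial={n_axial} with ILM near {ilm_base:.1f}"
            )


@dataclass
class GroundTruth:
    """True surfaces, per-voxel region labels and en-face distance map."""

    surfaces: SurfaceSet
    region_labels: np.ndarray          # uint8, shape (nb, na, nz)
    distance_map_true: np.ndarray      # µm, NaN where vitreous out of range

    @property
    def vitreous_defined(self) -> np.ndarray:
        return self.surfaces.vitreous_defined


def _radial_distance_um(nb: int, na: int, spacing: tuple[float, float, float]) -> np.ndarray:
    """Distance (µm) of each A-scan from the foveal centre of the grid."""
    _, lateral, inter = spacing
    yb = (np.arange(nb) - (nb - 1) / 2.0) * inter
    xa = (np.arange(na) - (na - 1) / 2.0) * lateral
    return np.hypot(yb[:, None], xa[None, :])


def _separation_profile_um(spec: PhantomSpec, r_um: np.ndarray) -> np.ndarray:
    """ILM–vitreous separation (µm) per A-scan for the in-range classes."""
    if spec.vma_class == "attached":
        return np.zeros_like(r_um)
    max_sep = spec.resolved_max_separation()
    r_edge = float(r_um.max())
    r0 = min(spec.adhesion_radius, r_edge)
    span = max(r_edge - r0, 1e-9)
    if spec.vma_class == "steep_vma":
        span *= _STEEP_RAMP_FRACTION
    ramp = np.clip((r_um - r0) / span, 0.0, 1.0)
    return max_sep * ramp


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Render a synthetic OCT volume with its ground truth.

    Deterministic for a fixed ``spec.seed``. With ``noise_level == 0`` the
    intensity along every A-scan has local maxima at the true ILM and RPE.
    """
    spec.validate()
    nb, na, nz = (int(g) for g in spec.grid_shape)
    spacing = spec.resolved_spacing()
    ax = spacing[0]

    # --- geometry (continuous, then voxelized) ---------------------------
    r_um = _radial_distance_um(nb, na, spacing)
    ilm_base = spec.ilm_depth_fraction * nz
    dip = 0.06 * nz * np.exp(-(r_um**2) / (2 * 500.0**2))  # foveal depression
    z_ilm = np.rint(ilm_base + dip).astype(np.float64)
    thickness = spec.retina_thickness_fraction * nz
    z_rpe = np.rint(ilm_base + dip * 0.25 + thickness).astype(np.float64)
    z_rpe = np.maximum(z_rpe, z_ilm + 10)
    z_rpe = np.minimum(z_rpe, nz - 2)

    if spec.vma_class == "complete_pvd":
        vit_top = np.full((nb, na), np.nan)
        vit_bottom = np.full((nb, na), np.nan)
    else:
        sep_vox = np.rint(_separation_profile_um(spec, r_um) / ax)
        vit_bottom = z_ilm - sep_vox
        vit_top = vit_bottom - _CORTEX_THICKNESS
        out = vit_top < 0  # separation locally beyond the axial range
        vit_bottom[out] = np.nan
        vit_top[out] = np.nan

    surfaces = SurfaceSet(vit_top, vit_bottom, z_ilm, z_rpe)
    surfaces.validate_ordering(min_cortex=_CORTEX_THICKNESS)

    distance = (surfaces.ilm - surfaces.vit_bottom) * ax  # NaN where undefined

    labels = labels_from_surfaces(surfaces, (nb, na, nz))

    # --- rendering -------------------------------------------------------
    z = np.arange(nz)[None, None, :]
    img = np.full((nb, na, nz), _I_VITREOUS_GEL, dtype=np.float32)
    img[(z >= z_ilm[..., None]) & (z < z_rpe[..., None])] = _I_RETINA
    img[z >= z_rpe[..., None]] = _I_BELOW_RPE
    defined = surfaces.vitreous_defined
    # the optically empty retrohyaloid gap; for out-of-range columns the whole
    # space above the ILM is retrohyaloid (the gel left the scanned range)
    vt = np.where(defined, surfaces.vit_top, 0.0)[..., None]
    vb = np.where(defined, surfaces.vit_bottom, 0.0)[..., None]
    img[(z >= vb) & (z < z_ilm[..., None])] = _I_GAP
    if defined.any():
        cortex = (z >= vt) & (z < vb)  # [vit_top, vit_bottom), always above ILM
        img[cortex] = _I_CORTEX
    img[(z >= z_ilm[..., None]) & (z < z_ilm[..., None] + 1)] = _I_ILM_LINE
    img[(z >= z_rpe[..., None]) & (z < z_rpe[..., None] + 2)] = _I_RPE_LINE

    # mild in-plane blur so bands have soft shoulders like real OCT
    img = gaussian_filter(img, sigma=(0.0, 0.5, 0.5), mode="nearest")

    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        shape_k = 1.0 / spec.noise_level**2
        speckle = rng.gamma(shape_k, 1.0 / shape_k, size=img.shape).astype(np.float32)
        img = img * speckle

    volume = OCTVolume(img, spacing)
    truth = GroundTruth(surfaces=surfaces, region_labels=labels, distance_map_true=distance)
    return volume, truth


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

#: Per-class clinical covariate distributions (mean, SD). The non-VMA classes
#: have smaller baseline CRT and smaller BCVA gains than the VMA classes,
#: echoing the gradients observed across vitreomacular interface phenotypes
#: in treated retinal vein occlusion.
DEFAULT_EFFECT_SPEC: dict[str, dict[str, tuple[float, float]]] = {
    "attached": {
        "baseline_bcva": (60.0, 12.0),
        "bcva_change": (11.0, 11.0),
        "baseline_crt": (360.0, 100.0),
        "crt_change": (-80.0, 76.0),
        "n_injections": (4.7, 1.1),
    },
    "complete_pvd": {
        "baseline_bcva": (60.0, 12.0),
        "bcva_change": (11.0, 11.0),
        "baseline_crt": (360.0, 100.0),
        "crt_change": (-80.0, 76.0),
        "n_injections": (4.7, 1.1),
    },
    "shallow_vma": {
        "baseline_bcva": (58.0, 13.0),
        "bcva_change": (15.0, 11.0),
        "baseline_crt": (525.0, 135.0),
        "crt_change": (-200.0, 153.0),
        "n_injections": (5.0, 0.9),
    },
    "steep_vma": {
        "baseline_bcva": (56.0, 13.0),
        "bcva_change": (13.0, 13.0),
        "baseline_crt": (595.0, 253.0),
        "crt_change": (-234.0, 263.0),
        "n_injections": (5.0, 0.9),
    },
}


def _stratified_counts(n_eyes: int, class_mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n_eyes`` across classes."""
    total = sum(class_mix.values())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"class mix proportions must sum to 1; got {total}")
    items = sorted(class_mix.items())
    exact = {c: p * n_eyes for c, p in items}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n_eyes - sum(counts.values())
    by_rem = sorted(items, key=lambda cp: (-(exact[cp[0]] - counts[cp[0]]), cp[0]))
    for c, _ in by_rem[:short]:
        counts[c] += 1
    return counts


def generate_cohort(
    n_eyes: int,
    class_mix: dict[str, float],
    effect_spec: Optional[dict[str, dict[str, tuple[float, float]]]] = None,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (16, 48, 96),
    noise_level: float = 0.3,
    geometry_jitter: float = 0.2,
) -> list[tuple[OCTVolume, GroundTruth, EyeRecord]]:
    """Generate a cohort of phantom eyes with planted classes and covariates.

    Allocation over classes is stratified (largest remainder), eye-level
    clinical covariates are drawn from the per-class normal distributions in
    ``effect_spec`` (defaulting to :data:`DEFAULT_EFFECT_SPEC`), and geometry
    parameters receive ±``geometry_jitter`` relative uniform jitter so eyes
    within a class are not identical. The planted class is stored on each
    :class:`~vitreoseg.types.EyeRecord` for recovery tests.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    for c in class_mix:
        if c not in VMA_CLASSES:
            raise ValueError(f"unknown class {c!r} in mix")
    spec_table = dict(DEFAULT_EFFECT_SPEC)
    if effect_spec:
        for c, cov in effect_spec.items():
            spec_table[c] = {**spec_table.get(c, {}), **cov}
    for c, cov in spec_table.items():
        for name, (_, sd) in cov.items():
            if sd < 0:
                raise ValueError(f"negative SD for {c}/{name}")

    counts = _stratified_counts(n_eyes, class_mix)
    rng = np.random.default_rng(seed)
    out: list[tuple[OCTVolume, GroundTruth, EyeRecord]] = []
    eye_idx = 0
    for cls in sorted(counts):
        for _ in range(counts[cls]):
            jit = 1.0 + geometry_jitter * rng.uniform(-1, 1)
            jit2 = 1.0 + geometry_jitter * rng.uniform(-1, 1)
            spec = PhantomSpec(
                grid_shape=grid_shape,
                vma_class=cls,
                adhesion_radius=750.0 * jit,
                max_separation=(
                    None if cls in ("attached", "complete_pvd")
                    else _DEFAULT_MAX_SEPARATION[cls] * jit2
                ),
                noise_level=noise_level,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            volume, truth = generate_phantom(spec)
            cov = spec_table[cls]
            dist = truth.distance_map_true
            mean_dist = float(np.nanmean(dist)) if np.isfinite(dist).any() else np.nan
            record = EyeRecord(
                eye_id=f"eye{eye_idx:04d}",
                baseline_bcva=float(np.clip(rng.normal(*cov["baseline_bcva"]), 0, 100)),
                bcva_change=float(rng.normal(*cov["bcva_change"])),
                baseline_crt=float(rng.normal(*cov["baseline_crt"])),
                crt_change=float(rng.normal(*cov["crt_change"])),
                n_injections=int(np.clip(np.rint(rng.normal(*cov["n_injections"])), 0, None)),
                baseline_ilm_vit_distance=mean_dist,
                planted_class=cls,
            )
            out.append((volume, truth, record))
            eye_idx += 1
    return out
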