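"""Core containers shared across the segmentation and phenotyping pipeline.

Axis conventions
----------------
Volumes are indexed ``[bscan, ascan, axial]``. The axial axis points from the
vitreous (index 0, "top" of the displayed B-scan) towards the choroid. Surface
positions are 0-based axial voxel indices; physical distances are obtained by
multiplying index differences with the axial voxel spacing in micrometres.

Voxel spacing is stored as ``(axial, lateral, inter_bscan)`` in µm, matching
the highly anisotropic sampling of clinical spectral-domain OCT
(roughly 3.8 x 11.1 x 118 µm for a 49 B-scan macular cube).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "REGION_NAMES",
    "ABOVE_VITREOUS",
    "VMI",
    "VMI_ILM",
    "ILM_RPE",
    "BELOW_RPE",
    "SURFACE_NAMES",
    "OCTVolume",
    "SurfaceSet",
    "EyeRecord",
]

# The five anatomical region classes, ordered from exterior (vitreous side)
# to interior (choroid side).
ABOVE_VITREOUS = 0   # vitreous gel above the posterior vitreous cortex
VMI = 1              # the posterior vitreous boundary (cortex band) itself
VMI_ILM = 2          # gap between the vitreous cortex and the ILM
ILM_RPE = 3          # the retina proper
BELOW_RPE = 4        # everything exterior to the RPE

REGION_NAMES = ("above_vitreous", "VMI", "VMI_ILM", "ILM_RPE", "below_RPE")

# The four boundary surfaces separating the five regions, exterior to interior.
SURFACE_NAMES = ("vit_top", "vit_bottom", "ilm", "rpe")


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        Intensity grid of shape ``(n_bscans, n_ascans, n_axial)``; float32.
    spacing:
        ``(axial, lateral, inter_bscan)`` voxel spacing in µm, all > 0.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3D (bscan, ascan, axial); got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be three positive values; got {self.spacing}")

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.data.shape[1]

    @property
    def n_axial(self) -> int:
        return self.data.shape[2]

    @property
    def axial_spacing(self) -> float:
        return self.spacing[0]


@dataclass
class SurfaceSet:
    """Per-A-scan axial positions of the four boundary surfaces.

    Each surface is an array of shape ``(n_bscans, n_ascans)`` holding axial
    voxel indices. Every surface marks the first voxel of the region interior
    to it: ``vit_top`` the first cortex voxel, ``vit_bottom`` the first voxel
    below the cortex (so the cortex band is ``[vit_top, vit_bottom)`` and the
    ILM–vitreous gap is ``ilm - vit_bottom``, exactly 0 for an attached
    vitreous), ``ilm`` the first retinal voxel and ``rpe`` the first sub-RPE
    voxel. The vitreous surfaces may be NaN where the posterior vitreous
    boundary is out of the axial scanning range (complete PVD); NaN is an
    explicit "unknown" sentinel, distinct from a distance of 0.
    """

    vit_top: np.ndarray
    vit_bottom: np.ndarray
    ilm: np.ndarray
    rpe: np.ndarray

    def __post_init__(self) -> None:
        arrs = {}
        shape = None
        for name in SURFACE_NAMES:
            a = np.asarray(getattr(self, name), dtype=np.float64)
            if a.ndim != 2:
                raise ValueError(f"surface '{name}' must be 2D (bscan, ascan)")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("all surfaces must share one (bscan, ascan) grid")
            arrs[name] = a
        for name, a in arrs.items():
            setattr(self, name, a)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.ilm.shape

    def surfaces(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in SURFACE_NAMES}

    @property
    def vitreous_defined(self) -> np.ndarray:
        """Boolean mask of A-scans where the vitreous boundary is in range."""
        return ~np.isnan(self.vit_bottom)

    def validate_ordering(self, min_cortex: int = 3) -> None:
        """Check exterior-to-interior ordering of the surfaces.

        Raises ``ValueError`` naming the first offending A-scan. Where the
        vitreous boundary is defined, the cortex band ``[vit_top, vit_bottom)``
        must contain at least ``min_cortex`` voxels.
        """
        if np.isnan(self.ilm).any() or np.isnan(self.rpe).any():
            b, a = np.argwhere(np.isnan(self.ilm) | np.isnan(self.rpe))[0]
            raise ValueError(f"ILM/RPE must be defined everywhere; missing at A-scan {(b, a)}")
        bad = self.ilm > self.rpe
        vd = self.vitreous_defined
        with np.errstate(invalid="ignore"):
            bad |= vd & (self.vit_bottom > self.ilm)
            bad |= vd & (self.vit_bottom - self.vit_top < min_cortex)
            bad |= vd ^ ~np.isnan(self.vit_top)
        if bad.any():
            b, a = np.argwhere(bad)[0]
            raise ValueError(
                f"surface ordering violated at A-scan (bscan={b}, ascan={a}): "
                f"vit_top={self.vit_top[b, a]}, vit_bottom={self.vit_bottom[b, a]}, "
                f"ilm={self.ilm[b, a]}, rpe={self.rpe[b, a]}"
            )

    def copy(self) -> "SurfaceSet":
        return SurfaceSet(
            self.vit_top.copy(), self.vit_bottom.copy(), self.ilm.copy(), self.rpe.copy()
        )


@dataclass
class EyeRecord:
    """Per-eye clinical covariates joined with the imaging phenotype.

    BCVA is in ETDRS letters (0–100), CRT in µm, the ILM–vitreous distance in
    µm averaged over the A-scans where it is defined.
    """

    eye_id: str
    baseline_bcva: float
    bcva_change: float
    baseline_crt: float
    crt_change: float
    n_injections: int
    baseline_ilm_vit_distance: float = np.nan
    planted_class: Optional[str] = None
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_bcva <= 100.0):
            raise ValueError(f"baseline BCVA must be within [0, 100] letters; got {self.baseline_bcva}")
        if self.n_injections < 0:
            raise ValueError("injection count must be non-negative")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
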