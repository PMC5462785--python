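"""Rotation-invariant eigenfeatures from masked image moments.

Instead of hand-crafted features, convolution kernels are learned as the
principal components of small circular image patches. A degree of rotation
invariance is obtained by estimating the local orientation of each patch from
its second-order masked image moments and rotating the patch (equivalently,
the kernel) into a canonical frame before projection.

For a patch ``I`` with pixel coordinates ``x`` (column) and ``y`` (row):

* raw moment        ``M_pq   = sum_x sum_y x^p y^q I[x, y]``
* masked moment     ``M^_pq  = sum_x sum_y x^p y^q I[x, y] mask[x, y]``
* centroid          ``x_bar = M_10 / M_00``, ``y_bar = M_01 / M_00``
* central moment    ``mu_pq  = sum (x - x_bar)^p (y - y_bar)^q I[x, y]``
* normalized        ``mu'_pq = mu_pq / M_00``
* covariance        ``cov(I) = [[mu'_20, mu'_11], [mu'_11, mu'_02]]``
* orientation       ``phi(I) = atan2(2 mu'_11, mu'_20 - mu'_02) / 2``

The two-argument arctangent resolves the quadrant ambiguity of the printed
half-angle formula so that ``phi`` is the angle of the covariance matrix's
largest eigenvector (the patch's major axis) modulo pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.decomposition import PCA

__all__ = [
    "PATCH_SIZE",
    "N_EIGENFEATURES",
    "circular_mask",
    "ImagePatch",
    "MomentSet",
    "raw_moment",
    "compute_moments",
    "patch_orientation",
    "rotate_patch",
    "OrientationMap",
    "orientation_map",
    "FilterBank",
    "learn_filter_bank",
    "FeatureStack",
    "extract_features",
]

PATCH_SIZE = 21
N_EIGENFEATURES = 20

_DEGENERATE_TOL = 1e-12


def circular_mask(size: int = PATCH_SIZE) -> np.ndarray:
    """Binary disc inscribed in a ``size``-by-``size`` square (odd ``size``).

    The disc radius is ``size / 2`` so the mask touches the patch borders;
    it is symmetric under 90° rotations.
    """
    if size % 2 != 1:
        raise ValueError("patch size must be odd")
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= (size / 2.0) ** 2


@dataclass
class ImagePatch:
    """A square intensity patch with its circular support mask."""

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("patch must be square")
        if self.pixels.shape[0] % 2 != 1:
            raise ValueError("patch side must be odd")
        if self.mask is None:
            self.mask = circular_mask(self.pixels.shape[0])
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask must match patch shape")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _coords(size: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:size, 0:size]
    return xx.astype(np.float64), yy.astype(np.float64)


def raw_moment(patch: ImagePatch, p: int, q: int, masked: bool = True) -> float:
    """Raw (or masked) image moment ``M_pq`` by direct summation."""
    if p < 0 or q < 0:
        raise ValueError("moment orders must be non-negative")
    if masked and not patch.mask.any():
        raise ValueError("degenerate patch: empty mask")
    xx, yy = _coords(patch.size)
    w = patch.pixels * patch.mask if masked else patch.pixels
    return float(np.sum(xx**p * yy**q * w))


@dataclass
class MomentSet:
    """Masked moments, centroid, normalized central moments and orientation."""

    raw: dict
    centroid: tuple[float, float]
    central_normalized: tuple[float, float, float]  # mu'_20, mu'_11, mu'_02
    covariance: np.ndarray
    orientation: float
    degenerate: bool


def compute_moments(patch: ImagePatch, masked: bool = True) -> MomentSet:
    """All moment-derived quantities of one patch, by direct summation."""
    raw = {(p, q): raw_moment(patch, p, q, masked) for p in range(3) for q in range(3) if p + q <= 2}
    m00 = raw[(0, 0)]
    if m00 == 0:
        # no intensity mass: centroid undefined, orientation degenerate
        return MomentSet(raw, (0.0, 0.0), (0.0, 0.0, 0.0), np.zeros((2, 2)), 0.0, True)
    xbar, ybar = raw[(1, 0)] / m00, raw[(0, 1)] / m00
    xx, yy = _coords(patch.size)
    w = patch.pixels * patch.mask if masked else patch.pixels
    mu20 = float(np.sum((xx - xbar) ** 2 * w)) / m00
    mu11 = float(np.sum((xx - xbar) * (yy - ybar) * w)) / m00
    mu02 = float(np.sum((yy - ybar) ** 2 * w)) / m00
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    scale = max(abs(mu20) + abs(mu02), 1.0)
    degenerate = abs(mu20 - mu02) < _DEGENERATE_TOL * scale and abs(mu11) < _DEGENERATE_TOL * scale
    phi = 0.0 if degenerate else 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return MomentSet(raw, (xbar, ybar), (mu20, mu11, mu02), cov, phi, degenerate)


def patch_orientation(patch: ImagePatch, return_degenerate: bool = False):
    """Major-axis angle ``phi`` of a patch from its masked moments.

    Isotropic patches return 0 by convention (``degenerate`` flag set when
    requested). The angle lies in ``(-pi/2, pi/2]``, defined modulo pi.
    """
    ms = compute_moments(patch, masked=True)
    if return_degenerate:
        return ms.orientation, ms.degenerate
    return ms.orientation


def rotate_patch(pixels: np.ndarray, angle: float, order: int = 1) -> np.ndarray:
    """Rotate patch content by ``angle`` (radians) about the patch centre.

    The sign convention is chosen so that orientation is equivariant:
    ``phi(rotate(I, theta)) == phi(I) + theta (mod pi)``. Bilinear
    interpolation by default. Samples falling just outside the square (the
    disc mask slightly exceeds the inscribed square radius at the rim) are
    edge-extended rather than zero-filled, which keeps rim pixels meaningful
    after the mask is applied.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    size = pixels.shape[0]
    c = (size - 1) / 2.0
    cos, sin = np.cos(angle), np.sin(angle)
    # output (y, x) sampled from input at R(-angle) . (y - c, x - c) + c,
    # with the rotation acting on (x, y) = (col, row) coordinates
    mat = np.array([[cos, -sin], [sin, cos]])  # (row, col) order
    offset = np.array([c, c]) - mat @ np.array([c, c])
    return ndimage.affine_transform(
        pixels, mat, offset=offset, order=order, mode="nearest"
    )


# ---------------------------------------------------------------------------
# Orientation maps
# ---------------------------------------------------------------------------


@dataclass
class OrientationMap:
    """Per-pixel local orientation with a degeneracy mask."""

    angles: np.ndarray
    degenerate: np.ndarray


def _moment_kernels(size: int) -> dict[tuple[int, int], np.ndarray]:
    xx, yy = _coords(size)
    mask = circular_mask(size).astype(np.float64)
    return {
        (p, q): (xx**p) * (yy**q) * mask
        for p, q in [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
    }


def orientation_map(image: np.ndarray, size: int = PATCH_SIZE) -> OrientationMap:
    """Local orientation of every pixel's centred masked window.

    Equivalent to evaluating :func:`patch_orientation` on the ``size`` x
    ``size`` window around each pixel, with reflective padding at the image
    border, but computed with six correlations instead of a per-pixel loop.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < size:
        raise ValueError(f"image must be 2D and at least {size} x {size}")
    kern = _moment_kernels(size)
    mom = {
        pq: ndimage.correlate(image, k, mode="reflect") for pq, k in kern.items()
    }
    m00 = mom[(0, 0)]
    with np.errstate(divide="ignore", invalid="ignore"):
        xbar = np.where(m00 != 0, mom[(1, 0)] / m00, 0.0)
        ybar = np.where(m00 != 0, mom[(0, 1)] / m00, 0.0)
        mu20 = np.where(m00 != 0, mom[(2, 0)] / m00 - xbar**2, 0.0)
        mu11 = np.where(m00 != 0, mom[(1, 1)] / m00 - xbar * ybar, 0.0)
        mu02 = np.where(m00 != 0, mom[(0, 2)] / m00 - ybar**2, 0.0)
    scale = np.maximum(np.abs(mu20) + np.abs(mu02), 1.0)
    degenerate = (np.abs(mu20 - mu02) < _DEGENERATE_TOL * scale) & (
        np.abs(mu11) < _DEGENERATE_TOL * scale
    )
    degenerate |= m00 == 0
    angles = np.where(degenerate, 0.0, 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02))
    return OrientationMap(angles=angles, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------


@dataclass
class FilterBank:
    """Eigenvector convolution kernels learned from canonically-rotated patches.

    ``kernels`` has shape ``(n_kernels, size, size)``; kernels are zero
    outside the circular mask and mutually orthonormal within it.
    ``mean_patch`` is the training mean in the canonical frame (used to
    centre projections). ``explained_variance`` fractions are stored for
    diagnostics.
    """

    kernels: np.ndarray
    mask: np.ndarray
    mean_patch: np.ndarray
    explained_variance: np.ndarray
    n_patches: int
    seed: int

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    @property
    def size(self) -> int:
        return self.kernels.shape[1]

    def kernel_offsets(self) -> np.ndarray:
        """Per-kernel constant ``mean_patch . kernel`` subtracted from responses."""
        m = (self.mean_patch * self.mask).reshape(-1)
        return self.kernels.reshape(self.n_kernels, -1) @ m


def _sample_centers(
    images: Sequence[np.ndarray], n_patches: int, rng: np.random.Generator, margin: int
) -> list[tuple[int, int, int]]:
    """Sample (image, row, col) patch centres: 75% foreground, 25% background."""
    fg_pool, bg_pool = [], []
    for i, img in enumerate(images):
        h, w = img.shape
        interior = img[margin : h - margin, margin : w - margin]
        try:
            thr = threshold_otsu(np.asarray(interior))
        except ValueError:  # constant image
            thr = np.inf
        fg = np.argwhere(interior > thr)
        bg = np.argwhere(interior <= thr)
        for pool, idx in ((fg_pool, fg), (bg_pool, bg)):
            if len(idx):
                pool.append(
                    np.column_stack([np.full(len(idx), i), idx + margin])
                )
    fg_all = np.concatenate(fg_pool) if fg_pool else np.empty((0, 3), int)
    bg_all = np.concatenate(bg_pool) if bg_pool else np.empty((0, 3), int)
    n_fg = min(int(round(0.75 * n_patches)), len(fg_all))
    n_bg = min(n_patches - n_fg, len(bg_all))
    n_fg = min(n_patches - n_bg, len(fg_all))
    if n_fg + n_bg < n_patches:
        raise ValueError(
            f"not enough pixels to sample {n_patches} patches "
            f"(available: {len(fg_all) + len(bg_all)})"
        )
    picks = []
    for pool, n in ((fg_all, n_fg), (bg_all, n_bg)):
        if n:
            sel = rng.choice(len(pool), size=n, replace=False)
            picks.append(pool[sel])
    out = np.concatenate(picks)
    return [tuple(row) for row in out]


def learn_filter_bank(
    training_images: Sequence[np.ndarray],
    n_patches: int = 50_000,
    seed: int = 0,
    n_kernels: int = N_EIGENFEATURES,
    size: int = PATCH_SIZE,
) -> FilterBank:
    """Learn the eigenfeature kernels from 2D B-scans.

    Pipeline: sample windows (75% above-Otsu foreground, 25% background) →
    estimate each window's orientation from masked moments → rotate the
    window into the canonical frame → vectorize masked pixels → PCA → the
    top ``n_kernels`` eigenvectors reshaped to kernels. Deterministic for a
    fixed seed.
    """
    if n_patches < n_kernels:
        raise ValueError(f"need at least {n_kernels} patches for rank-{n_kernels} PCA")
    images = [np.asarray(im, dtype=np.float64) for im in training_images]
    for im in images:
        if im.ndim != 2 or min(im.shape) < size:
            raise ValueError(f"training images must be 2D and at least {size} x {size}")
    rng = np.random.default_rng(seed)
    margin = size // 2
    centers = _sample_centers(images, n_patches, rng, margin)
    mask = circular_mask(size)
    flat_idx = np.flatnonzero(mask.ravel())

    vecs = np.empty((len(centers), len(flat_idx)))
    for n, (i, r, c) in enumerate(centers):
        win = images[i][r - margin : r + margin + 1, c - margin : c + margin + 1]
        phi = patch_orientation(ImagePatch(win, mask))
        canon = rotate_patch(win, -phi)
        vecs[n] = canon.ravel()[flat_idx]

    pca = PCA(n_components=n_kernels, svd_solver="full")
    pca.fit(vecs)
    comps = pca.components_
    # deterministic sign: largest-magnitude coefficient of each kernel positive
    signs = np.sign(comps[np.arange(n_kernels), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]

    kernels = np.zeros((n_kernels, size, size))
    kernels.reshape(n_kernels, -1)[:, flat_idx] = comps
    mean_patch = np.zeros((size, size))
    mean_patch.reshape(-1)[flat_idx] = pca.mean_
    total_var = pca.explained_variance_.sum()
    evr = pca.explained_variance_ratio_ if total_var > 0 else np.zeros(n_kernels)
    return FilterBank(
        kernels=kernels,
        mask=mask,
        mean_patch=mean_patch,
        explained_variance=np.asarray(evr),
        n_patches=len(centers),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureStack:
    """Per-voxel feature vectors with named layout.

    ``values`` has shape ``(n_bscans, n_ascans, n_axial, n_features)``.
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("feature stack must be (bscan, ascan, axial, feature)")
        if self.values.shape[-1] != len(self.names):
            raise ValueError("feature names must match the last axis")

    @property
    def n_features(self) -> int:
        return self.values.shape[-1]

    def concat(self, other: "FeatureStack") -> "FeatureStack":
        return FeatureStack(
            np.concatenate([self.values, other.values], axis=-1),
            list(self.names) + list(other.names),
        )


def _reflect_pad_correlate(image: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Correlate ``image`` with a stack of kernels, reflective border handling.

    Equivalent to ``scipy.ndimage.correlate(image, k, mode='reflect')`` for
    each kernel, but batched through one FFT of the padded image.
    """
    n_k, ks, _ = kernels.shape
    m = ks // 2
    pad = np.pad(image, m, mode="symmetric")  # ndimage 'reflect' == np 'symmetric'
    ph, pw = pad.shape
    f_img = np.fft.rfft2(pad)
    # correlation = convolution with the flipped kernel
    f_ker = np.fft.rfft2(kernels[:, ::-1, ::-1], s=(ph, pw))
    out = np.fft.irfft2(f_img[None] * f_ker, s=(ph, pw))
    # full-kernel overlap region: output pixel (y, x) <- pad window starting at (y, x)
    return out[:, 2 * m : 2 * m + image.shape[0] - 0, 2 * m : 2 * m + image.shape[1]].copy()


def rotated_kernel_bank(bank: FilterBank, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Pre-rotated kernels for each orientation bin (cached on the bank).

    Returns ``(bin_centers, kernels)`` with kernels of shape
    ``(n_bins, n_kernels, size, size)``; each kernel is rotated by the bin
    centre angle and re-masked.
    """
    cache = getattr(bank, "_rotated_cache", None)
    if cache is not None and n_bins in cache:
        return cache[n_bins]
    edges = np.linspace(-np.pi / 2, np.pi / 2, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.empty((n_bins, bank.n_kernels, bank.size, bank.size))
    for b, theta in enumerate(centers):
        for j in range(bank.n_kernels):
            out[b, j] = rotate_patch(bank.kernels[j], theta) * bank.mask
    if cache is None:
        cache = {}
        object.__setattr__(bank, "_rotated_cache", cache)
    cache[n_bins] = (centers, out)
    return centers, out


def extract_features(
    volume, bank: FilterBank, n_orientation_bins: int = 24
) -> FeatureStack:
    """Eigenfeature responses for every voxel of a volume.

    Each B-scan is processed independently (2D features). At every pixel the
    kernels are rotated by the local orientation (quantized to
    ``n_orientation_bins`` over the half-circle) before application, so a
    feature responds to the same structure regardless of its orientation.
    Responses are centred by the training-mean projection.
    """
    from .types import OCTVolume  # local import to keep module deps one-way

    if isinstance(volume, OCTVolume):
        data = volume.data
    else:
        data = np.asarray(volume)
        if data.ndim != 3:
            raise ValueError("expected an OCTVolume or a 3D array")
    nb, na, nz = data.shape
    centers, rot_kernels = rotated_kernel_bank(bank, n_orientation_bins)
    flat_kernels = rot_kernels.reshape(-1, bank.size, bank.size)
    offsets = bank.kernel_offsets()

    # kernel FFTs are shared by all B-scans (same padded shape); single
    # precision is ample for classifier features
    from scipy import fft as sfft

    m = bank.size // 2
    ph, pw = sfft.next_fast_len(na + 2 * m), sfft.next_fast_len(nz + 2 * m)
    f_ker = sfft.rfft2(
        flat_kernels[:, ::-1, ::-1].astype(np.float32), s=(ph, pw)
    ).reshape(n_orientation_bins, bank.n_kernels, ph, -1)

    values = np.empty((nb, na, nz, bank.n_kernels), dtype=np.float32)
    for b in range(nb):
        image = data[b].astype(np.float64)
        omap = orientation_map(image, bank.size)
        bins = np.floor((omap.angles + np.pi / 2) / np.pi * n_orientation_bins).astype(int)
        bins = np.clip(bins, 0, n_orientation_bins - 1)
        pad = np.pad(image.astype(np.float32), m, mode="symmetric")
        f_img = sfft.rfft2(pad, s=(ph, pw))
        present = np.unique(bins)
        resp = sfft.irfft2(f_img[None, None] * f_ker[present], s=(ph, pw))[
            ..., 2 * m : 2 * m + na, 2 * m : 2 * m + nz
        ]
        lookup = np.zeros(n_orientation_bins, dtype=int)
        lookup[present] = np.arange(len(present))
        picked = np.take_along_axis(resp, lookup[bins][None, None, :, :], axis=0)[0]
        values[b] = np.moveaxis(picked, 0, -1) - offsets[None, None, :].astype(np.float32)
    names = [f"eig{j:02d}" for j in range(bank.n_kernels)]
    return FeatureStack(values=values, names=names)
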