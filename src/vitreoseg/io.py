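"""Readers and writers for volumes, surfaces, cohorts and trained models.

Volumes round-trip through multi-page TIFF (B-scans as pages, spacing in the
image description) or NIfTI (spacing in the header zooms); surfaces use a
per-A-scan tab-separated table with ``NA`` for out-of-range vitreous;
cohort records are plain CSV. Trained models carry a format version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import joblib
import numpy as np
import pandas as pd
import tifffile

from .features import FilterBank
from .types import EyeRecord, OCTVolume, SurfaceSet, SURFACE_NAMES

__all__ = [
    "FORMAT_VERSION",
    "write_volume",
    "read_volume",
    "write_surfaces",
    "read_surfaces",
    "write_cohort",
    "read_cohort",
    "save_filter_bank",
    "load_filter_bank",
    "save_cascade",
    "load_cascade",
]

FORMAT_VERSION = 1

PathLike = Union[str, Path]

_TIFF_EXT = (".tif", ".tiff")
_NIFTI_EXT = (".nii", ".nii.gz")


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_TIFF_EXT):
        return "tiff_stack"
    if name.endswith(_NIFTI_EXT):
        return "nifti"
    raise ValueError(f"unknown volume format for {path.name!r}; expected .tif/.tiff or .nii/.nii.gz")


def write_volume(path: PathLike, volume: OCTVolume) -> None:
    """Write a volume as multi-page TIFF or NIfTI with spacing metadata."""
    path = Path(path)
    fmt = _format_of(path)
    if fmt == "tiff_stack":
        desc = json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "axes": "bscan,ascan,axial",
                "spacing_um": list(volume.spacing),
            }
        )
        tifffile.imwrite(path, volume.data, description=desc, photometric="minisblack")
    else:
        import nibabel as nib

        axial, lateral, inter = volume.spacing
        # array axes (bscan, ascan, axial) -> zooms in the same order, µm
        affine = np.diag([inter, lateral, axial, 1.0])
        img = nib.Nifti1Image(volume.data, affine)
        img.header.set_zooms((inter, lateral, axial))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))


def read_volume(path: PathLike) -> OCTVolume:
    """Read a volume, normalizing axes to (bscan, ascan, axial).

    Raises if the file carries no voxel spacing — spacing is never assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path)
    if fmt == "tiff_stack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        try:
            meta = json.loads(desc)
            spacing = tuple(meta["spacing_um"])
        except (json.JSONDecodeError, KeyError, TypeError) as err:
            raise ValueError(
                f"{path.name}: no voxel spacing in TIFF description; "
                "write volumes with vitreoseg.io.write_volume"
            ) from err
        return OCTVolume(data, spacing)
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path.name}: invalid voxel spacing in NIfTI header")
    data = np.asanyarray(img.dataobj)
    inter, lateral, axial = (float(z) for z in zooms)
    return OCTVolume(data, (axial, lateral, inter))


def write_surfaces(path: PathLike, surfaces: SurfaceSet) -> None:
    """Tab-separated per-A-scan surface table; missing values as ``NA``."""
    nb, na = surfaces.grid_shape
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    df = pd.DataFrame({"bscan_index": bb.ravel(), "ascan_index": aa.ravel()})
    for name in SURFACE_NAMES:
        df[name] = getattr(surfaces, name).ravel()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_surfaces(path: PathLike) -> SurfaceSet:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = ["bscan_index", "ascan_index", *SURFACE_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"surface table missing columns: {missing}")
    nb = int(df["bscan_index"].max()) + 1
    na = int(df["ascan_index"].max()) + 1
    arrays = {}
    for name in SURFACE_NAMES:
        a = np.full((nb, na), np.nan)
        a[df["bscan_index"], df["ascan_index"]] = df[name]
        arrays[name] = a
    return SurfaceSet(**arrays)


def write_cohort(path: PathLike, records: Sequence[EyeRecord]) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def read_cohort(path: PathLike) -> list[EyeRecord]:
    df = pd.read_csv(path)
    fields = EyeRecord.field_names()
    records = []
    for _, row in df.iterrows():
        kwargs = {f: row[f] for f in fields if f in df.columns}
        if "planted_class" in kwargs and pd.isna(kwargs["planted_class"]):
            kwargs["planted_class"] = None
        if "cluster_id" in kwargs:
            kwargs["cluster_id"] = None if pd.isna(kwargs["cluster_id"]) else int(kwargs["cluster_id"])
        records.append(EyeRecord(**kwargs))
    return records


def save_filter_bank(path: PathLike, bank: FilterBank) -> None:
    """Single-archive serialization (kernels + mask + metadata)."""
    np.savez(
        path,
        kernels=bank.kernels,
        mask=bank.mask,
        mean_patch=bank.mean_patch,
        explained_variance=bank.explained_variance,
        meta=json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "n_patches": bank.n_patches,
                "seed": bank.seed,
            }
        ),
    )


def load_filter_bank(path: PathLike) -> FilterBank:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported filter bank format: {meta.get('format_version')}")
        return FilterBank(
            kernels=z["kernels"],
            mask=z["mask"].astype(bool),
            mean_patch=z["mean_patch"],
            explained_variance=z["explained_variance"],
            n_patches=int(meta["n_patches"]),
            seed=int(meta["seed"]),
        )


def save_cascade(path: PathLike, model) -> None:
    """Persist a trained auto-context cascade (joblib)."""
    joblib.dump({"format_version": FORMAT_VERSION, "model": model}, path)


def load_cascade(path: PathLike):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"missing model file {path}; train one with the 'train-model' stage first"
        )
    payload = joblib.load(path)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported cascade format: {payload.get('format_version')}")
    return payload["model"]
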