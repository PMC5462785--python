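"""En-face ILM–vitreous distance maps and unsupervised VMA phenotyping.

The axial gap between the ILM and the posterior vitreous boundary, evaluated
at every A-scan, gives a 2D en-face distance map per eye. Each eye is then
summarized by the histogram of its defined distances, and eyes are clustered
by plain k-means on these histogram features with the number of clusters
varied over 2–4. Clusters are relabelled so cluster 0 is the one with the
smallest mean distance — the non-VMA phenotype, which contains both fully
attached eyes (distance 0 everywhere) and complete posterior vitreous
detachment (boundary out of range, distance unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .types import EyeRecord, SurfaceSet

__all__ = [
    "DistanceMap",
    "distance_map",
    "BinSpec",
    "DistanceHistogram",
    "distance_histogram",
    "ClusterModel",
    "cluster_eyes",
    "characterize_clusters",
]


@dataclass
class DistanceMap:
    """Per-A-scan ILM–vitreous distance in µm; NaN where out of range."""

    values: np.ndarray
    axial_spacing_um: float

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    @property
    def mean_defined_um(self) -> float:
        """Mean distance over defined A-scans (NaN if none defined)."""
        defined = np.isfinite(self.values)
        return float(self.values[defined].mean()) if defined.any() else float("nan")


def distance_map(
    surfaces: SurfaceSet, axial_spacing_um: float, vitreous_surface: str = "vit_bottom"
) -> DistanceMap:
    """En-face distance between the ILM and the posterior vitreous boundary.

    Uses the interior cortex surface (``vit_bottom``) by default — the
    anatomical ILM–vitreous gap; ``vit_top`` can be selected instead. A-scans
    with the vitreous out of range get the NaN sentinel (distinct from an
    attached distance of 0). The ILM must be defined at every A-scan.
    """
    if vitreous_surface not in ("vit_bottom", "vit_top"):
        raise ValueError("vitreous_surface must be 'vit_bottom' or 'vit_top'")
    if np.isnan(surfaces.ilm).any():
        bad = np.argwhere(np.isnan(surfaces.ilm))[0]
        raise ValueError(f"ILM undefined at A-scan {tuple(bad)}; the retina must be segmentable")
    vit = getattr(surfaces, vitreous_surface)
    values = (surfaces.ilm - vit) * float(axial_spacing_um)
    return DistanceMap(values=values, axial_spacing_um=float(axial_spacing_um))


@dataclass(frozen=True)
class BinSpec:
    """Shared histogram binning for one clustering run.

    ``n_bins`` equal-width bins over ``[0, max_um)`` plus one overflow bin.
    ``missing_policy`` controls how out-of-range (complete PVD) A-scans enter
    the feature vector:

    ``"fold_into_first_bin"``
        missing A-scans are counted in the first bin, so "no measurable
        separation" reads the same whether the vitreous is attached or
        detached beyond the scan range (the non-VMA phenotype);
    ``"exclude_with_fraction"``
        missing A-scans are excluded from the histogram mass and the missing
        fraction is appended as an extra feature component.
    """

    n_bins: int = 30
    max_um: float = 300.0
    overflow: bool = True
    missing_policy: str = "fold_into_first_bin"

    def edges(self) -> np.ndarray:
        edges = np.linspace(0.0, self.max_um, self.n_bins + 1)
        if self.overflow:
            edges = np.append(edges, np.inf)
        return edges

    def feature_names(self) -> list[str]:
        names = [f"bin{i:02d}" for i in range(self.n_bins)]
        if self.overflow:
            names.append("overflow")
        if self.missing_policy == "exclude_with_fraction":
            names.append("missing_fraction")
        return names


@dataclass
class DistanceHistogram:
    """Per-eye distance histogram feature vector.

    ``frequencies`` are normalized counts over the shared bin edges; the
    missing fraction is recorded separately, and ``mean_distance_um`` (mean
    over defined A-scans, NaN if none) is carried along for cluster
    relabelling and summaries.
    """

    frequencies: np.ndarray
    bin_edges: np.ndarray
    missing_fraction: float
    mean_distance_um: float
    bin_spec: BinSpec

    def features(self) -> np.ndarray:
        if self.bin_spec.missing_policy == "exclude_with_fraction":
            return np.append(self.frequencies, self.missing_fraction)
        return self.frequencies


def distance_histogram(dmap: DistanceMap, bin_spec: BinSpec = BinSpec()) -> DistanceHistogram:
    """Histogram of the defined ILM–vitreous distances of one eye.

    With the default policy, missing A-scans contribute to the first bin and
    frequencies always sum to 1. Under ``exclude_with_fraction`` they are
    excluded from the binning; an eye with no defined A-scans then has an
    all-zero histogram, which is an error if the missing-fraction feature is
    disabled (the eye would be featureless).
    """
    if bin_spec.missing_policy not in ("fold_into_first_bin", "exclude_with_fraction"):
        raise ValueError(f"unknown missing_policy {bin_spec.missing_policy!r}")
    values = np.asarray(dmap.values, dtype=np.float64).ravel()
    defined = np.isfinite(values)
    missing_fraction = float(1.0 - defined.mean()) if values.size else 0.0
    edges = bin_spec.edges()
    counts = np.histogram(np.clip(values[defined], 0, None), bins=edges)[0].astype(np.float64)

    if bin_spec.missing_policy == "fold_into_first_bin":
        counts[0] += values.size - defined.sum()
        freq = counts / values.size if values.size else counts
    else:
        if not defined.any():
            freq = np.zeros_like(counts)
        else:
            freq = counts / defined.sum()
    if not np.any(freq) and bin_spec.missing_policy == "exclude_with_fraction" and missing_fraction < 1.0:
        raise ValueError("empty histogram: no defined A-scans")
    mean_um = float(values[defined].mean()) if defined.any() else float("nan")
    return DistanceHistogram(
        frequencies=freq,
        bin_edges=edges,
        missing_fraction=missing_fraction,
        mean_distance_um=mean_um,
        bin_spec=bin_spec,
    )


@dataclass
class ClusterModel:
    """k-means phenotype model over per-eye distance histograms.

    Cluster ids are canonicalized so cluster 0 has the smallest mean
    ILM–vitreous distance (the non-VMA convention); ``centres`` are the
    reordered k-means centres in feature space.
    """

    k: int
    centres: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    cluster_mean_distance_um: np.ndarray
    inertia: float
    seed: int

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def cluster_eyes(
    histograms: Sequence[DistanceHistogram],
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    allow_any_k: bool = False,
) -> ClusterModel:
    """Cluster eyes by k-means on their distance-histogram features.

    Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by
    within-cluster sum of squares; deterministic under ``seed``. ``k`` is
    restricted to 2–4 (the clinically interpreted range) unless
    ``allow_any_k``; ``k=1`` is permitted for testing (centre = mean).
    """
    if not allow_any_k and k not in (1, 2, 3, 4):
        raise ValueError("k must be in 2..4 (k=1 allowed for testing)")
    if len(histograms) < k:
        raise ValueError(f"need at least k={k} eyes; got {len(histograms)}")
    specs = {id(h.bin_spec): h.bin_spec for h in histograms}
    if len({(s.n_bins, s.max_um, s.overflow, s.missing_policy) for s in specs.values()}) > 1:
        raise ValueError("all histograms in one run must share the bin spec")
    X = np.stack([h.features() for h in histograms])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed), algorithm="lloyd")
    raw_labels = km.fit_predict(X)

    mean_dists = np.array(
        [np.nan_to_num(h.mean_distance_um, nan=0.0) for h in histograms]
    )
    cluster_means = np.array(
        [mean_dists[raw_labels == c].mean() if np.any(raw_labels == c) else np.inf for c in range(k)]
    )
    order = np.argsort(cluster_means, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw_labels]
    return ClusterModel(
        k=k,
        centres=km.cluster_centers_[order],
        labels=labels,
        feature_names=histograms[0].bin_spec.feature_names(),
        cluster_mean_distance_um=cluster_means[order],
        inertia=float(km.inertia_),
        seed=seed,
    )


def characterize_clusters(
    model: ClusterModel,
    records: Sequence[EyeRecord],
    covariates: Sequence[str] = (
        "baseline_bcva",
        "bcva_change",
        "baseline_crt",
        "crt_change",
        "baseline_ilm_vit_distance",
        "n_injections",
    ),
) -> pd.DataFrame:
    """Per-cluster covariate summary (n, mean, sample SD).

    Long-format table with one row per (cluster, covariate); missing
    covariate values are excluded pairwise and reported in ``n_missing``.
    """
    if len(records) != len(model.labels):
        raise ValueError("every clustered eye needs a record")
    df = pd.DataFrame([{c: getattr(r, c) for c in covariates} for r in records])
    df["cluster"] = model.labels
    rows = []
    for c in range(model.k):
        sub = df[df["cluster"] == c]
        for cov in covariates:
            vals = sub[cov].astype(float)
            ok = vals.notna()
            rows.append(
                {
                    "cluster": c,
                    "covariate": cov,
                    "n": int(ok.sum()),
                    "n_missing": int((~ok).sum()),
                    "mean": float(vals[ok].mean()) if ok.any() else np.nan,
                    "sd": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
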