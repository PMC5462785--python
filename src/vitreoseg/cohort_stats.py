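"""Outcome comparisons across vitreomacular interface clusters.

Two analyses mirror the clinical evaluation of VMA phenotypes under
anti-VEGF therapy: a one-way ANOVA comparing outcome means across clusters,
and an ordinary least squares regression of BCVA change on cluster
membership adjusted for baseline BCVA. The package also ships a simulation
of the attenuation mechanism: when cluster membership is confounded with
baseline BCVA and outcomes regress to the mean, an unadjusted between-
cluster difference can be significant while the baseline-adjusted cluster
effect is not.

p-values are two-sided with no multiplicity adjustment (the analyses are
exploratory); the model fit is reported as the multiple correlation R, not
R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.oneway import anova_oneway

from .types import EyeRecord

__all__ = [
    "AnovaResult",
    "anova_by_cluster",
    "RegressionResult",
    "regress_bcva_change",
    "AttenuationConfig",
    "AttenuationSummary",
    "attenuation_experiment",
]

RecordsLike = Union[pd.DataFrame, Sequence[EyeRecord]]


def _to_frame(records: RecordsLike) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA with per-group summaries."""

    F: float
    p: float
    df_between: int
    df_within: float
    groups: pd.DataFrame  # columns: cluster, n, mean, sd
    outcome: str
    welch: bool


def anova_by_cluster(
    records: RecordsLike,
    outcome: str,
    group_col: str = "cluster_id",
    welch: bool = False,
) -> AnovaResult:
    """Compare outcome means across clusters with one-way ANOVA.

    Pooled-variance (classic) by default; ``welch=True`` switches to the
    Welch unequal-variance form. Every group needs n >= 2 for a variance.
    """
    df = _to_frame(records)[[group_col, outcome]].dropna()
    groups = [g[outcome].to_numpy(float) for _, g in df.groupby(group_col, sort=True)]
    keys = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    for key, g in zip(keys, groups):
        if len(g) < 2:
            raise ValueError(f"group {key!r} has n={len(g)} < 2; variance undefined")
    res = anova_oneway(groups, use_var="unequal" if welch else "equal", welch_correction=welch)
    summary = pd.DataFrame(
        {
            "cluster": keys,
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "sd": [float(np.std(g, ddof=1)) for g in groups],
        }
    )
    return AnovaResult(
        F=float(res.statistic),
        p=float(res.pvalue),
        df_between=int(res.df_num),
        df_within=float(res.df_denom),
        groups=summary,
        outcome=outcome,
        welch=welch,
    )


@dataclass
class RegressionResult:
    """OLS fit of BCVA change on baseline BCVA and cluster membership."""

    coefficients: pd.Series
    R: float
    overall_p: float
    term_p: pd.Series
    cluster_joint_p: float
    degenerate: bool
    model: object


def regress_bcva_change(
    records: RecordsLike,
    cluster_coding: str = "binary_vma",
    outcome: str = "bcva_change",
    baseline: str = "baseline_bcva",
    group_col: str = "cluster_id",
) -> RegressionResult:
    """OLS of BCVA change on baseline BCVA plus cluster terms.

    ``binary_vma`` codes a single VMA-presence indicator (any cluster > 0 vs
    cluster 0); ``categorical_k`` codes one indicator per cluster with
    cluster 0 (non-VMA) as reference. Reports the multiple correlation R,
    the overall F-test p, per-term p-values, and a joint F-test p over all
    cluster terms.
    """
    df = _to_frame(records)
    cols = [outcome, baseline, group_col]
    if df[cols].isna().any().any():
        bad = [c for c in cols if df[c].isna().any()]
        raise ValueError(f"missing values in required columns: {bad}")
    y = df[outcome].to_numpy(float)
    X = pd.DataFrame({"const": 1.0, baseline: df[baseline].to_numpy(float)})
    clusters = df[group_col].to_numpy(int)
    if cluster_coding == "binary_vma":
        X["vma"] = (clusters > 0).astype(float)
        cluster_terms = ["vma"]
    elif cluster_coding == "categorical_k":
        cluster_terms = []
        for c in sorted(set(clusters) - {0}):
            X[f"cluster_{c}"] = (clusters == c).astype(float)
            cluster_terms.append(f"cluster_{c}")
    else:
        raise ValueError("cluster_coding must be 'binary_vma' or 'categorical_k'")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by rank-increment scan
        aliased, seen = [], []
        for col in X.columns:
            trial = X[seen + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(seen):
                aliased.append(col)
            else:
                seen.append(col)
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")

    fit = sm.OLS(y, X).fit()
    degenerate = float(np.var(y)) == 0.0
    R = 0.0 if degenerate else float(np.sqrt(max(fit.rsquared, 0.0)))
    joint = fit.f_test([f"{t} = 0" for t in cluster_terms])
    return RegressionResult(
        coefficients=fit.params,
        R=R,
        overall_p=float(fit.f_pvalue) if not degenerate else 1.0,
        term_p=fit.pvalues,
        cluster_joint_p=float(joint.pvalue),
        degenerate=degenerate,
        model=fit,
    )


# ---------------------------------------------------------------------------
# Attenuation mechanism
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttenuationConfig:
    """Generative model planting a cluster↔baseline confound.

    Half the eyes carry VMA. Baseline BCVA differs between VMA and non-VMA
    eyes by the shift that yields point-biserial correlation ``confound_r``;
    BCVA change depends on baseline through ``baseline_slope`` (regression
    to the mean: lower baselines gain more letters) plus an optional direct
    VMA effect. Units are ETDRS letters.
    """

    n: int = 200
    confound_r: float = -0.4
    baseline_mean: float = 58.0
    baseline_sd: float = 13.0
    baseline_slope: float = -0.4
    change_mean: float = 12.0
    change_sd: float = 11.0
    direct_effect: float = 0.0
    alpha: float = 0.05

    def baseline_shift(self) -> float:
        """VMA-vs-non-VMA baseline difference implied by ``confound_r``."""
        r = self.confound_r
        return 2.0 * r * self.baseline_sd / np.sqrt(1.0 - r**2)


def _simulate_records(config: AttenuationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    vma = np.zeros(n, dtype=int)
    vma[n // 2 :] = 1
    delta = config.baseline_shift()
    baseline = (
        config.baseline_mean
        + delta * (vma - 0.5)
        + rng.normal(0.0, config.baseline_sd, n)
    )
    change = (
        config.change_mean
        + config.baseline_slope * (baseline - config.baseline_mean)
        + config.direct_effect * vma
        + rng.normal(0.0, config.change_sd, n)
    )
    return pd.DataFrame(
        {"cluster_id": vma, "baseline_bcva": baseline, "bcva_change": change}
    )


@dataclass
class AttenuationSummary:
    """How often the unadjusted cluster effect survives adjustment."""

    n_reps: int
    frac_unadjusted_significant: float
    frac_adjusted_significant: float
    frac_attenuated: float  # unadjusted significant AND adjusted not
    config: AttenuationConfig


def attenuation_experiment(
    config: AttenuationConfig = AttenuationConfig(),
    n_reps: int = 500,
    seed: int = 0,
) -> AttenuationSummary:
    """Replicate the baseline-adjustment attenuation pattern by simulation.

    For each replicate, an unadjusted one-way ANOVA of BCVA change across
    clusters and a baseline-adjusted OLS are fitted; the attenuation
    frequency is the fraction of replicates where the unadjusted effect is
    significant while the adjusted cluster term is not. With zero
    confounding (and no direct effect) this frequency falls to about the
    nominal level. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    unadj = np.empty(n_reps, dtype=bool)
    adj = np.empty(n_reps, dtype=bool)
    for i in range(n_reps):
        df = _simulate_records(config, rng)
        a = anova_by_cluster(df, "bcva_change")
        r = regress_bcva_change(df, cluster_coding="binary_vma")
        unadj[i] = a.p < config.alpha
        adj[i] = r.term_p["vma"] < config.alpha
    return AttenuationSummary(
        n_reps=n_reps,
        frac_unadjusted_significant=float(unadj.mean()),
        frac_adjusted_significant=float(adj.mean()),
        frac_attenuated=float((unadj & ~adj).mean()),
        config=config,
    )
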