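"""Differential statistics: PCA with PC-covariate correlations, per-feature
Welch t-tests with Benjamini-Hochberg adjustment, volcano classification,
and hierarchically-clustered heatmap matrices."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .types import FeatureTable, ValidationError

log = logging.getLogger(__name__)

DEFAULT_P_CUT = 0.05
DEFAULT_FC_CUT = 1.2


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Welch t-test + fold change
# ---------------------------------------------------------------------------

def welch_bh(
    linear: np.ndarray, group_a: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t-test on log10 of a linear-scale matrix.

    Returns (log2fc of group A over B computed on linear-scale means, raw p,
    BH-adjusted q) for each feature (row).
    """
    group_a = np.asarray(group_a, dtype=bool)
    if group_a.sum() < 2 or (~group_a).sum() < 2:
        raise ValidationError("both groups need at least 2 samples")
    a_lin = linear[:, group_a]
    b_lin = linear[:, ~group_a]
    with np.errstate(divide="raise"):
        log_a = np.log10(a_lin)
        log_b = np.log10(b_lin)
    _, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    log2fc = np.log2(a_lin.mean(axis=1) / b_lin.mean(axis=1))
    return log2fc, p, bh_adjust(p)


def differential_test(
    table: FeatureTable,
    group_label: str = "outcome",
    groups: tuple[str, str] = ("preterm", "term"),
) -> pd.DataFrame:
    """Per-feature Welch t-test of ``groups[0]`` against ``groups[1]``.

    Tests run on log10 abundances; the fold change is the base-2 log of the
    ratio of linear-scale group means. Requires a complete matrix.
    """
    if table.abundance.isna().any().any():
        raise ValidationError("differential test requires a complete matrix")
    labels = table.samples[group_label]
    in_test = labels.isin(groups)
    sub = table.subset_samples(table.samples.index[in_test])
    group_a = (sub.samples[group_label] == groups[0]).to_numpy()
    log2fc, p, q = welch_bh(sub.abundance.to_numpy(dtype=float), group_a)
    return pd.DataFrame(
        {"feature_id": list(table.abundance.index), "log2fc": log2fc, "p": p, "q": q}
    ).set_index("feature_id")


def volcano_classify(
    results: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
) -> pd.DataFrame:
    """Add a volcano class: up (p < p_cut and log2fc > fc_cut), down
    (p < p_cut and log2fc < -fc_cut), else not_significant."""
    out = results.copy()
    up = (out["p"] < p_cut) & (out["log2fc"] > fc_cut)
    down = (out["p"] < p_cut) & (out["log2fc"] < -fc_cut)
    out["volcano_class"] = "not_significant"
    out.loc[up, "volcano_class"] = "up"
    out.loc[down, "volcano_class"] = "down"
    return out


# ---------------------------------------------------------------------------
# PCA with covariate correlations
# ---------------------------------------------------------------------------

@dataclass
class PcaSummary:
    scores: pd.DataFrame              # samples x PCs
    loadings: pd.DataFrame            # features x PCs
    variance_explained: np.ndarray
    covariate_correlations: pd.DataFrame  # rows: (pc, covariate) with r and p
    excluded_features: list


def _encode_covariate(values: pd.Series) -> Optional[np.ndarray]:
    """Numeric coding for correlation: numeric as-is, binary as 0/1,
    otherwise ordinal over sorted levels."""
    vals = values.dropna()
    if vals.empty:
        return None
    if pd.api.types.is_numeric_dtype(vals):
        coded = pd.to_numeric(values, errors="coerce")
    else:
        levels = sorted(vals.unique())
        mapping = {lev: i for i, lev in enumerate(levels)}
        coded = values.map(mapping)
    return coded.to_numpy(dtype=float)


def run_pca(
    table: FeatureTable,
    covariates: Sequence[str] = ("matrix", "batch", "outcome"),
    n_components: int = 3,
) -> PcaSummary:
    """PCA on feature-standardized log10 abundances plus Pearson correlation
    of PC scores 1..n against numerically-coded covariates. For multi-level
    categorical covariates (batch) a one-way ANOVA p-value is reported too.
    """
    if table.n_samples < 3:
        raise ValidationError("PCA requires at least 3 samples")
    if table.abundance.isna().any().any():
        raise ValidationError("PCA requires a complete matrix")
    x = table.log10_abundance().to_numpy()
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    excluded = list(table.abundance.index[constant])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} constant feature(s) from PCA")
        x = x[~constant]
        sd = sd[~constant]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    n_components = min(n_components, z.shape[0], table.n_samples - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.T)
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    rows = []
    for k, pc in enumerate(pc_names):
        for cov in covariates:
            if cov not in table.samples.columns:
                continue
            coded = _encode_covariate(table.samples[cov])
            if coded is None:
                continue
            mask = ~np.isnan(coded)
            if np.unique(coded[mask]).size < 2:
                continue
            r, p = stats.pearsonr(scores[mask, k], coded[mask])
            row = {"pc": pc, "covariate": cov, "r": r, "p": p}
            levels = np.unique(coded[mask])
            if levels.size > 2:
                groups = [scores[mask & (coded == lev), k] for lev in levels]
                _, anova_p = stats.f_oneway(*groups)
                row["anova_p"] = anova_p
            rows.append(row)
    return PcaSummary(
        scores=pd.DataFrame(scores, index=table.samples.index, columns=pc_names),
        loadings=pd.DataFrame(
            pca.components_.T,
            index=[f for f, c in zip(table.abundance.index, ~constant) if c],
            columns=pc_names,
        ),
        variance_explained=pca.explained_variance_ratio_,
        covariate_correlations=pd.DataFrame(rows),
        excluded_features=excluded,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering for heatmaps
# ---------------------------------------------------------------------------

@dataclass
class ClusterMatrices:
    matrix: pd.DataFrame              # standardized, reordered (features x samples)
    feature_linkage: np.ndarray
    sample_linkage: np.ndarray
    feature_order: list
    sample_order: list


def cluster_heatmap_matrix(table: FeatureTable) -> ClusterMatrices:
    """Average-linkage clustering: correlation distance over features,
    Euclidean distance over standardized sample profiles."""
    if table.n_features < 2 or table.n_samples < 2:
        raise ValidationError("clustering needs at least 2 features and 2 samples")
    if table.abundance.isna().any().any():
        raise ValidationError("clustering requires a complete matrix")
    x = table.log10_abundance().to_numpy()
    sd = x.std(axis=1, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    feat_dist = pdist(z, metric="correlation")
    feat_dist = np.clip(feat_dist, 0.0, None)  # guard fp noise for identical rows
    feature_linkage = hierarchy.linkage(feat_dist, method="average")
    sample_linkage = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")
    feature_order = hierarchy.leaves_list(feature_linkage).tolist()
    sample_order = hierarchy.leaves_list(sample_linkage).tolist()
    zdf = pd.DataFrame(z, index=table.abundance.index, columns=table.abundance.columns)
    reordered = zdf.iloc[feature_order, sample_order]
    return ClusterMatrices(
        matrix=reordered,
        feature_linkage=feature_linkage,
        sample_linkage=sample_linkage,
        feature_order=[table.abundance.index[i] for i in feature_order],
        sample_order=[table.abundance.columns[i] for i in sample_order],
    )
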