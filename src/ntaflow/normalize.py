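"""Creatinine normalization, below-MDL imputation, and parametric
empirical-Bayes batch correction (location/scale model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureTable, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# creatinine normalization
# ---------------------------------------------------------------------------

def creatinine_normalize(
    table: FeatureTable, strategy: str = "median-ratio"
) -> FeatureTable:
    """Scale urine abundances for dilution using urinary creatinine.

    ``median-ratio``: multiply each urine sample by
    (median cohort creatinine / sample creatinine), so a sample twice as
    concentrated as the median is halved. ``direct``: divide areas by the
    creatinine concentration. Serum samples are never touched.
    """
    if strategy not in ("median-ratio", "direct"):
        raise ValueError(f"unknown creatinine strategy {strategy!r}")
    samples = table.samples
    urine = samples.index[samples["matrix"] == "urine"]
    if len(urine) == 0:
        return table.copy()
    creat = pd.to_numeric(samples.loc[urine, "creatinine"], errors="coerce")
    if creat.isna().any() or (creat <= 0).any():
        bad = creat.index[creat.isna() | (creat <= 0)][0]
        raise ValidationError(f"urine sample {bad!r} lacks a positive creatinine value")
    out = table.copy()
    if strategy == "median-ratio":
        factors = float(creat.median()) / creat
    else:
        factors = 1.0 / creat
    out.abundance.loc[:, urine] = out.abundance.loc[:, urine] * factors
    return out


# ---------------------------------------------------------------------------
# below-MDL imputation
# ---------------------------------------------------------------------------

def impute_below_mdl(
    table: FeatureTable, seed: int, mdl: Optional[float] = None
) -> FeatureTable:
    """Fill missing (below-MDL) areas per feature from the observed data.

    For each feature, draws come from Normal(median, sd) of the observed
    log10 areas, truncated above at min(observed log minimum, log10 MDL), so
    every fill is guaranteed to sit below both the smallest measured value
    and the detection limit. Observed values are never modified; a fixed
    seed makes the fill deterministic.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    ab = out.abundance
    log_mdl = np.log10(mdl) if mdl is not None and mdl > 0 else np.inf
    for fid in ab.index:
        row = ab.loc[fid]
        missing = row.isna()
        if not missing.any():
            continue
        observed = np.log10(row[~missing].to_numpy(dtype=float))
        if len(observed) < 2:
            raise ValidationError(
                f"feature {fid!r} has {len(observed)} observed value(s); "
                "cannot estimate a fill distribution"
            )
        med = float(np.median(observed))
        sd = float(np.std(observed, ddof=1))
        upper = min(float(observed.min()), log_mdl)
        if sd <= 0:
            fills = np.full(int(missing.sum()), min(med, upper))
        else:
            b = (upper - med) / sd
            fills = stats.truncnorm.rvs(
                -np.inf, b, loc=med, scale=sd, size=int(missing.sum()), random_state=rng
            )
        ab.loc[fid, missing[missing].index] = np.power(10.0, fills)
    return out


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch correction
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted location/scale batch model on the log10 scale."""

    batch_levels: list
    grand_mean: np.ndarray            # per feature
    var_pooled: np.ndarray            # per feature
    gamma_hat: np.ndarray             # batches x features (standardized units)
    delta_hat: np.ndarray             # batches x features
    gamma_star: np.ndarray
    delta_star: np.ndarray
    gamma_bar: np.ndarray             # per batch prior means
    t2: np.ndarray                    # per batch prior variances
    a_prior: np.ndarray
    b_prior: np.ndarray
    n_iterations: list = field(default_factory=list)
    converged: bool = True

    def shift_estimates(self) -> dict:
        """Per-batch mean additive effect in log10 units (feature-averaged)."""
        scale = np.sqrt(self.var_pooled)
        return {
            int(level): float(np.mean(self.gamma_star[b] * scale))
            for b, level in enumerate(self.batch_levels)
        }

    def to_dict(self) -> dict:
        return {
            "batch_levels": [int(b) for b in self.batch_levels],
            "shift_estimates_log10": self.shift_estimates(),
            "gamma_bar": self.gamma_bar.tolist(),
            "t2": self.t2.tolist(),
            "a_prior": self.a_prior.tolist(),
            "b_prior": self.b_prior.tolist(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m ** 3) / s2


def _eb_solve(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Iterate the EB posterior updates for one batch until the largest
    absolute change falls below ``conv`` (cap ``max_iter``)."""
    n = z_batch.shape[1]
    gamma_old = gamma_hat.copy()
    delta_old = delta_hat.copy()
    for iteration in range(1, max_iter + 1):
        gamma_new = (t2 * n * gamma_hat + delta_old * gamma_bar) / (t2 * n + delta_old)
        sum2 = ((z_batch - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(gamma_new - gamma_old).max(), np.abs(delta_new - delta_old).max()
        )
        gamma_old, delta_old = gamma_new, delta_new
        if change < conv:
            return gamma_new, delta_new, iteration, True
    return gamma_old, delta_old, max_iter, False


def combat_correct(
    table: FeatureTable,
    batch_key: str = "batch",
    covariates: Sequence[str] = ("matrix", "outcome"),
    conv: float = 1e-4,
    max_iter: int = 100,
) -> tuple[FeatureTable, BatchModel]:
    """Parametric empirical-Bayes batch correction on log10 abundances.

    The model is the standard location/scale one: each feature is
    standardized against its batch-size-weighted grand mean and pooled
    variance while preserving the listed biological covariates; per-batch
    additive effects (normal prior) and variance effects (inverse-gamma
    prior) are estimated by method of moments across features and shrunk to
    their EB posteriors by fixed-point iteration; the adjusted data is then
    mapped back to the original location/scale and exponentiated.

    Requires a complete matrix (run after imputation). A single-batch table
    is returned unchanged.
    """
    if table.abundance.isna().any().any():
        raise ValidationError("batch correction requires a complete matrix; impute first")
    samples = table.samples
    batch = samples[batch_key]
    levels = sorted(batch.unique())
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValidationError(f"batch {bad!r} has fewer than 2 samples")

    x = table.log10_abundance().to_numpy()
    n_features, n_samples = x.shape

    if len(levels) == 1:
        model = BatchModel(
            batch_levels=levels,
            grand_mean=x.mean(axis=1),
            var_pooled=x.var(axis=1) + 1e-12,
            gamma_hat=np.zeros((1, n_features)),
            delta_hat=np.ones((1, n_features)),
            gamma_star=np.zeros((1, n_features)),
            delta_star=np.ones((1, n_features)),
            gamma_bar=np.zeros(1),
            t2=np.zeros(1),
            a_prior=np.zeros(1),
            b_prior=np.zeros(1),
        )
        return table.copy(), model

    batch_design = pd.get_dummies(
        pd.Categorical(batch, categories=levels), dtype=float
    ).to_numpy()
    design_parts = [batch_design]
    # biological covariates enter as one crossed factor so that group
    # structure (including interactions, e.g. an effect present in only one
    # matrix) survives standardization and variance scaling intact
    present = [c for c in covariates if c in samples.columns]
    if present:
        combined = samples[present].astype(str).agg("|".join, axis=1)
        if combined.nunique() > 1:
            dummies = pd.get_dummies(combined, drop_first=True, dtype=float)
            design_parts.append(dummies.to_numpy())
    design = np.hstack(design_parts)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError(
            "design matrix is rank-deficient (covariate confounded with batch?)"
        )

    n_batch = len(levels)
    batch_idx = [np.where((batch == level).to_numpy())[0] for level in levels]
    n_per_batch = np.array([len(idx) for idx in batch_idx], dtype=float)

    b_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)   # (p, features)
    grand_mean = (n_per_batch / n_samples) @ b_hat[:n_batch]
    fitted = (design @ b_hat).T
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    if np.any(var_pooled <= 0):
        warnings.warn("zero-variance feature(s); clipping pooled variance")
        var_pooled = np.clip(var_pooled, 1e-12, None)

    stand_mean = grand_mean[:, None] + (design[:, n_batch:] @ b_hat[n_batch:]).T
    scale = np.sqrt(var_pooled)[:, None]
    z = (x - stand_mean) / scale

    gamma_hat = np.vstack([z[:, idx].mean(axis=1) for idx in batch_idx])
    delta_hat = np.vstack([z[:, idx].var(axis=1, ddof=1) for idx in batch_idx])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1)
    a_prior = np.array([_aprior(delta_hat[b]) for b in range(n_batch)])
    b_prior = np.array([_bprior(delta_hat[b]) for b in range(n_batch)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    iterations: list[int] = []
    all_converged = True
    for b in range(n_batch):
        g, d, n_iter, ok = _eb_solve(
            z[:, batch_idx[b]], gamma_hat[b], delta_hat[b],
            gamma_bar[b], t2[b], a_prior[b], b_prior[b], conv, max_iter,
        )
        gamma_star[b], delta_star[b] = g, d
        iterations.append(n_iter)
        all_converged &= ok
    if not all_converged:
        warnings.warn(
            f"EB iteration did not converge within {max_iter} iterations "
            f"(per-batch iterations: {iterations}); returning last iterate"
        )

    z_adj = z.copy()
    for b, idx in enumerate(batch_idx):
        z_adj[:, idx] = (z[:, idx] - gamma_star[b][:, None]) / np.sqrt(
            delta_star[b]
        )[:, None]
    x_adj = z_adj * scale + stand_mean

    out = table.copy()
    out.abundance = pd.DataFrame(
        np.power(10.0, x_adj),
        index=table.abundance.index,
        columns=table.abundance.columns,
    )
    model = BatchModel(
        batch_levels=levels,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        t2=t2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iterations=iterations,
        converged=all_converged,
    )
    return out, model
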