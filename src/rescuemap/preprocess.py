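"""Count filtering, median-of-ratios normalization and batch adjustment.

The preprocessing contract mirrors standard bulk RNA-seq practice for a
replicated knockdown/rescue design: genes averaging under one count per
sample are dropped, per-sample size factors come from the median-of-ratios
estimator, and replicate batches are harmonized with a parametric
empirical-Bayes location/scale adjustment on log2 normalized expression
while preserving the condition effects encoded in a design matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "filter_low_counts",
    "estimate_size_factors",
    "normalized_log2",
    "condition_design",
    "combat_adjust",
    "adjusted_pseudocounts",
]

log = logging.getLogger(__name__)


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")


def filter_low_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes averaging fewer than one count per sample.

    A gene is retained when its total across samples is at least the number
    of samples (mean count per sample >= 1); the exactly-one-per-sample gene
    sits on the retained side of the boundary.  Gene order is preserved.
    """
    _check_counts(counts)
    if counts.empty:
        log.warning("empty count matrix passed to filter_low_counts")
        return counts.copy()
    keep = counts.sum(axis=1) >= counts.shape[1]
    return counts.loc[keep].copy()


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    For each sample, the factor is the median over reference genes of
    ``count / geometric-mean-across-samples``; genes with any zero count
    (zero geometric mean) are excluded from the reference set.
    """
    _check_counts(counts)
    vals = counts.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; relax the reference "
            "set (e.g. drop sparse samples) before estimating size factors"
        )
    ref = vals[positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log2(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the scale batch adjustment operates on."""
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


def condition_design(samples: pd.DataFrame, drop_first: bool = True) -> pd.DataFrame:
    """One-hot condition covariates (reference level dropped), sample-indexed."""
    d = pd.get_dummies(samples.set_index("sample")["condition"], dtype=float)
    d = d[sorted(d.columns)]
    if drop_first and d.shape[1] > 1:
        d = d.iloc[:, 1:]
    return d


def _check_confounding(samples: pd.DataFrame) -> None:
    ct = pd.crosstab(samples["condition"], samples["batch"])
    for cond in ct.index:
        present = ct.loc[cond] > 0
        if present.sum() == 1:
            batch = present.idxmax()
            others = ct.loc[ct.index != cond, batch]
            if (others == 0).all():
                raise ValueError(
                    f"batch {batch!r} is perfectly confounded with condition "
                    f"{cond!r}; the batch effect is not identifiable"
                )


def combat_adjust(logexpr: pd.DataFrame, samples: pd.DataFrame,
                  design: pd.DataFrame | None = None,
                  tol: float = 1e-6, max_iter: int = 100) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment of a gene x sample matrix.

    Per gene, expression is standardized against a pooled model holding
    batch means and the condition covariates in ``design``; batch location
    parameters get a normal prior and batch scale parameters an
    inverse-gamma prior, both with moment-matched hyperparameters, solved by
    fixed-point iteration of the conditional posterior means.  The adjusted
    matrix has batch effects removed (up to EB shrinkage) with the design's
    condition effects re-added.

    With a single batch the input is returned unchanged.
    """
    samples = samples.set_index("sample").loc[logexpr.columns].reset_index()
    batches = samples["batch"].astype(str)
    batch_levels = list(dict.fromkeys(batches))
    if len(batch_levels) < 2:
        return logexpr.copy()
    sizes = batches.value_counts()
    if (sizes < 2).any():
        raise ValueError("every batch needs at least 2 samples for adjustment")
    _check_confounding(samples)

    Y = logexpr.to_numpy(dtype=float)
    G, N = Y.shape
    B = np.stack([(batches == b).to_numpy(float) for b in batch_levels], axis=1)
    if design is not None and design.shape[1]:
        C = design.loc[logexpr.columns].to_numpy(dtype=float)
        X = np.hstack([B, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design covariates are confounded with batch")
    else:
        C = np.zeros((N, 0))
        X = B

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    nb = len(batch_levels)
    n_i = B.sum(axis=0)
    grand = (n_i / N) @ beta[:nb]                      # weighted grand mean per gene
    stand_mean = grand[:, None] + (C @ beta[nb:]).T    # gene x sample
    resid = Y - (X @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    sd = np.sqrt(np.maximum(var_pooled, 1e-16))

    Z = (Y - stand_mean) / sd[:, None]
    out = np.empty_like(Z)
    for bi, b in enumerate(batch_levels):
        cols = (batches == b).to_numpy()
        n = int(cols.sum())
        Zb = Z[:, cols]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)

        if t2 <= 1e-12 or not np.isfinite(t2):
            gamma_star = gamma_hat.copy()
        else:
            gamma_star = gamma_hat.copy()
        if s2 <= 1e-12 or not np.isfinite(s2):
            delta_star = np.maximum(delta_hat, 1e-8)
            if t2 > 1e-12:
                gamma_star = (n * t2 * gamma_hat + delta_star * gamma_bar) / (n * t2 + delta_star)
        else:
            a_prior = (2.0 * s2 + m ** 2) / s2
            b_prior = (m * s2 + m ** 3) / s2
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                if t2 > 1e-12:
                    gamma_new = (n * t2 * gamma_hat + delta_star * gamma_bar) / (n * t2 + delta_star)
                else:
                    gamma_new = gamma_hat
                sum2 = ((Zb - gamma_new[:, None]) ** 2).sum(axis=1)
                delta_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
                change = max(np.abs(gamma_new - gamma_star).max(),
                             np.abs(delta_new - delta_star).max())
                gamma_star, delta_star = gamma_new, delta_new
                if change < tol:
                    break
            delta_star = np.maximum(delta_star, 1e-8)

        out[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    adjusted = out * sd[:, None] + stand_mean
    return pd.DataFrame(adjusted, index=logexpr.index, columns=logexpr.columns)


def adjusted_pseudocounts(adjusted_log2: pd.DataFrame) -> pd.DataFrame:
    """Back-transform adjusted log2 expression to integer pseudo-counts.

    The count-model DE stage consumes ``round(max(2**x - 1, 0))``; the
    un-rounded adjusted matrix remains available for clustering and PCA.
    """
    vals = np.rint(np.clip(np.exp2(adjusted_log2.to_numpy()) - 1.0, 0.0, None))
    return pd.DataFrame(vals.astype(np.int64), index=adjusted_log2.index,
                        columns=adjusted_log2.columns)
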