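"""Negative-binomial Wald differential expression with BH correction.

Each contrast (a test condition against the ``iEF`` knockdown reference, or
``iLuc`` against ``iEF`` for the endogenous profile) is fit per gene as an
NB generalized linear model with log link, size factors as multiplicative
offsets and a single condition indicator.  Fold changes are reported
unshrunk; the Wald statistic uses the observed information at the fitted
coefficients and a two-sided normal tail; BH adjustment is applied per
contrast across all testable genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import estimate_size_factors

__all__ = [
    "Contrast",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "differential_expression",
]

LN2 = float(np.log(2.0))
ALPHA_FLOOR = 1e-8
#: bound on |log2 fold change|; keeps one-group-all-zero genes finite without
#: biasing estimable effects
LFC_BOUND = 10.0


@dataclass
class Contrast:
    test: str
    reference: str = "iEF"


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series,
                        conditions: pd.Series | None = None,
                        n_bins: int = 20,
                        max_raw_weight: float = 0.7) -> tuple[pd.Series, pd.Series]:
    """Moderated method-of-moments NB dispersions, one per gene.

    The gene-wise (raw) estimate equates the pooled within-condition
    variance of normalized counts with its expectation
    ``mu * mean(1/s_j) + alpha * mu**2``.  With few residual degrees of
    freedom these estimates are far too noisy to plug into a Wald test, so
    each is moderated toward the mean dispersion of genes with similar
    expression (``n_bins`` quantile bins) by a per-gene empirical-Bayes
    weight: the chi-square sampling variance of the raw estimate against the
    estimated biological spread of dispersions around the trend.  The raw
    estimate never receives more than ``max_raw_weight`` of the weight, so
    at least 30% of every gene's value comes from the trend by default.

    Because the moderated value still carries sampling uncertainty that a
    plug-in Wald statistic would ignore, the estimator also reports a
    per-gene effective degrees of freedom ``nu = 2 / Var(log se^2)`` derived
    from the posterior variance of the dispersion; the Wald test uses it as
    the tail reference (a noisy variance makes the statistic a normal scale
    mixture, i.e. t-like).

    Returns
    -------
    alphas : Series, floored at 1e-8
    flagged : boolean Series, True for genes with no information (all zero)
    nu : Series, effective degrees of freedom for the Wald tail
    """
    q = counts.div(size_factors, axis=1).to_numpy(dtype=float)
    G, N = q.shape
    if N < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    if conditions is None:
        groups = [np.arange(N)]
    else:
        cond = conditions.to_numpy()
        groups = [np.flatnonzero(cond == c) for c in pd.unique(cond)]
    df_resid = N - len(groups)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for dispersion")

    m = q.mean(axis=1)
    ss = np.zeros(G)
    for idx in groups:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = ss / df_resid
    shot = m * float((1.0 / size_factors.to_numpy()).mean())  # Poisson + scaling term
    m2 = np.where(m > 0, m, np.nan) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - shot) / m2
    flagged = pd.Series(~(m > 0), index=counts.index, name="no_information")

    # trend: per-bin means of the raw estimate (clipped below at zero; the
    # raw statistic is unbiased, so the clipped mean errs slightly high,
    # which protects the Wald tail rather than inflating it)
    order = np.argsort(m, kind="stable")
    expressed = order[m[order] > 0]
    bins = np.array_split(expressed, min(n_bins, max(len(expressed), 1)))
    trend = np.full(G, np.nan)
    for idx in bins:
        if len(idx):
            trend[idx] = max(float(np.nanmean(np.clip(raw[idx], 0.0, None))), ALPHA_FLOOR)
    trend = np.where(np.isnan(trend), ALPHA_FLOOR, trend)

    # per-gene sampling variance of the raw estimate from chi-square theory,
    # evaluated at the trend: Var(raw) ~= (2/df) * (shot/m^2 + alpha)^2
    with np.errstate(invalid="ignore"):
        s2 = (2.0 / df_resid) * (shot / m2 + trend) ** 2
    s2 = np.where(np.isfinite(s2), s2, np.inf)

    # biological spread around the trend, as a multiple c of the trend level.
    # When the design has too few residual df for the moment estimate to see
    # any spread, fall back to a conservative default (dispersion sd = half
    # the trend, a typical bulk RNA-seq fold-spread); underestimating this
    # spread is what inflates Wald tails, so the default is a floor.
    resid2 = (raw - trend) ** 2
    ok = np.isfinite(resid2) & np.isfinite(s2) & (trend > ALPHA_FLOOR)
    c2 = 0.25
    if ok.sum() >= 10:
        excess = resid2[ok] - s2[ok]
        hi = np.quantile(excess, 0.995)
        est = float(np.mean(np.clip(excess, None, hi))) / float(np.mean(trend[ok] ** 2))
        c2 = float(np.clip(est, 0.25, 9.0))
    tau2 = c2 * trend ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.clip(tau2 / (tau2 + s2), 0.0, max_raw_weight)
    w = np.where(np.isfinite(w), w, 0.0)
    raw_filled = np.where(np.isfinite(raw), raw, trend)
    alphas = w * raw_filled + (1.0 - w) * trend
    alphas = np.maximum(np.where(m > 0, alphas, ALPHA_FLOOR), ALPHA_FLOOR)

    # effective df: Var(log se^2) ~= postvar / (shot/m^2 + alpha)^2 since the
    # per-gene Wald variance scales with (1/mu + alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        postvar = w * s2  # normal-normal posterior variance tau2*s2/(tau2+s2)
        var_log_se2 = postvar / (shot / m2 + alphas) ** 2
        nu = 2.0 / var_log_se2
    nu = np.clip(np.where(np.isfinite(nu), nu, 1e6), 3.0, 1e6)
    return (pd.Series(alphas, index=counts.index, name="alpha"), flagged,
            pd.Series(nu, index=counts.index, name="nu"))


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * (np.log(np.maximum(y, 1e-300)) - np.log(mu)), 0.0)
        r = 1.0 / np.maximum(alpha, 1e-12)
        t2 = (y + r) * (np.log1p(alpha * mu) - np.log1p(alpha * y))
    return 2.0 * (t1 + t2).sum(axis=1)


def wald_test(counts: pd.DataFrame, samples: pd.DataFrame, contrast: Contrast,
              size_factors: pd.Series, alphas: pd.Series,
              nu: pd.Series | None = None,
              max_iter: int = 50, tol: float = 1e-8) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast.test`` over ``contrast.reference``.

    IRLS on the two-coefficient log-link GLM (intercept + condition
    indicator) with ``log(size factor)`` offsets, run vectorized across
    genes; convergence is declared on the NB deviance.  The two-sided tail
    is normal by default, or a per-gene t reference when ``nu`` (effective
    degrees of freedom from dispersion-estimation uncertainty) is given.
    Genes with zero counts in both groups are untestable (``p`` = NA); genes
    that fail to converge are flagged.

    Returns a table with gene, baseMean, log2fc (test over reference), se,
    p and a status column; no multiplicity adjustment (see ``bh_adjust``).
    """
    meta = samples.set_index("sample")
    for cond in (contrast.test, contrast.reference):
        n = int((meta["condition"] == cond).sum())
        if n < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 samples, found {n}")
    cols = meta.index[meta["condition"].isin([contrast.test, contrast.reference])]
    cols = [c for c in counts.columns if c in set(cols)]
    y = counts[cols].to_numpy(dtype=float)
    x = (meta.loc[cols, "condition"] == contrast.test).to_numpy(dtype=float)
    sf = size_factors.loc[cols].to_numpy(dtype=float)
    offset = np.log(sf)
    alpha = alphas.loc[counts.index].to_numpy(dtype=float)[:, None]

    G, N = y.shape
    n_test, n_ref = x.sum(), N - x.sum()
    q = y / sf
    mean_ref = (q * (1 - x)).sum(axis=1) / n_ref
    mean_test = (q * x).sum(axis=1) / n_test
    untestable = (mean_ref == 0) & (mean_test == 0)

    bmax = LFC_BOUND * LN2
    beta0 = np.log(np.maximum(mean_ref, 1e-8))
    beta1 = np.clip(np.log(np.maximum(mean_test, 1e-8)) - beta0, -bmax, bmax)

    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    Sw = Swx = det = np.ones(G)
    for _ in range(max_iter):
        eta = np.clip(beta0[:, None] + beta1[:, None] * x + offset, -40.0, 40.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Sw = W.sum(axis=1)
        Swx = (W * x).sum(axis=1)        # x binary: also equals sum W x^2
        Swz = (W * z).sum(axis=1)
        Swxz = (W * x * z).sum(axis=1)
        det = Sw * Swx - Swx ** 2
        ok = det > 1e-12
        new0 = np.where(ok, (Swx * Swz - Swx * Swxz) / np.where(ok, det, 1.0), beta0)
        new1 = np.where(ok, (Sw * Swxz - Swx * Swz) / np.where(ok, det, 1.0), beta1)
        beta0 = np.clip(new0, -40.0, 40.0)
        beta1 = np.clip(new1, -bmax, bmax)
        eta = np.clip(beta0[:, None] + beta1[:, None] * x + offset, -40.0, 40.0)
        new_dev = _nb_deviance(y, np.exp(eta), alpha[:, 0][:, None])
        converged = np.abs(new_dev - dev) <= tol * (np.abs(new_dev) + 0.1)
        dev = new_dev
        if converged.all():
            break

    mu = np.exp(np.clip(beta0[:, None] + beta1[:, None] * x + offset, -40.0, 40.0))
    W = mu / (1.0 + alpha * mu)
    Sw = W.sum(axis=1)
    Swx = (W * x).sum(axis=1)
    det = Sw * Swx - Swx ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_beta1 = np.sqrt(np.where(det > 0, Sw / np.where(det > 0, det, 1.0), np.nan))
        zstat = beta1 / se_beta1
    if nu is None:
        p = 2.0 * stats.norm.sf(np.abs(zstat))
    else:
        dof = nu.loc[counts.index].to_numpy(dtype=float)
        p = 2.0 * stats.t.sf(np.abs(zstat), dof)

    status = np.full(G, "ok", dtype=object)
    status[~converged] = "nonconvergent"
    status[untestable] = "untestable"
    bad = untestable | ~converged
    p = np.where(bad, np.nan, p)

    base_mean = q.mean(axis=1)
    return pd.DataFrame(
        {
            "gene": counts.index.to_numpy(),
            "baseMean": base_mean,
            "log2fc": beta1 / LN2,
            "se": se_beta1 / LN2,
            "p": p,
            "status": status,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NA entries are preserved and excluded from the number of tests; output
    is capped at 1 and monotone in the rank of the raw p-value.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[valid] = res
    return out


def differential_expression(counts: pd.DataFrame, samples: pd.DataFrame,
                            contrast: Contrast,
                            size_factors: pd.Series | None = None,
                            alphas: pd.Series | None = None,
                            nu: pd.Series | None = None) -> pd.DataFrame:
    """Full single-contrast DE: normalization, dispersion, Wald, BH.

    Size factors default to median-of-ratios on the supplied matrix and
    dispersions to the moderated method-of-moments estimate pooled over all
    conditions present (each condition contributing within-group residuals),
    as is standard when one experiment supports several contrasts.  ``padj``
    is BH across all testable genes of this contrast.  Deterministic for
    fixed input.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if alphas is None:
        meta = samples.set_index("sample")
        cols = [c for c in counts.columns if c in meta.index]
        alphas, _, nu = estimate_dispersion(
            counts[cols], size_factors.loc[cols],
            conditions=meta.loc[cols, "condition"],
        )
    table = wald_test(counts, samples, contrast, size_factors, alphas, nu=nu)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    return table
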