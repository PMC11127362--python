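"""Differential abundance of genes and gene clusters from count matrices.

Counts are modelled as negative binomial (NB2): Var(K) = mu + alpha*mu^2.
Samples are first normalized with median-of-ratios size factors, then a
two-group NB generalized linear model with log link is fitted per gene
and the responder-vs-non-responder contrast is tested with a Wald
statistic.  Dispersion is estimated per gene by method of moments on
normalized counts (no empirical-Bayes shrinkage); multiple testing is
controlled with Benjamini-Hochberg q-values across the tested genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample column.

    For each gene with all-positive counts, compute count/geometric-mean;
    the size factor of a sample is the median of those ratios.  Falls
    back (with a warning) to genes positive in that sample when no row
    is positive everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise ValueError("empty count matrix")
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    all_pos = np.all(mat > 0, axis=1)
    if all_pos.any():
        loggeo = logmat[all_pos].mean(axis=1)
        ratios = logmat[all_pos] - loggeo[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene has positive counts in every sample; "
            "using positive-subset ratios",
            stacklevel=2,
        )
        # per-gene geometric mean over positive entries only
        pos = mat > 0
        loggeo = np.where(
            pos.any(axis=1), np.nanmean(np.where(pos, logmat, np.nan), axis=1), np.nan
        )
        ratios = logmat - loggeo[:, None]
        sf = np.exp(np.nanmedian(np.where(pos, ratios, np.nan), axis=0))
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("could not compute positive size factors for all samples")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _fit_group_mean(k: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fisher scoring for per-gene NB group means with sample offsets.

    k: genes x samples counts of one group; s: per-sample size factors;
    alpha: per-gene dispersion.  Returns per-gene mean on the normalized
    scale (mu such that E[k_ij] = s_j * mu_i).
    """
    y = k / s[None, :]
    mu = np.maximum(y.mean(axis=1), 1e-8)
    theta = np.log(mu)
    for _ in range(50):
        mu = np.exp(theta)
        m = s[None, :] * mu[:, None]
        denom = 1.0 + alpha[:, None] * m
        score = ((k - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(theta)


def _mom_dispersion(
    k: np.ndarray, s: np.ndarray, group_masks: list[np.ndarray]
) -> np.ndarray:
    """Pooled method-of-moments NB dispersion on normalized counts.

    With y = k/s, Var(y_ij) = mu_i/s_j + alpha_i*mu_i^2.  Pools the
    within-group residual sums of squares over both groups, subtracts
    the expected Poisson (shot-noise) component and solves for alpha.
    """
    y = k / s[None, :]
    num = np.zeros(k.shape[0])
    den = np.zeros(k.shape[0])
    for mask in group_masks:
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        y_g = y[:, mask]
        mu_g = y_g.mean(axis=1)
        rss = ((y_g - mu_g[:, None]) ** 2).sum(axis=1)
        inv_s = (1.0 / s[mask]).mean()
        num += rss - (n_g - 1) * mu_g * inv_s
        den += (n_g - 1) * mu_g**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: pd.DataFrame,
    labels,
    sf: pd.Series | None = None,
    *,
    min_mean: float = 1.0,
    positive_label: str = "R",
) -> pd.DataFrame:
    """Per-gene NB Wald test of responder vs non-responder abundance.

    Parameters
    ----------
    counts : genes x samples integer counts.
    labels : per-sample group labels aligned with the columns;
        ``positive_label`` marks the numerator group of the fold change.
    sf : optional precomputed size factors (median of ratios otherwise).
    min_mean : independent filter; genes whose mean normalized count is
        below this are excluded from testing and flagged ``low_count``.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``wald_z``, ``p``, ``q``, ``mean_normalized_count``, ``dispersion``,
    ``status`` (ok / low_count / all_zero).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != counts.shape[1]:
        raise ValueError("labels must align with count-matrix columns")
    pos = labels == positive_label
    neg = ~pos
    if pos.sum() < 3 or neg.sum() < 3:
        raise ValueError("need >= 3 samples per group for the NB Wald test")
    if sf is None:
        sf = size_factors(counts)
    s = sf.to_numpy(dtype=float)
    k = counts.to_numpy(dtype=float)
    base_mean = (k / s[None, :]).mean(axis=1)

    out = pd.DataFrame(
        {
            "log2fc": np.nan,
            "wald_z": np.nan,
            "p": np.nan,
            "q": np.nan,
            "mean_normalized_count": base_mean,
            "dispersion": np.nan,
            "status": "ok",
        },
        index=counts.index,
    )
    all_zero = k.sum(axis=1) == 0
    low = (base_mean < min_mean) & ~all_zero
    out.loc[all_zero, "status"] = "all_zero"
    out.loc[low, "status"] = "low_count"
    test = ~(all_zero | low)
    if not test.any():
        return out

    kt = k[test]
    alpha = _mom_dispersion(kt, s, [pos, neg])
    mu1 = _fit_group_mean(kt[:, pos], s[pos], alpha)
    mu0 = _fit_group_mean(kt[:, neg], s[neg], alpha)
    # Fisher information of each group's log-mean at the fitted values
    info1 = (s[pos][None, :] * mu1[:, None] / (1 + alpha[:, None] * s[pos][None, :] * mu1[:, None])).sum(axis=1)
    info0 = (s[neg][None, :] * mu0[:, None] / (1 + alpha[:, None] * s[neg][None, :] * mu0[:, None])).sum(axis=1)
    beta = np.log(mu1) - np.log(mu0)
    se = np.sqrt(1.0 / info1 + 1.0 / info0)
    z = beta / se
    # t reference with n - 2 df absorbs the cost of estimating two group
    # means from few samples; converges to the normal Wald for large n
    df = pos.sum() + neg.sum() - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)
    q = multipletests(p, method="fdr_bh")[1]

    out.loc[test, "log2fc"] = beta / np.log(2.0)
    out.loc[test, "wald_z"] = z
    out.loc[test, "p"] = p
    out.loc[test, "q"] = q
    out.loc[test, "dispersion"] = alpha
    return out


def chisq_gof(observed, expected_proportions=None) -> dict:
    """Chi-square goodness of fit of category counts to expected proportions."""
    obs = np.asarray(observed, dtype=float)
    if expected_proportions is None:
        exp = np.full(obs.shape, obs.sum() / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        exp = props / props.sum() * obs.sum()
    if np.any(exp < 1):
        raise ValueError("expected counts must be >= 1")
    chi2, p = stats.chisquare(obs, exp)
    return {"chi2": float(chi2), "df": int(obs.size - 1), "p": float(p)}


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small tie-free samples (n <= 25 per
    group); tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(x.size, y.size) <= 25:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return {"W": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def adjust_p(p, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment: Holm step-down or Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = method.lower().replace("-", "_")
    if key in ("holm", "holm_bonferroni"):
        sm_method = "holm"
    elif key in ("bh", "fdr_bh", "benjamini_hochberg", "fdr"):
        sm_method = "fdr_bh"
    else:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return multipletests(p, method=sm_method)[1]
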