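"""Responder/non-responder phenotyping from in vitro SCFA fermentation data.

The response read-out is the baseline-subtracted sum of acetate and
butyrate (mM).  Per subject, each prebiotic arm (FOS, INU, XOS) is
compared against the matched no-prebiotic (NP) control arm with
Dunnett's many-to-one test; a subject is a responder for a substrate
when the family-wise adjusted p-value is below alpha AND the mean
difference is positive.

The Dunnett adjusted p-values are computed by deterministic quadrature
over the one-factor (equicorrelated) multivariate-t representation of
the contrast vector, which is exact for any many-to-one design with a
common pooled variance; k = 1 reduces to the ordinary pooled t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .da import adjust_p

SCFA_COLUMNS = [
    "subject_id",
    "treatment",
    "replicate",
    "timepoint_h",
    "acetate_mM",
    "butyrate_mM",
    "propionate_mM",
    "pH",
    "pct_fermented",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical settings for phenotyping.

    alpha: significance level for the responder call (default 0.05).
    adjust_method: family-wide adjustment used by helper analyses
        ("holm" for multiple comparisons, "BH" for discovery-style
        families); the Dunnett test carries its own FWER control.
    sidedness: "two" or "greater" for the Dunnett contrasts.
    average_replicates: average duplicate fermentations per timepoint
        before testing (the alternative treats replicates as
        observations).
    """

    alpha: float = 0.05
    adjust_method: str = "holm"
    sidedness: str = "two"
    average_replicates: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in ("two", "greater"):
            raise ValueError("sidedness must be 'two' or 'greater'")


def orq_transform(values) -> np.ndarray:
    """Ordered-quantile (rank-based inverse normal) transformation.

    Maps value with (average) rank r among n to Phi^-1((r - 0.5) / n);
    strictly rank-preserving, ties map to equal outputs.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-d vector with n >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        warnings.warn("constant input: ORQ transform returns all zeros", stacklevel=2)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------


def _max_t_cdf(t: float, lambdas: np.ndarray, df: int, *, two_sided: bool = True,
               n_z: int = 48, n_s: int = 96) -> float:
    """P(max_i |T_i| <= t) (or max T_i for one-sided) under H0.

    T is the Dunnett contrast vector: multivariate t with one-factor
    correlation rho_ij = lambda_i * lambda_j, lambda_i^2 = n_i/(n_i+n0),
    on df degrees of freedom.  Conditioning on the shared control factor
    Z0 = z and the pooled scale S = s factorizes the joint probability
    into a product of univariate normal probabilities; the two outer
    integrals are evaluated with Gauss-Hermite (z) and Gauss-Legendre
    (s, against the scaled-chi density) quadrature.
    """
    if t <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    gam = np.sqrt(1.0 - lam**2)
    zx, zw = np.polynomial.hermite_e.hermegauss(n_z)
    zw = zw / np.sqrt(2.0 * np.pi)
    s_lo = stats.chi.ppf(1e-12, df) / np.sqrt(df)
    s_hi = stats.chi.ppf(1.0 - 1e-13, df) / np.sqrt(df)
    gx, gw = np.polynomial.legendre.leggauss(n_s)
    s = 0.5 * (s_hi - s_lo) * gx + 0.5 * (s_hi + s_lo)
    sw = 0.5 * (s_hi - s_lo) * gw * stats.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df)
    # grid: s (axis 0) x z (axis 1) x contrast (axis 2)
    ts = (t * s)[:, None, None]
    lz = (lam[None, None, :] * zx[None, :, None])
    upper = stats.norm.cdf((ts + lz) / gam[None, None, :])
    if two_sided:
        lower = stats.norm.cdf((-ts + lz) / gam[None, None, :])
        probs = np.prod(upper - lower, axis=2)
    else:
        probs = np.prod(upper, axis=2)
    return float(sw @ probs @ zw)


def dunnett_vs_control(
    groups: Mapping[str, np.ndarray],
    control: str = "NP",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Dunnett's test of every treatment arm against a shared control.

    ``groups`` maps arm name -> observations (replicate/timepoint means).
    Returns one row per non-control arm with the mean difference, the
    t statistic on the pooled within-group variance, and the family-wise
    adjusted p-value from the multivariate-t distribution of the
    contrasts.
    """
    config = config or AnalysisConfig()
    if control not in groups:
        raise ValueError(f"control arm {control!r} missing")
    arms = [a for a in groups if a != control]
    if not arms:
        raise ValueError("need at least one treatment arm")
    obs = {a: np.asarray(v, dtype=float) for a, v in groups.items()}
    for a, v in obs.items():
        if v.size < 2:
            raise ValueError(f"arm {a!r} needs >= 2 observations")
    n0 = obs[control].size
    df = sum(v.size for v in obs.values()) - len(obs)
    ss = sum(((v - v.mean()) ** 2).sum() for v in obs.values())
    if ss <= 0:
        raise ValueError("zero pooled variance: cannot test")
    s2 = ss / df
    x0 = obs[control].mean()

    rows = []
    lambdas = np.array([np.sqrt(obs[a].size / (obs[a].size + n0)) for a in arms])
    for i, a in enumerate(arms):
        ni = obs[a].size
        diff = obs[a].mean() - x0
        se = np.sqrt(s2 * (1.0 / ni + 1.0 / n0))
        t = diff / se
        if len(arms) == 1:
            # exact reduction: Dunnett with one arm is the pooled t-test
            if config.sidedness == "two":
                p = 2.0 * stats.t.sf(abs(t), df)
            else:
                p = stats.t.sf(t, df)
        else:
            if config.sidedness == "two":
                p = 1.0 - _max_t_cdf(abs(t), lambdas, df, two_sided=True)
            else:
                p = 1.0 - _max_t_cdf(t, lambdas, df, two_sided=False)
        rows.append(
            {
                "treatment": a,
                "mean_diff": diff,
                "t": t,
                "df": df,
                "p_adj": min(max(p, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)


def dunnett_critical_value(
    k: int, n_per_arm: int, n_control: int, alpha: float = 0.05
) -> float:
    """Two-sided Dunnett critical value for a balanced many-to-one design."""
    lam = np.full(k, np.sqrt(n_per_arm / (n_per_arm + n_control)))
    df = k * n_per_arm + n_control - (k + 1)
    from scipy.optimize import brentq

    return brentq(
        lambda t: _max_t_cdf(t, lam, df, two_sided=True) - (1.0 - alpha), 0.5, 20.0
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova_two_way(scfa: pd.DataFrame, response: str = "ab_sum") -> dict:
    """Two-way (treatment x time) repeated-measures ANOVA on SCFA data.

    Replicates are averaged first; both factors are within-subject.
    Returns {"treatment": {F, p, ...}, "time": ..., "interaction": ...}.
    The interaction p-value tells the caller whether averaging over
    timepoints before phenotyping is defensible.
    """
    df = scfa.copy()
    if response == "ab_sum":
        df["ab_sum"] = df["acetate_mM"] + df["butyrate_mM"]
    cell = (
        df.groupby(["subject_id", "treatment", "timepoint_h"], sort=True)[response]
        .mean()
        .reset_index()
    )
    n_subj = cell["subject_id"].nunique()
    n_treat = cell["treatment"].nunique()
    n_time = cell["timepoint_h"].nunique()
    if len(cell) != n_subj * n_treat * n_time:
        full = pd.MultiIndex.from_product(
            [cell["subject_id"].unique(), cell["treatment"].unique(),
             cell["timepoint_h"].unique()],
            names=["subject_id", "treatment", "timepoint_h"],
        )
        have = pd.MultiIndex.from_frame(cell[["subject_id", "treatment", "timepoint_h"]])
        missing = full.difference(have)
        raise ValueError(f"unbalanced design; missing cells: {list(missing[:10])}")
    if np.ptp(cell[response].to_numpy()) == 0:
        raise ValueError("degenerate variance: response is constant")
    fit = AnovaRM(
        cell,
        depvar=response,
        subject="subject_id",
        within=["treatment", "timepoint_h"],
    ).fit()
    tbl = fit.anova_table
    out = {}
    for key, row in (
        ("treatment", "treatment"),
        ("time", "timepoint_h"),
        ("interaction", "treatment:timepoint_h"),
    ):
        out[key] = {
            "F": float(tbl.loc[row, "F Value"]),
            "p": float(tbl.loc[row, "Pr > F"]),
            "df_num": float(tbl.loc[row, "Num DF"]),
            "df_den": float(tbl.loc[row, "Den DF"]),
        }
    return out


# ---------------------------------------------------------------------------
# Phenotype assignment
# ---------------------------------------------------------------------------


def _subject_arm_observations(
    sub: pd.DataFrame, config: AnalysisConfig
) -> dict[str, np.ndarray]:
    """Per-arm observation vectors for one subject.

    With ``average_replicates`` the duplicate fermentations are averaged
    per timepoint, so each arm contributes one observation per timepoint.
    """
    sub = sub.assign(ab_sum=sub["acetate_mM"] + sub["butyrate_mM"])
    out = {}
    for arm, grp in sub.groupby("treatment", sort=False):
        if config.average_replicates:
            vals = grp.groupby("timepoint_h")["ab_sum"].mean().to_numpy()
        else:
            vals = grp["ab_sum"].to_numpy()
        out[str(arm)] = vals
    return out


def assign_phenotypes(
    scfa: pd.DataFrame,
    config: AnalysisConfig | None = None,
    control: str = "NP",
) -> pd.DataFrame:
    """Call responder (R) / non-responder (NR) per subject x substrate.

    For each subject the acetate+butyrate sums of every prebiotic arm
    are compared with the NP control arm by Dunnett's test; substrate
    labels follow ``R iff p_adj < alpha and mean difference > 0``.
    """
    config = config or AnalysisConfig()
    missing_np = [
        s
        for s, grp in scfa.groupby("subject_id")
        if control not in set(grp["treatment"])
    ]
    if missing_np:
        raise ValueError(f"subjects missing the {control} control arm: {missing_np}")

    rows = []
    for subject, sub in scfa.groupby("subject_id", sort=True):
        groups = _subject_arm_observations(sub, config)
        res = dunnett_vs_control(groups, control=control, config=config)
        for _, r in res.iterrows():
            is_r = (r["p_adj"] < config.alpha) and (r["mean_diff"] > 0)
            rows.append(
                {
                    "subject_id": subject,
                    "substrate": r["treatment"],
                    "label": "R" if is_r else "NR",
                    "mean_delta_ab_mM": r["mean_diff"],
                    "p_adj": r["p_adj"],
                }
            )
    return pd.DataFrame(rows)


def phenotype_diagnostics(
    scfa: pd.DataFrame,
    config: AnalysisConfig | None = None,
    control: str = "NP",
) -> pd.DataFrame:
    """Per-subject one-way ANOVA across arms plus pairwise-t follow-up.

    Diagnostic only: labels come from the Dunnett contrasts in
    :func:`assign_phenotypes`.
    """
    config = config or AnalysisConfig()
    rows = []
    for subject, sub in scfa.groupby("subject_id", sort=True):
        groups = _subject_arm_observations(sub, config)
        arrays = list(groups.values())
        f, p = stats.f_oneway(*arrays)
        arms = [a for a in groups if a != control]
        pt = [
            stats.ttest_ind(groups[a], groups[control]).pvalue for a in arms
        ]
        pt_adj = adjust_p(pt, method=config.adjust_method)
        for a, raw, adj in zip(arms, pt, pt_adj):
            rows.append(
                {
                    "subject_id": subject,
                    "substrate": a,
                    "anova_F": float(f),
                    "anova_p": float(p),
                    "pairwise_t_p": float(raw),
                    "pairwise_t_p_adj": float(adj),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Screening utilities
# ---------------------------------------------------------------------------


def outlier_scan(values, groups=None) -> pd.DataFrame:
    """Boxplot-rule univariate outlier flags.

    Flags points outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] as outliers and
    outside 3*IQR as extreme; groups of fewer than 4 observations are
    left unflagged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.zeros(values.size) if groups is None else np.asarray(groups)
    out = pd.DataFrame({"value": values, "group": groups,
                        "is_outlier": False, "is_extreme": False})
    for _, idx in out.groupby("group").groups.items():
        v = out.loc[idx, "value"].to_numpy()
        if v.size < 4:
            continue
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        out.loc[idx, "is_outlier"] = (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
        out.loc[idx, "is_extreme"] = (v < q1 - 3.0 * iqr) | (v > q3 + 3.0 * iqr)
    return out


def spearman_matrix(
    left: pd.DataFrame, right: pd.DataFrame, adjust: str = "BH"
) -> pd.DataFrame:
    """All-pairs Spearman correlations between two column sets.

    Rows are aligned on the shared index; constant vectors yield missing
    correlations.  Adjusted p-values are computed across the whole pair
    family (BH by default).
    """
    idx = left.index.intersection(right.index)
    if len(idx) < 3:
        raise ValueError("need >= 3 paired observations")
    rows = []
    for cl in left.columns:
        for cr in right.columns:
            x = left.loc[idx, cl].to_numpy(dtype=float)
            y = right.loc[idx, cr].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"left": cl, "right": cr, "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"left": cl, "right": cr, "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows)
    mask = df["p"].notna()
    df["q"] = np.nan
    if mask.any():
        df.loc[mask, "q"] = adjust_p(df.loc[mask, "p"].to_numpy(), method=adjust)
    return df
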