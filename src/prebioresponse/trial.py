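"""Feeding-trial evaluation: stratification, paired tests and ordination.

Subjects enter the trial with per-substrate predicted phenotypes; arms
are assigned so that single-substrate responders get their substrate,
multi-substrate responders are balanced across their predicted
substrates, and all-non-responders form an XOS control arm.  Pre/post
changes are tested with paired t-tests; community structure uses the
Shannon index, Bray-Curtis dissimilarities and principal coordinates
analysis (PCoA).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

XOS_CONTROL_ARM = "XOS"


def stratify_arms(
    predictions: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Assign each subject to one treatment arm from predicted labels.

    ``predictions`` is subjects x substrates with entries "R"/"NR".
    Single-substrate responders go to that substrate's arm;
    multi-substrate responders are assigned (seeded, balance-greedy) to
    one of their predicted substrates so responder arm sizes differ by
    at most 1 when feasible; subjects predicted non-responders to every
    substrate receive XOS and are flagged as the control group.
    """
    if predictions.isna().any().any():
        raise ValueError("every subject needs a prediction for every substrate")
    rng = np.random.default_rng(seed)
    substrates = list(predictions.columns)
    arm_counts = {s: 0 for s in substrates}
    rows = []
    multi: list[tuple[str, list[str]]] = []
    for subject, row in predictions.iterrows():
        r_subs = [s for s in substrates if row[s] == "R"]
        if len(r_subs) == 0:
            rows.append({"subject_id": subject, "arm": XOS_CONTROL_ARM,
                         "is_control": True})
        elif len(r_subs) == 1:
            arm_counts[r_subs[0]] += 1
            rows.append({"subject_id": subject, "arm": r_subs[0],
                         "is_control": False})
        else:
            multi.append((subject, r_subs))
    # balance-greedy pass over multi-substrate responders in seeded order
    order = rng.permutation(len(multi))
    for i in order:
        subject, r_subs = multi[i]
        counts = np.array([arm_counts[s] for s in r_subs])
        candidates = [s for s, c in zip(r_subs, counts) if c == counts.min()]
        arm = candidates[int(rng.integers(len(candidates)))]
        arm_counts[arm] += 1
        rows.append({"subject_id": subject, "arm": arm, "is_control": False})
    out = pd.DataFrame(rows).set_index("subject_id").loc[predictions.index]
    out.index.name = "subject_id"
    return out.reset_index()


def paired_t(pre, post) -> dict:
    """Paired t-test on post - pre differences (two-sided)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need paired vectors with n >= 2")
    d = post - pre
    if np.ptp(d) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(post, pre)
    return {"t": float(t), "df": int(d.size - 1), "p": float(p)}


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i over nonzero proportions."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundances must sum to > 0")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("profiles must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        warnings.warn("both profiles all-zero; dissimilarity defined as 0",
                      stacklevel=2)
        return 0.0
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between profile rows."""
    n = len(profiles)
    mat = np.zeros((n, n))
    vals = profiles.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(mat, index=profiles.index, columns=profiles.index)


def pcoa(dissimilarity: pd.DataFrame, atol: float = 1e-8) -> dict:
    """Principal coordinates analysis of a dissimilarity matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition;
    coordinates are returned for positive eigenvalues only, scaled by
    sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean input) are
    reported without correction.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if np.max(np.abs(np.diag(d))) > atol:
        raise ValueError("dissimilarity matrix must have zero diagonal")
    if np.max(np.abs(d - d.T)) > atol:
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > atol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    index = (
        dissimilarity.index
        if isinstance(dissimilarity, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    rel = eigvals / eigvals[pos].sum() if pos.any() else eigvals
    return {
        "coordinates": pd.DataFrame(
            coords, index=index,
            columns=[f"PC{i + 1}" for i in range(int(pos.sum()))],
        ),
        "eigenvalues": eigvals,
        "relative_eigenvalues": rel,
        "negative_eigenvalues": eigvals[eigvals < -atol],
    }


def friedman(blocks: pd.DataFrame) -> dict:
    """Friedman rank test across repeated measures (columns) per block (row)."""
    if blocks.shape[1] < 3:
        raise ValueError("need >= 3 conditions for the Friedman test")
    chi2, p = stats.friedmanchisquare(*[blocks[c] for c in blocks.columns])
    return {"chi2": float(chi2), "df": int(blocks.shape[1] - 1), "p": float(p)}
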