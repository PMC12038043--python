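"""Between-cluster differential expression and accessibility.

Differential expression uses a two-sided Wilcoxon rank-sum test on
log-normalized counts (counts per cell scaled to 10,000, then log1p).
Differential accessibility uses a logistic regression of group membership
on the binarized peak signal with the per-cell fragment total as a
covariate, tested by a likelihood-ratio test of the full model against the
covariate-only model (chi-square, 1 d.f.) — so accessibility differences
explained purely by sequencing depth are not called.

Both tests are Benjamini-Hochberg corrected per contrast; significance is
strict adj_p < 0.05 by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .config import Thresholds
from .containers import FeatureMatrix

logger = logging.getLogger("gonadomics")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_normalize(matrix: FeatureMatrix, scale: float = 1e4) -> FeatureMatrix:
    """Counts per cell scaled to ``scale`` total, then log1p."""
    if matrix.normalized:
        return matrix
    X = sparse.csr_matrix(matrix.X, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    X = X.multiply(scale / totals).tocsr()
    X.data = np.log1p(X.data)
    return FeatureMatrix(X, matrix.feature_ids, matrix.cell_ids, normalized=True)


def _group_columns(matrix: FeatureMatrix, labels: pd.Series, a, b):
    labels = pd.Series(np.asarray(labels), index=matrix.cell_ids) \
        if len(labels) == matrix.shape[1] and not isinstance(labels, pd.Series) \
        else pd.Series(labels)
    labels = labels.reindex(matrix.cell_ids)
    idx_a = np.where(labels.to_numpy() == a)[0]
    idx_b = np.where(labels.to_numpy() == b)[0]
    return idx_a, idx_b


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact enumeration only for small tie-free data."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    exact_ok = (
        len(x) <= 50 and len(y) <= 50
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def de_test(
    rna: FeatureMatrix,
    labels,
    a,
    b,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Wilcoxon differential expression between clusters ``a`` and ``b``.

    Returns one row per gene: effect (log2 fold change of mean normalized
    expression, a-over-b), p, adj_p, direction and a ``significant`` flag.
    """
    t = t or Thresholds()
    idx_a, idx_b = _group_columns(rna, labels, a, b)
    if len(idx_a) < t.min_cluster_cells or len(idx_b) < t.min_cluster_cells:
        raise ValueError(
            f"clusters {a!r}/{b!r} need >= {t.min_cluster_cells} cells each"
        )
    norm = log_normalize(rna)
    X = norm.X.toarray()
    Xa, Xb = X[:, idx_a], X[:, idx_b]
    pvals = np.array([_wilcoxon(Xa[i], Xb[i]) for i in range(X.shape[0])])
    eps = 1.0 / (len(idx_a) + len(idx_b))
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    effect = np.log2((mean_a + eps) / (mean_b + eps))
    adj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "feature_id": norm.feature_ids,
            "group_a": a,
            "group_b": b,
            "effect": effect,
            "p": pvals,
            "adj_p": adj,
            "direction": np.where(effect >= 0, "up_in_a", "up_in_b"),
        }
    )
    out["significant"] = out["adj_p"] < t.adj_p_max
    return out


def _logit_llf(X: np.ndarray, y: np.ndarray) -> float:
    """Maximized log-likelihood of a logistic regression (binomial GLM)."""
    import warnings

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    return float(res.llf)


def da_test(
    atac: FeatureMatrix,
    labels,
    a,
    b,
    covariate,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio differential accessibility between ``a`` and ``b``.

    ``covariate`` is the per-cell fragment-in-peaks total (aligned with
    the matrix cells); it enters the model as standardized log counts.
    Effect is log2((rate_a + eps) / (rate_b + eps)), eps = 1/(n_a + n_b).
    Peaks closed in every cell of both groups are skipped.
    """
    t = t or Thresholds()
    idx_a, idx_b = _group_columns(atac, labels, a, b)
    if len(idx_a) < t.min_cluster_cells or len(idx_b) < t.min_cluster_cells:
        raise ValueError(
            f"clusters {a!r}/{b!r} need >= {t.min_cluster_cells} cells each"
        )
    cov = np.asarray(covariate, dtype=float)
    if isinstance(covariate, pd.Series):
        cov = covariate.reindex(atac.cell_ids).to_numpy(dtype=float)
    if np.any(cov <= 0):
        raise ValueError("fragment-count covariate must be positive")

    idx = np.concatenate([idx_a, idx_b])
    y = np.concatenate([np.ones(len(idx_a)), np.zeros(len(idx_b))])
    z = np.log(cov[idx])
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    X = (atac.X[:, idx].toarray() > 0).astype(float)

    n = len(idx)
    reduced = np.column_stack([np.ones(n), z])
    llf_reduced = _logit_llf(reduced, y)

    rows = []
    eps = 1.0 / n
    n_a, n_b = len(idx_a), len(idx_b)
    for i in range(X.shape[0]):
        x = X[i]
        rate_a = x[:n_a].mean()
        rate_b = x[n_a:].mean()
        if x.sum() == 0:
            logger.info("peak %s closed in both groups; skipped",
                        atac.feature_ids[i])
            continue
        full = np.column_stack([np.ones(n), z, x])
        llr = max(0.0, 2.0 * (_logit_llf(full, y) - llf_reduced))
        p = float(stats.chi2.sf(llr, df=1))
        effect = float(np.log2((rate_a + eps) / (rate_b + eps)))
        rows.append((atac.feature_ids[i], effect, p))
    out = pd.DataFrame(rows, columns=["feature_id", "effect", "p"])
    out.insert(1, "group_a", a)
    out.insert(2, "group_b", b)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["effect"] >= 0, "up_in_a", "up_in_b")
    out["significant"] = out["adj_p"] < t.adj_p_max
    return out
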