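"""Group-level evaluation of composite scores and gene correlations.

Composite scores of two sample groups are compared with Welch's
unpaired two-sample t-test (unequal variance, unequal sample size,
Welch-Satterthwaite degrees of freedom) together with the composite
score's own classification strength: a rank ROC-AUC and the accuracy
of the best single score threshold.  Gene-gene co-expression is
measured with the Pearson product-moment correlation by default
(Spearman rank correlation optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selection import _as_positive_mask


@dataclass(frozen=True)
class GroupComparison:
    cluster: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    welch_t: float
    welch_df: float
    p_value: float
    composite_auc: float
    composite_accuracy: float
    accuracy_threshold: float


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float | None
    n: int
    method: str
    undefined: bool = False


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: statistic, Welch-Satterthwaite df,
    two-sided p-value.

    Raises
    ------
    ValueError
        If either group has fewer than 2 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _threshold_sweep_accuracy(
    scores: np.ndarray, pos: np.ndarray
) -> tuple[float, float]:
    """Best accuracy of the rule score > t, ties broken to lower t.

    Candidate thresholds are -inf and every observed score, so the
    rule can always call everything positive or everything negative;
    accuracy therefore never falls below the larger class prevalence.
    """
    candidates = np.concatenate(([-np.inf], np.unique(scores)))
    best_acc, best_t = -1.0, -np.inf
    n = scores.size
    for t in candidates:
        pred = scores > t
        acc = float((pred == pos).sum()) / n
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    return best_acc, best_t


def compare_groups(
    scores: pd.Series,
    groups: pd.Series,
    positive: str,
    cluster: str = "",
) -> GroupComparison:
    """Compare composite scores between two groups.

    *positive* names the group expected to score higher; the AUC is
    the probability that a random positive sample outscores a random
    negative one (ties 1/2), and the accuracy comes from the score
    threshold that classifies best (lower threshold on ties).
    """
    groups = groups.reindex(scores.index)
    labels = groups.dropna()
    if labels.nunique() != 2:
        raise ValueError(
            f"need exactly two groups, got {sorted(labels.unique())}"
        )
    s = scores.loc[labels.index].to_numpy(dtype=float)
    pos = _as_positive_mask(labels.to_numpy(), positive)
    neg_label = [g for g in labels.unique() if g != positive][0]

    a, b = s[pos], s[~pos]
    t, df, p = welch_t(a, b)
    ranks = stats.rankdata(s)
    auc = float(
        (ranks[pos].sum() - pos.sum() * (pos.sum() + 1) / 2)
        / (pos.sum() * (~pos).sum())
    )
    acc, thr = _threshold_sweep_accuracy(s, pos)
    return GroupComparison(
        cluster=cluster,
        group_a=str(positive),
        group_b=str(neg_label),
        n_a=int(pos.sum()),
        n_b=int((~pos).sum()),
        welch_t=t,
        welch_df=df,
        p_value=p,
        composite_auc=auc,
        composite_accuracy=acc,
        accuracy_threshold=thr,
    )


def gene_correlation(
    X: pd.DataFrame, gene_a: str, gene_b: str, method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two genes over their shared finite samples.

    Returns an undefined-flagged result when either gene is constant
    over the shared samples.

    Raises
    ------
    KeyError
        If a gene is absent from the matrix.
    ValueError
        If fewer than 3 shared finite samples remain.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    xa = X.loc[gene_a].to_numpy(dtype=float)
    xb = X.loc[gene_b].to_numpy(dtype=float)
    keep = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[keep], xb[keep]
    if xa.size < 3:
        raise ValueError(
            f"{gene_a}/{gene_b}: need >= 3 shared samples, got {xa.size}"
        )
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return CorrelationResult(gene_a, gene_b, None, int(xa.size), method, True)
    if method == "pearson":
        r = stats.pearsonr(xa, xb).statistic
    else:
        r = stats.spearmanr(xa, xb).statistic
    return CorrelationResult(gene_a, gene_b, float(r), int(xa.size), method)
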