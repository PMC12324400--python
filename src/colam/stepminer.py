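"""StepMiner adaptive one-step regression.

StepMiner fits a step function to an ordered series of values by
evaluating every possible breakpoint, taking the mean of the values on
either side of the step, and keeping the breakpoint that minimizes the
sum of squared errors against the fitted step.  On a time series the
breakpoint locates the sharpest expression switch; on ascending-sorted
cross-sample values the midpoint of the two segment means defines a
per-gene high/low binarization threshold (``SThr``).

A regression F-like statistic compares the variance explained by the
fitted step against the residual variance:

    F = [ sum_i (Xhat_i - Xbar)^2 / (m - 1) ] / [ sum_i (X_i - Xhat_i)^2 / (n - m) ]

where ``Xhat`` are the fitted step values, ``Xbar`` the grand mean, and
``m`` the degrees of freedom of the adaptive fit (default 3: two
segment means plus one breakpoint).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

Ordering = Literal["as-given", "ascending"]

#: Default degrees of freedom for the one-step adaptive fit.
DEFAULT_DF = 3

#: Default half-width of the intermediate zone around SThr (log2 units).
DEFAULT_MARGIN = 0.5


@dataclass(frozen=True)
class StepFit:
    """Result of a one-step regression.

    ``k`` is the 1-based index of the last point in the left segment,
    so the step sits between positions ``k`` and ``k + 1``.
    ``degenerate`` marks series where no step strictly reduces the SSE
    below the constant (grand-mean) fit — e.g. a constant series.
    """

    k: int
    left_mean: float
    right_mean: float
    grand_mean: float
    sse_step: float
    sse_constant: float
    n: int
    degenerate: bool

    def fitted(self) -> np.ndarray:
        """Fitted step values Xhat (left_mean up to k, right_mean after)."""
        out = np.full(self.n, self.right_mean, dtype=float)
        out[: self.k] = self.left_mean
        return out


@dataclass(frozen=True)
class FStatistic:
    """F-like regression statistic; ``perfect_fit`` flags a zero residual."""

    value: float | None
    perfect_fit: bool
    m: int


@dataclass(frozen=True)
class GeneThreshold:
    """Per-gene binarization threshold on the log-expression scale.

    ``sthr`` is the midpoint of the two StepMiner segment means, ``sd``
    the sample standard deviation across samples, and ``margin`` the
    half-width of the intermediate zone used by :func:`binarize`.
    Degenerate genes (no improving step) carry the median as ``sthr``.
    """

    gene: str
    sthr: float
    sd: float
    margin: float = DEFAULT_MARGIN
    degenerate: bool = False


def _validate_series(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 2:
        raise ValueError(f"series needs at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def fit_step(values, ordering: Ordering = "as-given") -> StepFit:
    """Fit the best single step to *values*.

    Evaluates every breakpoint k in 1..n-1, computing segment means and
    the step SSE; ties in SSE are broken toward the smallest k.  With
    ``ordering="ascending"`` the values are sorted before fitting
    (cross-sample binarization mode).

    Raises
    ------
    ValueError
        If the series has fewer than 2 values or non-finite entries.
    """
    x = _validate_series(values)
    if ordering == "ascending":
        x = np.sort(x)
    elif ordering != "as-given":
        raise ValueError(f"unknown ordering {ordering!r}")

    n = x.size
    grand_mean = float(x.mean())
    sse_constant = float(np.sum((x - grand_mean) ** 2))

    # Prefix-sum evaluation of all n-1 breakpoints:
    #   SSE_left(k) = sum(x_i^2, i<=k) - (sum x_i, i<=k)^2 / k
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(1, n)
    left_sum, left_sq = cs[:-1], cs2[:-1]
    right_sum, right_sq = cs[-1] - left_sum, cs2[-1] - left_sq
    sse = (left_sq - left_sum**2 / k) + (right_sq - right_sum**2 / (n - k))
    # Guard tiny negative values from floating cancellation.
    sse = np.maximum(sse, 0.0)

    best = int(np.argmin(sse))  # argmin returns the first minimum: smallest k
    k_star = best + 1
    left_mean = float(left_sum[best] / k_star)
    right_mean = float(right_sum[best] / (n - k_star))
    sse_step = float(sse[best])

    degenerate = not (sse_step < sse_constant) or left_mean == right_mean
    return StepFit(
        k=k_star,
        left_mean=left_mean,
        right_mean=right_mean,
        grand_mean=grand_mean,
        sse_step=sse_step,
        sse_constant=sse_constant,
        n=n,
        degenerate=degenerate,
    )


def f_statistic(fit: StepFit, m: int = DEFAULT_DF) -> FStatistic:
    """Regression F statistic of a step fit.

    The explained sum of squares is computed from the fit's segment
    means; the residual sum of squares is ``fit.sse_step``.  A zero
    residual (perfect step) returns ``value=None`` with
    ``perfect_fit=True`` rather than an infinite statistic.

    Raises
    ------
    ValueError
        If ``m >= n`` (the ratio's denominator degrees of freedom must
        be positive) or ``m < 2``.
    """
    if m >= fit.n:
        raise ValueError(f"degrees of freedom m={m} must be < n={fit.n}")
    if m < 2:
        raise ValueError(f"degrees of freedom m={m} must be >= 2")
    explained = fit.k * (fit.left_mean - fit.grand_mean) ** 2 + (
        fit.n - fit.k
    ) * (fit.right_mean - fit.grand_mean) ** 2
    if fit.sse_step == 0.0:
        return FStatistic(value=None, perfect_fit=True, m=m)
    value = (explained / (m - 1)) / (fit.sse_step / (fit.n - m))
    return FStatistic(value=float(value), perfect_fit=False, m=m)


def gene_threshold(
    values, gene: str = "", margin: float = DEFAULT_MARGIN
) -> GeneThreshold:
    """StepMiner binarization threshold for one gene across samples.

    Values are sorted ascending, a step is fitted, and SThr is the
    midpoint of the two segment means.  ``sd`` is the sample standard
    deviation (ddof=1) of the values in their given order.  Degenerate
    genes (e.g. constant expression) get the median as SThr and a
    degenerate marker; callers exclude them from selection by default.
    """
    x = _validate_series(values)
    fit = fit_step(x, ordering="ascending")
    sd = float(np.std(x, ddof=1))
    if fit.degenerate:
        sthr = float(np.median(x))
    else:
        sthr = (fit.left_mean + fit.right_mean) / 2.0
    return GeneThreshold(
        gene=gene, sthr=sthr, sd=sd, margin=margin, degenerate=fit.degenerate
    )


def binarize(value: float, th: GeneThreshold) -> str:
    """Label a value low / intermediate / high against a threshold.

    The intermediate zone is ``[SThr - margin, SThr + margin]``; with
    margin 0 the split is strict two-way and a value equal to SThr maps
    to low.
    """
    if th.margin == 0:
        return "high" if value > th.sthr else "low"
    if value < th.sthr - th.margin:
        return "low"
    if value > th.sthr + th.margin:
        return "high"
    return "intermediate"


def fit_matrix_thresholds(
    X: pd.DataFrame, margin: float = DEFAULT_MARGIN
) -> pd.DataFrame:
    """Per-gene thresholds for a gene-by-sample expression matrix.

    Missing entries are excluded per gene.  Returns a DataFrame indexed
    by gene with columns ``SThr``, ``sd``, ``degenerate``.
    """
    rows = {}
    for gene, row in X.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(f"gene {gene!r} has fewer than 2 finite values")
        th = gene_threshold(vals, gene=str(gene), margin=margin)
        rows[gene] = (th.sthr, th.sd, th.degenerate)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["SThr", "sd", "degenerate"]
    )
    out.index.name = "gene"
    return out
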