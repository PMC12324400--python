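"""Modified Z-score normalization and composite signature scores.

Expression is normalized around each gene's StepMiner threshold with a
modified Z-score, z = (expr - SThr) / (3 * sd), so z = 0 at the high/low
boundary and |z| = 1 three standard deviations away.  A composite
signature score for a sample is the sum of z over a signature cluster's
genes, with Down-direction genes entering negated so that a higher
score always means more of the cluster's state.  Samples are ordered
by their composite score.

Composite scores compare groups *within* a dataset; they are not
comparable across signatures of different sizes or across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIRECTIONS = ("Up", "Down")


@dataclass(frozen=True)
class SignatureGene:
    gene: str
    direction: str = "Up"

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be Up or Down, got {self.direction!r}")


@dataclass
class GeneSignature:
    """Named clusters of signature genes with regulation directions.

    A gene may belong to at most one cluster.
    """

    clusters: dict[str, list[SignatureGene]] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for name, members in self.clusters.items():
            for sg in members:
                if sg.gene in seen:
                    raise ValueError(
                        f"gene {sg.gene!r} appears in clusters "
                        f"{seen[sg.gene]!r} and {name!r}"
                    )
                seen[sg.gene] = name

    def genes(self, cluster: str | None = None) -> list[str]:
        if cluster is not None:
            return [sg.gene for sg in self.clusters[cluster]]
        return [sg.gene for members in self.clusters.values() for sg in members]

    def cluster_of(self, gene: str) -> str | None:
        for name, members in self.clusters.items():
            if any(sg.gene == gene for sg in members):
                return name
        return None


@dataclass
class CompositeScoreTable:
    """Per-sample composite scores for one signature cluster.

    ``order`` lists samples ascending by score; ``flagged_samples`` are
    samples that were missing more than half of the cluster's genes and
    whose score should be treated with caution.
    """

    cluster: str
    scores: pd.Series
    order: list[str]
    genes_used: list[str]
    genes_missing: list[str]
    flagged_samples: list[str]


def normalize_matrix(
    X: pd.DataFrame, thresholds: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Modified Z-score matrix z = (X - SThr) / (3 * sd).

    *thresholds* is the frame from
    :func:`colam.stepminer.fit_matrix_thresholds` (columns ``SThr``,
    ``sd``).  Genes with sd = 0 are unusable for scoring and are
    dropped with a warning rather than divided.

    Raises
    ------
    KeyError
        If any requested gene lacks a threshold; the message lists them.
    """
    wanted = list(X.index if genes is None else genes)
    missing = [g for g in wanted if g not in thresholds.index]
    if missing:
        raise KeyError(f"no threshold for genes: {sorted(map(str, missing))}")
    sub = X.loc[wanted]
    th = thresholds.loc[wanted]
    usable = th["sd"] > 0
    if not usable.all():
        dropped = [str(g) for g in th.index[~usable]]
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped)
        sub, th = sub.loc[usable], th.loc[usable]
    z = sub.sub(th["SThr"], axis=0).div(3.0 * th["sd"], axis=0)
    return z


def composite_score(
    Z: pd.DataFrame,
    cluster: list[SignatureGene],
    name: str = "",
    flag_missing_fraction: float = 0.5,
) -> CompositeScoreTable:
    """Summed composite score of a signature cluster per sample.

    Down-direction genes are negated before summing.  Genes absent from
    the normalized matrix are skipped (and reported); missing values
    are excluded per gene, and samples missing more than
    *flag_missing_fraction* of the cluster's genes are flagged.

    Raises
    ------
    ValueError
        If no cluster gene is present in the matrix.
    """
    present = [sg for sg in cluster if sg.gene in Z.index]
    missing = [sg.gene for sg in cluster if sg.gene not in Z.index]
    if not present:
        raise ValueError(f"cluster {name!r}: none of its genes are in the matrix")
    if missing:
        logger.warning("cluster %r: %d genes absent from matrix", name, len(missing))

    signs = pd.Series(
        [1.0 if sg.direction == "Up" else -1.0 for sg in present],
        index=[sg.gene for sg in present],
    )
    sub = Z.loc[signs.index]
    signed = sub.mul(signs, axis=0)
    scores = signed.sum(axis=0, skipna=True)

    n_missing = sub.isna().sum(axis=0)
    flagged = list(scores.index[n_missing > flag_missing_fraction * len(present)])
    order = list(scores.sort_values(kind="stable").index)
    return CompositeScoreTable(
        cluster=name,
        scores=scores,
        order=order,
        genes_used=list(signs.index),
        genes_missing=missing,
        flagged_samples=[str(s) for s in flagged],
    )
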