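"""Per-gene classification strength and signature refinement.

Each gene's classifier is its StepMiner-thresholded normalized
expression: the ROC-AUC measures how well the gene's values rank
positive-class samples above negative ones (ties count 1/2), and the
confusion-matrix metrics (accuracy, precision, recall, F1) come from
the high/low call at the gene's own threshold SThr.  Genes whose raw
AUC falls below 0.5 discriminate in the opposite orientation and are
reported as Down-regulated in the positive class with AUC 1 - raw, so
reported AUCs live in [0.5, 1].

A base signature (e.g. the 338-gene SMaRT macrophage reactivity /
tolerance signature with clusters R, T1, T2) is refined into a
dataset-specific signature by keeping genes whose AUC exceeds a cutoff
(default 0.70, strict) and mapping each source cluster to a refined
cluster (default: reactive R -> inflammatory "iColAM", tolerant T1/T2
-> non-inflammatory "niColAM").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signature import GeneSignature, SignatureGene, normalize_matrix
from .stepminer import DEFAULT_MARGIN, fit_matrix_thresholds

logger = logging.getLogger(__name__)

DEFAULT_AUC_CUTOFF = 0.70
DEFAULT_CLUSTER_MAP = {"R": "iColAM", "T1": "niColAM", "T2": "niColAM"}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision, recall and F1; None where the denominator is 0."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass
class SelectionReport:
    """Per-gene records plus the refined signature and its provenance."""

    records: pd.DataFrame
    refined: GeneSignature
    provenance: dict


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy (TP+TN)/N, precision TP/(TP+FP), recall TP/(TP+FN),
    F1 = 2*precision*recall/(precision+recall)."""
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.n
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(accuracy, precision, recall, f1)


def _as_positive_mask(labels, positive=None) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        mask = labels
    elif positive is not None:
        pos = {positive} if isinstance(positive, str) else set(positive)
        mask = np.isin(labels, list(pos))
    else:
        mask = labels.astype(bool)
    if mask.all() or not mask.any():
        raise ValueError("both classes must be non-empty")
    return mask


def gene_roc_auc(values, labels, positive=None) -> tuple[float, str]:
    """Rank AUC of one gene's values against binary groups.

    Returns ``(auc, direction)`` with auc in [0.5, 1]: if the raw AUC
    (positive class ranking high) is below 0.5 the gene is reported as
    Down with ``1 - raw``.  Missing values are dropped pairwise.

    The AUC is the Mann-Whitney rank form of the concordant-pair
    probability, which handles ties at exactly 1/2.
    """
    x = np.asarray(values, dtype=float)
    mask = _as_positive_mask(labels, positive)
    keep = np.isfinite(x)
    x, mask = x[keep], mask[keep]
    if mask.all() or not mask.any():
        raise ValueError("both classes must be non-empty after dropping missing")
    n_pos, n_neg = int(mask.sum()), int((~mask).sum())
    ranks = rankdata(x)
    raw = float((ranks[mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    if raw < 0.5:
        return 1.0 - raw, "Down"
    return raw, "Up"


def auc_matrix(Z: np.ndarray, positive_mask: np.ndarray) -> np.ndarray:
    """Raw rank AUCs for every row of *Z* at once (ties count 1/2).

    Vectorized Mann-Whitney form used by the permutation null; finite
    values only.
    """
    n_pos = int(positive_mask.sum())
    n_neg = positive_mask.size - n_pos
    ranks = rankdata(Z, axis=1)
    u = ranks[:, positive_mask].sum(axis=1) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def refine_signature(
    X: pd.DataFrame,
    groups: pd.Series,
    base: GeneSignature,
    positive,
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
    cluster_map: dict[str, str] | None = None,
    margin: float = DEFAULT_MARGIN,
    thresholds: pd.DataFrame | None = None,
    dataset_id: str = "",
) -> SelectionReport:
    """Refine *base* into a dataset-specific signature by per-gene AUC.

    For each base gene present in *X* and non-degenerate: fit the
    StepMiner threshold, normalize, compute the rank AUC and direction,
    and the confusion metrics of the high/low call at SThr.  Genes with
    ``auc > auc_cutoff`` (strict) are selected and assigned to the
    refined cluster that *cluster_map* gives for their source cluster
    (source clusters absent from the map keep their own name).

    Returns per-gene records for every base gene found in the matrix,
    selected or not; degenerate genes carry NaN metrics and are never
    selected.
    """
    if cluster_map is None:
        cluster_map = dict(DEFAULT_CLUSTER_MAP)
    groups = groups.reindex(X.columns)
    if groups.isna().any():
        missing = list(X.columns[groups.isna()])
        raise ValueError(f"samples without group labels: {missing}")
    pos_mask = _as_positive_mask(groups.to_numpy(), positive)

    base_genes = base.genes()
    present = [g for g in base_genes if g in X.index]
    if not present:
        raise ValueError("no base signature genes found in the matrix")
    absent = sorted(set(base_genes) - set(present))
    if absent:
        logger.warning("%d base genes absent from matrix", len(absent))

    sub = X.loc[present]
    if thresholds is None:
        thresholds = fit_matrix_thresholds(sub, margin=margin)
    else:
        thresholds = thresholds.loc[present]
    if thresholds["degenerate"].all():
        raise ValueError("all base genes are degenerate; nothing to select")

    Z = normalize_matrix(sub, thresholds)

    rows = []
    for gene in present:
        cluster = base.cluster_of(gene)
        if thresholds.loc[gene, "degenerate"] or gene not in Z.index:
            rows.append(
                dict(
                    gene=gene, cluster=cluster, auc=np.nan, direction="",
                    accuracy=np.nan, precision=np.nan, recall=np.nan,
                    f1=np.nan, degenerate=True, selected=False,
                )
            )
            continue
        z = Z.loc[gene].to_numpy(dtype=float)
        auc, direction = gene_roc_auc(z, pos_mask)
        # High/low call at SThr (z > 0), oriented by the gene's direction.
        call_high = z > 0
        pred_pos = call_high if direction == "Up" else ~call_high
        c = ConfusionCounts(
            tp=int((pred_pos & pos_mask).sum()),
            tn=int((~pred_pos & ~pos_mask).sum()),
            fp=int((pred_pos & ~pos_mask).sum()),
            fn=int((~pred_pos & pos_mask).sum()),
        )
        m = classification_metrics(c)
        rows.append(
            dict(
                gene=gene, cluster=cluster, auc=auc, direction=direction,
                accuracy=m.accuracy,
                precision=np.nan if m.precision is None else m.precision,
                recall=np.nan if m.recall is None else m.recall,
                f1=np.nan if m.f1 is None else m.f1,
                degenerate=False,
                selected=bool(auc > auc_cutoff),
            )
        )
    records = pd.DataFrame(rows).set_index("gene")

    refined_clusters: dict[str, list[SignatureGene]] = {}
    for gene, row in records[records["selected"]].iterrows():
        target = cluster_map.get(row["cluster"], row["cluster"])
        refined_clusters.setdefault(target, []).append(
            SignatureGene(gene=str(gene), direction=str(row["direction"]))
        )
    refined = GeneSignature(clusters=refined_clusters)

    provenance = dict(
        dataset_id=dataset_id,
        auc_cutoff=auc_cutoff,
        positive=positive if isinstance(positive, str) else sorted(positive),
        cluster_map=dict(cluster_map),
        n_base_genes=len(base_genes),
        n_present=len(present),
        n_selected=int(records["selected"].sum()),
    )
    return SelectionReport(records=records, refined=refined, provenance=provenance)


def permutation_null_counts(
    X: pd.DataFrame,
    groups: pd.Series,
    genes,
    positive,
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
    n_permutations: int = 200,
    seed: int = 0,
    thresholds: pd.DataFrame | None = None,
) -> np.ndarray:
    """Null distribution of the number of genes passing the AUC cutoff.

    Group labels are permuted across samples *n_permutations* times and
    the genes among *genes* whose reported AUC (max of raw and 1-raw)
    exceeds the cutoff are counted each time.  StepMiner thresholds do
    not depend on the labels, so normalization is computed once.
    """
    genes = [g for g in genes if g in X.index]
    sub = X.loc[genes]
    if thresholds is None:
        thresholds = fit_matrix_thresholds(sub)
    else:
        thresholds = thresholds.loc[genes]
    usable = ~thresholds["degenerate"].to_numpy(dtype=bool)
    Z = normalize_matrix(sub.loc[np.array(genes)[usable]], thresholds)
    values = Z.to_numpy(dtype=float)

    groups = groups.reindex(X.columns)
    pos_mask = _as_positive_mask(groups.to_numpy(), positive)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        perm = rng.permutation(pos_mask)
        raw = auc_matrix(values, perm)
        reported = np.maximum(raw, 1.0 - raw)
        counts[i] = int((reported > auc_cutoff).sum())
    return counts
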