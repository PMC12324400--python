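"""Synthetic expression cohorts with ground truth.

The generator emulates the statistical structure the signature
pipeline assumes in a two-group (healthy vs disease) bulk cohort:
every gene is bimodal on the log scale, drawing each value from a
low-expression or high-expression Gaussian mode, so StepMiner
thresholds between the modes are well defined.  Signature genes
differ between groups in their probability of occupying the high
mode; background genes occupy it with the same probability in both
groups and carry no signal.

The ``effect`` parameter is the separation of high-mode probabilities
between groups: an Up gene has P(high | disease) = 0.5 + effect/2 and
P(high | healthy) = 0.5 - effect/2 (mirrored for Down genes), so
effect 0 is an exact null and effect 1 puts every disease sample high
and every healthy sample low.  Background genes use p = 0.5 in both
groups.  All randomness flows from the single seed in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import GeneSignature, SignatureGene


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults give a cohort of 15 samples per group with 10 inflammatory
    (Up-in-disease) and 10 non-inflammatory signature genes over 200
    null background genes; modes at 4 and 8 log2 units with noise sd
    0.7, a clean but not degenerate separation.
    """

    n_per_group: int = 15
    n_inflammatory: int = 10
    n_noninflammatory: int = 10
    n_background: int = 200
    mu_lo: float = 4.0
    mu_hi: float = 8.0
    noise_sd: float = 0.7
    effect: float = 1.0
    ni_direction: str = "Down"
    group_names: tuple[str, str] = ("Healthy", "IBD")
    seed: int = 0

    def __post_init__(self):
        if not self.mu_hi > self.mu_lo:
            raise ValueError("mu_hi must exceed mu_lo")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be in [0, 1]")
        if self.ni_direction not in ("Up", "Down"):
            raise ValueError("ni_direction must be Up or Down")


def _mode_probs(direction: str, effect: float) -> tuple[float, float]:
    """(P(high | negative group), P(high | positive group))."""
    hi, lo = 0.5 + effect / 2.0, 0.5 - effect / 2.0
    return (lo, hi) if direction == "Up" else (hi, lo)


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, GeneSignature, pd.DataFrame]:
    """Generate (expression matrix, group labels, signature, truth).

    The matrix is genes x samples on the log scale; the signature has
    clusters ``"i"`` (Up in the disease group) and ``"ni"``; the truth
    frame records every gene's class, direction and per-group
    high-mode probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    neg, pos = spec.group_names
    samples = [f"{neg}_{i + 1:03d}" for i in range(spec.n_per_group)] + [
        f"{pos}_{i + 1:03d}" for i in range(spec.n_per_group)
    ]
    groups = pd.Series(
        [neg] * spec.n_per_group + [pos] * spec.n_per_group,
        index=samples,
        name="group",
    )
    is_pos = (groups == pos).to_numpy()

    genes, gene_class, gene_dir, p_neg_list, p_pos_list = [], [], [], [], []

    def add(prefix, count, klass, direction):
        for i in range(count):
            genes.append(f"{prefix}{i + 1:04d}")
            gene_class.append(klass)
            gene_dir.append(direction)
            if klass == "background":
                p_n = p_p = 0.5
            else:
                p_n, p_p = _mode_probs(direction, spec.effect)
            p_neg_list.append(p_n)
            p_pos_list.append(p_p)

    add("SIG_I_", spec.n_inflammatory, "i", "Up")
    add("SIG_NI_", spec.n_noninflammatory, "ni", spec.ni_direction)
    add("BG_", spec.n_background, "background", "")

    p = np.where(
        is_pos[None, :],
        np.asarray(p_pos_list)[:, None],
        np.asarray(p_neg_list)[:, None],
    )
    high = rng.random((len(genes), len(samples))) < p
    means = np.where(high, spec.mu_hi, spec.mu_lo)
    values = means + rng.normal(0.0, spec.noise_sd, size=means.shape)
    X = pd.DataFrame(values, index=genes, columns=samples)
    X.index.name = "gene"

    sig = GeneSignature(
        clusters={
            "i": [
                SignatureGene(g, "Up")
                for g, c in zip(genes, gene_class)
                if c == "i"
            ],
            "ni": [
                SignatureGene(g, spec.ni_direction)
                for g, c in zip(genes, gene_class)
                if c == "ni"
            ],
        }
    )
    truth = pd.DataFrame(
        {
            "class": gene_class,
            "direction": gene_dir,
            "p_high_negative": p_neg_list,
            "p_high_positive": p_pos_list,
        },
        index=pd.Index(genes, name="gene"),
    )
    return X, groups, sig, truth


def generate_step_series(
    n: int,
    k: int,
    left_level: float,
    right_level: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """One noisy step series plus its ground truth.

    The first *k* values sit at *left_level* and the remaining n-k at
    *right_level*, with Gaussian noise of sd *noise_sd* added.
    """
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1], got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    values = np.full(n, right_level, dtype=float)
    values[:k] = left_level
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    truth = dict(k=k, left_level=left_level, right_level=right_level)
    return values, truth
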