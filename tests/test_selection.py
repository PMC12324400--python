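import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import auc_oracle
from colam.selection import (
    ConfusionCounts,
    classification_metrics,
    gene_roc_auc,
    permutation_null_counts,
    refine_signature,
)
from colam.signature import GeneSignature, SignatureGene
from colam.synthetic import SyntheticSpec, generate_cohort


class TestGeneRocAuc:
    def test_perfect_separation(self):
        auc, direction = gene_roc_auc([0, 1, 2, 3], [False, False, True, True])
        assert (auc, direction) == (1.0, "Up")

    def test_all_ties(self):
        auc, _ = gene_roc_auc([1, 2, 1, 2], [True, True, False, False])
        assert auc == pytest.approx(0.5)

    def test_pair_counting_fixture(self):
        # positives {1,3,3} vs negatives {2,3,5}: 3 concordant halves of 9 pairs
        values = [1, 3, 3, 2, 3, 5]
        labels = [True, True, True, False, False, False]
        raw = auc_oracle([1, 3, 3], [2, 3, 5])
        assert raw == pytest.approx(1 / 3)
        auc, direction = gene_roc_auc(values, labels)
        assert auc == pytest.approx(1 - raw)
        assert direction == "Down"

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_roc_auc([1, 2, 3], [True, True, True])

    def test_oracle_equivalence_random(self, rng):
        """Reported AUC equals exhaustive pair counting (ties 1/2)."""
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            values = rng.integers(0, 5, size=n).astype(float)  # many ties
            raw = auc_oracle(values[labels], values[~labels])
            auc, direction = gene_roc_auc(values, labels)
            assert auc == pytest.approx(max(raw, 1 - raw), abs=1e-12)
            assert auc >= 0.5

    def test_agrees_with_sklearn_on_untied_data(self, rng):
        """Cross-check against the ROC-curve integral on tie-free values."""
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            n = int(rng.integers(4, 20))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            values = rng.normal(size=n)
            raw = float(roc_auc_score(labels, values))
            auc, _ = gene_roc_auc(values, labels)
            assert auc == pytest.approx(max(raw, 1 - raw), abs=1e-12)

    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n_pos + n_neg)
        labels = np.array([True] * n_pos + [False] * n_neg)
        a1, d1 = gene_roc_auc(values, labels)
        a2, d2 = gene_roc_auc(np.exp(values), labels)
        assert a1 == pytest.approx(a2)
        assert d1 == d2


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_precision_flagged(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m.precision is None
        assert m.recall == 0.0
        assert m.f1 is None

    def test_hand_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestRefineSignature:
    def test_true_shifted_genes_selected(self):
        """Only the genes carrying a group shift pass the AUC cutoff."""
        spec = SyntheticSpec(
            n_per_group=15,
            n_inflammatory=5,
            n_noninflammatory=0,
            n_background=15,
            noise_sd=(8.0 - 4.0) / 3.0,
            effect=1.0,
            seed=7,
        )
        X, groups, _, truth = generate_cohort(spec)
        base = GeneSignature(
            clusters={"R": [SignatureGene(g) for g in X.index[:20]]}
        )
        report = refine_signature(X, groups, base, positive="IBD", auc_cutoff=0.70)
        selected = set(report.records.index[report.records["selected"]])
        true_genes = set(truth.index[truth["class"] == "i"])
        assert true_genes <= selected
        # background genes may sporadically pass but the bulk should not
        assert len(selected - true_genes) <= 3

    def test_cutoff_extremes(self, clean_cohort):
        X, groups, sig, _ = clean_cohort
        base = GeneSignature(
            clusters={"R": [SignatureGene(g) for g in sig.genes("i")]}
        )
        none = refine_signature(X, groups, base, positive="IBD", auc_cutoff=1.0)
        assert none.provenance["n_selected"] == 0
        non_degen = refine_signature(
            X, groups, base, positive="IBD", auc_cutoff=0.5 - 1e-9
        )
        records = non_degen.records
        assert records.loc[~records["degenerate"], "selected"].all()

    def test_cluster_mapping_and_directions(self, clean_cohort):
        """Reactive-origin genes land in the inflammatory refined cluster."""
        X, groups, _, truth = clean_cohort
        base = GeneSignature(
            clusters={
                "R": [SignatureGene(g) for g in truth.index[truth["class"] == "i"]],
                "T1": [SignatureGene(g) for g in truth.index[truth["class"] == "ni"]],
            }
        )
        report = refine_signature(X, groups, base, positive="IBD")
        assert set(report.refined.clusters) == {"iColAM", "niColAM"}
        i_dirs = {sg.direction for sg in report.refined.clusters["iColAM"]}
        ni_dirs = {sg.direction for sg in report.refined.clusters["niColAM"]}
        assert i_dirs == {"Up"}
        assert ni_dirs == {"Down"}

    def test_no_base_genes_present_raises(self, clean_cohort):
        X, groups, _, _ = clean_cohort
        base = GeneSignature(clusters={"R": [SignatureGene("NOT_A_GENE")]})
        with pytest.raises(ValueError, match="no base signature genes"):
            refine_signature(X, groups, base, positive="IBD")

    def test_degenerate_genes_never_selected(self, clean_cohort):
        X, groups, _, _ = clean_cohort
        X = X.copy()
        X.loc["FLAT"] = 5.0
        base = GeneSignature(
            clusters={"R": [SignatureGene("FLAT"), SignatureGene(X.index[0])]}
        )
        report = refine_signature(X, groups, base, positive="IBD")
        assert report.records.loc["FLAT", "degenerate"]
        assert not report.records.loc["FLAT", "selected"]


def test_permutation_null_matches_observed_null_rate():
    """Label permutation reproduces the false-positive rate of null genes."""
    spec = SyntheticSpec(
        n_per_group=15,
        n_inflammatory=0,
        n_noninflammatory=0,
        n_background=100,
        effect=0.0,
        seed=11,
    )
    X, groups, _, _ = generate_cohort(spec)
    counts = permutation_null_counts(
        X, groups, list(X.index), positive="IBD", n_permutations=100, seed=3
    )
    base = GeneSignature(clusters={"R": [SignatureGene(g) for g in X.index]})
    observed = refine_signature(X, groups, base, positive="IBD").provenance[
        "n_selected"
    ]
    lo, hi = np.percentile(counts, [2.5, 97.5])
    assert lo - 1 <= observed <= hi + 1
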