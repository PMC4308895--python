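import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from exprvar.classify import (AUCSummary, FeatureSpec, build_feature_spec,
                              compute_auc, cross_cohort_classify,
                              median_distance_features)
from exprvar.differential import differential_variability
from exprvar.errors import ValidationError
from exprvar.simulate import SyntheticSpec, generate_cohorts


class TestMedianDistanceFeatures:
    def test_hand_example(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 10.0]], index=["g1"],
                         columns=list("abcd"))
        out = median_distance_features(m, ["g1"])
        assert out.loc["g1"].tolist() == [1.5, 0.5, 0.5, 7.5]

    def test_constant_gene_all_zero(self):
        m = pd.DataFrame([[4.0] * 5], index=["g1"], columns=list("abcde"))
        assert (median_distance_features(m, ["g1"]) == 0).all().all()

    def test_matches_per_gene_loop(self, rng):
        m = pd.DataFrame(rng.normal(8, 1, (200, 15)),
                         index=[f"g{i}" for i in range(200)],
                         columns=[f"s{j}" for j in range(15)])
        out = median_distance_features(m, list(m.index))
        for gene in m.index[::20]:
            med = float(np.median(m.loc[gene]))
            expect = np.abs(m.loc[gene].to_numpy() - med)
            assert np.abs(out.loc[gene].to_numpy() - expect).max() < 1e-12

    def test_missing_gene_named(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="gX"):
            median_distance_features(m, ["gX"])


class TestComputeAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_pairwise_enumeration(self):
        # positives (0.9, 0.3), negatives (0.8, 0.1): 3 of 4 pairs concordant
        assert compute_auc([0.9, 0.3, 0.8, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding makes ties
            assert compute_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_label_independent_scores_near_half(self, rng):
        labels = rng.uniform(size=10_000) < 0.4
        scores = rng.normal(size=10_000)
        assert 0.47 <= compute_auc(scores, labels) <= 0.53

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_negating_scores_flips_auc(self, seed):
        r = np.random.default_rng(seed)
        n = 20
        labels = np.arange(n) < 7
        scores = r.normal(size=n)
        assert compute_auc(-scores, labels) == pytest.approx(
            1 - compute_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_auc([0.1, 0.2], [1, 1])


class TestBuildFeatureSpec:
    def test_random_source_deterministic(self):
        shared = [f"g{i}" for i in range(100)]
        s1 = build_feature_spec("expression", "random", k=10,
                                shared_genes=shared, seed=4)
        s2 = build_feature_spec("expression", "random", k=10,
                                shared_genes=shared, seed=4)
        assert s1.genes == s2.genes
        s3 = build_feature_spec("expression", "random", k=10,
                                shared_genes=shared, seed=5)
        assert s3.genes != s1.genes

    def test_top_de_with_too_large_k_reports_count(self, small_cohorts):
        from exprvar.differential import differential_expression
        de = differential_expression(small_cohorts["m1"], small_cohorts["g1"])
        n_sig = int((de["q"] < 0.05).sum())
        with pytest.raises(ValidationError, match=str(n_sig)):
            build_feature_spec("expression", "top_de", k=n_sig + 1,
                               shared_genes=list(small_cohorts["m1"].index),
                               de_table=de)

    def test_top_dv_cv_list_recovers_true_dv_genes(self, small_cohorts):
        dv = differential_variability(small_cohorts["m1"], small_cohorts["g1"])
        spec = build_feature_spec("median_distance", "top_dv_cv", k=20,
                                  shared_genes=list(small_cohorts["m1"].index),
                                  dv_table=dv)
        overlap = len(set(spec.genes) & small_cohorts["truth"].dv_genes)
        assert overlap >= 16

    def test_unknown_source_rejected(self):
        with pytest.raises(ValidationError, match="unknown feature source"):
            build_feature_spec("expression", "best", shared_genes=["g1"])


@pytest.fixture(scope="module")
def cohorts():
    spec = dataclasses.replace(SyntheticSpec(), n_genes=300, frac_de=0.0,
                               seed=17)
    m1, g1, m2, g2, truth = generate_cohorts(spec)
    return m1, g1, m2, g2, truth


class TestCrossCohortClassify:
    def test_perfectly_separated_features_reach_ceiling(self, cohorts):
        m1, g1, *_ = cohorts
        m = m1.copy()
        m.loc["g000001"] = np.where(g1.reindex(m.columns) == "U", 12.0, 4.0)
        spec = FeatureSpec(kind="expression", genes=("g000001",))
        out = cross_cohort_classify(m, g1, m, g1, spec, n_trees=25,
                                    n_repeats=3, seed=0)
        assert out.mean >= 0.99

    def test_reproducible_given_seed(self, cohorts):
        m1, g1, m2, g2, truth = cohorts
        spec = FeatureSpec(kind="median_distance",
                           genes=tuple(sorted(truth.dv_genes)[:10]))
        a = cross_cohort_classify(m1, g1, m2, g2, spec, n_trees=25,
                                  n_repeats=4, seed=8)
        b = cross_cohort_classify(m1, g1, m2, g2, spec, n_trees=25,
                                  n_repeats=4, seed=8)
        assert np.array_equal(a.aucs, b.aucs)

    def test_label_independent_features_score_near_chance(self):
        """Null cohorts + random genes: mean AUC within the chance band."""
        aucs = []
        for seed in range(5):
            spec = dataclasses.replace(SyntheticSpec(), n_genes=200,
                                       frac_dv=0.0, frac_de=0.0, seed=40 + seed)
            m1, g1, m2, g2, _ = generate_cohorts(spec)
            fspec = build_feature_spec("expression", "random", k=50,
                                       shared_genes=list(m1.index), seed=seed)
            out = cross_cohort_classify(m1, g1, m2, g2, fspec, n_trees=25,
                                        n_repeats=10, seed=seed)
            aucs.append(out.mean)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_summary_statistics_consistent(self):
        s = AUCSummary(aucs=np.array([0.5, 0.7, 0.6, 0.9]))
        assert s.min <= s.median <= s.max
        assert s.mean == pytest.approx(0.675)
        assert s.n_repeats == 4

    def test_mismatched_labels_rejected(self, cohorts):
        m1, g1, m2, g2, truth = cohorts
        bad = g2.map({"M": "X", "U": "Y"})
        spec = FeatureSpec(kind="expression", genes=(m1.index[0],))
        with pytest.raises(ValidationError, match="labels differ"):
            cross_cohort_classify(m1, g1, m2, bad, spec, n_trees=5,
                                  n_repeats=1, seed=0)
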