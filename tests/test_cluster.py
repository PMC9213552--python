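"""Consensus k-means, Fisher enrichment, human ICM staging."""

import numpy as np
import pytest

from icmcoord import (HumanMixtureConfig, InputError, adjusted_rand_index,
                      anchor_cluster_enrichment, classify_human_icm, fit_pca,
                      log2_transform, repeated_kmeans, simulate_human_mixture)
from icmcoord.cluster import ClusterResult
from icmcoord.simulate import HUMAN_TE_MARKERS
from oracles import ari_oracle, fisher_exact_p


def two_blobs(rng, n=20, sep=5.0):
    a = rng.normal(size=(n, 2)) * 0.3
    b = rng.normal(size=(n, 2)) * 0.3 + sep
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


class TestRepeatedKmeans:
    def test_separable_blobs_recovered_with_full_agreement(self, rng):
        points, truth = two_blobs(rng)
        res = repeated_kmeans(points, k=2, n_restarts=25, seed=0)
        assert res.consensus_agreement == 1.0
        assert adjusted_rand_index(res.labels, truth) == 1.0

    def test_invariant_to_input_order_and_seed_when_separable(self, rng):
        points, truth = two_blobs(rng)
        perm = rng.permutation(len(points))
        res_a = repeated_kmeans(points, k=2, n_restarts=10, seed=1)
        res_b = repeated_kmeans(points[perm], k=2, n_restarts=10, seed=99)
        assert adjusted_rand_index(res_a.labels[perm], res_b.labels) == 1.0

    def test_one_dimensional_bimodal_stable_across_seeds(self, rng):
        """NANOG-like high/low intensities: the 2-cluster allocation is
        reproducible over independent restarts and seeds (the convention
        used to call NANOG-high vs NANOG-low nuclei)."""
        intensities = np.concatenate([rng.normal(1.0, 0.15, 40),
                                      rng.normal(2.2, 0.2, 25)])
        runs = [repeated_kmeans(intensities, k=2, n_restarts=250, seed=s)
                for s in (0, 1)]
        assert adjusted_rand_index(runs[0].labels, runs[1].labels) == 1.0
        assert runs[0].consensus_agreement > 0.99

    def test_all_identical_points_single_cluster_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            res = repeated_kmeans(np.ones((5, 2)), k=2, n_restarts=3, seed=0)
        assert set(res.labels) == {0}

    def test_k_exceeding_distinct_points_rejected(self):
        points = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(InputError):
            repeated_kmeans(points, k=3, n_restarts=2, seed=0)

    def test_deterministic_given_seed(self, rng):
        points = rng.normal(size=(30, 2))
        a = repeated_kmeans(points, k=2, n_restarts=20, seed=5)
        b = repeated_kmeans(points, k=2, n_restarts=20, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestAnchorEnrichment:
    def _result(self, labels):
        return ClusterResult(labels=np.asarray(labels), k=2, n_restarts=1,
                             consensus_agreement=1.0, seed=0)

    @pytest.mark.parametrize("labels,positive,expected", [
        ([0] * 10 + [1] * 10, [True] * 10 + [False] * 10, 2 / 184756),
        ([0, 0, 1, 1], [True, True, False, False], 2 / 6),
        ([0] * 5 + [1] * 5 + [0] * 5 + [1] * 5,
         [True] * 10 + [False] * 10, 1.0),
    ])
    def test_small_tables_match_enumeration(self, labels, positive, expected):
        res = anchor_cluster_enrichment(self._result(labels),
                                        np.asarray(positive))
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_matches_hypergeometric_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 31))
            labels = rng.integers(0, 2, n)
            positive = rng.random(n) < rng.uniform(0.2, 0.8)
            if len(set(labels)) < 2:
                continue
            res = anchor_cluster_enrichment(self._result(labels), positive)
            assert res.p_value == pytest.approx(
                fisher_exact_p(res.contingency), rel=1e-9)

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            res = anchor_cluster_enrichment(self._result([0, 0, 1, 1]),
                                            np.array([True] * 4))
        assert res.p_value == 1.0


class TestAdjustedRandIndex:
    def test_matches_contingency_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 4, n)
            assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a, b))


@pytest.fixture(scope="module")
def staged():
    m, ann = simulate_human_mixture(HumanMixtureConfig(seed=8))
    pca = fit_pca(log2_transform(m), n_components=3, seed=0, tol=1e-7)
    res = classify_human_icm(m, ann, pca, te_markers=HUMAN_TE_MARKERS, seed=0)
    return m, ann, res


class TestClassifyHumanIcm:

    def test_recovers_planted_populations(self, staged):
        m, ann, res = staged
        truth = ann.set_index("cell_id")["population"].map(
            {"TE": "TE", "ICMp": "ICMp", "Epi": "ICMd", "PrE": "ICMd"})
        keep = res.labels != "discarded_no_TE_embryo"
        ari = adjusted_rand_index(truth[keep.index[keep]], res.labels[keep])
        assert ari >= 0.95

    def test_every_cell_gets_exactly_one_label(self, staged):
        m, _, res = staged
        assert set(res.labels.index) == set(m.cell_ids)
        assert set(res.labels) <= {"TE", "discarded_no_TE_embryo", "ICMp", "ICMd"}

    def test_no_te_embryos_fully_discarded_from_progenitor_cluster(self, staged):
        m, ann, res = staged
        embryo = ann.set_index("cell_id")["embryo_id"]
        te_embryos = set(embryo[res.labels.index[res.labels == "TE"]])
        for cell in res.labels.index[res.labels == "ICMp"]:
            assert embryo[cell] in te_embryos
        for cell in res.discarded_no_te:
            assert embryo[cell] not in te_embryos

    def test_vacuous_te_markers_warn_and_pass_everyone(self):
        m, ann = simulate_human_mixture(HumanMixtureConfig(seed=9))
        zeroed = m.copy()
        for g in HUMAN_TE_MARKERS:
            zeroed.values[:, zeroed.gene_index(g)] = 0.0
        pca = fit_pca(log2_transform(zeroed), n_components=3, seed=0, tol=1e-6)
        with pytest.warns(UserWarning, match="no TE cluster"):
            res = classify_human_icm(zeroed, ann, pca,
                                     te_markers=HUMAN_TE_MARKERS, seed=0)
        assert "TE" not in set(res.labels)

    def test_deterministic_given_seed(self, staged):
        m, ann, res = staged
        pca = fit_pca(log2_transform(m), n_components=3, seed=0, tol=1e-7)
        res2 = classify_human_icm(m, ann, pca, te_markers=HUMAN_TE_MARKERS,
                                  seed=0)
        assert res.labels.equals(res2.labels)
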