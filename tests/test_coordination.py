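"""Anchor signatures, Spearman machinery and coordination summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from icmcoord import (InputError, build_signature, compare_coordination,
                      coordination_fraction, spearman, threshold_for_n,
                      transfer_signature)
from icmcoord.coordination import discretize, pairwise_spearman
from conftest import make_matrix
from oracles import spearman_exact_perm_p, spearman_rho_oracle


class TestSpearman:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
        ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
        ([1, 2, 3, 5], [3, 1, 2, 4], None),  # checked against oracle below
    ])
    def test_monotone_and_oracle_cases(self, x, y, expected):
        res = spearman(x, y)
        if expected is not None:
            assert res.rho == pytest.approx(expected)
        assert res.rho == pytest.approx(spearman_rho_oracle(x, y))

    def test_classical_d_squared_example(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) on a tie-free permutation
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 2, 5, 4]
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        expected = 1 - 6 * d2 / (5 * 24)
        assert spearman(x, y).rho == pytest.approx(expected)

    def test_matches_scipy_on_random_fixtures(self, rng):
        for _ in range(100):
            n = rng.integers(4, 11)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.5:      # inject ties
                x = np.round(x)
            res = spearman(x, y)
            ref_rho, ref_p = spearmanr(x, y)
            if np.isnan(ref_rho):
                assert np.isnan(res.rho)
                continue
            assert res.rho == pytest.approx(ref_rho, abs=1e-12)
            assert res.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_exact_permutation_null_agrees_at_small_n(self, rng):
        """The t-approximate p tracks the exhaustive permutation p at n<=7."""
        diffs = []
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            res = spearman(x, y)
            diffs.append(abs(res.p_value - spearman_exact_perm_p(x, y)))
        assert np.median(diffs) < 0.06

    def test_masked_pairs_dropped(self):
        x = [1, 2, 3, 4, np.nan]
        y = [10, 20, 30, 40, 0]
        assert spearman(x, y).n == 4

    def test_too_few_pairs_raise(self):
        with pytest.raises(InputError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.rho)


class TestThresholdForN:
    def test_published_values(self):
        assert threshold_for_n(40, "published_table") == 0.3
        assert threshold_for_n(33, "published_table") == 0.345

    def test_unlisted_n_refused_with_pointer(self):
        with pytest.raises(InputError, match="t_approx"):
            threshold_for_n(50, "published_table")

    def test_t_approx_is_root_of_p_curve(self):
        from scipy.stats import t as t_dist

        for n in (33, 40, 50):
            thr = threshold_for_n(n, "t_approx")
            stat = thr * np.sqrt((n - 2) / (1 - thr**2))
            assert 2 * t_dist.sf(stat, n - 2) <= 0.05
            below = thr - 0.001
            stat_b = below * np.sqrt((n - 2) / (1 - below**2))
            assert 2 * t_dist.sf(stat_b, n - 2) > 0.05


class TestDiscretize:
    def test_three_level_rule(self):
        rho = np.array([[1.0, 0.35, -0.31, 0.2]] * 4)
        out = discretize(rho, 0.3)
        assert out[1, 1] == 1  # diagonal forced to 1
        assert out[0, 1] == 1 and out[0, 2] == -1 and out[0, 3] == 0


class TestBuildSignature:
    def _copycat_matrix(self, rng, n=200):
        anchor = rng.normal(size=n)
        a = anchor + 0.1 * rng.normal(size=n)
        b = -anchor + 0.1 * rng.normal(size=n)
        c = rng.normal(size=n)
        d = rng.normal(size=n)
        return make_matrix(np.column_stack([anchor, a, b, c, d]),
                           genes=["anchor", "A", "B", "C", "D"])

    def test_copycat_genes_selected_with_signs(self, rng):
        m = self._copycat_matrix(rng)
        sig = build_signature(m, "anchor", 0.3)
        by_gene = {g: s for g, _, _, s in sig.correlates}
        assert by_gene.get("A") == 1 and by_gene.get("B") == -1
        assert "C" not in by_gene and "D" not in by_gene
        block = sig.discretized[:3, :3]  # anchor, A, B all inter-correlated
        assert np.all(np.abs(block) == 1)

    def test_pairwise_matches_spearman_oracle(self, rng):
        m = self._copycat_matrix(rng)
        sig = build_signature(m, "anchor", 0.3)
        for i, gi in enumerate(sig.matrix_genes):
            for j, gj in enumerate(sig.matrix_genes):
                expected = spearman_rho_oracle(m.gene_values(gi),
                                               m.gene_values(gj))
                assert sig.pairwise_rho[i, j] == pytest.approx(expected)

    def test_gene_order_invariance(self, rng):
        m = self._copycat_matrix(rng)
        shuffled = m.subset(genes=["D", "B", "anchor", "C", "A"])
        a = build_signature(m, "anchor", 0.3)
        b = build_signature(shuffled, "anchor", 0.3)
        assert sorted(a.correlate_genes) == sorted(b.correlate_genes)

    def test_monotone_transform_invariance(self, rng):
        m = self._copycat_matrix(rng)
        m.values -= m.values.min() - 1.0
        transformed = make_matrix(np.log(m.values), genes=m.gene_ids)
        a = build_signature(m, "anchor", 0.3)
        b = build_signature(transformed, "anchor", 0.3)
        assert a.correlate_genes == b.correlate_genes
        assert np.allclose(a.pairwise_rho, b.pairwise_rho)

    def test_uncorrelated_anchor_warns_empty(self, rng):
        vals = rng.normal(size=(40, 3))
        m = make_matrix(vals, genes=["anchor", "x", "y"])
        sig = build_signature(m, "anchor", 0.99)
        assert sig.correlates == [] and sig.discretized.size == 0


class TestTransferSignature:
    def test_self_transfer_reproduces_build(self, coordinated_dataset):
        m, _ = coordinated_dataset
        sig = build_signature(m, "Fgf4", 0.3)
        tr = transfer_signature(m, sig.matrix_genes, 0.3, anchor="Fgf4")
        assert tr.matrix_genes == sig.matrix_genes
        assert np.allclose(tr.pairwise_rho, sig.pairwise_rho, equal_nan=True)
        assert np.array_equal(tr.discretized, sig.discretized)

    def test_absent_genes_dropped_with_warning(self, coordinated_dataset):
        m, _ = coordinated_dataset
        with pytest.warns(UserWarning, match="dropped"):
            tr = transfer_signature(m, ["Fgf4", "Nanog", "NOTAGENE"], 0.3)
        assert tr.matrix_genes == ["Fgf4", "Nanog"]

    def test_too_few_transferable_genes_error(self, coordinated_dataset):
        m, _ = coordinated_dataset
        with pytest.raises(InputError):
            with pytest.warns(UserWarning):
                transfer_signature(m, ["Fgf4", "NOPE"], 0.3)


class TestCoordinationFraction:
    @pytest.mark.parametrize("fill,expected", [(0, 0.0), (1, 1.0), (-1, 1.0)])
    def test_extremes(self, fill, expected):
        from icmcoord.coordination import SignatureResult

        disc = np.full((4, 4), fill, dtype=int)
        np.fill_diagonal(disc, 1)
        sig = SignatureResult(anchor="a", n_cells=40, rho_threshold=0.3,
                              correlates=[], matrix_genes=list("abcd"),
                              pairwise_rho=disc.astype(float), discretized=disc)
        assert coordination_fraction(sig).fraction_significant_pairs == expected

    def test_cross_regime_delta(self, coordinated_dataset, independent_dataset):
        mc, _ = coordinated_dataset
        mi, _ = independent_dataset
        sig = build_signature(mc, "Fgf4", 0.3)
        tr = transfer_signature(mi, sig.matrix_genes, 0.3)
        cmpd = compare_coordination(sig, tr)
        assert cmpd.cross_regime_delta == pytest.approx(
            coordination_fraction(sig).fraction_significant_pairs
            - coordination_fraction(tr).fraction_significant_pairs)
        assert cmpd.cross_regime_delta > 0.3


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=5, max_size=12, unique=True),
       st.randoms(use_true_random=False))
def test_spearman_symmetry_and_bounds(xs, rnd):
    """|rho| <= 1 and rho(x, y) == rho(y, x) on arbitrary tie-free data."""
    ys = list(xs)
    rnd.shuffle(ys)
    a = spearman(xs, ys)
    b = spearman(ys, xs)
    assert -1.0 <= a.rho <= 1.0
    assert a.rho == pytest.approx(b.rho)


def test_pairwise_spearman_handles_masks(rng):
    vals = rng.normal(size=(30, 5))
    mask = rng.random((30, 5)) < 0.15
    m = make_matrix(vals, mask=mask)
    rho = pairwise_spearman(m)
    nan_vals = m.nan_values()
    for i in range(5):
        for j in range(i + 1, 5):
            keep = ~(np.isnan(nan_vals[:, i]) | np.isnan(nan_vals[:, j]))
            ref = spearmanr(nan_vals[keep, i], nan_vals[keep, j])[0]
            assert rho[i, j] == pytest.approx(ref, abs=1e-12)
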