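"""Nonparametric group tests against enumeration and reference oracles."""

import shutil
import subprocess

import numpy as np
import pytest

from icmcoord import (boxplot_stats, fligner_killeen,
                      kruskal_wallis_with_pairwise, wilcoxon_rank_sum)
from oracles import fligner_oracle, quartiles_oracle, wilcoxon_exact_p


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_sample_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_exact_mode_matches_enumeration(self, rng):
        for _ in range(60):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            a, b = pooled[:n1], pooled[n1:]
            res = wilcoxon_rank_sum(a, b)
            assert res.mode == "exact"
            assert res.p_value == pytest.approx(wilcoxon_exact_p(a, b))

    def test_asymptotic_mode_tracks_enumeration_just_past_cutoff(self, rng):
        """At combined n = 13 (asymptotic mode) the tie-corrected normal
        approximation stays close to the exhaustive enumeration."""
        gaps = []
        for _ in range(20):
            pooled = rng.choice(1000, size=13, replace=False).astype(float)
            a, b = pooled[:6], pooled[6:]
            res = wilcoxon_rank_sum(a, b)
            assert res.mode == "asymptotic_tie_corrected"
            gaps.append(abs(res.p_value - wilcoxon_exact_p(a, b)))
        assert np.median(gaps) < 0.01
        assert max(gaps) < 0.05

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=7) + 0.5
        raw = wilcoxon_rank_sum(a, b)
        trans = wilcoxon_rank_sum(np.exp(a), np.exp(b))
        assert raw.p_value == pytest.approx(trans.p_value)

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1], [1, 2])


class TestKruskalWallis:
    def test_identical_constant_groups_no_pairwise(self):
        rep = kruskal_wallis_with_pairwise([[1, 1], [1, 1], [1, 1]])
        assert rep.omnibus.p_value == 1.0
        assert rep.pairwise == {}

    def test_separated_groups_gate_opens(self, rng):
        groups = [rng.normal(loc, 0.2, 8) for loc in (0, 3, 6)]
        rep = kruskal_wallis_with_pairwise(groups)
        assert rep.omnibus.p_value < 0.01
        assert set(rep.pairwise) == {(0, 1), (0, 2), (1, 2)}
        assert all(r.p_value < 0.05 for r in rep.pairwise.values())

    def test_gate_alpha_one_always_runs_pairwise(self, rng):
        groups = [rng.normal(0, 1, 5) for _ in range(3)]
        rep = kruskal_wallis_with_pairwise(groups, alpha=1.0)
        assert len(rep.pairwise) == 3

    def test_holm_adjustment_monotone(self, rng):
        groups = [rng.normal(loc, 0.5, 8) for loc in (0, 2, 4)]
        raw = kruskal_wallis_with_pairwise(groups)
        adj = kruskal_wallis_with_pairwise(groups, holm=True)
        for pair in raw.pairwise:
            assert adj.pairwise[pair].p_value >= raw.pairwise[pair].p_value - 1e-15


class TestFlignerKilleen:
    def test_identical_groups_zero_statistic(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = fligner_killeen(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_scale_difference_detected(self, rng):
        a = rng.normal(0, 1, 20)
        b = 10 * (a - np.median(a)) + np.median(a)
        res = fligner_killeen(a, b)
        assert res.p_value < 1e-4

    def test_matches_direct_formula_on_random_fixtures(self, rng):
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 2), int(rng.integers(5, 15)))
            b = rng.normal(0, rng.uniform(0.5, 2), int(rng.integers(5, 15)))
            res = fligner_killeen(a, b)
            stat, p = fligner_oracle(a, b)
            assert res.statistic == pytest.approx(stat, abs=1e-6)
            assert res.p_value == pytest.approx(p, abs=1e-6)

    def test_constant_data_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = fligner_killeen([1, 1, 1], [1, 1, 1])
        assert res.p_value == 1.0

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_agrees_with_r_reference(self, rng, tmp_path):
        """Cross-check against R's fligner.test on 12 random fixtures in a
        single batched Rscript call."""
        fixtures = []
        for _ in range(12):
            a = rng.normal(0, rng.uniform(0.5, 2), int(rng.integers(6, 14)))
            b = rng.normal(0, rng.uniform(0.5, 3), int(rng.integers(6, 14)))
            fixtures.append((a, b))
        lines = ["out <- c()"]
        for a, b in fixtures:
            av = ",".join(f"{v:.17g}" for v in a)
            bv = ",".join(f"{v:.17g}" for v in b)
            lines.append(
                f"r <- fligner.test(list(c({av}), c({bv})));"
                "out <- c(out, r$statistic, r$p.value)")
        lines.append('cat(sprintf("%.12g", out), sep="\\n")')
        script = tmp_path / "fk.R"
        script.write_text("\n".join(lines))
        res = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        numbers = [float(t) for t in res.stdout.split()]
        for i, (a, b) in enumerate(fixtures):
            mine = fligner_killeen(a, b)
            assert mine.statistic == pytest.approx(numbers[2 * i], abs=1e-6)
            assert mine.p_value == pytest.approx(numbers[2 * i + 1], abs=1e-6)


class TestBoxplotStats:
    def test_centile_convention_on_1_to_100(self):
        res = boxplot_stats(np.arange(1, 101, dtype=float))
        assert res.q1 == pytest.approx(25.75)
        assert res.median == pytest.approx(50.5)
        assert res.q3 == pytest.approx(75.25)

    def test_single_value_degenerate(self):
        res = boxplot_stats([7.0])
        assert res.q1 == res.median == res.q3 == 7.0
        assert res.whisker_low == res.whisker_high == 7.0
        assert res.outliers.size == 0

    def test_symmetric_data_median_equidistant(self, rng):
        base = rng.normal(size=200)
        sym = np.concatenate([base, -base])
        res = boxplot_stats(sym)
        assert res.median == pytest.approx(0.0, abs=1e-12)
        assert res.q3 == pytest.approx(-res.q1, abs=1e-9)

    def test_outliers_beyond_whiskers(self, rng):
        values = np.concatenate([rng.normal(size=50), [25.0, -30.0]])
        res = boxplot_stats(values)
        assert set(res.outliers) == {25.0, -30.0}
        assert res.whisker_high <= res.q3 + 1.5 * (res.q3 - res.q1)

    def test_quartiles_match_direct_formula(self, rng):
        for _ in range(25):
            v = rng.normal(size=int(rng.integers(3, 40)))
            res = boxplot_stats(v)
            q1, med, q3 = quartiles_oracle(v)
            assert (res.q1, res.median, res.q3) == pytest.approx((q1, med, q3))
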