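"""Enrichment-score running sum, ranking modes, and cohort scoring."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from csflink import gsea, synthetic
from csflink.data_io import ExpressionMatrix
from csflink.gsea import RankedList, enrichment_score, rank_per_sample, rank_two_class


def es_oracle(stats, member_positions, alpha):
    """Exact rational step-by-step P_hit/P_miss running sum.

    Returns (max |deviation| as Fraction, list of (index, deviation) ties).
    alpha must be 0 or 1 so the arithmetic stays rational.
    """
    assert alpha in (0, 1)
    n = len(stats)
    members = set(member_positions)
    n_h = len(members)
    weights = {
        i: (abs(Fraction(stats[i])) if alpha == 1 else Fraction(1)) for i in members
    }
    n_r = sum(weights.values())
    if n_r == 0:
        weights = {i: Fraction(1) for i in members}
        n_r = Fraction(n_h)
    p_hit = Fraction(0)
    p_miss = Fraction(0)
    devs = []
    for i in range(n):
        if i in members:
            p_hit += weights[i] / n_r
        else:
            p_miss += Fraction(1, n - n_h)
        devs.append(p_hit - p_miss)
    peak = max(abs(d) for d in devs)
    return peak, [(i, d) for i, d in enumerate(devs) if abs(d) == peak]


def ranked(stats):
    stats = list(stats)
    return RankedList([f"G{i}" for i in range(len(stats))], stats)


class TestEnrichmentScore:
    def test_tied_extremes_example(self):
        # S at ranks 2 and 4 of (5,4,3,2,1), alpha=1: the running sum reaches
        # -1/3 at step 1 and +1/3 at step 2 — an exact tie in magnitude.
        result = enrichment_score(ranked([5, 4, 3, 2, 1]), {"G1", "G3"}, 1.0)
        peak, winners = es_oracle([5, 4, 3, 2, 1], [1, 3], 1)
        assert peak == Fraction(1, 3)
        assert {i for i, _ in winners} == {0, 1, 3}
        assert abs(result.es) == pytest.approx(1 / 3, abs=1e-12)

    def test_top_loaded_set_is_one(self):
        for alpha in (0.0, 0.25, 1.0):
            result = enrichment_score(ranked([5, 4, 3, 2, 1]), {"G0", "G1"}, alpha)
            assert result.es == pytest.approx(1.0)
            assert result.index == 1

    def test_bottom_loaded_set_is_minus_one(self):
        # all misses precede all hits: deviation reaches -1 after the misses
        result = enrichment_score(ranked([5, 4, 3, 2, 1]), {"G3", "G4"}, 0.0)
        assert result.es == pytest.approx(-1.0)
        assert result.index == 2

    def test_empty_and_full_sets_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(ranked([3, 2, 1]), {"X"}, 1.0)
        with pytest.raises(ValueError, match="whole ranked list"):
            enrichment_score(ranked([3, 2, 1]), {"G0", "G1", "G2"}, 1.0)

    def test_zero_weight_fallback_warns(self):
        with pytest.warns(UserWarning, match="alpha=0"):
            result = enrichment_score(ranked([1, 0, 0, -1]), {"G1", "G2"}, 1.0)
        expected = enrichment_score(ranked([1, 0, 0, -1]), {"G1", "G2"}, 0.0)
        assert result.es == expected.es

    @pytest.mark.parametrize("alpha", [0, 1])
    def test_oracle_equivalence_small_lists(self, alpha):
        """Vectorized ES equals the exact rational oracle for all subsets, N <= 6."""
        for n in range(2, 7):
            stats = [n - i for i in range(n)]
            rl = ranked(stats)
            for size in range(1, n):
                for members in itertools.combinations(range(n), size):
                    ids = {f"G{i}" for i in members}
                    result = enrichment_score(rl, ids, float(alpha))
                    peak, winners = es_oracle(stats, members, alpha)
                    assert abs(result.es) == pytest.approx(float(peak), abs=1e-12)
                    signs = {d > 0 for _, d in winners}
                    if len(signs) == 1:
                        expected = float(peak) if signs.pop() else -float(peak)
                        assert result.es == pytest.approx(expected, abs=1e-12)

    def test_reversal_symmetry(self, rng):
        """Reversing the list and negating stats mirrors the deviation profile."""
        for _ in range(20):
            n = int(rng.integers(3, 9))
            stats = np.sort(rng.standard_normal(n))[::-1]
            rl = ranked(stats.tolist())
            members = set(
                f"G{i}" for i in rng.choice(n, size=int(rng.integers(1, n)), replace=False)
            )
            rev = RankedList([f"G{i}" for i in range(n - 1, -1, -1)], -stats[::-1])
            fwd = enrichment_score(rl, members, 1.0)
            bwd = enrichment_score(rev, members, 1.0)
            assert abs(bwd.es) == pytest.approx(abs(fwd.es), abs=1e-9)

    @given(st.lists(st.integers(-20, 20), min_size=4, max_size=10, unique=True),
           st.data())
    def test_monotone_invariance_alpha_zero(self, values, data):
        """With alpha=0 the ES depends only on rank order, not on the stats."""
        values = sorted(values, reverse=True)
        n = len(values)
        size = data.draw(st.integers(1, n - 1))
        members = set(f"G{i}" for i in data.draw(
            st.permutations(range(n)).map(lambda p: p[:size])))
        rl = ranked([float(v) for v in values])
        # strictly monotone transform: affine with positive slope + cubic drift
        transformed = ranked([3.0 * v + 0.001 * v**3 + 7.0 for v in values])
        a = enrichment_score(rl, members, 0.0)
        b = enrichment_score(transformed, members, 0.0)
        assert a.es == pytest.approx(b.es, abs=1e-12)
        assert a.index == b.index

    def test_bounds(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            stats = np.sort(rng.standard_normal(n))[::-1]
            members = set(f"G{i}" for i in rng.choice(n, size=int(rng.integers(1, n)), replace=False))
            es = enrichment_score(ranked(stats.tolist()), members, 0.25).es
            assert -1.0 <= es <= 1.0


class TestRanking:
    def test_per_sample_order(self):
        expr = ExpressionMatrix(["G1", "G2", "G3"], ["S1"], [[1.0], [3.0], [2.0]])
        rl = rank_per_sample(expr, "S1")
        assert rl.gene_ids == ["G2", "G3", "G1"]

    def test_per_sample_tie_rule_lexicographic(self):
        expr = ExpressionMatrix(["G2", "G1", "G3"], ["S1"], [[5.0], [5.0], [5.0]])
        assert rank_per_sample(expr, "S1").gene_ids == ["G1", "G2", "G3"]

    def test_nan_column_rejected_at_construction(self):
        with pytest.raises(ValueError, match="finite"):
            ExpressionMatrix(["G1"], ["S1"], [[np.nan]])

    def test_signal_to_noise_with_floor(self):
        expr = ExpressionMatrix(
            ["G1"], ["a", "b", "c", "d"], [[2.0, 2.0, 1.0, 1.0]]
        )
        rl = rank_two_class(expr, [1, 1, 0, 0])
        # sd floors: 0.2*|2|=0.4 (cases), 0.2*|1|=0.2 (controls)
        assert rl.ranking_stats[0] == pytest.approx((2 - 1) / (0.4 + 0.2))

    def test_identical_distributions_score_zero(self):
        expr = ExpressionMatrix(["G1"], list("abcd"), [[1.0, 2.0, 1.0, 2.0]])
        assert rank_two_class(expr, [1, 1, 0, 0]).ranking_stats[0] == 0.0

    def test_label_flip_antisymmetry(self, rng):
        values = rng.standard_normal((10, 8))
        expr = ExpressionMatrix([f"G{i}" for i in range(10)], [f"S{j}" for j in range(8)], values)
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        fwd = gsea.signal_to_noise(values, labels)
        rev = gsea.signal_to_noise(values, 1 - labels)
        np.testing.assert_allclose(rev, -fwd, atol=1e-12)

    def test_small_class_rejected(self):
        expr = ExpressionMatrix(["G1"], list("abc"), [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="at least 2"):
            rank_two_class(expr, [1, 0, 0])


class TestScoreCohort:
    def test_range_invariant_and_shape(self, rng):
        sc = synthetic.generate(
            synthetic.SimulationConfig(n_genes=600, signature_size=10), seed=11
        )
        table = gsea.score_cohort(sc.cohort.expression, sc.truth.signatures)
        assert table.values.shape == (28, 36)
        assert np.all(table.values >= -1.0) and np.all(table.values <= 1.0)
        assert all(v == 10 for v in table.overlap_counts.values())

    def test_top_expressed_set_scores_one(self):
        values = np.array([[9.0], [8.0], [3.0], [2.0], [1.0]])
        expr = ExpressionMatrix([f"G{i}" for i in range(5)], ["S1"], values)
        table = gsea.score_cohort(expr, {"top": ["G0", "G1"]})
        assert table.values[0, 0] == pytest.approx(1.0)

    def test_missing_signature_genes_dropped(self):
        expr = ExpressionMatrix(["G1", "G2", "G3"], ["S1"], [[3.0], [2.0], [1.0]])
        table = gsea.score_cohort(expr, {"a": ["G1", "NOPE"]})
        assert table.overlap_counts["a"] == 1
        with pytest.warns(UserWarning, match="dropped"):
            table = gsea.score_cohort(expr, {"a": ["G1"], "b": ["ZZ"]})
        assert table.cell_types == ["a"]
        with pytest.raises(ValueError, match="no signature"):
            gsea.score_cohort(expr, {"b": ["ZZ"]})

    def test_planted_abundance_recovery(self):
        """Per-cell-type Spearman between ES and planted abundance exceeds 0.7."""
        from scipy.stats import spearmanr

        config = synthetic.SimulationConfig(
            n_case=56, n_control=44, n_genes=2000, signature_size=30
        )
        sc = synthetic.generate(config, seed=100)
        table = gsea.score_cohort(sc.cohort.expression, sc.truth.signatures)
        for i, cell in enumerate(table.cell_types):
            rho = spearmanr(
                table.values[i], sc.truth.abundances.loc[cell].to_numpy()
            ).statistic
            assert rho > 0.7, cell
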