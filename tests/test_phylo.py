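"""Distances, neighbor joining, bootstrap and Newick round-trips."""

import numpy as np
import pytest

from stsclades import (
    Alignment,
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    jtt_ml_distance,
    make_model_tree,
    newick_read,
    newick_write,
    nj_tree,
    p_distance,
    pairwise_sites,
    poisson_distance,
)
from stsclades.phylo import AA_ORDER, DistanceError, NewickError

AA = list(AA_ORDER)


def simulate_pair(model, t, n_sites, seed):
    """Draw an ancestral/descendant pair under the model at divergence t."""
    rng = np.random.default_rng(seed)
    a = rng.choice(20, size=n_sites, p=model.freqs)
    P = model.transition_matrix(t)
    cdf = np.cumsum(P, axis=1)
    b = (rng.random(n_sites)[:, None] > cdf[a]).sum(axis=1)
    return (
        "".join(AA[i] for i in a),
        "".join(AA[i] for i in b),
    )


class TestPairwiseSites:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AC-D", "A-CD", [0, 3]),
            ("ACDE", "ACDE", [0, 1, 2, 3]),
            ("----", "AAAA", []),
            ("AXCD", "AACD", [0, 2, 3]),  # X removed like a gap
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_sites(a, b).tolist() == expected

    def test_length_mismatch(self):
        with pytest.raises(DistanceError):
            pairwise_sites("AA", "AAA")


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACDEF", "ACDEF") == 0.0

    def test_half(self):
        assert p_distance("AC", "AD") == 0.5

    def test_undefined(self):
        assert np.isnan(p_distance("--", "AA"))

    def test_matches_bruteforce_columns(self, rng):
        a = "".join(rng.choice(AA + ["-"], 120))
        b = "".join(rng.choice(AA + ["-"], 120))
        shared = [
            i for i in range(120) if a[i] not in "-X" and b[i] not in "-X"
        ]
        expected = sum(a[i] != b[i] for i in shared) / len(shared)
        assert p_distance(a, b) == pytest.approx(expected)

    def test_poisson_correction(self):
        p = p_distance("AACC", "AACD")
        assert poisson_distance("AACC", "AACD") == pytest.approx(-np.log(1 - p))


class TestJttDistance:
    def test_identical_pair_is_zero(self, jtt):
        seq = "".join(np.random.default_rng(0).choice(AA, 100))
        assert jtt_ml_distance(seq, seq, jtt) == pytest.approx(0.0, abs=1e-6)

    def test_all_gap_overlap_undefined(self, jtt):
        assert np.isnan(jtt_ml_distance("AA--", "--AA", jtt))

    @pytest.mark.parametrize("t_true", [0.1, 0.3, 0.5])
    def test_simulation_recovery(self, jtt, t_true):
        a, b = simulate_pair(jtt, t_true, 10_000, seed=int(t_true * 1000))
        est = jtt_ml_distance(a, b, jtt)
        assert est == pytest.approx(t_true, rel=0.10)

    def test_small_t_limit_equals_p_distance(self, jtt):
        # at p <= 0.02 multiple hits are negligible: d ~ p / mean-rate (=1)
        a, b = simulate_pair(jtt, 0.015, 20_000, seed=5)
        p = p_distance(a, b)
        assert p <= 0.02
        assert jtt_ml_distance(a, b, jtt) == pytest.approx(p, rel=0.05)

    def test_monotone_in_mismatches(self, jtt):
        base = "".join(np.random.default_rng(3).choice(AA, 200))
        prev = 0.0
        seq = list(base)
        for i in range(0, 40, 5):
            seq[i] = "W" if base[i] != "W" else "Y"
            d = jtt_ml_distance(base, "".join(seq), jtt)
            assert d >= prev - 1e-9
            prev = d


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, jtt, rng):
        rows = ["".join(rng.choice(AA + ["-"], 60)) for _ in range(5)]
        aln = Alignment(ids=tuple("abcde"), rows=tuple(rows))
        for model in ("p", "poisson", jtt):
            dm = distance_matrix(aln, model)
            assert np.allclose(np.diag(dm.values), 0)
            assert np.allclose(dm.values, dm.values.T, equal_nan=True)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            DistanceMatrix(
                labels=("a", "b"),
                values=np.array([[0.0, 1.0], [2.0, 0.0]]),
                n_sites=np.ones((2, 2), int),
            )


def tip_distances(tree):
    """Path-length matrix via scikit-bio (oracle independent of NJ)."""
    dm = tree.tip_tip_distances()
    return dm


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives additive distances
        vals = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(
            labels=("A", "B", "C", "D"), values=vals, n_sites=np.full((4, 4), 1)
        )
        tree = nj_tree(dm)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == [pytest.approx(1.0)]

    def test_three_taxa_closed_form(self):
        vals = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        dm = DistanceMatrix(
            labels=("a", "b", "c"), values=vals, n_sites=np.ones((3, 3), int)
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_undefined_pair_rejected(self):
        vals = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        dm = DistanceMatrix(
            labels=("a", "b", "c"), values=vals, n_sites=np.ones((3, 3), int)
        )
        with pytest.raises(DistanceError, match="undefined"):
            nj_tree(dm)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_exact_on_random_additive_matrices(self, n_taxa):
        """Oracle: generate a tree, take its path metric, NJ must return it."""
        for trial in range(25):
            tree = make_model_tree(n_taxa, 0.3, seed=[n_taxa, trial])
            dm_true = tip_distances(tree)
            labels = tuple(str(i) for i in dm_true.ids)
            dm = DistanceMatrix(
                labels=labels,
                values=np.asarray(dm_true.data, float),
                n_sites=np.ones((n_taxa, n_taxa), int),
            )
            rebuilt = nj_tree(dm)
            assert bipartitions(rebuilt) == bipartitions(tree)
            dm_rebuilt = tip_distances(rebuilt)
            a = np.asarray(dm_true.filter(dm_rebuilt.ids).data)
            assert np.allclose(a, np.asarray(dm_rebuilt.data), atol=1e-9)

    def test_agrees_with_skbio_nj(self, rng):
        """Independent implementation cross-check on a noisy matrix."""
        import skbio

        n = 7
        tree = make_model_tree(n, 0.4, seed=99)
        base = tip_distances(tree)
        noise = rng.uniform(0, 0.02, size=(n, n))
        noisy = np.asarray(base.data) + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        labels = tuple(base.ids)
        mine = nj_tree(
            DistanceMatrix(labels=labels, values=noisy, n_sites=np.ones((n, n), int))
        )
        theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=labels))
        assert bipartitions(mine) == bipartitions(theirs)


class TestBootstrap:
    def make_signal_alignment(self):
        # every column supports AB|CD
        rows = (
            "AAAAWWWW",
            "AAAAWWWW",
            "CCCCYYYY",
            "CCCCYYYY",
        )
        return Alignment(ids=("A", "B", "C", "D"), rows=rows)

    def test_strong_signal_full_support(self):
        aln = self.make_signal_alignment()
        tree, res = bootstrap_support(aln, n_reps=10, seed=1, model="p")
        assert res.supports[frozenset({"C", "D"})] == 1.0

    def test_single_replicate_supports_binary(self, bench):
        ids = bench.alignment.ids[:6]
        aln = Alignment(ids=ids, rows=tuple(bench.alignment.row(i) for i in ids))
        _, res = bootstrap_support(aln, n_reps=1, seed=3, model="p")
        assert set(res.supports.values()) <= {0.0, 1.0}

    def test_deterministic_under_seed(self):
        aln = self.make_signal_alignment()
        _, r1 = bootstrap_support(aln, n_reps=5, seed=11, model="p")
        _, r2 = bootstrap_support(aln, n_reps=5, seed=11, model="p")
        assert r1.supports == r2.supports


class TestNewick:
    def test_round_trip(self):
        text = "(A:1.0,B:2.0,(C:3.0,D:4.0):1.0);\n"
        tree = newick_read(text)
        assert bipartitions(newick_read(newick_write(tree))) == bipartitions(tree)
        assert {t.name for t in tree.tips()} == {"A", "B", "C", "D"}

    def test_supports_preserved(self):
        text = "(A:1.0,B:2.0,(C:3.0,D:4.0)0.990:1.0);\n"
        tree = newick_read(text)
        out = newick_write(tree)
        assert "0.990" in out

    def test_malformed_input(self):
        with pytest.raises(NewickError):
            newick_read("(A:1,B:2;\n")
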