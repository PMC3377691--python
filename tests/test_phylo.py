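import itertools
import math

import numpy as np
import pytest

from homoeosort.phylo import (DistanceMatrix, FitchEngine, bootstrap_support,
                              fitch_length, ild_test, jc69_distance,
                              jc_matrix, kh_constraint_test, nj_build,
                              nni_search)
from homoeosort.seqs import Alignment
from homoeosort.trees import parse_newick

from conftest import evolve_on_tree, random_binary_tree


# ---------------------------------------------------------------------------
# distances

def test_jc69_identical_sequences_is_zero():
    assert jc69_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_jc69_matches_closed_form_at_p_ten_percent():
    a = "A" * 100
    b = "C" * 10 + "A" * 90
    assert jc69_distance(a, b) == pytest.approx(0.1073256, abs=1e-6)


def test_jc69_saturation_and_empty_overlap():
    assert math.isinf(jc69_distance("A" * 100, "C" * 80 + "A" * 20))
    with pytest.raises(ValueError):
        jc69_distance("NNNN", "ACGT")


def test_jc69_pairwise_deletion_ignores_gap_sites():
    d = jc69_distance("AC-TA", "ACNTA")
    assert d == 0.0


def test_jc_matrix_agrees_with_scalar_distance():
    aln = Alignment(["a", "b", "c"], ["ACGTACGTAC", "ACGTACGTCC",
                                      "TCGTACGAAC"])
    dm = jc_matrix(aln)
    for i, x in enumerate(aln.names):
        for j, y in enumerate(aln.names):
            if i < j:
                assert dm.matrix[i, j] == pytest.approx(
                    jc69_distance(aln.seqs[i], aln.seqs[j]))


# ---------------------------------------------------------------------------
# neighbor joining

def test_nj_three_taxa_solves_three_point_formulas():
    names = ["a", "b", "c"]
    m = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = nj_build(DistanceMatrix(names, m))
    lengths = {n.name: n.length for n in tree.leaves()}
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def test_nj_recovers_additive_topology(rng):
    for _ in range(100):
        n = int(rng.integers(4, 13))
        true = random_binary_tree(n, rng)
        names = sorted(true.leaf_names())
        d = true.patristic_distances()
        m = np.zeros((n, n))
        for i, a in enumerate(names):
            for j in range(i + 1, n):
                b = names[j]
                m[i, j] = m[j, i] = d[(min(a, b), max(a, b))]
        nj = nj_build(DistanceMatrix(names, m))
        assert set(nj.bipartitions()) == set(true.bipartitions())


def test_nj_star_matrix_is_deterministic():
    names = list("abcde")
    m = np.full((5, 5), 2.0)
    np.fill_diagonal(m, 0.0)
    t1 = nj_build(DistanceMatrix(names, m))
    t2 = nj_build(DistanceMatrix(names, m))
    assert t1.newick() == t2.newick()


def test_nj_rejects_asymmetric_and_tiny_matrices():
    with pytest.raises(ValueError):
        nj_build(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    bad = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.raises(ValueError):
        nj_build(DistanceMatrix(["a", "b", "c"], bad))


def test_distance_matrix_flags_saturation_and_caps():
    m = np.array([[0.0, np.inf], [np.inf, 0.0]])
    dm = DistanceMatrix(["a", "b"], m)
    assert dm.saturated.sum() == 2
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_single_replicate_gives_binary_support(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,e:0.1);",
                         300, rng)
    tree = bootstrap_support(aln, n_reps=1, seed=0)
    sups = {n.support for n in tree.postorder() if n.support is not None}
    assert sups <= {0.0, 100.0}


def test_bootstrap_supports_clear_split(rng):
    # two clades separated by many diagnostic sites
    aln = evolve_on_tree("((a:0.02,b:0.02):0.2,(c:0.02,d:0.02):0.2,"
                         "(e:0.02,f:0.02):0.2);", 500, rng)
    tree = bootstrap_support(aln, n_reps=100, seed=1)
    sups = [n.support for n in tree.postorder() if n.support is not None]
    assert max(sups) >= 95.0


def test_bootstrap_no_signal_alignment_has_weak_support(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,"
                         "(e:0.1,f:0.1):0.1);", 300, rng)
    codes = aln.codes.copy()
    for col in range(codes.shape[1]):  # destroy signal column by column
        codes[:, col] = codes[rng.permutation(codes.shape[0]), col]
    from homoeosort.seqs import decode
    shuffled = Alignment(aln.names, [decode(r) for r in codes])
    tree = bootstrap_support(shuffled, n_reps=100, seed=2)
    sups = sorted(n.support for n in tree.postorder()
                  if n.support is not None)
    assert np.median(sups) < 70.0


# ---------------------------------------------------------------------------
# Fitch parsimony

def test_fitch_identical_sequences_zero():
    aln = Alignment(list("abcd"), ["ACGT"] * 4)
    tree = parse_newick("((a,b),(c,d));")
    assert fitch_length(tree, aln) == 0


def test_fitch_single_informative_site():
    aln = Alignment(list("abcd"), ["A", "A", "C", "C"])
    tree = parse_newick("((a,b),(c,d));")
    assert fitch_length(tree, aln) == 1


def test_fitch_gaps_cost_nothing():
    aln = Alignment(list("abcd"), ["A", "-", "C", "N"])
    tree = parse_newick("((a,b),(c,d));")
    assert fitch_length(tree, aln) == 1


def test_fitch_matches_exhaustive_minimum(rng):
    from conftest import brute_force_fitch
    for _ in range(10):
        tree = random_binary_tree(6, rng)
        names = sorted(tree.leaf_names())
        seqs = ["".join(rng.choice(list("ACGT-"), 30)) for _ in names]
        aln = Alignment(names, seqs)
        assert fitch_length(tree, aln) == brute_force_fitch(tree, aln)


def test_fitch_invariant_to_rerooting(rng):
    tree = random_binary_tree(7, rng)
    names = sorted(tree.leaf_names())
    aln = Alignment(names, ["".join(rng.choice(list("ACGT"), 40))
                            for _ in names])
    baseline = fitch_length(tree, aln)
    assert fitch_length(tree.midpoint_root(), aln) == baseline
    shuffled = Alignment(names[::-1], [aln.row(n) for n in names[::-1]])
    assert fitch_length(tree, shuffled) == baseline


def test_nni_search_never_worsens(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,"
                         "(e:0.1,f:0.1):0.05);", 200, rng)
    from homoeosort.phylo import nj_from_alignment
    start = nj_from_alignment(aln)
    engine = FitchEngine(aln)
    refined = nni_search(start, engine)
    assert engine.length(refined) <= engine.length(start)


# ---------------------------------------------------------------------------
# ILD

def test_ild_identical_partitions_are_congruent(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,e:0.1);",
                         200, rng)
    stat, p = ild_test(aln, aln, n_reps=20, seed=0)
    assert stat == 0
    assert p == pytest.approx(1.0)


def test_ild_rejects_conflicting_topologies(rng):
    t1 = ("((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05,"
          "(e:0.05,(f:0.05,g:0.05):0.05):0.05);")
    t2 = ("((a:0.05,c:0.05):0.05,(b:0.05,d:0.05):0.05,"
          "(g:0.05,(f:0.05,e:0.05):0.05):0.05);")
    a1 = evolve_on_tree(t1, 300, rng)
    a2 = evolve_on_tree(t2, 300, rng)
    stat, p = ild_test(a1, a2, n_reps=99, seed=3)
    assert stat > 0
    assert p <= 0.05


def test_ild_input_validation(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.1,c:0.1);", 50, rng)
    with pytest.raises(ValueError):
        ild_test(aln, aln, n_reps=20, seed=0)  # < 4 taxa
    big = evolve_on_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,e:0.1);",
                         50, rng)
    with pytest.raises(ValueError):
        ild_test(big, big, n_reps=5, seed=0)  # too few replicates


# ---------------------------------------------------------------------------
# KH constraint test

def test_kh_constraint_already_true_is_null(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,"
                         "(e:0.1,f:0.1):0.1);", 400, rng)
    delta, p = kh_constraint_test(aln, {"a", "b"}, n_rell=500, seed=0)
    assert delta == 0
    assert p == pytest.approx(1.0)


def test_kh_rejects_false_sister_grouping(rng):
    aln = evolve_on_tree("((a:0.05,(c:0.05,d:0.05):0.1):0.1,"
                         "(b:0.05,(e:0.05,f:0.05):0.1):0.1,g:0.1);",
                         600, rng)
    delta, p = kh_constraint_test(aln, {"a", "b"}, n_rell=2000, seed=1)
    assert delta > 0
    assert p < 0.05


def test_kh_constant_alignment_has_no_signal():
    aln = Alignment(list("abcde"), ["AAAA"] * 5)
    delta, p = kh_constraint_test(aln, {"a", "c"}, n_rell=100, seed=0)
    assert delta == 0
    assert p == pytest.approx(1.0)


def test_kh_unsatisfiable_constraint_errors(rng):
    aln = evolve_on_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,e:0.1);",
                         100, rng)
    with pytest.raises(ValueError):
        kh_constraint_test(aln, {"a", "x"}, n_rell=100, seed=0)
    with pytest.raises(ValueError):
        kh_constraint_test(aln, {"a", "b", "c", "d"}, n_rell=100, seed=0)
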