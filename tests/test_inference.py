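import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homoeosort.inference import (GenomicComposition, LocusAssignment,
                                  assign_homoeologues,
                                  classify_hexaploid_origin,
                                  delimit_genome_clades,
                                  infer_maternal_genome,
                                  reconcile_and_infer_ploidy,
                                  summarize_reticulation)
from homoeosort.phylo import bootstrap_support
from homoeosort.trees import parse_newick

from conftest import evolve_on_tree

PLOIDY_RANK = {"2x": 1, "4x": 2, "6x": 3, "8x": 4, "unknown": 5}


# ---------------------------------------------------------------------------
# clade delimitation

def _two_genome_alignment(rng):
    newick = ("((a1:0.003,a2:0.003,a3:0.003,a4:0.003):0.025,"
              "(b1:0.003,b2:0.003,b3:0.003,b4:0.003):0.025);")
    return evolve_on_tree(newick, 800, rng)


def test_two_genomes_give_two_full_clades(rng):
    aln = _two_genome_alignment(rng)
    tree = bootstrap_support(aln, n_reps=100, seed=0)
    part = delimit_genome_clades(tree)
    assert len(part.clades) == 2
    assert sorted(m for c in part.clades for m in c.members) == aln.names
    sides = {frozenset(c.members) for c in part.clades}
    assert frozenset(["a1", "a2", "a3", "a4"]) in sides


def test_unresolved_tree_returns_single_clade_with_warning(rng, caplog):
    from homoeosort.seqs import Alignment
    aln = Alignment(list("abcde"), ["ACGTACGTAC"] * 5)
    tree = bootstrap_support(aln, n_reps=50, seed=1)
    with caplog.at_level("WARNING"):
        part = delimit_genome_clades(tree)
    assert len(part.clades) == 1
    assert sorted(part.clades[0].members) == aln.names


def test_reference_anchoring_orders_labels_by_distance(rng):
    newick = ("(((a1:0.003,a2:0.003):0.02,(e1:0.003,e2:0.003):0.02):0.01,"
              "(b1:0.003,b2:0.003):0.045);")
    aln = evolve_on_tree(newick, 1000, rng)
    tree = bootstrap_support(aln, n_reps=100, seed=2)
    part = delimit_genome_clades(tree, reference={"e1", "e2"})
    label_of = {m: c.label for c in part.clades for m in c.members}
    assert label_of["a1"] == "A"        # closest to the reference
    assert label_of["b1"] == "B"
    assert label_of["e1"] == "C"        # reference clade labelled last


# ---------------------------------------------------------------------------
# homoeologue assignment

def _partition_for(tree):
    return delimit_genome_clades(tree)


def test_tetraploid_assignment_counts_one_copy_per_genome(rng):
    aln = _two_genome_alignment(rng)
    tree = bootstrap_support(aln, n_reps=100, seed=3)
    part = _partition_for(tree)
    consensi = {n: aln.row(n) for n in ("a1", "a2", "b1", "b2")}
    out = assign_homoeologues(consensi, part, "ind", "locus")
    assert sorted(out.counts.values()) == [1, 1]


def test_sister_same_clade_consensi_merge_as_alleles(rng):
    aln = _two_genome_alignment(rng)
    tree = bootstrap_support(aln, n_reps=100, seed=4)
    part = _partition_for(tree)
    consensi = {"a1": aln.row("a1"), "a2": aln.row("a2")}
    out = assign_homoeologues(consensi, part, "ind", "locus")
    assert out.counts == {part.label_of("a1"): 1}


def test_divergent_non_sister_copies_split_into_subtypes(rng):
    newick = ("(((a1:0.002,x1:0.002):0.012,(a2:0.002,x2:0.002):0.012):0.03,"
              "(b1:0.002,b2:0.002):0.05);")
    aln = evolve_on_tree(newick, 1200, rng)
    tree = bootstrap_support(aln, n_reps=100, seed=5)
    part = delimit_genome_clades(tree)
    label = part.label_of("a1")
    assert part.label_of("a2") == label  # same genome clade
    consensi = {"a1": aln.row("a1"), "a2": aln.row("a2")}
    out = assign_homoeologues(consensi, part, "ind", "locus")
    assert out.counts[label] == 2


def test_missing_consensus_errors(rng):
    aln = _two_genome_alignment(rng)
    tree = bootstrap_support(aln, n_reps=50, seed=6)
    part = _partition_for(tree)
    with pytest.raises(KeyError):
        assign_homoeologues({"zzz": "ACGT"}, part, "ind", "locus")


# ---------------------------------------------------------------------------
# reconciliation and ploidy

def _assignment(locus, counts):
    return LocusAssignment("ind", locus, counts,
                           {k: [[f"{k}{i}"] for i in range(v)]
                            for k, v in counts.items()})


def test_diploid_reconciliation():
    comp = reconcile_and_infer_ploidy([_assignment(l, {"F": 1})
                                       for l in ("l1", "l2", "l3")])
    assert comp.labels == {"F": 1}
    assert comp.ploidy == "2x"
    assert not comp.conflict


def test_missing_locus_is_tolerated_via_maximum():
    loci = [_assignment(f"l{i}", {"F": 1, "H": 1}) for i in range(4)]
    loci.append(_assignment("l4", {"F": 1}))
    comp = reconcile_and_infer_ploidy(loci)
    assert comp.labels == {"F": 1, "H": 1}
    assert comp.ploidy == "4x"
    assert "l4" in comp.missing_loci
    assert comp.conflict


def test_four_genomes_read_as_octoploid():
    comp = reconcile_and_infer_ploidy(
        [_assignment("l1", {"I": 1, "J": 1, "K": 1, "L": 1})])
    assert comp.ploidy == "8x"
    assert comp.formula == "IJKL"


def test_more_than_four_types_is_unknown():
    comp = reconcile_and_infer_ploidy(
        [_assignment("l1", {"A": 3, "B": 2})])
    assert comp.ploidy == "unknown"


def test_reconciliation_invariant_to_locus_order():
    loci = [_assignment("l1", {"A": 1, "B": 2}),
            _assignment("l2", {"A": 2}),
            _assignment("l3", {"B": 1})]
    fwd = reconcile_and_infer_ploidy(loci)
    rev = reconcile_and_infer_ploidy(loci[::-1])
    assert fwd.labels == rev.labels
    assert fwd.ploidy == rev.ploidy


@settings(max_examples=50, derandomize=True)
@given(st.dictionaries(st.sampled_from("ABCDEF"),
                       st.integers(min_value=1, max_value=3),
                       min_size=1, max_size=4),
       st.sampled_from("GHIJ"))
def test_adding_a_genome_never_lowers_ploidy(counts, new_label):
    base = reconcile_and_infer_ploidy([_assignment("l1", counts)])
    extended = dict(counts)
    extended[new_label] = 1
    more = reconcile_and_infer_ploidy([_assignment("l1", extended)])
    assert PLOIDY_RANK[more.ploidy] >= PLOIDY_RANK[base.ploidy]


# ---------------------------------------------------------------------------
# hexaploid origin

def _hex_composition():
    return GenomicComposition(
        "hex", {"l1": {"A": 1, "B": 2}, "l2": {"A": 1, "B": 2}},
        {"A": 1, "B": 2}, "6x")


def test_hexaploid_single_locus_is_ambiguous():
    comp = GenomicComposition("hex", {"l1": {"A": 1, "B": 2}},
                              {"A": 1, "B": 2}, "6x")
    assert classify_hexaploid_origin(comp, {}, {}) == "ambiguous"


def test_hexaploid_shared_octoploid_allele_wins():
    comp = _hex_composition()
    seq = "ACGT" * 50
    verdict = classify_hexaploid_origin(
        comp, {"l1": [("A", seq)]}, {"l1": [("A", seq)]})
    assert verdict == "tetraploid×octoploid"


def test_hexaploid_two_one_pattern_means_unreduced_gamete():
    comp = _hex_composition()
    verdict = classify_hexaploid_origin(
        comp, {"l1": [("A", "AAAA")]}, {"l1": [("A", "TTTT")]})
    assert verdict == "tetraploid×tetraploid-unreduced"


def test_non_hexaploid_input_errors():
    comp = GenomicComposition("tet", {"l1": {"A": 1, "B": 1}},
                              {"A": 1, "B": 1}, "4x")
    with pytest.raises(ValueError):
        classify_hexaploid_origin(comp, {}, {})


# ---------------------------------------------------------------------------
# maternal genome

def test_maternal_matches_concordant_subtree():
    cp = parse_newick("((w:1,x:1):1,(y:1,z:1):1);")
    sub_a = parse_newick("((w:1,x:1):1,(y:1,z:1):1);")
    sub_b = parse_newick("((w:1,y:1):1,(x:1,z:1):1);")
    assert infer_maternal_genome(cp, {"A": sub_a, "B": sub_b}) == "A"


def test_maternal_tie_is_ambiguous():
    cp = parse_newick("((w:1,x:1):1,(y:1,z:1):1);")
    sub = parse_newick("((w:1,y:1):1,(x:1,z:1):1);")
    assert infer_maternal_genome(cp, {"A": sub.copy(), "B": sub.copy()}) \
        == "ambiguous"


def test_maternal_needs_four_shared_taxa():
    cp = parse_newick("((w:1,x:1):1,(y:1,z:1):1);")
    small = parse_newick("((w:1,x:1):1,y:1);")
    with pytest.raises(ValueError):
        infer_maternal_genome(cp, {"A": small, "B": small.copy()})


# ---------------------------------------------------------------------------
# reticulation summary

def test_diploids_produce_no_events():
    comps = [GenomicComposition(f"d{i}", {"l1": {"E": 1}}, {"E": 1}, "2x")
             for i in range(3)]
    assert summarize_reticulation(comps) == []


def test_shared_formula_is_one_ancestral_event():
    comps = [GenomicComposition(f"t{i}", {"l1": {"A": 1, "B": 1}},
                                {"A": 1, "B": 1}, "4x") for i in range(3)]
    events = summarize_reticulation(comps, maternal="A")
    assert len(events) == 1
    assert events[0]["parents"] == "A+B"
    assert events[0]["n_individuals"] == 3
    assert events[0]["maternal"] == "A"


def test_octoploids_get_second_round_events():
    comps = [GenomicComposition("oct", {"l1": {"A": 2, "B": 2}},
                                {"A": 2, "B": 2}, "8x")]
    events = summarize_reticulation(comps)
    kinds = [e["event"] for e in events]
    assert "hybridization" in kinds
    assert any(k.startswith("second-round") for k in kinds)
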