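import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homoeosort.clones import (CloneAlignment, CloneRecord, align_clones,
                               call_consensus, cluster_alleles,
                               detect_chimeras, detect_nontarget,
                               group_clone_fasta, process_clone_set)


def _records(seqs, individual="ind", locus="loc"):
    return [CloneRecord(f"{individual}|{locus}|c{i + 1}", individual, locus,
                        seq) for i, seq in enumerate(seqs)]


def _aln(rows, ids=None):
    ids = ids or [f"ind|loc|c{i + 1}" for i in range(len(rows))]
    return CloneAlignment("loc", "ind", ids, rows)


# ---------------------------------------------------------------------------
# alignment

def test_identical_clones_align_without_gaps():
    aln = align_clones(_records(["ACGTACGT"] * 4))
    assert aln.n_columns == 8
    assert all(set(r) <= set("ACGT") for r in aln.rows)


def test_single_deletion_introduces_three_gap_columns():
    full = "ACGTTACGGTACCA"
    deleted = full[:5] + full[8:]
    aln = align_clones(_records([full, deleted]))
    assert aln.n_columns == len(full)
    gappy = [r for r in aln.rows if "-" in r]
    assert len(gappy) == 1
    assert gappy[0].count("-") == 3


def test_substitution_only_clones_keep_original_width(rng):
    base = "".join(rng.choice(list("ACGT"), 120))
    variants = []
    for _ in range(5):
        chars = list(base)
        for pos in rng.choice(120, 4, replace=False):
            chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
        variants.append("".join(chars))
    aln = align_clones(_records(variants))
    assert aln.n_columns == 120


def test_align_rejects_empty_and_mixed_sets():
    with pytest.raises(ValueError):
        align_clones([])
    mixed = _records(["ACGT"], "a") + _records(["ACGT"], "b")
    with pytest.raises(ValueError):
        align_clones(mixed)


# ---------------------------------------------------------------------------
# off-target screening

def test_random_insert_is_flagged_and_close_clone_is_not(rng):
    base = "".join(rng.choice(list("ACGT"), 500))
    near = "C" + base[1:] if base[0] != "C" else "G" + base[1:]
    junk = "".join(rng.choice(list("ACGT"), 500))
    aln = align_clones(_records([base, base, near, junk]))
    flags = detect_nontarget(aln)
    assert flags == {"ind|loc|c4"}


def test_single_clone_is_never_flagged():
    aln = _aln(["ACGT"])
    assert detect_nontarget(aln) == set()


# ---------------------------------------------------------------------------
# allele clustering

def test_identical_clones_form_one_cluster():
    aln = _aln(["ACGTACGT"] * 8)
    clusters = cluster_alleles(aln)
    assert len(clusters) == 1
    assert clusters[0].size == 8


def test_two_clones_one_difference_merge_as_pcr_error():
    aln = _aln(["ACGTACGT", "ACGTACGA"])
    clusters = cluster_alleles(aln)
    assert len(clusters) == 1


def test_two_haplotypes_with_singleton_errors_resolve(rng):
    base = "".join(rng.choice(list("ACGT"), 300))
    hap2 = list(base)
    for pos in (10, 60, 120, 200, 280):
        hap2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hap2[pos]]
    hap2 = "".join(hap2)
    seqs = []
    for k in range(8):
        src = base if k < 4 else hap2
        chars = list(src)
        pos = int(rng.integers(300))  # one private error per clone
        chars[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[chars[pos]]
        seqs.append("".join(chars))
    clusters = cluster_alleles(_aln(seqs))
    assert len(clusters) == 2
    assert sorted(c.size for c in clusters) == [4, 4]
    assert {clusters[0].consensus, clusters[1].consensus} == {base, hap2}


def test_clusters_partition_retained_clones(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(3)]
    seqs = [seqs[int(rng.integers(3))] for _ in range(10)]
    aln = _aln(seqs)
    clusters = cluster_alleles(aln)
    members = [m for c in clusters for m in c.members]
    assert sorted(members) == sorted(aln.ids)


# ---------------------------------------------------------------------------
# consensus

def test_singleton_substitution_is_outvoted():
    aln = _aln(["ACGTACGT", "ACGTACGT", "ACGTACGG"])
    cluster = call_consensus(aln)
    assert cluster.consensus == "ACGTACGT"
    assert cluster.singleton_errors == {7: 1}


def test_single_clone_consensus_is_identity():
    aln = _aln(["AC-TACGT"])
    assert call_consensus(aln).consensus == "AC-TACGT"


def test_ties_become_iupac_ambiguity():
    aln = _aln(["ACGA", "ACGC"])
    assert call_consensus(aln).consensus == "ACGM"


def test_consensus_invariant_to_clone_order():
    rows = ["ACGTACGT", "ACGAACGT", "ACGTACGT", "ACGTACGC"]
    fwd = call_consensus(_aln(rows))
    rev = call_consensus(_aln(rows[::-1], ids=[f"ind|loc|c{i}" for i in
                                               (4, 3, 2, 1)]))
    assert fwd.consensus == rev.consensus


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.text(alphabet="ACGT", min_size=20, max_size=20),
                min_size=2, max_size=6))
def test_consensus_states_are_drawn_from_observed_columns(rows):
    cons = call_consensus(_aln(rows)).consensus
    from homoeosort.seqs import IUPAC_BITS, encode
    codes = np.vstack([encode(r) for r in rows])
    for col, state in enumerate(cons):
        union = 0
        for v in codes[:, col]:
            union |= int(v)
        assert IUPAC_BITS[state] & union == IUPAC_BITS[state]


# ---------------------------------------------------------------------------
# chimera detection

def _two_cluster_alignment(rng, n_diag=10, length=400, per_cluster=4):
    base = "".join(rng.choice(list("ACGT"), length))
    other = list(base)
    positions = sorted(rng.choice(length, n_diag, replace=False))
    for pos in positions:
        other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
    other = "".join(other)
    rows = [base] * per_cluster + [other] * per_cluster
    return base, other, positions, rows


def test_constructed_mosaic_is_called_with_breakpoint_in_interval(rng):
    base, other, positions, rows = _two_cluster_alignment(rng)
    breakpoint = (positions[4] + positions[5]) // 2 + 1
    mosaic = base[:breakpoint] + other[breakpoint:]
    aln = _aln(rows + [mosaic])
    clusters = cluster_alleles(aln)
    calls = detect_chimeras(aln, clusters)
    assert [c.clone_id for c in calls] == [aln.ids[-1]]
    call = calls[0]
    assert positions[4] < call.breakpoint <= positions[5]
    assert call.left_support >= 2 and call.right_support >= 2


def test_pure_cluster_member_is_not_called(rng):
    _, _, _, rows = _two_cluster_alignment(rng)
    aln = _aln(rows)
    clusters = cluster_alleles(aln)
    assert detect_chimeras(aln, clusters) == []


def test_fewer_than_two_clusters_yields_no_calls():
    aln = _aln(["ACGTACGT"] * 3)
    assert detect_chimeras(aln, cluster_alleles(aln)) == []


# ---------------------------------------------------------------------------
# orchestration

def test_process_clone_set_partitions_input(rng):
    base, other, _, rows = _two_cluster_alignment(rng)
    mosaic = base[:200] + other[200:]
    junk = "".join(rng.choice(list("ACGT"), 400))
    ps = process_clone_set(_records(rows + [mosaic, junk]))
    clustered = {m for c in ps.clusters for m in c.members}
    assert clustered | ps.excluded == set(ps.alignment.ids)
    assert not clustered & ps.excluded
    assert len(ps.clusters) == 2
    assert len(ps.consensi) == 2
    assert all(name.startswith("ind.t") for name, _ in ps.consensi)


def test_group_clone_fasta_parses_id_grammar():
    records = [("a|adh1|c1", "ACGT"), ("a|adh1|c2", "ACGT"),
               ("b|adh1|c1", "ACGT")]
    groups = group_clone_fasta(records)
    assert set(groups) == {("a", "adh1"), ("b", "adh1")}
    with pytest.raises(ValueError):
        group_clone_fasta([("badid", "ACGT")])
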