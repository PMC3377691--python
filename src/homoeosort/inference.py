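"""Genome-clade delimitation, homoeologue assignment, ploidy inference and
reticulation classification.

This is the interpretive layer of the pipeline: given per-locus trees of
polished consensus sequences, it delimits the deeply divergent "genome
clades" (labelled A, B, C, ...), assigns each individual's consensi to
those clades, counts distinct sequence subtypes per clade, and converts
subtype counts into a genomic formula and ploidy class (1 type -> 2x,
2 -> 4x, 3 -> 6x, 4 -> 8x). Constraint tests and chloroplast/nuclear tree
concordance then classify allo- vs autopolyploid origin and identify the
maternal (seed-parent) genome.
"""

from __future__ import annotations

import logging
import string
from collections import Counter
from dataclasses import dataclass, field

from .phylo import kh_constraint_test, _is_monophyletic
from .seqs import Alignment, p_distance
from .trees import Tree, robinson_foulds

log = logging.getLogger(__name__)

__all__ = [
    "GenomeClade", "GenomeCladePartition", "LocusAssignment",
    "GenomicComposition", "delimit_genome_clades", "harmonize_partitions",
    "assign_homoeologues", "reconcile_and_infer_ploidy",
    "classify_polyploid_origin", "classify_hexaploid_origin",
    "infer_maternal_genome", "summarize_reticulation",
]

PLOIDY_BY_TYPES = {1: "2x", 2: "4x", 3: "6x", 4: "8x"}


@dataclass
class GenomeClade:
    label: str
    members: list[str]
    support: float
    stem_length: float


@dataclass
class GenomeCladePartition:
    tree: Tree
    clades: list[GenomeClade]
    unplaced: list[str] = field(default_factory=list)

    def label_of(self, leaf: str) -> str | None:
        for clade in self.clades:
            if leaf in clade.members:
                return clade.label
        return None

    def members_of(self, label: str) -> list[str]:
        members = [m for clade in self.clades if clade.label == label
                   for m in clade.members]
        if not members:
            raise KeyError(label)
        return members


def _median(values: list[float]) -> float:
    if not values:
        return 0.0
    vals = sorted(values)
    mid = len(vals) // 2
    return vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2


def delimit_genome_clades(tree: Tree, min_support: float = 70.0,
                          stem_ratio: float = 2.0,
                          reference: set[str] | None = None
                          ) -> GenomeCladePartition:
    """Partition tree leaves into major genome clades.

    A clade qualifies if its stem bipartition has bootstrap support >=
    ``min_support`` and its stem length is at least ``stem_ratio`` times
    the median pairwise patristic distance among its leaves; maximal
    (shallowest) qualifying clades are taken. Leaves contained in no
    qualifying clade become singleton clades when their pendant edge is
    long on the same criterion, otherwise they are left unplaced.

    Labels: with ``reference`` leaves given, the non-reference clade
    nearest the reference (mean patristic distance) is "A", the rest
    follow in increasing distance, and the reference clade is labelled
    last. Without a reference, clades are labelled in ladderized traversal
    order. ``stem_ratio`` sets the scale of the partition: the default
    delimits the finest strongly supported long-stem level.
    """
    rooted = tree.copy()
    rooted.ladderize()
    dists = rooted.patristic_distances()
    all_leaves = rooted.leaf_names()

    def pair(a: str, b: str) -> float:
        return dists[(a, b) if a < b else (b, a)]

    def within_median(leaf_list: list[str]) -> float:
        return _median([pair(a, b) for i, a in enumerate(leaf_list)
                        for b in leaf_list[i + 1:]])

    def side_scale(leaf_list: list[str]) -> float:
        """Median nearest-neighbour distance within a side: the allele-
        level noise floor a clade stem must stand clear of. (The median
        *pairwise* distance would be dominated by legitimate deep
        substructure such as homoeologue subtypes within a clade.)"""
        if len(leaf_list) < 2:
            return 0.0
        return _median([min(pair(a, b) for b in leaf_list if b != a)
                        for a in leaf_list])

    # allele-scale noise floor: typical nearest-neighbour leaf distance
    nn_scale = _median([min(pair(a, b) for b in all_leaves if b != a)
                        for a in all_leaves]) if len(all_leaves) > 1 else 0.0

    # decide, per edge, whether it is a genome-clade stem; the criterion
    # is evaluated on unrooted bipartitions so the answer does not depend
    # on where the tree happens to be rooted. The clade proper is the
    # side of the edge with the smaller internal diversity.
    below: dict[int, list[str]] = {}
    candidates: dict[int, tuple[frozenset, float, float]] = {}
    for node in rooted.postorder():
        if node.is_leaf:
            below[id(node)] = [node.name]
        else:
            below[id(node)] = [x for c in node.children
                               for x in below[id(c)]]
        if node.parent is None:
            continue
        side = below[id(node)]
        other = [x for x in all_leaves if x not in set(side)]
        if not other:
            continue
        def diam(leaf_list: list[str]) -> float:
            if len(leaf_list) < 2:
                return 0.0
            return max(pair(a, b) for i, a in enumerate(leaf_list)
                       for b in leaf_list[i + 1:])

        if node.is_leaf:
            if nn_scale > 0 and node.length >= stem_ratio * nn_scale:
                fs = frozenset(side)
                candidates[id(node)] = (fs, 100.0, node.length, [fs])
            continue
        support = node.support if node.support is not None else 0.0
        sc_side, sc_other = side_scale(side), side_scale(other)
        scale = min(sc_side, sc_other)
        if (support >= min_support and node.length > 0
                and node.length >= stem_ratio * max(scale, nn_scale)):
            # the clade proper is the compact side of the edge (a genome
            # clade's diameter is small against a multi-genome remainder);
            # when the two sides are of comparable diameter the edge
            # separates two genome clades and delimits both sides at once
            diam_side, diam_other = diam(side), diam(other)
            clade_side = frozenset(side if diam_side <= diam_other else other)
            delimited = [clade_side]
            lo, hi = sorted((diam_side, diam_other))
            if hi <= 1.3 * lo:
                delimited = [frozenset(side), frozenset(other)]
            candidates[id(node)] = (clade_side, support, node.length,
                                    delimited)

    # a candidate lying inside a side delimited by another candidate's
    # edge is internal substructure (allele families within a genome
    # clade) unless its own stem is decisively longer; drop it. The 1.5x
    # margin keeps the choice of scale stable against branch-length
    # estimation noise on ~1 kb loci.
    nested_drop = set()
    for nid, (cs, _, length, _) in candidates.items():
        for oid, (_, _, olen, delimited) in candidates.items():
            if oid == nid or length > 1.5 * olen:
                continue
            if any(cs < s for s in delimited):
                nested_drop.add(nid)
                break
    candidates = {nid: v[:3] for nid, v in candidates.items()
                  if nid not in nested_drop}

    # greedy selection, longest stem first, keeping clades disjoint: a
    # genome clade's own stem is longer than the stem of any super-clade
    # grouping several genomes, so this resolves the remaining conflicts
    # at the genome-clade scale
    cut: set[int] = set()
    stems: dict[int, tuple[float, float]] = {}
    accepted: list[frozenset] = []
    order = sorted(candidates.items(),
                   key=lambda kv: (-kv[1][2], -kv[1][1], len(kv[1][0]),
                                   min(kv[1][0])))
    for nid, (side, support, length) in order:
        if any(side & other for other in accepted):
            continue
        accepted.append(side)
        cut.add(nid)
        stems[nid] = (support, length)

    if not cut:
        log.warning("no supported long-stem edge found; "
                    "returning a single-clade partition")
        clades = [GenomeClade("A", sorted(all_leaves), 0.0, 0.0)]
        return GenomeCladePartition(rooted, clades, [])

    # components of the tree after removing every qualifying stem edge
    comp_of: dict[int, int] = {id(rooted.root): 0}
    comp_stems: dict[int, tuple[float, float]] = {}
    n_comp = 1
    for node in rooted.preorder():
        if node.parent is None:
            continue
        if id(node) in cut:
            comp_of[id(node)] = n_comp
            comp_stems[n_comp] = stems[id(node)]
            n_comp += 1
        else:
            comp_of[id(node)] = comp_of[id(node.parent)]
    groups: dict[int, list[str]] = {}
    for node in rooted.postorder():
        if node.is_leaf:
            groups.setdefault(comp_of[id(node)], []).append(node.name)

    found = [(sorted(leaf_list), *comp_stems.get(comp, (0.0, 0.0)))
             for comp, leaf_list in sorted(groups.items())]
    unplaced: list[str] = []

    # deterministic base order: ladderized traversal
    order_index = {name: i for i, name in enumerate(all_leaves)}
    found.sort(key=lambda f: min(order_index[x] for x in f[0]))

    def mean_dist(set_a: list[str], set_b: list[str]) -> float:
        vals = [dists[(a, b) if a < b else (b, a)]
                for a in set_a for b in set_b if a != b]
        return sum(vals) / len(vals) if vals else 0.0

    if reference:
        ref_idx = max(range(len(found)),
                      key=lambda i: len(set(found[i][0]) & set(reference)))
        others = [i for i in range(len(found)) if i != ref_idx]
        others.sort(key=lambda i: (mean_dist(found[i][0], found[ref_idx][0]),
                                   min(found[i][0])))
        ordering = others + [ref_idx]
    else:
        ordering = list(range(len(found)))

    labels = _labels(len(found))
    clades = []
    for label, i in zip(labels, ordering):
        leaf_list, support, stem = found[i]
        clades.append(GenomeClade(label, sorted(leaf_list), support, stem))
    clades.sort(key=lambda c: c.label)
    return GenomeCladePartition(rooted, clades, sorted(unplaced))


def _labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        if i < 26:
            out.append(letters[i])
        else:
            out.append(letters[(i // 26) - 1] + letters[i % 26])
    return out


def harmonize_partitions(partitions: dict[str, GenomeCladePartition],
                         individual_of: dict[str, str]
                         ) -> dict[str, GenomeCladePartition]:
    """Make clade labels consistent across loci.

    The first locus (in dict order) anchors the lettering; clades of every
    other locus are matched to anchor clades by maximal overlap in
    *individual* membership, and unmatched clades receive fresh letters.
    Since homoeologous clades of one hybrid lineage share their carriers
    (every AB tetraploid appears in both the A and the B clade), ties in
    membership overlap are resolved in favour of the clade's own
    (reference-anchored) label.
    """
    loci = list(partitions)
    if not loci:
        return partitions
    anchor = partitions[loci[0]]
    anchor_members = {c.label: {individual_of[m] for m in c.members}
                      for c in anchor.clades}
    used = set(anchor_members)
    fresh = (lab for lab in _labels(200) if lab not in used)

    for locus in loci[1:]:
        part = partitions[locus]
        taken: set[str] = set()
        assignments: list[tuple[GenomeClade, str]] = []
        for clade in sorted(part.clades,
                            key=lambda c: (-len(c.members), c.label)):
            inds = {individual_of[m] for m in clade.members}
            best_label, best_score = None, 0.0
            for label, ref_inds in anchor_members.items():
                if label in taken:
                    continue
                inter = len(inds & ref_inds)
                if inter == 0:
                    continue
                score = inter / len(inds | ref_inds)
                if label == clade.label:
                    score += 0.5
                if score > best_score or (score == best_score
                                          and best_label is not None
                                          and label < best_label):
                    best_label, best_score = label, score
            if best_label is None:
                # no free anchor matches; if a taken anchor overlaps well,
                # this clade is an over-split fragment of it — share the
                # label (subtype counting within the label absorbs it)
                fallback, fb_score = None, 0.0
                for label, ref_inds in anchor_members.items():
                    score = len(inds & ref_inds) / len(inds | ref_inds)
                    if score > fb_score or (score == fb_score
                                            and fallback is not None
                                            and label < fallback):
                        fallback, fb_score = label, score
                if fallback is not None and fb_score >= 0.2:
                    assignments.append((clade, fallback))
                    continue
                best_label = next(fresh)
                anchor_members[best_label] = inds
            taken.add(best_label)
            assignments.append((clade, best_label))
        for clade, label in assignments:
            clade.label = label
        part.clades.sort(key=lambda c: c.label)
    return partitions


# ---------------------------------------------------------------------------
# homoeologue assignment

@dataclass
class LocusAssignment:
    individual: str
    locus: str
    counts: dict[str, int]                      # genome label -> subtype count
    subtypes: dict[str, list[list[str]]]        # label -> groups of leaf names
    uncertain: list[tuple[str, str]] = field(default_factory=list)


def _is_sister(tree: Tree, a: str, b: str) -> bool:
    """True iff no other leaf descends from the MRCA of a and b."""
    below: dict[int, set] = {}
    target = {a, b}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.name}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
        if target <= below[id(node)]:
            return below[id(node)] == target
    return False


def assign_homoeologues(consensi: dict[str, str],
                        partition: GenomeCladePartition,
                        individual: str, locus: str,
                        min_subtype_divergence: float = 0.015
                        ) -> LocusAssignment:
    """Assign one individual's consensus sequences to genome clades.

    Same-clade consensi of one individual are split into distinct
    subtypes (homoeologous copies) only when they are non-sister within
    the clade *and* at least ``min_subtype_divergence`` apart; otherwise
    they are treated as alleles of a single copy. Consensi falling in no
    clade get a lowercase compound label naming the two nearest clades
    and are excluded from ploidy arithmetic.
    """
    tree = partition.tree
    leaf_set = set(tree.leaf_names())
    for name in consensi:
        if name not in leaf_set:
            raise KeyError(f"consensus {name!r} absent from the tree")
    by_label: dict[str, list[str]] = {}
    uncertain: list[tuple[str, str]] = []
    dists = None
    for name in sorted(consensi):
        label = partition.label_of(name)
        if label is None:
            if dists is None:
                dists = tree.patristic_distances()

            def clade_dist(clade):
                vals = [dists[(name, m) if name < m else (m, name)]
                        for m in clade.members if m != name]
                return min(vals) if vals else float("inf")

            nearest = sorted(partition.clades, key=clade_dist)[:2]
            compound = "".join(sorted(c.label.lower() for c in nearest))
            uncertain.append((name, compound))
            continue
        by_label.setdefault(label, []).append(name)

    counts: dict[str, int] = {}
    subtypes: dict[str, list[list[str]]] = {}
    for label, names in sorted(by_label.items()):
        groups: list[list[str]] = []
        for name in names:
            placed = False
            for group in groups:
                rep = group[0]
                close = p_distance(consensi[name],
                                   consensi[rep]) < min_subtype_divergence
                if close or _is_sister(tree, name, rep):
                    group.append(name)
                    placed = True
                    break
            if not placed:
                groups.append([name])
        counts[label] = len(groups)
        subtypes[label] = groups
    return LocusAssignment(individual, locus, counts, subtypes, uncertain)


# ---------------------------------------------------------------------------
# ploidy reconciliation

@dataclass
class GenomicComposition:
    individual: str
    per_locus: dict[str, dict[str, int]]
    labels: dict[str, int]
    ploidy: str
    conflict: bool = False
    missing_loci: list[str] = field(default_factory=list)
    uncertain: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def formula(self) -> str:
        return "".join(lab * n for lab, n in sorted(self.labels.items()))

    @property
    def total_types(self) -> int:
        return sum(self.labels.values())


def reconcile_and_infer_ploidy(assignments: list[LocusAssignment]
                               ) -> GenomicComposition:
    """Combine per-locus assignments into one genomic composition.

    The label set is the union across loci and each label's subtype count
    the maximum across loci: a locus missing a copy is treated as
    amplification/cloning dropout, not absence. Total type count T maps to
    ploidy as 1/2/3/4 -> 2x/4x/6x/8x; T > 4 is flagged unknown. Loci that
    disagree on T raise the conflict flag. Invariant to locus order.
    """
    if not assignments:
        raise ValueError("no locus assignments")
    individual = assignments[0].individual
    per_locus = {a.locus: dict(a.counts) for a in assignments}
    labels: dict[str, int] = {}
    for a in assignments:
        for lab, n in a.counts.items():
            labels[lab] = max(labels.get(lab, 0), n)
    totals = {loc: sum(c.values()) for loc, c in per_locus.items() if c}
    conflict = len(set(totals.values())) > 1
    missing = sorted(loc for loc, c in per_locus.items()
                     if set(c) != set(labels) or
                     any(c.get(lab, 0) < n for lab, n in labels.items()))
    total = sum(labels.values())
    ploidy = PLOIDY_BY_TYPES.get(total, "unknown")
    uncertain = [(a.locus, leaf, lab)
                 for a in assignments for leaf, lab in a.uncertain]
    return GenomicComposition(individual, per_locus, labels, ploidy,
                              conflict, missing, uncertain)


# ---------------------------------------------------------------------------
# origin classification

def classify_polyploid_origin(aln: Alignment, tree: Tree,
                              partition: GenomeCladePartition,
                              composition: GenomicComposition,
                              labels: tuple[str, str] | None = None,
                              alpha: float = 0.05, n_rell: int = 1000,
                              seed: int = 0) -> str:
    """Allo- vs autopolyploid test for a multi-genome composition.

    Forces the individual's two (primary) genome clades to be sister and
    asks whether the data reject that constraint: rejection plus
    non-sister placement in the unconstrained tree means the two copies
    entered via a wide cross (allopolyploidy); sister placement that the
    data cannot reject is consistent with autopolyploidy.
    """
    if len(composition.labels) < 2:
        raise ValueError("composition has a single genome label")
    if labels is None:
        ordered = sorted(composition.labels,
                         key=lambda lab: (-composition.labels[lab], lab))
        labels = (ordered[0], ordered[1])
    group = frozenset(partition.members_of(labels[0])
                      + partition.members_of(labels[1]))
    taxa = set(tree.leaf_names())
    group &= taxa
    if len(taxa - group) < 2 or len(group) < 2:
        return "ambiguous"
    sister = _is_monophyletic(tree, group)
    _, p = kh_constraint_test(aln, group, tree=tree, n_rell=n_rell, seed=seed)
    if not sister and p < alpha:
        return "allopolyploid"
    if sister and p >= alpha:
        return "autopolyploid-consistent"
    return "ambiguous"


def classify_hexaploid_origin(composition: GenomicComposition,
                              hex_sequences: dict[str, list[tuple[str, str]]],
                              oct_sequences: dict[str, list[tuple[str, str]]],
                              max_shared_diff: int = 1) -> str:
    """Distinguish the two classical routes to a hexaploid.

    A hexaploid may come from octoploid x tetraploid (then it should share
    near-identical alleles with octoploids) or from tetraploid x
    tetraploid with one unreduced gamete (then no octoploid allele
    sharing, and one genome carries two subtypes against one of the
    other). Sequences are given per locus as (label, consensus) lists.
    """
    if composition.ploidy != "6x":
        raise ValueError("composition is not hexaploid")
    informative_loci = [loc for loc, c in composition.per_locus.items() if c]
    if len(informative_loci) < 2:
        return "ambiguous"
    for locus, hseqs in hex_sequences.items():
        oseqs = oct_sequences.get(locus, [])
        for _, hs in hseqs:
            for _, os in oseqs:
                if len(hs) == len(os):
                    diffs = sum(1 for a, b in zip(hs, os)
                                if a != b and a in "ACGT" and b in "ACGT")
                    if diffs <= max_shared_diff:
                        return "tetraploid×octoploid"
    counts = sorted(composition.labels.values())
    if len(counts) == 2 and counts == [1, 2]:
        return "tetraploid×tetraploid-unreduced"
    return "ambiguous"


def infer_maternal_genome(cp_tree: Tree,
                          genome_subtrees: dict[str, Tree]) -> str:
    """Identify the seed-parent genome by cp/nuclear tree concordance.

    The chloroplast is maternally inherited, so the genome whose subtree
    is topologically closest (minimum Robinson-Foulds distance on shared
    taxa) to the chloroplast tree is called maternal; ties are ambiguous.
    """
    if len(genome_subtrees) < 2:
        raise ValueError("need subtrees for at least two genomes")
    scores: dict[str, float] = {}
    for label, sub in sorted(genome_subtrees.items()):
        shared = set(cp_tree.leaf_names()) & set(sub.leaf_names())
        if len(shared) < 4:
            raise ValueError(f"genome {label}: fewer than 4 shared taxa")
        scores[label] = robinson_foulds(cp_tree, sub)
    best = min(scores.values())
    winners = [lab for lab, s in scores.items() if s == best]
    return winners[0] if len(winners) == 1 else "ambiguous"


# ---------------------------------------------------------------------------
# reticulation summary

def summarize_reticulation(compositions: list[GenomicComposition],
                           origins: dict[str, str] | None = None,
                           maternal: str | None = None) -> list[dict]:
    """Deterministic aggregation of the inferred hybridization events.

    One row per distinct multi-genome formula: the parental genome labels,
    the ploidy classes observed among its carriers, the maternal genome
    when known, and (for 6x/8x carriers) the second-round event implied by
    the origin classification.
    """
    origins = origins or {}
    by_formula: dict[tuple, list[GenomicComposition]] = {}
    for comp in compositions:
        if len(comp.labels) < 2 and comp.total_types < 2:
            continue
        key = tuple(sorted(comp.labels.items()))
        by_formula.setdefault(key, []).append(comp)
    events = []
    for key in sorted(by_formula):
        members = by_formula[key]
        labels = dict(key)
        parents = "+".join(sorted(labels))
        ploidies = sorted({c.ploidy for c in members})
        event = {
            "event": "hybridization",
            "parents": parents,
            "ploidy_classes": ",".join(ploidies),
            "n_individuals": len(members),
            "individuals": ",".join(sorted(c.individual for c in members)),
            "maternal": maternal or "",
        }
        events.append(event)
        for comp in sorted(members, key=lambda c: c.individual):
            if comp.ploidy in ("6x", "8x"):
                events.append({
                    "event": f"second-round ({comp.ploidy})",
                    "parents": parents,
                    "ploidy_classes": comp.ploidy,
                    "n_individuals": 1,
                    "individuals": comp.individual,
                    "maternal": origins.get(comp.individual, ""),
                })
    return events
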