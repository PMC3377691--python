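"""Score pipeline output against simulation ground truth.

Recovered genome-clade labels are arbitrary letters, and a partition may
legitimately resolve clades at a finer scale than whole lineages (post-
polyploid sub-lineages), so comparisons go through a label -> true-lineage
map built from the truth records of each clade's member clones: per-lineage
subtype counts are then directly comparable to the pedigree expectation.
"""

from __future__ import annotations

from collections import Counter

from .pipeline import PipelineResult
from .simulate import Dataset

__all__ = ["label_lineage_map", "recovered_lineage_counts",
           "formula_recovery", "type_counts_by_ploidy", "chimera_confusion",
           "nontarget_confusion", "lineage_subtype_count"]


def label_lineage_map(dataset: Dataset, result: PipelineResult
                      ) -> dict[str, str]:
    """Majority true lineage of each (harmonized) genome-clade label."""
    by_clone = dataset.truth.by_clone()
    votes: dict[str, Counter] = {}
    for locus, part in result.partitions.items():
        for clade in part.clades:
            for leaf in clade.members:
                ind = result.leaf_individual[leaf]
                ps = result.processed.get((ind, locus))
                if ps is None or leaf not in ps.consensus_members:
                    continue
                for clone_id in ps.consensus_members[leaf]:
                    truth = by_clone.get(clone_id)
                    if truth is not None and truth.lineage:
                        votes.setdefault(clade.label, Counter())[
                            truth.lineage] += 1
    return {label: counter.most_common(1)[0][0]
            for label, counter in votes.items() if counter}


def recovered_lineage_counts(dataset: Dataset, result: PipelineResult
                             ) -> dict[str, dict[str, int]]:
    """Per individual: recovered subtype count per *true* lineage."""
    mapping = label_lineage_map(dataset, result)
    out: dict[str, dict[str, int]] = {}
    for ind, comp in result.compositions.items():
        counts: Counter = Counter()
        for label, n in comp.labels.items():
            lineage = mapping.get(label)
            if lineage is None:
                counts[f"?{label}"] += n
            else:
                counts[lineage] += n
    # a lineage split across several labels accumulates its subtype counts
        out[ind] = dict(counts)
    return out


def formula_recovery(dataset: Dataset, result: PipelineResult) -> float:
    """Fraction of individuals whose recovered per-lineage subtype counts
    equal the pedigree expectation (genomic formula + ploidy)."""
    recovered = recovered_lineage_counts(dataset, result)
    hits = total = 0
    for ind, expected in dataset.truth.expected_types.items():
        total += 1
        if recovered.get(ind) == expected:
            hits += 1
    return hits / total if total else 0.0


def type_counts_by_ploidy(dataset: Dataset, result: PipelineResult
                          ) -> dict[str, list[int]]:
    """Reconciled total sequence-type counts grouped by true ploidy."""
    out: dict[str, list[int]] = {}
    for ind in dataset.individuals:
        comp = result.compositions.get(ind.id)
        if comp is None:
            continue
        out.setdefault(ind.entry.ploidy, []).append(comp.total_types)
    return out


def lineage_subtype_count(dataset: Dataset, result: PipelineResult,
                          individual: str, lineage: str) -> int:
    """Recovered subtype count for one true lineage of one individual."""
    return recovered_lineage_counts(dataset, result).get(
        individual, {}).get(lineage, 0)


def chimera_confusion(dataset: Dataset, result: PipelineResult
                      ) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) of chimera detection over all emitted clones."""
    detected = {call.clone_id
                for ps in result.processed.values()
                for call in ps.chimera_calls}
    tp = fn = fp = tn = 0
    for truth in dataset.truth.clones:
        if truth.offtarget:
            continue
        if truth.is_chimera:
            if truth.clone_id in detected:
                tp += 1
            else:
                fn += 1
        else:
            if truth.clone_id in detected:
                fp += 1
            else:
                tn += 1
    return tp, fn, fp, tn


def nontarget_confusion(dataset: Dataset, result: PipelineResult
                        ) -> tuple[int, int, int, int]:
    flagged = {cid for ps in result.processed.values()
               for cid in ps.nontarget_ids}
    tp = fn = fp = tn = 0
    for truth in dataset.truth.clones:
        if truth.offtarget:
            if truth.clone_id in flagged:
                tp += 1
            else:
                fn += 1
        else:
            if truth.clone_id in flagged:
                fp += 1
            else:
                tn += 1
    return tp, fn, fp, tn
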