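"""End-to-end orchestration: polish clone sets, build per-locus trees,
delimit genome clades, and reconcile genomic compositions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clones import CloneRecord, PolishParams, ProcessedSet, process_clone_set
from .inference import (GenomeCladePartition, GenomicComposition,
                        LocusAssignment, assign_homoeologues,
                        delimit_genome_clades, harmonize_partitions,
                        infer_maternal_genome, reconcile_and_infer_ploidy,
                        summarize_reticulation)
from .phylo import bootstrap_support, nj_from_alignment
from .seqs import Alignment, write_fasta
from .trees import Tree

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline",
           "write_reports"]


@dataclass
class PipelineParams:
    polish: PolishParams = field(default_factory=PolishParams)
    min_support: float = 70.0
    stem_ratio: float = 2.0
    min_subtype_divergence: float = 0.015
    bootstrap_reps: int = 100
    alpha: float = 0.05
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "nontarget_ceiling": self.polish.nontarget_ceiling,
            "chimera_m": self.polish.chimera_m,
            "chimera_d": self.polish.chimera_d,
            "min_support": self.min_support,
            "stem_ratio": self.stem_ratio,
            "min_subtype_divergence": self.min_subtype_divergence,
            "bootstrap_reps": self.bootstrap_reps,
            "alpha": self.alpha,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    processed: dict[tuple[str, str], ProcessedSet]
    locus_alignments: dict[str, Alignment]
    trees: dict[str, Tree]
    partitions: dict[str, GenomeCladePartition]
    assignments: dict[str, list[LocusAssignment]]
    compositions: dict[str, GenomicComposition]
    leaf_individual: dict[str, str]
    cp_tree: Tree | None = None
    maternal: str | None = None

    def composition_table(self) -> pd.DataFrame:
        rows = []
        for ind in sorted(self.compositions):
            comp = self.compositions[ind]
            rows.append({
                "individual": ind,
                "ploidy": comp.ploidy,
                "formula": comp.formula,
                "n_types": comp.total_types,
                "locus_conflict": comp.conflict,
                "dropout_loci": ";".join(comp.missing_loci),
                "uncertain": ";".join(f"{loc}:{leaf}:{lab}"
                                      for loc, leaf, lab in comp.uncertain),
            })
        return pd.DataFrame(rows)

    def reticulation_table(self, origins: dict[str, str] | None = None
                           ) -> pd.DataFrame:
        events = summarize_reticulation(
            list(self.compositions.values()), origins, self.maternal)
        return pd.DataFrame(events)


def run_pipeline(clone_sets: dict[tuple[str, str], list[CloneRecord]],
                 loci: list[str] | None = None,
                 plastid: dict[str, str] | None = None,
                 reference: set[str] | None = None,
                 params: PipelineParams | None = None) -> PipelineResult:
    """Polish clones, build bootstrapped trees per locus, delimit genome
    clades (labels harmonized across loci), and infer compositions.

    ``clone_sets`` maps (individual, locus) to clone records; ``plastid``
    optionally maps individuals to a concatenated chloroplast sequence,
    enabling maternal-genome inference; ``reference`` names individuals
    (typically known diploids) whose clade anchors the A label.
    """
    params = params or PipelineParams()
    if not clone_sets:
        raise ValueError("no clone sets supplied")
    if loci is None:
        loci = sorted({locus for _, locus in clone_sets})

    processed: dict[tuple[str, str], ProcessedSet] = {}
    for key in sorted(clone_sets):
        processed[key] = process_clone_set(clone_sets[key], params.polish)

    rng = np.random.default_rng(params.seed)
    locus_seeds = {locus: int(rng.integers(2 ** 31)) for locus in loci}

    leaf_individual: dict[str, str] = {}
    locus_alignments: dict[str, Alignment] = {}
    trees: dict[str, Tree] = {}
    partitions: dict[str, GenomeCladePartition] = {}
    for locus in loci:
        names, seqs = [], []
        for (ind, loc), ps in sorted(processed.items()):
            if loc != locus:
                continue
            for name, seq in ps.consensi:
                names.append(name)
                seqs.append(_degap(seq))
                leaf_individual[name] = ind
        if len(names) < 4:
            continue
        aln = Alignment(names, seqs)
        locus_alignments[locus] = aln
        tree = bootstrap_support(aln, n_reps=params.bootstrap_reps,
                                 seed=locus_seeds[locus])
        trees[locus] = tree
        ref_leaves = None
        if reference:
            ref_leaves = {n for n in names if leaf_individual[n] in reference}
        partitions[locus] = delimit_genome_clades(
            tree, min_support=params.min_support,
            stem_ratio=params.stem_ratio,
            reference=ref_leaves or None)
    if not partitions:
        raise ValueError("no locus yielded enough consensi for a tree")

    harmonize_partitions(partitions, leaf_individual)

    assignments: dict[str, list[LocusAssignment]] = {}
    for (ind, locus), ps in sorted(processed.items()):
        if locus not in partitions:
            continue
        consensi = {name: _degap(seq) for name, seq in ps.consensi}
        assignment = assign_homoeologues(
            consensi, partitions[locus], ind, locus,
            min_subtype_divergence=params.min_subtype_divergence)
        assignments.setdefault(ind, []).append(assignment)

    compositions = {ind: reconcile_and_infer_ploidy(alist)
                    for ind, alist in assignments.items()}

    cp_tree = maternal = None
    if plastid and len(plastid) >= 4:
        cp_aln = Alignment(sorted(plastid), [plastid[k]
                                             for k in sorted(plastid)])
        cp_tree = nj_from_alignment(cp_aln)
        maternal = _maternal_call(cp_tree, partitions, leaf_individual)

    return PipelineResult(processed, locus_alignments, trees, partitions,
                          assignments, compositions, leaf_individual,
                          cp_tree, maternal)


def _degap(seq: str) -> str:
    """Consensus sequences enter tree building with gaps as missing."""
    return seq.replace("-", "N")


def _maternal_call(cp_tree: Tree,
                   partitions: dict[str, GenomeCladePartition],
                   leaf_individual: dict[str, str]) -> str | None:
    cp_taxa = set(cp_tree.leaf_names())
    anchor_locus = next(iter(partitions))
    part = partitions[anchor_locus]
    subtrees: dict[str, Tree] = {}
    for clade in part.clades:
        by_ind: dict[str, str] = {}
        for leaf in sorted(clade.members):
            ind = leaf_individual[leaf]
            by_ind.setdefault(ind, leaf)
        shared = set(by_ind) & cp_taxa
        if len(shared) < 4:
            continue
        sub = part.tree.restrict([by_ind[i] for i in sorted(shared)])
        for node in sub.postorder():
            if node.is_leaf:
                node.name = leaf_individual[node.name]
        subtrees[clade.label] = sub
    if len(subtrees) < 2:
        return None
    try:
        return infer_maternal_genome(cp_tree, subtrees)
    except ValueError:
        return None


def write_reports(result: PipelineResult, outdir: str | Path,
                  params: PipelineParams | None = None) -> None:
    """Emit consensus FASTAs, Newick trees, composition and reticulation
    TSVs, and a run manifest; every table embeds the run metadata."""
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"homoeosort {__version__}"] + \
        [f"{k}: {v}" for k, v in params.as_dict().items()]

    for locus, aln in result.locus_alignments.items():
        write_fasta(outdir / f"{locus}.consensi.fasta",
                    list(zip(aln.names, aln.seqs)))
    for locus, tree in result.trees.items():
        (outdir / f"{locus}.nwk").write_text(tree.newick() + "\n")
    if result.cp_tree is not None:
        (outdir / "plastid.nwk").write_text(result.cp_tree.newick() + "\n")

    def dump(df: pd.DataFrame, name: str) -> None:
        with open(outdir / name, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    dump(result.composition_table(), "compositions.tsv")
    dump(result.reticulation_table(), "reticulation.tsv")

    chim_rows = []
    for (ind, locus), ps in sorted(result.processed.items()):
        for call in ps.chimera_calls:
            chim_rows.append({"individual": ind, "locus": locus,
                              "clone": call.clone_id,
                              "breakpoint_column": call.breakpoint + 1,
                              "left_support": call.left_support,
                              "right_support": call.right_support,
                              "saved_mismatches": call.saved_mismatches})
        for cid in sorted(ps.nontarget_ids):
            chim_rows.append({"individual": ind, "locus": locus,
                              "clone": cid, "breakpoint_column": "",
                              "left_support": "", "right_support": "",
                              "saved_mismatches": "nontarget"})
    dump(pd.DataFrame(chim_rows), "exclusions.tsv")

    with open(outdir / "manifest.txt", "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write(f"maternal: {result.maternal or 'NA'}\n")
        fh.write(f"loci: {','.join(sorted(result.trees))}\n")
        fh.write(f"individuals: {','.join(sorted(result.compositions))}\n")
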