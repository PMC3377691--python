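# homoeosort

Resolving allopolyploid history from cloned low-copy nuclear amplicons.

Polyploid plants carry several diverged copies (homoeologues) of every
low-copy nuclear gene — one per parental subgenome. A classic way to
untangle such a history is to PCR-amplify a handful of single-copy loci,
clone the products, sequence 8–24 colonies per individual, and sort the
reads: masking PCR point errors, excluding PCR recombinants, collapsing
clones into allele consensus sequences, and placing those consensi on gene
trees where each deeply divergent "genome clade" (lettered A, B, C, …)
stands for one parental lineage. The number of distinct sequence types an
individual shows then tracks its ploidy — one type for diploids (2x), two
for tetraploids (4x), three for hexaploids (6x), four for octoploids (8x)
— and the letters it combines are its genomic formula (AB, FH, IJKL, …).

`homoeosort` implements that whole desk workflow for Python users:

- **`simulate`** — a synthetic-data generator that emulates the study
  design (divergent genome lineages, pedigreed individuals from 2x to 8x,
  clone sets with PCR errors, one-breakpoint chimeras and off-target
  inserts) with complete ground truth for every clone.
- **`clones`** — center-star alignment, off-target screening, the
  singleton-error / two-difference allele clustering rules, a formalized
  mosaic test for PCR recombinants, and majority-rule consensus calling
  (ties become IUPAC codes).
- **`phylo`** — Jukes–Cantor distances, neighbor joining with
  deterministic tie-breaking, column-bootstrap support, Fitch parsimony
  lengths, NNI hill-climbing, the incongruence length difference (ILD)
  partition-homogeneity test, and a Kishino–Hasegawa-style constraint
  test with RELL resampling.
- **`inference`** — genome-clade delimitation on bootstrapped trees,
  homoeologue-to-clade assignment with allele/subtype discrimination,
  reconciliation of per-locus counts into genomic formulas and ploidy
  classes, allo- vs autopolyploid classification, hexaploid-origin
  classification (unreduced gamete vs octoploid parent), maternal-genome
  identification from chloroplast/nuclear tree concordance, and a
  reticulation-event summary.
- **`flow`** — flow-cytometry ploidy calls from fluorescence ratios
  against an internal standard of known ploidy.
- **`tables`** — packaged machine-readable tables from the switchgrass
  polyploidy survey the pipeline emulates (flow-cytometry calls, genome
  clade membership, per-species genomic compositions).

## Worked example

```
python examples/03_ploidy_formulas.py
```

simulates the default community (two diploids, four AB allotetraploids,
an unreduced-gamete hexaploid, a wide-cross octoploid; five nuclear loci
of 751–1279 bp, 8–24 clones each) and prints:

```
individual ploidy formula  n_types  locus_conflict       dropout_loci uncertain
      ama1     4x      AB        2           False
      amb1     4x      AB        2           False
      hex1     6x     ABB        3            True       PvCel1;pabp1
      oct1     8x    AABB        4            True PvCel1;PvCel2;adh1
      rud1     2x       C        1           False
      rud2     2x       C        1           False
      vir1     4x      AB        2           False
      vir2     4x      AB        2           False
```

Each formula letter is one inferred genome copy: the tetraploids combine
one A and one B copy, the hexaploid shows one A and two distinct B copies
(`ABB`, the signature of a tetraploid × tetraploid cross with one
unreduced gamete), and the octoploid shows two of each (`AABB`, a wide
cross of two divergent tetraploids). `dropout_loci` lists loci at which a
copy went undetected — treated as amplification/cloning dropout, not
absence — and the diploid reference clade is lettered last (`C` here).

The other scripts in `examples/` demonstrate clone polishing and chimera
screening, clade delimitation, origin classification plus maternal-genome
inference, and flow cytometry. A thin CLI wraps the same pipeline
(`homoeosort simulate|process|tree|infer|flow|fixtures|run`).

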