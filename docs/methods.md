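# Methods

`homoeosort` reconstructs allopolyploid history from cloned low-copy
nuclear amplicons. This note records the models, the tunable parameters,
the numerical choices, and the limits of what the synthetic benchmarks
demonstrate.

## The inference problem

An allopolyploid of ploidy 2k carries k homologous chromosome-set pairs;
at a single-copy nuclear locus it therefore carries up to k divergent
gene copies (homoeologues), each with two alleles. Cloning a PCR product
samples these copies together with three artifact classes: per-site
polymerase errors, template-switch recombinants ("chimeras"), and
occasional off-target inserts. The pipeline inverts that process:

1. **Polish** each individual × locus clone set into allele consensus
   sequences.
2. **Place** all consensi on a per-locus distance tree with bootstrap
   support and partition the leaves into deeply divergent *genome
   clades*, lettered A, B, C, …; each clade stands for one parental
   lineage.
3. **Count** the distinct sequence subtypes each individual carries per
   clade, reconcile the counts across loci into a genomic formula
   (e.g. `ABB`), and map the total subtype count T onto ploidy:
   T = 1/2/3/4 → 2x/4x/6x/8x (T > 4 is flagged unknown).
4. **Classify** the hybridization events behind multi-genome formulas:
   wide-cross allopolyploidy vs autopolyploidy by a topology-constraint
   test, hexaploid origin (unreduced gamete vs octoploid parent) by
   allele sharing and copy-count pattern, and the maternal (seed-parent)
   genome by chloroplast/nuclear tree concordance.

## Clone polishing

*Alignment.* Clone sets are aligned by center-star alignment: the center
is the clone minimizing summed pairwise edit distance (edlib), others are
aligned to it globally with match +1, mismatch −1, gap −2 (linear). Under
this scoring, equal-length inputs can never profit from gaps, so
substitution-only sets short-circuit to the identity alignment.

*Error and allele rules.* A column state carried by a single clone is
masked as PCR error; a state shared by ≥2 clones is a real variant.
Clones sharing exactly the same real-variant profile form a provisional
cluster, and clusters whose profiles differ at fewer than two columns are
merged — one shared difference does not make a new allele, and lone
error-laden clones fold into their nearest cluster. The two-difference
rule is applied after singleton masking; applying it to raw differences
would let independent PCR errors inflate allele counts. Consensus is
per-column majority with gap as an ordinary state; ties among bases are
written as IUPAC ambiguity codes (excluded later from distance
computations), and a tie involving a gap keeps the tied bases.

*Off-target screen.* A clone whose gap-excluded p-distance to every
other clone exceeds `nontarget_ceiling` (default 0.25, far above any
within-genus divergence but far below the ≈0.75 expected for unrelated
sequence) is removed before clustering.

*Chimera screen.* The by-eye recombinant screen is formalized as a
mosaic test. For an ordered cluster pair (X, Y), diagnostic columns are
those where the two consensi disagree; a clone is chimeric if some
breakpoint leaves ≥ m diagnostic matches to X on the left and ≥ m to Y on
the right (default m = 2) and the mosaic explanation saves ≥ d mismatches
over the best single-cluster explanation (default d = 2). The clone is
excluded from its own cluster's consensus while testing. Because two
recombinants with nearby breakpoints can validate each other into a
bogus "allele" cluster, every cluster consensus is additionally screened
as a mosaic of strictly larger clusters; a chimeric cluster is excluded
member by member. The size constraint is essential in the other
direction too: without it, two opposite-phase chimeric singletons could
"explain" a genuine allele cluster as their mosaic.

*Detection ceiling.* A recombinant whose breakpoint leaves fewer than
m = 2 diagnostic sites on one flank is information-theoretically
indistinguishable from an ordinary clone with one error, and the cluster
merge rule silently absorbs it (harmlessly — its lone foreign site is
outvoted in consensus). With ≈ n diagnostic sites per locus, a uniform
internal breakpoint falls in such a terminal window with probability
≈ 4/(n+1); at the benchmark divergence (0.05, loci of 751–1279 bp,
n ≈ 38–64) the expected detection ceiling is ≈ 0.92–0.94. Measured
sensitivity sits at that ceiling (every missed recombinant in the
benchmark has ≤ 1 diagnostic site on one flank) with a false-positive
rate of 0.

## Tree building and tests

Distances are Jukes–Cantor with pairwise deletion of gap/N sites;
p ≥ 0.75 is flagged as saturation (infinite distance; `capped()`
substitutes 1.25× the largest finite entry when a tree is still wanted).
Neighbor joining follows the Saitou–Nei Q criterion with ties broken by
the lexicographically smallest cluster-label pair and negative branch
lengths clamped to zero. Bootstrap support is the percentage of
column-resampled replicates containing each internal bipartition of the
point tree; the default JC+NJ builder computes replicate distances by
multinomial site weighting. Parsimony lengths use Fitch counting with
site-pattern compression and bitmask state sets; gaps/N are missing data
(no cost). Searches are NJ + first-improvement NNI hill-climbing — on
data whose clades are separated by dozens of diagnostic sites, full
heuristic search machinery buys nothing.

The ILD test statistic is L(combined) − [L(p1) + L(p2)] with lengths
from NJ+NNI trees; the null redistributes characters randomly into
partitions of the original sizes, and p = (1 + #{null ≥ observed}) /
(n_reps + 1). Note a structural property: on strongly structured,
homoplasy-free partitions both the observed and all null statistics are
zero and the p-value degenerates to 1. The test's p-values are uniform
under homogeneity only in regimes where the statistic is non-degenerate
(appreciable homoplasy); the uniformity suite therefore simulates
partitions with multiple hits (branch lengths 0.9/0.25, 90 sites).

The constraint test builds the best tree forcing a leaf group
monophyletic (the group's NJ subtree is attached at the Fitch-optimal
backbone edge, then refined by constraint-respecting NNI) and compares
per-site Fitch lengths against the unconstrained tree by RELL
resampling: the two-sided p is the fraction of centered resampled length
differences at least as extreme as the observed difference. With no
differing sites the test returns (0, 1).

## Genome-clade delimitation

A clade's stem must be both well supported and long relative to the
allele-level noise floor. The criterion is evaluated per unrooted edge
(so it cannot depend on where a tree happens to be rooted): an edge is a
candidate stem if its bipartition support is ≥ `min_support` (default
70%) and its length is ≥ `stem_ratio` (default 2) times the local scale,
taken as the median within-side nearest-neighbour patristic distance
(floored by the global nearest-neighbour median). The *median pairwise*
distance is deliberately not used as the scale: it is dominated by
legitimate deep substructure — the divergent homoeologue subtypes inside
a clade — and would veto genuine genome stems.

Candidate edges are nested (families within genomes within
super-groups), and the genome-clade scale is picked in two steps. First,
a candidate lying inside a side delimited by another candidate's edge is
discarded as internal substructure unless its own stem is ≥1.5× longer;
an edge delimits its compact side (smaller diameter), or both sides when
their diameters are within 1.3× of each other (the two-clade case: one
deep edge separating two genome clades delimits both at once). Second,
surviving candidates are accepted greedily, longest stem first, keeping
clades disjoint. Cutting the accepted edges partitions the tree;
leaf-bearing residual components become clades too (reported with stem
0), and a leaf on its own long pendant becomes a singleton clade. The
1.5×/1.3× margins keep the chosen scale stable against branch-length
estimation noise on ~1 kb loci; delimitation is the most delicate step
of the pipeline and these guards are what make its granularity
reproducible across loci.

Labels: with reference leaves given (typically known diploids), "A" is
the non-reference clade nearest the reference by mean patristic
distance, the rest follow in increasing distance, and the reference
clade is lettered last; without a reference, ladderized traversal order.
Across loci, letters are matched by overlap in *individual* membership —
with the caveat that homoeologous clades of one hybrid lineage share
their carriers exactly, so membership ties are resolved in favour of the
per-locus (reference-anchored) letter. A clade that matches only an
already-taken letter with good overlap (Jaccard ≥ 0.2) is treated as an
over-split fragment and shares that letter; subtype counting inside the
label absorbs the split. Letter identity across loci is only meaningful
where reference asymmetry or membership can distinguish clades; between
perfectly symmetric clades (e.g. two genomes carried by exactly the same
individuals at equal reference distance) the letters are arbitrary per
locus, which leaves per-individual counts intact but makes cross-locus
letter bookkeeping cosmetic.

## Subtypes, formulas, ploidy

Within a clade, two consensi of one individual are distinct subtypes
(homoeologous copies) only if they are non-sister in the tree *and* at
least `min_subtype_divergence` apart; otherwise they are alleles of one
copy. Requiring both conditions matters: under star-like allele
structure, sisterhood of two alleles of one individual is nearly random
(alleles of different individuals interleave), so a disjunctive rule
would fragment ordinary heterozygotes. The divergence default is 0.015
substitutions/site — the midpoint of the two scales it must separate,
allelic heterozygosity (≈0.005) and post-polyploid subtype divergence
(≈0.02); a cutoff at 0.01 sits only twice the allele scale and Poisson
site-sampling noise at ~1 kb crosses it often enough to inflate
formulas. Consensi placed in no clade get a lowercase compound label
naming the two nearest clades and are excluded from ploidy arithmetic.

Per-locus counts reconcile by label union and per-label maximum: a locus
missing a copy is treated as amplification/cloning dropout, not absence
(hence the `dropout_loci` column), and loci disagreeing on total type
count set a conflict flag. The maximum rule makes reconciliation
maximally sensitive to over-splitting — which is why the subtype rule
above is conservative.

## Origin classification

*Allo- vs autopolyploid.* For a two-genome composition, the union of
the two clades is forced monophyletic and the constraint test asks
whether the data reject it. Rejection (p < 0.05) plus non-sister
placement in the unconstrained tree → allopolyploid; sister placement
the data cannot reject → autopolyploid-consistent; anything else →
ambiguous. The test is only meaningful with at least two further clades
in the tree (on an unrooted three-group tree every pair union is
trivially monophyletic); with fewer the verdict is ambiguous.

*Hexaploid origin.* A hexaploid from octoploid × tetraploid should share
near-identical alleles (≤1 difference) with octoploids; one from
tetraploid × tetraploid with an unreduced gamete should share none and
show a 2:1 copy-count pattern between two genomes. A single informative
locus is never considered sufficient. The allele-sharing discriminator
presumes hexaploids and octoploids do not independently descend from the
same narrow tetraploid families; same-family alleles of unrelated
individuals differ by ~θL sites and can fall under the 1-difference
threshold by chance.

*Maternal genome.* The chloroplast is maternally inherited, so the
genome whose subtree (pruned to shared taxa, one leaf per individual) has
the minimum Robinson–Foulds distance to the chloroplast tree is called
maternal; ties are ambiguous, and fewer than four shared taxa is an
error. RF concordance is one formalization of "similar topology"; it
needs real internal structure within the genome clades to discriminate.

## The synthetic-data generator

Substitutions follow a Jukes–Cantor-style process: Poisson-many per
sequence, uniform among the three alternatives. `genome_divergence`
(default 0.05) and `allele_theta` (default 0.005) are *pairwise*
expected substitutions/site, so lineages receive half that from the
common ancestor and each haplotype half of θ from its founder.
Post-polyploid sub-lineages ("families", `sublineage_divergence` 0.02
pairwise) give higher polyploids their distinct within-clade subtypes.
Loci default to five nuclear amplicons of 751–1279 bp plus two plastid
spacers; clone counts are uniform on 8–24; PCR errors are i.i.d. at
5 × 10⁻⁴/site/clone; with probability `chimera_rate` (default 0.05) a
clone is a single-breakpoint splice of two *distinct* haplotypes at a
uniform internal breakpoint (a same-template splice carries no
recombination signal); off-target clones are uniform random sequences of
locus length (default rate 0).

Lineages are star-shaped by default; a Newick `lineage_tree` (edge
lengths in substitutions/site) imposes structure. The standard A/B/E
communities use `((A:0.02,E:0.02):0.01,B:0.045)` — the A genome closer
to the diploid reference E than B is, mirroring the survey system where
the B donor is unsampled — which is also what makes the A/B letters
identifiable per locus; the asymmetry gap (~0.03) is ≈3σ of the Poisson
edge-count noise at the shortest locus. The origin-test community adds
an F outgroup so that forced A+B sisterhood is genuinely rejectable.
Crosses copy parental allele sequences verbatim (reduced gametes sample
one member of each consecutive haplotype pair, unreduced gametes copy
all), and offspring inherit the mother's plastid.

What the generator does **not** model: coalescent variation within
lineages, recombination within genomes, gene loss and conversion, indels
(so center-star alignment is exercised only by dedicated unit tests),
amplification bias among haplotypes, and base-calling quality. Passing
benchmarks therefore demonstrate the pipeline's logic under clean
point-substitution structure, not robustness to alignment error or
systematic amplification artifacts.

## Benchmark problem sizes

The default community holds eight individuals (two 2x, four 4x, one 6x,
one 8x) at five loci; formula recovery is scored over 50 replicate
communities by mapping recovered clade labels to true lineages through
each clade's member-clone truth records (a label→lineage map, so
legitimate fine-scale splits are not penalized). The ILD uniformity
suite runs 200 replicates of 7-taxon, 90-site partition pairs with 99
permutations each; NJ consistency is checked on 500 random additive
matrices of up to 12 taxa; Fitch lengths are verified against exhaustive
minimization on 6-taxon, 30-site instances; the chimera benchmark scores
~500 clones of two-haplotype individuals at recombination rate 0.1.
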