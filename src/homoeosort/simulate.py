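"""Synthetic allopolyploid amplicon-cloning datasets with ground truth.

The generator emulates a multi-locus cloning study of a polyploid plant
complex: a set of deeply divergent genome lineages, individuals of ploidy
2x-8x whose subgenomes are drawn from those lineages, and per-locus clone
sets carrying PCR point errors, PCR recombinants (chimeras) and optional
off-target sequences. Every emitted clone has a complete truth record, so
the downstream polishing and inference stages can be scored exactly.

Model choices: substitutions are placed Poisson-per-sequence with uniform
choice among the three alternative bases (a Jukes-Cantor-style process);
``genome_divergence`` and ``allele_theta`` are *pairwise* expected
substitutions/site, so each lineage (or allele) receives half that rate
relative to its ancestor. Tetraploid "families" (sub-lineages that have
diverged after polyploidization) let crosses between tetraploids produce
the distinct within-clade sequence subtypes that higher-order polyploids
display. There is no coalescent machinery, recombination within genomes,
or gene loss.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqs import write_fasta

__all__ = [
    "SimConfig", "HaplotypeSpec", "PedigreeEntry", "Individual",
    "CloneTruth", "SimTruth", "Dataset", "GenomePool",
    "simulate_genomes", "simulate_individual", "simulate_clones",
    "cross_individuals", "realize_clones",
    "standard_community", "twelve_genome_community", "maternal_community",
    "wide_cross_community", "autotetraploid_community",
    "higher_polyploid_community", "write_dataset",
]

LINEAGE_LETTERS = "ABCDEFGHIJKL"

#: the five nuclear amplicons (name, aligned length in bp) and the two
#: plastid spacers the study design uses
DEFAULT_LOCI: tuple[tuple[str, int], ...] = (
    ("adh1", 1279), ("knotted1", 986), ("pabp1", 1128),
    ("PvCel1", 757), ("PvCel2", 751),
)
PLASTID_LOCI: tuple[tuple[str, int], ...] = (
    ("rps16-trnQ", 1739), ("trnC-rpoB", 1465),
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default guide tree for the A/B/E communities: the A genome is closer to
#: the diploid reference lineage E than B is (B's diploid donor unsampled),
#: so "closest clade to the reference" identifies A consistently per locus
ABE_GUIDE_TREE = "((A:0.02,E:0.02):0.01,B:0.045);"

#: as above plus an F outgroup lineage; with four groups in the tree,
#: forcing A and B sister becomes a genuine (rejectable) constraint
ABEF_GUIDE_TREE = "(((A:0.02,E:0.02):0.01,B:0.045):0.005,F:0.05);"


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_genomes: int = 12
    genome_divergence: float = 0.05   # expected pairwise subst/site between lineages
    allele_theta: float = 0.005       # expected pairwise subst/site within a lineage
    sublineage_divergence: float = 0.02  # pairwise divergence between tetraploid families
    loci: tuple[tuple[str, int], ...] = DEFAULT_LOCI
    plastid_loci: tuple[tuple[str, int], ...] = PLASTID_LOCI
    clones_per_individual: tuple[int, int] = (8, 24)
    pcr_error_rate: float = 5e-4      # per-site per-clone
    chimera_rate: float = 0.05        # per-clone
    nontarget_rate: float = 0.0       # per-clone
    #: optional Newick over lineage letters; edge lengths are expected
    #: substitutions/site, giving the lineages non-star structure
    lineage_tree: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_genomes <= len(LINEAGE_LETTERS):
            raise ValueError("n_genomes must be in 1..12")
        for rate in (self.genome_divergence, self.allele_theta,
                     self.sublineage_divergence, self.pcr_error_rate,
                     self.chimera_rate, self.nontarget_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for name, length in list(self.loci) + list(self.plastid_loci):
            if length < 100:
                raise ValueError(f"locus {name} shorter than 100 bp")
        lo, hi = self.clones_per_individual
        if lo > hi or lo < 1:
            raise ValueError("invalid clones_per_individual range")

    @property
    def lineages(self) -> list[str]:
        return list(LINEAGE_LETTERS[: self.n_genomes])


@dataclass(frozen=True)
class HaplotypeSpec:
    """One subgenome haplotype: its source lineage and (optional) family."""
    hap_id: str
    lineage: str
    family: str | None = None


@dataclass
class PedigreeEntry:
    individual: str
    species: str
    haplotypes: list[HaplotypeSpec]
    gametes: list[tuple[str, str]] = field(default_factory=list)  # (parent, reduced|unreduced)
    maternal: str = ""

    def __post_init__(self) -> None:
        if len(self.haplotypes) not in (2, 4, 6, 8):
            raise ValueError("haplotype count must be 2, 4, 6 or 8")
        lineages = {h.lineage for h in self.haplotypes}
        if self.maternal and self.maternal not in lineages:
            raise ValueError("maternal genome must be one of the subgenomes")

    @property
    def ploidy(self) -> str:
        return f"{len(self.haplotypes)}x"


class GenomePool:
    """Per-locus ancestral and lineage sequences plus family mutation sets."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.lineage_seqs: dict[str, dict[str, str]] = {}  # lineage -> locus -> seq
        self.families: dict[str, tuple[str, dict[str, list[tuple[int, str]]]]] = {}

    def all_loci(self) -> list[tuple[str, int]]:
        return list(self.config.loci) + list(self.config.plastid_loci)

    def add_family(self, family_id: str, lineage: str,
                   rng: np.random.Generator) -> None:
        """Register a post-polyploid sub-lineage of ``lineage``."""
        if lineage not in self.lineage_seqs:
            raise KeyError(f"unknown lineage {lineage!r}")
        rate = self.config.sublineage_divergence / 2.0
        muts: dict[str, list[tuple[int, str]]] = {}
        for locus, length in self.all_loci():
            base = self.lineage_seqs[lineage][locus]
            muts[locus] = _draw_mutations(base, rate * length, rng)
        self.families[family_id] = (lineage, muts)

    def haplotype_founder(self, spec: HaplotypeSpec, locus: str) -> str:
        seq = self.lineage_seqs[spec.lineage][locus]
        if spec.family is not None:
            lineage, muts = self.families[spec.family]
            if lineage != spec.lineage:
                raise ValueError("family/lineage mismatch")
            seq = _apply_mutations(seq, muts[locus])
        return seq


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _draw_mutations(seq: str, expected: float,
                    rng: np.random.Generator) -> list[tuple[int, str]]:
    """Poisson-many substitutions at distinct uniform sites."""
    k = min(int(rng.poisson(expected)), len(seq))
    if k == 0:
        return []
    positions = rng.choice(len(seq), size=k, replace=False)
    out = []
    for pos in sorted(int(p) for p in positions):
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        out.append((pos, alternatives[rng.integers(3)]))
    return out


def _apply_mutations(seq: str, muts: list[tuple[int, str]]) -> str:
    if not muts:
        return seq
    chars = list(seq)
    for pos, base in muts:
        chars[pos] = base
    return "".join(chars)


def simulate_genomes(config: SimConfig,
                     rng: np.random.Generator | None = None) -> GenomePool:
    """Draw ancestral sequences and one divergent copy per genome lineage.

    Each lineage receives Poisson(divergence/2 x L) substitutions relative
    to the shared ancestor, so lineage pairs differ at about
    ``genome_divergence x L`` sites.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pool = GenomePool(config)
    rate = config.genome_divergence / 2.0
    ancestral = {locus: _random_seq(length, rng)
                 for locus, length in pool.all_loci()}

    structured: dict[str, dict[str, str]] = {}
    if config.lineage_tree is not None:
        from .trees import parse_newick
        guide = parse_newick(config.lineage_tree)
        for locus, length in pool.all_loci():
            seqs_at: dict[int, str] = {id(guide.root): ancestral[locus]}
            for node in guide.preorder():
                if node.parent is not None:
                    parent_seq = seqs_at[id(node.parent)]
                    muts = _draw_mutations(parent_seq, node.length * length, rng)
                    seqs_at[id(node)] = _apply_mutations(parent_seq, muts)
                if node.is_leaf:
                    if node.name not in config.lineages:
                        raise ValueError(
                            f"lineage tree leaf {node.name!r} not a lineage")
                    structured.setdefault(node.name, {})[locus] = seqs_at[id(node)]

    for lineage in config.lineages:
        if lineage in structured:
            pool.lineage_seqs[lineage] = structured[lineage]
            continue
        seqs = {}
        for locus, length in pool.all_loci():
            muts = _draw_mutations(ancestral[locus], rate * length, rng)
            seqs[locus] = _apply_mutations(ancestral[locus], muts)
        pool.lineage_seqs[lineage] = seqs
    return pool


@dataclass
class Individual:
    entry: PedigreeEntry
    haplotypes: dict[str, dict[str, str]]  # locus -> hap_id -> seq
    plastid: dict[str, str]                # plastid locus -> seq

    @property
    def id(self) -> str:
        return self.entry.individual


def simulate_individual(entry: PedigreeEntry, pool: GenomePool,
                        rng: np.random.Generator,
                        plastid_family: str | None = None) -> Individual:
    """Realize haplotype sequences for a pedigree entry.

    Each haplotype is its founder (lineage sequence plus any family-level
    mutations) with Poisson(theta/2 x L) private allele mutations, so two
    alleles of one subgenome differ at about ``allele_theta x L`` sites.
    The plastid is copied from the maternal lineage (plus the maternal
    family, if given) with allele-level noise.
    """
    config = pool.config
    for spec in entry.haplotypes:
        if spec.lineage not in pool.lineage_seqs:
            raise KeyError(f"unknown lineage {spec.lineage!r}")
    theta = config.allele_theta / 2.0
    haps: dict[str, dict[str, str]] = {}
    for locus, length in config.loci:
        by_id = {}
        for spec in entry.haplotypes:
            founder = pool.haplotype_founder(spec, locus)
            by_id[spec.hap_id] = _apply_mutations(
                founder, _draw_mutations(founder, theta * length, rng))
        haps[locus] = by_id
    plastid = {}
    maternal = entry.maternal or entry.haplotypes[0].lineage
    for locus, length in config.plastid_loci:
        spec = HaplotypeSpec("cp", maternal, plastid_family)
        founder = pool.haplotype_founder(spec, locus)
        plastid[locus] = _apply_mutations(
            founder, _draw_mutations(founder, theta * length, rng))
    return Individual(entry, haps, plastid)


def _gamete(parent: Individual, mode: str,
            rng: np.random.Generator
            ) -> list[tuple[HaplotypeSpec, dict[str, str], str]]:
    """Sample a gamete as (spec, per-locus sequence, note) triples.

    Haplotypes pair consecutively (h0-h1, h2-h3, ...); a reduced gamete
    takes one member of each pair, an unreduced gamete takes everything.
    Sequences are copied exactly: offspring share their parents' alleles.
    """
    specs = parent.entry.haplotypes
    if mode not in ("reduced", "unreduced"):
        raise ValueError("gamete mode must be 'reduced' or 'unreduced'")
    if mode == "unreduced":
        chosen = list(specs)
    else:
        chosen = []
        for k in range(0, len(specs), 2):
            a, b = specs[k], specs[k + 1]
            if (a.lineage, a.family) != (b.lineage, b.family):
                raise ValueError("reduced gamete requires homologous pairs")
            chosen.append(a if rng.random() < 0.5 else b)
    out = []
    for spec in chosen:
        seqs = {locus: parent.haplotypes[locus][spec.hap_id]
                for locus in parent.haplotypes}
        out.append((spec, seqs, parent.id))
    return out


def cross_individuals(ind_id: str, species: str, mother: Individual,
                      father: Individual, mother_gamete: str,
                      father_gamete: str,
                      rng: np.random.Generator) -> Individual:
    """Realize an offspring from two parents' gametes.

    Allele sequences are inherited verbatim; the plastid is copied from
    the mother (maternal inheritance).
    """
    contributions = (_gamete(mother, mother_gamete, rng)
                     + _gamete(father, father_gamete, rng))
    if len(contributions) not in (2, 4, 6, 8):
        raise ValueError("cross yields an unsupported ploidy")
    specs = []
    haps: dict[str, dict[str, str]] = {}
    for k, (spec, seqs, _) in enumerate(contributions):
        new = HaplotypeSpec(f"h{k + 1}", spec.lineage, spec.family)
        specs.append(new)
        for locus, seq in seqs.items():
            haps.setdefault(locus, {})[new.hap_id] = seq
    entry = PedigreeEntry(
        ind_id, species, specs,
        gametes=[(mother.id, mother_gamete), (father.id, father_gamete)],
        maternal=mother.entry.maternal or mother.entry.haplotypes[0].lineage)
    return Individual(entry, haps, dict(mother.plastid))


# ---------------------------------------------------------------------------
# clone generation

@dataclass
class CloneTruth:
    clone_id: str
    individual: str
    locus: str
    source_hap: str | None       # primary (left) template; None for off-target
    source_hap2: str | None      # right template when chimeric
    lineage: str | None
    error_positions: list[int]
    breakpoint: int | None
    offtarget: bool

    @property
    def is_chimera(self) -> bool:
        return self.breakpoint is not None


@dataclass
class SimTruth:
    clones: list[CloneTruth] = field(default_factory=list)
    # (individual, locus, hap_id) -> true haplotype sequence
    haplotypes: dict[tuple[str, str, str], str] = field(default_factory=dict)
    # individual -> lineage -> number of distinct subtypes (families)
    expected_types: dict[str, dict[str, int]] = field(default_factory=dict)

    def by_clone(self) -> dict[str, CloneTruth]:
        return {t.clone_id: t for t in self.clones}


def _expected_type_counts(entry: PedigreeEntry) -> dict[str, int]:
    groups = {(h.lineage, h.family) for h in entry.haplotypes}
    counts: Counter = Counter(lineage for lineage, _ in groups)
    return dict(counts)


def _pcr_errors(seq: str, rate: float,
                rng: np.random.Generator) -> tuple[str, list[int]]:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    muts = []
    for pos in hits:
        pos = int(pos)
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        muts.append((pos, alternatives[rng.integers(3)]))
    return _apply_mutations(seq, muts), [p for p, _ in muts]


def simulate_clones(individual: Individual, locus: str, config: SimConfig,
                    rng: np.random.Generator,
                    n_clones: int | None = None
                    ) -> tuple[list[tuple[str, str]], list[CloneTruth]]:
    """Emit the cloned amplicon reads for one individual x locus.

    The clone count is uniform over ``clones_per_individual``; each clone
    copies a uniformly chosen haplotype with i.i.d. per-site PCR errors.
    With probability ``chimera_rate`` the clone is instead a single-
    breakpoint splice of two distinct haplotypes (a PCR recombinant), and
    with probability ``nontarget_rate`` an unrelated random sequence.
    """
    haps = individual.haplotypes[locus]
    if not haps:
        raise ValueError("individual has no haplotypes at this locus")
    hap_ids = sorted(haps)
    length = len(next(iter(haps.values())))
    lineage_of = {h.hap_id: h.lineage for h in individual.entry.haplotypes}
    lo, hi = config.clones_per_individual
    n = n_clones if n_clones is not None else int(rng.integers(lo, hi + 1))
    clones, truths = [], []
    for k in range(n):
        clone_id = f"{individual.id}|{locus}|c{k + 1}"
        u = rng.random()
        if u < config.nontarget_rate:
            seq = _random_seq(length, rng)
            clones.append((clone_id, seq))
            truths.append(CloneTruth(clone_id, individual.id, locus,
                                     None, None, None, [], None, True))
            continue
        chimeric = (rng.random() < config.chimera_rate) and len(hap_ids) >= 2
        if chimeric:
            h1, h2 = rng.choice(len(hap_ids), size=2, replace=False)
            h1, h2 = hap_ids[int(h1)], hap_ids[int(h2)]
            bp = int(rng.integers(1, length))
            seq = haps[h1][:bp] + haps[h2][bp:]
            seq, errs = _pcr_errors(seq, config.pcr_error_rate, rng)
            clones.append((clone_id, seq))
            truths.append(CloneTruth(clone_id, individual.id, locus,
                                     h1, h2, lineage_of[h1], errs, bp, False))
        else:
            hap = hap_ids[int(rng.integers(len(hap_ids)))]
            seq, errs = _pcr_errors(haps[hap], config.pcr_error_rate, rng)
            clones.append((clone_id, seq))
            truths.append(CloneTruth(clone_id, individual.id, locus,
                                     hap, None, lineage_of[hap], errs, None,
                                     False))
    return clones, truths


# ---------------------------------------------------------------------------
# community scenarios

@dataclass
class Dataset:
    config: SimConfig
    pool: GenomePool
    individuals: list[Individual]
    clones: dict[tuple[str, str], list[tuple[str, str]]]
    truth: SimTruth

    def individual(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    def clone_records(self) -> dict:
        """Clone sets in the form the pipeline consumes."""
        from .clones import CloneRecord
        return {(ind, locus): [CloneRecord(cid, ind, locus, seq, len(seq))
                               for cid, seq in recs]
                for (ind, locus), recs in self.clones.items()}

    def plastid_concat(self) -> dict[str, str]:
        """Concatenated plastid spacers per individual."""
        order = [name for name, _ in self.config.plastid_loci]
        return {ind.id: "".join(ind.plastid[k] for k in order)
                for ind in self.individuals}

    def diploid_ids(self) -> set[str]:
        return {ind.id for ind in self.individuals
                if len(ind.entry.haplotypes) == 2}


def realize_clones(config: SimConfig, pool: GenomePool,
                   individuals: list[Individual],
                   rng: np.random.Generator) -> Dataset:
    """Emit clone sets and truth records for already-realized individuals."""
    truth = SimTruth()
    clones: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for ind in individuals:
        truth.expected_types[ind.id] = _expected_type_counts(ind.entry)
        for locus, _ in config.loci:
            for hap_id, seq in ind.haplotypes[locus].items():
                truth.haplotypes[(ind.id, locus, hap_id)] = seq
            recs, truths = simulate_clones(ind, locus, config, rng)
            clones[(ind.id, locus)] = recs
            truth.clones.extend(truths)
    return Dataset(config, pool, individuals, clones, truth)


def _realize(config: SimConfig, pool: GenomePool,
             entries: list[tuple[PedigreeEntry, str | None]],
             rng: np.random.Generator) -> Dataset:
    individuals = [simulate_individual(entry, pool, rng, plastid_family=cp)
                   for entry, cp in entries]
    return realize_clones(config, pool, individuals, rng)


def _tetraploid(ind_id: str, species: str, fam_a: str, fam_b: str,
                lin_a: str = "A", lin_b: str = "B") -> PedigreeEntry:
    return PedigreeEntry(
        ind_id, species,
        [HaplotypeSpec(f"{lin_a.lower()}1", lin_a, fam_a),
         HaplotypeSpec(f"{lin_a.lower()}2", lin_a, fam_a),
         HaplotypeSpec(f"{lin_b.lower()}1", lin_b, fam_b),
         HaplotypeSpec(f"{lin_b.lower()}2", lin_b, fam_b)],
        gametes=[("founder", "reduced"), ("founder", "reduced")],
        maternal=lin_a)


def _diploid(ind_id: str, species: str, lineage: str) -> PedigreeEntry:
    return PedigreeEntry(
        ind_id, species,
        [HaplotypeSpec("h1", lineage), HaplotypeSpec("h2", lineage)],
        maternal=lineage)


def standard_community(config: SimConfig | None = None) -> Dataset:
    """The default mixed-ploidy community used throughout testing.

    Two diploids (reference lineage E), four AB allotetraploids drawn from
    three post-polyploid families, one hexaploid formed by an unreduced x
    reduced cross between tetraploids that share their A family but carry
    different B families, and one octoploid formed by a wide cross of two
    tetraploids differing in both families. Expected sequence types per
    locus: 1 (2x), 2 (4x), 3 (6x), 4 (8x).
    """
    config = config if config is not None else SimConfig()
    if config.n_genomes < 5:
        raise ValueError("standard community needs lineages A..E")
    if config.lineage_tree is None:
        config = replace(config, lineage_tree=ABE_GUIDE_TREE)
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    for fam, lin in [("Af1", "A"), ("Af2", "A"),
                     ("Bf1", "B"), ("Bf2", "B"), ("Bf3", "B")]:
        pool.add_family(fam, lin, rng)

    hexaploid = PedigreeEntry(
        "hex1", "P. hexa",
        # unreduced gamete from (Af1,Bf1) + reduced gamete from (Af1,Bf2)
        [HaplotypeSpec("a1", "A", "Af1"), HaplotypeSpec("a2", "A", "Af1"),
         HaplotypeSpec("a3", "A", "Af1"),
         HaplotypeSpec("b1", "B", "Bf1"), HaplotypeSpec("b2", "B", "Bf1"),
         HaplotypeSpec("b3", "B", "Bf2")],
        gametes=[("tet_Af1Bf1", "unreduced"), ("tet_Af1Bf2", "reduced")],
        maternal="A")
    octoploid = PedigreeEntry(
        "oct1", "P. octo",
        # two unreduced gametes from tetraploids of different families
        [HaplotypeSpec("a1", "A", "Af1"), HaplotypeSpec("a2", "A", "Af1"),
         HaplotypeSpec("a3", "A", "Af2"), HaplotypeSpec("a4", "A", "Af2"),
         HaplotypeSpec("b1", "B", "Bf1"), HaplotypeSpec("b2", "B", "Bf1"),
         HaplotypeSpec("b3", "B", "Bf3"), HaplotypeSpec("b4", "B", "Bf3")],
        gametes=[("tet_Af1Bf1", "unreduced"), ("tet_Af2Bf3", "unreduced")],
        maternal="A")

    entries: list[tuple[PedigreeEntry, str | None]] = [
        (_diploid("rud1", "P. dip", "E"), None),
        (_diploid("rud2", "P. dip", "E"), None),
        (_tetraploid("vir1", "P. tet", "Af1", "Bf1"), "Af1"),
        (_tetraploid("vir2", "P. tet", "Af1", "Bf1"), "Af1"),
        (_tetraploid("ama1", "P. tet2", "Af1", "Bf2"), "Af1"),
        (_tetraploid("amb1", "P. tet3", "Af2", "Bf3"), "Af2"),
        (hexaploid, "Af1"),
        (octoploid, "Af1"),
    ]
    return _realize(config, pool, entries, rng)


def twelve_genome_community(config: SimConfig | None = None) -> Dataset:
    """A community touching all twelve genome lineages A..L.

    Mirrors the structure of the study's sampled sections: diploids in E
    and F, AB tetraploids, a CD tetraploid and CDE hexaploid, FG and FH
    tetraploids, IL / JK tetraploids and IJKL octoploids.
    """
    config = config if config is not None else SimConfig()
    if config.n_genomes < 12:
        config = replace(config, n_genomes=12)
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    pool.add_family("Af1", "A", rng)
    pool.add_family("Bf1", "B", rng)

    def multi(ind_id, species, lineages):
        haps = []
        for lin in lineages:
            haps.append(HaplotypeSpec(f"{lin.lower()}1", lin))
            haps.append(HaplotypeSpec(f"{lin.lower()}2", lin))
        return PedigreeEntry(ind_id, species, haps, maternal=lineages[0])

    entries = [
        (_diploid("rud1", "P. dipE", "E"), None),
        (_diploid("rud2", "P. dipE", "E"), None),
        (_diploid("cap1", "P. dipF", "F"), None),
        (_diploid("nep1", "P. dipF", "F"), None),
        (_tetraploid("vir1", "P. tetAB", "Af1", "Bf1"), "Af1"),
        (_tetraploid("vir2", "P. tetAB", "Af1", "Bf1"), "Af1"),
        (multi("oly1", "P. tetCD", "CD"), None),
        (multi("oly2", "P. tetCD", "CD"), None),
        (multi("mys1", "P. hexCDE", "CDE"), None),
        (multi("ber1", "P. tetFG", "FG"), None),
        (multi("str1", "P. tetFG", "FG"), None),
        (multi("mil1", "P. tetFH", "FH"), None),
        (multi("mil2", "P. tetFH", "FH"), None),
        (multi("dic1", "P. tetIL", "IL"), None),
        (multi("gou1", "P. tetJK", "JK"), None),
        (multi("aqu1", "P. octIJKL", "IJKL"), None),
        (multi("ped1", "P. octIJKL", "IJKL"), None),
    ]
    return _realize(config, pool, entries, rng)


def maternal_community(config: SimConfig | None = None, n_families: int = 4,
                       inds_per_family: int = 2) -> Dataset:
    """AB tetraploids whose plastid travels with the A (maternal) genome.

    Each tetraploid family carries its own A sub-lineage and plastid
    haplotype (co-inherited), while B families are assigned out of step
    with the A families, so chloroplast relationships mirror the A genome
    tree and conflict with the B genome tree.
    """
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    for f in range(n_families):
        pool.add_family(f"Af{f + 1}", "A", rng)
        pool.add_family(f"Bf{f + 1}", "B", rng)
    entries = []
    k = 0
    for f in range(n_families):
        for i in range(inds_per_family):
            # B family deliberately decoupled from the A family
            bfam = f"Bf{(f + 1 + i) % n_families + 1}"
            entry = _tetraploid(f"t{k + 1}", f"P. fam{f + 1}",
                                f"Af{f + 1}", bfam)
            entries.append((entry, f"Af{f + 1}"))
            k += 1
    return _realize(config, pool, entries, rng)


def chimera_benchmark_community(config: SimConfig | None = None,
                                n_individuals: int = 6) -> Dataset:
    """F1-style individuals carrying one A and one B haplotype.

    Every PCR recombinant is then a splice of two strongly divergent
    templates, the setting in which chimera screening is evaluated.
    """
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    entries: list[tuple[PedigreeEntry, str | None]] = []
    for k in range(n_individuals):
        entries.append((PedigreeEntry(
            f"f1_{k + 1}", "P. f1hybrid",
            [HaplotypeSpec("hA", "A"), HaplotypeSpec("hB", "B")],
            maternal="A"), None))
    return _realize(config, pool, entries, rng)


def wide_cross_community(config: SimConfig | None = None) -> Dataset:
    """Allotetraploids whose A genome is sister to the diploid reference.

    The lineage guide tree places A next to E with B outside, mirroring
    the asymmetry that lets a constraint test reject A+B sisterhood: the
    AB tetraploids must then be the product of a wide cross.
    """
    config = config if config is not None else SimConfig()
    if config.lineage_tree is None:
        config = replace(config, lineage_tree=ABEF_GUIDE_TREE)
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    entries: list[tuple[PedigreeEntry, str | None]] = [
        (_diploid("rud1", "P. dip", "E"), None),
        (_diploid("rud2", "P. dip", "E"), None),
        (_diploid("out1", "P. out", "F"), None),
        (_diploid("out2", "P. out", "F"), None),
        (_tetraploid("wid1", "P. wide", None, None), None),
        (_tetraploid("wid2", "P. wide", None, None), None),
        (_tetraploid("wid3", "P. wide", None, None), None),
    ]
    return _realize(config, pool, entries, rng)


def autotetraploid_community(config: SimConfig | None = None) -> Dataset:
    """Autotetraploids: four haplotypes of one lineage (two sub-lineages),
    with diploid E individuals as the reference outgroup."""
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    pool.add_family("Af1", "A", rng)
    pool.add_family("Af2", "A", rng)
    entries: list[tuple[PedigreeEntry, str | None]] = [
        (_diploid("rud1", "P. dip", "E"), None),
        (_diploid("rud2", "P. dip", "E"), None),
        (_diploid("out1", "P. out", "F"), None),
        (_diploid("out2", "P. out", "F"), None),
    ]
    for k in range(3):
        entries.append((PedigreeEntry(
            f"aut{k + 1}", "P. auto",
            [HaplotypeSpec("a1", "A", "Af1"), HaplotypeSpec("a2", "A", "Af1"),
             HaplotypeSpec("a3", "A", "Af2"), HaplotypeSpec("a4", "A", "Af2")],
            gametes=[("doubling", "unreduced")], maternal="A"), None))
    return _realize(config, pool, entries, rng)


def higher_polyploid_community(config: SimConfig | None = None,
                               route: str = "unreduced") -> Dataset:
    """Hexaploid-origin scenarios with explicitly inherited alleles.

    route='unreduced': the hexaploid is an unreduced x reduced cross of
    two tetraploids that share their A family but differ in B family;
    the co-sampled octoploid descends from unrelated families, so no
    alleles are shared with the hexaploid.
    route='octoploid': the hexaploid is a reduced x reduced cross of an
    octoploid and a tetraploid, and therefore carries exact copies of
    octoploid alleles.
    """
    if route not in ("unreduced", "octoploid"):
        raise ValueError("route must be 'unreduced' or 'octoploid'")
    config = config if config is not None else SimConfig()
    if config.lineage_tree is None:
        config = replace(config, lineage_tree=ABE_GUIDE_TREE)
    rng = np.random.default_rng(config.seed)
    pool = simulate_genomes(config, rng)
    for fam, lin in [("Af1", "A"), ("Af2", "A"), ("Bf1", "B"),
                     ("Bf2", "B"), ("Bf3", "B")]:
        pool.add_family(fam, lin, rng)

    def tet(ind_id, fa, fb):
        return simulate_individual(_tetraploid(ind_id, "P. tet", fa, fb),
                                   pool, rng, plastid_family=fa)

    t1 = tet("tet1", "Af1", "Bf1")
    t2 = tet("tet2", "Af1", "Bf1")
    t3 = tet("tet3", "Af1", "Bf2")
    individuals = [simulate_individual(_diploid("rud1", "P. dip", "E"),
                                       pool, rng),
                   simulate_individual(_diploid("rud2", "P. dip", "E"),
                                       pool, rng),
                   t1, t2, t3]
    if route == "unreduced":
        t4 = tet("tet4", "Af2", "Bf3")
        t5 = tet("tet5", "Af2", "Bf3")
        oct1 = cross_individuals("oct1", "P. octo", t4, t5,
                                 "unreduced", "unreduced", rng)
        hex1 = cross_individuals("hex1", "P. hexa", t1, t3,
                                 "unreduced", "reduced", rng)
        individuals += [t4, oct1, hex1]
    else:
        t4 = tet("tet4", "Af2", "Bf1")
        oct1 = cross_individuals("oct1", "P. octo", t1, t4,
                                 "unreduced", "unreduced", rng)
        hex1 = cross_individuals("hex1", "P. hexa", oct1, t2,
                                 "reduced", "reduced", rng)
        individuals += [t4, oct1, hex1]
    return realize_clones(config, pool, individuals, rng)


# ---------------------------------------------------------------------------
# on-disk form

def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """One clone FASTA per nuclear locus, plastid FASTAs, truth and
    pedigree TSVs, and the generating configuration as key: value text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, _ in dataset.config.loci:
        records = []
        for ind in dataset.individuals:
            records.extend(dataset.clones[(ind.id, locus)])
        write_fasta(outdir / f"{locus}.clones.fasta", records)
    for locus, _ in dataset.config.plastid_loci:
        write_fasta(outdir / f"{locus}.fasta",
                    [(ind.id, ind.plastid[locus])
                     for ind in dataset.individuals])

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("clone_id\tindividual\tlocus\tsource_hap\tsource_hap2\t"
                 "lineage\terror_positions\tbreakpoint\tofftarget\n")
        for t in dataset.truth.clones:
            fh.write("\t".join([
                t.clone_id, t.individual, t.locus,
                t.source_hap or "", t.source_hap2 or "", t.lineage or "",
                ";".join(str(p) for p in t.error_positions),
                "" if t.breakpoint is None else str(t.breakpoint),
                "1" if t.offtarget else "0"]) + "\n")

    with open(outdir / "pedigree.tsv", "w") as fh:
        fh.write("individual\tspecies\tploidy\tmaternal\thaplotypes\tgametes\n")
        for ind in dataset.individuals:
            e = ind.entry
            haps = ";".join(f"{h.hap_id}:{h.lineage}:{h.family or '-'}"
                            for h in e.haplotypes)
            gam = ";".join(f"{p}:{g}" for p, g in e.gametes)
            fh.write(f"{e.individual}\t{e.species}\t{e.ploidy}\t"
                     f"{e.maternal}\t{haps}\t{gam}\n")

    with open(outdir / "config.txt", "w") as fh:
        c = dataset.config
        fh.write(f"n_genomes: {c.n_genomes}\n")
        fh.write(f"genome_divergence: {c.genome_divergence}\n")
        fh.write(f"allele_theta: {c.allele_theta}\n")
        fh.write(f"sublineage_divergence: {c.sublineage_divergence}\n")
        fh.write("loci: " + ",".join(f"{n}={l}" for n, l in c.loci) + "\n")
        fh.write("plastid_loci: " +
                 ",".join(f"{n}={l}" for n, l in c.plastid_loci) + "\n")
        fh.write(f"clones_per_individual: {c.clones_per_individual[0]}-"
                 f"{c.clones_per_individual[1]}\n")
        fh.write(f"pcr_error_rate: {c.pcr_error_rate}\n")
        fh.write(f"chimera_rate: {c.chimera_rate}\n")
        fh.write(f"nontarget_rate: {c.nontarget_rate}\n")
        fh.write(f"seed: {c.seed}\n")
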