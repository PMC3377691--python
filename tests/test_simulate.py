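import numpy as np
import pytest
from scipy import stats

from homoeosort.seqs import p_distance, read_fasta
from homoeosort.simulate import (Dataset, HaplotypeSpec, PedigreeEntry,
                                 SimConfig, cross_individuals,
                                 simulate_clones, simulate_genomes,
                                 simulate_individual, standard_community,
                                 write_dataset)

TWO_LOCI = (("adh1", 1279), ("knotted1", 986))


# ---------------------------------------------------------------------------
# configuration

@pytest.mark.parametrize("kwargs", [
    {"n_genomes": 0},
    {"n_genomes": 13},
    {"pcr_error_rate": -0.1},
    {"chimera_rate": 1.5},
    {"loci": (("short", 50),)},
    {"clones_per_individual": (10, 4)},
])
def test_config_validation_rejects_bad_values(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# genome simulation

def test_two_lineages_diverge_at_poisson_rate():
    cfg = SimConfig(n_genomes=2, genome_divergence=0.05,
                    loci=(("locus", 1000),), plastid_loci=(("cp", 1000),),
                    seed=7)
    pool = simulate_genomes(cfg)
    a = pool.lineage_seqs["A"]["locus"]
    b = pool.lineage_seqs["B"]["locus"]
    diffs = sum(1 for x, y in zip(a, b) if x != y)
    lo, hi = stats.poisson.ppf([0.005, 0.995], 50)
    assert lo <= diffs <= hi


def test_zero_divergence_gives_identical_lineages():
    cfg = SimConfig(n_genomes=3, genome_divergence=0.0, loci=TWO_LOCI, seed=0)
    pool = simulate_genomes(cfg)
    assert (pool.lineage_seqs["A"]["adh1"] == pool.lineage_seqs["B"]["adh1"]
            == pool.lineage_seqs["C"]["adh1"])


def test_single_lineage_is_allowed():
    cfg = SimConfig(n_genomes=1, loci=TWO_LOCI, seed=0)
    pool = simulate_genomes(cfg)
    assert list(pool.lineage_seqs) == ["A"]


def test_inter_lineage_distance_dominates_allelic_distance():
    cfg = SimConfig(seed=3, loci=TWO_LOCI)
    pool = simulate_genomes(cfg)
    rng = np.random.default_rng(3)
    entry = PedigreeEntry("x", "sp", [HaplotypeSpec("h1", "A"),
                                      HaplotypeSpec("h2", "A"),
                                      HaplotypeSpec("h3", "B"),
                                      HaplotypeSpec("h4", "B")],
                          maternal="A")
    ind = simulate_individual(entry, pool, rng)
    haps = ind.haplotypes["adh1"]
    intra = [p_distance(haps["h1"], haps["h2"]),
             p_distance(haps["h3"], haps["h4"])]
    inter = [p_distance(haps[a], haps[b])
             for a in ("h1", "h2") for b in ("h3", "h4")]
    assert min(inter) > max(intra)


# ---------------------------------------------------------------------------
# individuals and gametes

def test_diploid_has_two_same_lineage_haplotypes():
    cfg = SimConfig(seed=1, loci=TWO_LOCI)
    pool = simulate_genomes(cfg)
    rng = np.random.default_rng(1)
    entry = PedigreeEntry("d", "sp", [HaplotypeSpec("h1", "E"),
                                      HaplotypeSpec("h2", "E")],
                          maternal="E")
    ind = simulate_individual(entry, pool, rng)
    assert len(ind.haplotypes["adh1"]) == 2


def test_allotetraploid_has_two_haplotypes_per_genome():
    ds = standard_community(SimConfig(seed=1, loci=TWO_LOCI))
    vir1 = ds.individual("vir1")
    lineages = [h.lineage for h in vir1.entry.haplotypes]
    assert sorted(lineages) == ["A", "A", "B", "B"]
    assert len(vir1.haplotypes["adh1"]) == 4


def test_octoploid_cross_yields_eight_haplotypes_in_four_groups():
    ds = standard_community(SimConfig(seed=1, loci=TWO_LOCI))
    oct1 = ds.individual("oct1")
    assert len(oct1.haplotypes["adh1"]) == 8
    groups = {(h.lineage, h.family) for h in oct1.entry.haplotypes}
    assert len(groups) == 4
    assert ds.truth.expected_types["oct1"] == {"A": 2, "B": 2}


def test_unreduced_gamete_copies_parent_alleles_verbatim():
    cfg = SimConfig(seed=5, loci=TWO_LOCI)
    pool = simulate_genomes(cfg)
    rng = np.random.default_rng(5)
    tet = PedigreeEntry("t", "sp",
                        [HaplotypeSpec("a1", "A"), HaplotypeSpec("a2", "A"),
                         HaplotypeSpec("b1", "B"), HaplotypeSpec("b2", "B")],
                        maternal="A")
    mother = simulate_individual(tet, pool, rng)
    father = simulate_individual(
        PedigreeEntry("f", "sp", tet.haplotypes, maternal="A"), pool, rng)
    child = cross_individuals("c", "sp", mother, father,
                              "unreduced", "reduced", rng)
    assert len(child.haplotypes["adh1"]) == 6
    child_seqs = set(child.haplotypes["adh1"].values())
    assert set(mother.haplotypes["adh1"].values()) <= child_seqs
    assert child.plastid == mother.plastid


def test_bad_gamete_mode_and_unknown_lineage_error():
    cfg = SimConfig(seed=2, loci=TWO_LOCI)
    pool = simulate_genomes(cfg)
    rng = np.random.default_rng(2)
    with pytest.raises(KeyError):
        simulate_individual(
            PedigreeEntry("x", "sp", [HaplotypeSpec("h1", "Z"),
                                      HaplotypeSpec("h2", "Z")],
                          maternal="Z"),
            pool, rng)


# ---------------------------------------------------------------------------
# clones

def _simple_individual(cfg, seed=0):
    pool = simulate_genomes(cfg)
    rng = np.random.default_rng(seed)
    entry = PedigreeEntry("x", "sp", [HaplotypeSpec("h1", "A"),
                                      HaplotypeSpec("h2", "B")],
                          maternal="A")
    return simulate_individual(entry, pool, rng), rng


def test_noise_free_clones_copy_their_haplotype():
    cfg = SimConfig(seed=0, loci=TWO_LOCI, pcr_error_rate=0.0,
                    chimera_rate=0.0)
    ind, rng = _simple_individual(cfg)
    clones, truths = simulate_clones(ind, "adh1", cfg, rng)
    for (cid, seq), truth in zip(clones, truths):
        assert seq == ind.haplotypes["adh1"][truth.source_hap]
        assert truth.error_positions == []
        assert not truth.is_chimera


def test_forced_chimeras_are_single_breakpoint_mosaics():
    cfg = SimConfig(seed=0, loci=TWO_LOCI, pcr_error_rate=0.0,
                    chimera_rate=1.0)
    ind, rng = _simple_individual(cfg)
    clones, truths = simulate_clones(ind, "adh1", cfg, rng)
    for (cid, seq), truth in zip(clones, truths):
        assert truth.is_chimera
        assert truth.source_hap != truth.source_hap2
        left = ind.haplotypes["adh1"][truth.source_hap]
        right = ind.haplotypes["adh1"][truth.source_hap2]
        assert seq == left[:truth.breakpoint] + right[truth.breakpoint:]
        assert 0 < truth.breakpoint < len(seq)


def test_pcr_error_count_within_binomial_interval():
    cfg = SimConfig(seed=11, loci=(("locus", 1000),),
                    plastid_loci=(("cp", 1000),),
                    chimera_rate=0.0, clones_per_individual=(16, 16))
    ind, rng = _simple_individual(cfg, seed=11)
    _, truths = simulate_clones(ind, "locus", cfg, rng)
    total = sum(len(t.error_positions) for t in truths)
    n = 16 * 1000
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 5e-4)
    assert lo <= total <= hi
    for t in truths:
        assert all(0 <= p < 1000 for p in t.error_positions)


def test_every_clone_has_exactly_one_truth_record():
    ds = standard_community(SimConfig(seed=4, loci=TWO_LOCI))
    clone_ids = [cid for recs in ds.clones.values() for cid, _ in recs]
    truth_ids = [t.clone_id for t in ds.truth.clones]
    assert sorted(clone_ids) == sorted(truth_ids)
    assert len(set(truth_ids)) == len(truth_ids)


# ---------------------------------------------------------------------------
# determinism and round trips

def test_fixed_seed_reproduces_dataset_exactly():
    d1 = standard_community(SimConfig(seed=9, loci=TWO_LOCI))
    d2 = standard_community(SimConfig(seed=9, loci=TWO_LOCI))
    assert d1.clones == d2.clones
    assert d1.plastid_concat() == d2.plastid_concat()


def test_written_fasta_reparses_identically(tmp_path):
    ds = standard_community(SimConfig(seed=2, loci=TWO_LOCI))
    write_dataset(ds, tmp_path)
    for locus, _ in ds.config.loci:
        records = read_fasta(tmp_path / f"{locus}.clones.fasta")
        expected = [rec for ind in ds.individuals
                    for rec in ds.clones[(ind.id, locus)]]
        assert records == expected
    assert (tmp_path / "truth.tsv").exists()
    assert (tmp_path / "pedigree.tsv").exists()
    assert "seed: 2" in (tmp_path / "config.txt").read_text()
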