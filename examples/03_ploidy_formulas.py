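"""End-to-end ploidy inference: sequence types -> genomic formulas.

Runs the full pipeline on the default community (diploids, AB
allotetraploids, an unreduced-gamete hexaploid and a wide-cross
octoploid, five nuclear loci) and prints the per-individual genomic
composition table. One sequence type means diploid, two tetraploid,
three hexaploid, four octoploid.
"""

from homoeosort.pipeline import PipelineParams, run_pipeline
from homoeosort.simulate import SimConfig, standard_community

dataset = standard_community(SimConfig(seed=1))
result = run_pipeline(dataset.clone_records(),
                      loci=[n for n, _ in dataset.config.loci],
                      plastid=dataset.plastid_concat(),
                      reference=dataset.diploid_ids(),
                      params=PipelineParams(seed=1))

print(result.composition_table().to_string(index=False))
print()
print("true ploidies:",
      {ind.id: ind.entry.ploidy for ind in dataset.individuals})
# The formula column lists one letter per inferred genome copy, e.g. the
# hexaploid reads ABB: one A-clade copy and two distinct B-clade copies,
# the signature of a tetraploid x tetraploid cross with one unreduced
# gamete from parents differing in their B subgenome.
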