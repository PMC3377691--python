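"""Flow-cytometry ploidy classification against a tetraploid standard.

Nuclear DNA fluorescence scales with chromosome-set number, so the ratio
to a co-measured 4x standard reads out ploidy directly. Ratios falling
between the accepted bands stay unclassified.
"""

import pandas as pd

from homoeosort.flow import classify_table

samples = pd.DataFrame({
    "taxon": ["P. amarulum", "P. amarum", "P. virgatum (upland)",
              "P. virgatum (upland)", "ambiguous sample"],
    "accession": ["aml419", "ama8", "vir414069", "vir315725", "x1"],
    "fluorescence": [101.0, 148.0, 204.0, 99.0, 125.0],
    "standard_fluorescence": [100.0, 100.0, 100.0, 100.0, 100.0],
})
print(classify_table(samples, tolerance=0.12).to_string(index=False))
# 1.0x the standard -> 4x, 1.5x -> 6x, 2x -> 8x; the 1.25 ratio is midway
# between the 4x and 6x bands and is reported unclassified.
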