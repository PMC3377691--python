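"""Flow-cytometry ploidy classification against an internal standard.

Nuclear DNA content scales linearly with chromosome-set number, so the
ratio of a sample's mean fluorescence to that of a co-measured standard
of known ploidy estimates the sample's ploidy directly. A sample is
classified to the nearest even ploidy level (2x/4x/6x/8x) only when its
ratio falls within ``tolerance`` of that level's expected ratio;
otherwise it is reported unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["FlowSample", "classify_ploidy", "classify_table",
           "read_flow_tsv", "write_flow_tsv"]

LEVELS = (2, 4, 6, 8)


@dataclass(frozen=True)
class FlowSample:
    accession: str
    fluorescence: float
    standard_fluorescence: float
    n_nuclei: int = 3000
    standard_ploidy: int = 4

    def __post_init__(self) -> None:
        if self.fluorescence <= 0 or self.standard_fluorescence <= 0:
            raise ValueError("fluorescence values must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.standard_ploidy not in LEVELS:
            raise ValueError("standard ploidy must be one of 2, 4, 6, 8")


def classify_ploidy(sample: FlowSample, tolerance: float = 0.12) -> str:
    """Nearest-level ploidy call from the fluorescence ratio.

    The default tolerance (0.12) keeps the acceptance bands of adjacent
    levels disjoint for a tetraploid standard (level spacing 0.5).
    """
    if not 0.0 < tolerance < 0.25:
        raise ValueError("tolerance must lie in (0, 0.25)")
    r = sample.fluorescence / sample.standard_fluorescence
    level = min(LEVELS, key=lambda lv: (abs(r - lv / sample.standard_ploidy), lv))
    if abs(r - level / sample.standard_ploidy) <= tolerance:
        return f"{level}x"
    return "unclassified"


def classify_table(df: pd.DataFrame, tolerance: float = 0.12) -> pd.DataFrame:
    """Classify a table with columns taxon, accession, fluorescence,
    standard_fluorescence (optional n_nuclei, standard_ploidy)."""
    out = df.copy()
    calls = []
    for _, row in df.iterrows():
        sample = FlowSample(
            accession=str(row["accession"]),
            fluorescence=float(row["fluorescence"]),
            standard_fluorescence=float(row["standard_fluorescence"]),
            n_nuclei=int(row.get("n_nuclei", 3000)),
            standard_ploidy=int(row.get("standard_ploidy", 4)))
        calls.append(classify_ploidy(sample, tolerance))
    out["ploidy_estimate"] = calls
    return out


def read_flow_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_flow_tsv(df: pd.DataFrame, path: str | Path,
                   header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
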