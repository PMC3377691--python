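"""Packaged reference tables: flow-cytometry calls, genome-clade
membership, and per-species genomic compositions from the original
switchgrass polyploidy survey, as machine-readable TSVs."""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

__all__ = [
    "load_table", "flow_cytometry_table", "genome_membership_table",
    "genomic_composition_table", "fixture_text", "species_key",
    "component_letters", "multigenome_species", "distinct_genome_letters",
]

_FILES = {
    2: "table2_flow_cytometry.tsv",
    5: "table5_genome_membership.tsv",
    6: "table6_genomic_compositions.tsv",
}


def fixture_text(table: int) -> str:
    """Raw fixture content (byte-stable)."""
    if table not in _FILES:
        raise KeyError(f"no packaged table {table}")
    return (resources.files("homoeosort.fixtures") / _FILES[table]).read_text()


def load_table(table: int) -> pd.DataFrame:
    if table not in _FILES:
        raise KeyError(f"no packaged table {table}")
    with resources.as_file(resources.files("homoeosort.fixtures")
                           / _FILES[table]) as path:
        return pd.read_csv(path, sep="\t")


def flow_cytometry_table() -> pd.DataFrame:
    return load_table(2)


def genome_membership_table() -> pd.DataFrame:
    return load_table(5)


def genomic_composition_table() -> pd.DataFrame:
    return load_table(6)


def species_key(name: str) -> str:
    """Collapse infraspecific rows onto their species.

    'P. virgatum subsp. cubense' -> 'P. virgatum'; 'P. aff. aquaticum'
    -> 'P. aquaticum' (the affinis row is a population of uncertain
    identity counted with its nearest species, matching the survey's
    count of 23 sampled species).
    """
    name = re.sub(r"\s*\(.*\)", "", name).strip()
    name = name.replace(" aff. ", " ")
    name = re.sub(r"\s+subsp\..*$", "", name)
    parts = name.split()
    return " ".join(parts[:2])


def component_letters(components: str) -> set[str]:
    """Distinct genome letters in a composition string (annotations such
    as '(+)' or '?' are ignored; lowercase = uncertain, ignored)."""
    return {ch for ch in components if ch.isupper()}


def multigenome_species(df: pd.DataFrame | None = None) -> tuple[int, int]:
    """(number of species with >= 2 genome lineages, number of species)."""
    df = genomic_composition_table() if df is None else df
    per_species: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        key = species_key(row["species"])
        per_species.setdefault(key, set()).update(
            component_letters(row["components"]))
    multi = sum(1 for letters in per_species.values() if len(letters) >= 2)
    return multi, len(per_species)


def distinct_genome_letters(df: pd.DataFrame | None = None) -> set[str]:
    df = genomic_composition_table() if df is None else df
    letters: set[str] = set()
    for comp in df["components"]:
        letters |= component_letters(comp)
    return letters
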