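"""Sequence containers, IUPAC coding, and FASTA I/O."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# 4-bit encoding: A=1, C=2, G=4, T=8; ambiguity codes are unions; gaps and
# N carry no information and map to the full set.
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15,
}
BITS_TO_IUPAC = {v: k for k, v in IUPAC_BITS.items() if k not in "-?"}

_ENCODE = np.zeros(256, dtype=np.uint8)
for ch, bits in IUPAC_BITS.items():
    _ENCODE[ord(ch)] = bits
    _ENCODE[ord(ch.lower())] = bits

_SINGLE = {1, 2, 4, 8}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into 4-bit state masks."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes == 0).any():
        bad = seq[int(np.argmax(codes == 0))]
        raise ValueError(f"unrecognized base {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BITS_TO_IUPAC[int(c)] for c in codes)


class Alignment:
    """An immutable multiple sequence alignment (equal-length rows)."""

    def __init__(self, names: Iterable[str], seqs: Iterable[str]):
        self.names = list(names)
        self.seqs = [s.upper() for s in seqs]
        if not self.names:
            raise ValueError("empty alignment")
        if len(self.names) != len(self.seqs):
            raise ValueError("names/sequences length mismatch")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = np.vstack([encode(s) for s in self.seqs])
        return self._codes

    def row(self, name: str) -> str:
        return self.seqs[self.names.index(name)]

    def take_columns(self, cols: np.ndarray) -> "Alignment":
        sub = self.codes[:, cols]
        return Alignment(self.names, [decode(r) for r in sub])

    def subset(self, names: Iterable[str]) -> "Alignment":
        names = list(names)
        idx = {n: i for i, n in enumerate(self.names)}
        return Alignment(names, [self.seqs[idx[n]] for n in names])

    def concat(self, other: "Alignment") -> "Alignment":
        if self.names != other.names:
            raise ValueError("concatenation requires identical taxa")
        return Alignment(self.names,
                         [a + b for a, b in zip(self.seqs, other.seqs)])


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-complete ACGT sites."""
    ca, cb = encode(a), encode(b)
    if ca.shape != cb.shape:
        raise ValueError("sequences differ in length")
    single = np.isin(ca, (1, 2, 4, 8)) & np.isin(cb, (1, 2, 4, 8))
    n = int(single.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    return float((ca[single] != cb[single]).sum()) / n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")
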