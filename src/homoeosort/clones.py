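"""Clone polishing: alignment, off-target and chimera screening, allele
clustering and consensus calling for cloned amplicon reads.

The polishing logic follows the classic cloning-study rules: a substitution
seen in a single clone is treated as PCR error; variants shared by two or
more clones are real, and clones separated by two or more real differences
are different alleles. PCR recombinants (one-breakpoint mosaics of two
allele clusters) and off-target inserts are excluded before consensus
sequences are called by per-column majority (ties become IUPAC ambiguity
codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from .seqs import BITS_TO_IUPAC, IUPAC_BITS

__all__ = [
    "CloneRecord", "CloneAlignment", "AlleleCluster", "ChimeraCall",
    "PolishParams", "ProcessedSet", "align_clones", "detect_nontarget",
    "detect_chimeras", "cluster_alleles", "call_consensus",
    "process_clone_set",
]

ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class CloneRecord:
    id: str
    individual: str
    locus: str
    seq: str
    raw_length: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty clone sequence")
        bad = set(self.seq.upper()) - ALPHABET
        if bad:
            raise ValueError(f"clone {self.id}: invalid characters {bad}")


@dataclass
class CloneAlignment:
    locus: str
    individual: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one clone")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, clone_id: str) -> str:
        return self.rows[self.ids.index(clone_id)]

    def subset(self, ids: list[str]) -> "CloneAlignment":
        keep = [self.ids.index(i) for i in ids]
        return CloneAlignment(self.locus, self.individual,
                              [self.ids[k] for k in keep],
                              [self.rows[k] for k in keep])


@dataclass
class AlleleCluster:
    members: list[str]
    consensus: str
    singleton_errors: dict[int, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ChimeraCall:
    clone_id: str
    parents: tuple[int, int]        # indices into the provisional clusters
    breakpoint: int                 # 0-based alignment column
    left_support: int
    right_support: int
    saved_mismatches: int
    verdict: str = "chimeric"


# ---------------------------------------------------------------------------
# alignment

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def align_clones(clones: list[CloneRecord]) -> CloneAlignment:
    """Center-star multiple alignment of one individual x locus clone set.

    The center is the clone minimizing summed pairwise edit distance (ties
    by lowest id); all others are aligned to it by global pairwise
    alignment (match +1, mismatch -1, gap -2). When every clone has the
    same length, gaps can never pay for themselves under this scoring and
    the identity alignment is returned directly.
    """
    if not clones:
        raise ValueError("no clones to align")
    key = {(c.individual, c.locus) for c in clones}
    if len(key) != 1:
        raise ValueError("clones span multiple individual x locus sets")
    individual, locus = clones[0].individual, clones[0].locus
    order = sorted(clones, key=lambda c: c.id)
    ids = [c.id for c in order]
    seqs = [c.seq.upper() for c in order]

    if len({len(s) for s in seqs}) == 1:
        return CloneAlignment(locus, individual, ids, seqs)

    total = np.zeros(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = edlib.align(seqs[i], seqs[j])["editDistance"]
            total[i] += d
            total[j] += d
    center = min(range(len(seqs)), key=lambda i: (total[i], ids[i]))
    aligner = _aligner()
    cseq = seqs[center]

    # per-sequence: inserted run before each center position (plus trailing)
    parsed: list[tuple[list[str], list[str]]] = []
    for i, s in enumerate(seqs):
        if i == center:
            parsed.append(([""] * (len(cseq) + 1), list(cseq)))
            continue
        aln = aligner.align(cseq, s)[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        inserts = [""]
        chars: list[str] = []
        for cc, sc in zip(c_aln, s_aln):
            if cc == "-":
                inserts[-1] += sc
            else:
                chars.append(sc)
                inserts.append("")
        parsed.append((inserts, chars))

    max_ins = [max(p[0][k] and len(p[0][k]) or 0 for p in parsed)
               for k in range(len(cseq) + 1)]
    rows = []
    for inserts, chars in parsed:
        row = []
        for k in range(len(cseq)):
            row.append(inserts[k].ljust(max_ins[k], "-"))
            row.append(chars[k])
        row.append(inserts[len(cseq)].ljust(max_ins[len(cseq)], "-"))
        rows.append("".join(row))
    return CloneAlignment(locus, individual, ids, rows)


# ---------------------------------------------------------------------------
# off-target screening

def detect_nontarget(alignment: CloneAlignment,
                     ceiling: float = 0.25) -> set[str]:
    """Flag clones whose p-distance to *every* other clone exceeds the
    inter-genome ceiling. Single-clone sets are never flagged."""
    n = len(alignment.ids)
    if n < 2:
        return set()
    mat = _matrix(alignment.rows)
    single = np.isin(mat, (1, 2, 4, 8))
    flagged = set()
    for i in range(n):
        all_far = True
        for j in range(n):
            if i == j:
                continue
            both = single[i] & single[j]
            nsites = int(both.sum())
            p = ((mat[i] != mat[j]) & both).sum() / nsites if nsites else 1.0
            if p <= ceiling:
                all_far = False
                break
        if all_far:
            flagged.add(alignment.ids[i])
    return flagged


def _matrix(rows: list[str]) -> np.ndarray:
    out = np.zeros((len(rows), len(rows[0])), dtype=np.uint8)
    table = np.zeros(256, dtype=np.uint8)
    for ch, bits in IUPAC_BITS.items():
        table[ord(ch)] = bits
    # keep gaps distinct from N for clustering/consensus purposes
    table[ord("-")] = 16
    for i, r in enumerate(rows):
        out[i] = table[np.frombuffer(r.encode(), dtype=np.uint8)]
    return out


# clustering/consensus states: the four bases plus gap; N (15) is missing
STATES = np.array([1, 2, 4, 8, 16], dtype=np.uint8)


def _state_counts(mat: np.ndarray) -> np.ndarray:
    """(5, L) per-column counts of A, C, G, T and gap."""
    return np.stack([(mat == s).sum(axis=0) for s in STATES]).astype(np.int32)


def _consensus_from_counts(counts: np.ndarray) -> np.ndarray:
    """Majority state per column; base ties become IUPAC unions (a tie
    that involves a gap keeps the tied bases); all-missing columns -> N."""
    best = counts.max(axis=0)
    winners = counts == best[None, :]
    or_val = (winners[0].astype(np.uint8) * 1
              | winners[1].astype(np.uint8) * 2
              | winners[2].astype(np.uint8) * 4
              | winners[3].astype(np.uint8) * 8)
    return np.where(or_val > 0, or_val, np.uint8(16)).astype(np.uint8)


# ---------------------------------------------------------------------------
# allele clustering

def cluster_alleles(alignment: CloneAlignment,
                    exclude: set[str] | None = None) -> list[AlleleCluster]:
    """Group clones into allele clusters under the singleton-error /
    two-difference rules.

    A column state differing from the column majority is a *real* variant
    iff at least two clones carry it; singleton variants are masked as PCR
    error. Clones sharing exactly the same set of real variants form a
    cluster; clusters whose real-variant profiles differ at fewer than two
    columns are then merged (a single shared difference does not make a
    new allele), which also folds in lone error-laden clones.
    """
    exclude = exclude or set()
    ids = [i for i in alignment.ids if i not in exclude]
    if not ids:
        raise ValueError("no clones retained")
    sub = alignment.subset(ids)
    mat = _matrix(sub.rows)
    n, L = mat.shape

    counts = _state_counts(mat)
    # majority per column; ties resolve to the smallest state code
    majority = STATES[np.argmax(counts, axis=0)]
    variant = (mat != majority[None, :]) & (mat != 15)
    # real variants: a (column, state) carried by >= 2 clones
    real = np.zeros_like(variant)
    for col in np.flatnonzero(variant.any(axis=0)):
        states, counts = np.unique(mat[variant[:, col], col],
                                   return_counts=True)
        for st, c in zip(states, counts):
            if c >= 2:
                real[:, col] |= variant[:, col] & (mat[:, col] == st)

    signatures: dict[frozenset, list[int]] = {}
    for i in range(n):
        cols = np.flatnonzero(real[i])
        sig = frozenset((int(c), int(mat[i, c])) for c in cols)
        signatures.setdefault(sig, []).append(i)

    clusters = [(sig, rows) for sig, rows in signatures.items()]
    clusters.sort(key=lambda c: (-len(c[1]), min(ids[r] for r in c[1])))

    def profile_diff(s1: frozenset, s2: frozenset) -> int:
        m1, m2 = dict(s1), dict(s2)
        cols = set(m1) | set(m2)
        return sum(1 for c in cols if m1.get(c) != m2.get(c))

    merged = True
    while merged and len(clusters) > 1:
        merged = False
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                diff = profile_diff(clusters[a][0], clusters[b][0])
                if diff <= 1:
                    key = (diff, min(ids[r] for r in clusters[a][1]),
                           min(ids[r] for r in clusters[b][1]))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        if best is not None:
            _, a, b = best
            sig_a, rows_a = clusters[a]
            _, rows_b = clusters[b]
            bigger = sig_a if len(rows_a) >= len(clusters[b][1]) else clusters[b][0]
            clusters[a] = (bigger, rows_a + rows_b)
            del clusters[b]
            clusters.sort(key=lambda c: (-len(c[1]), min(ids[r] for r in c[1])))
            merged = True

    out = []
    for _, rows in clusters:
        members = sorted(ids[r] for r in rows)
        out.append(call_consensus(sub.subset(members)))
    out.sort(key=lambda c: (-c.size, c.members[0]))
    return out


def call_consensus(alignment: CloneAlignment) -> AlleleCluster:
    """Majority-rule consensus over a cluster of clones.

    Gap is an ordinary state; ties among bases are encoded as IUPAC
    ambiguity codes (a tie that involves a gap keeps the tied bases).
    """
    mat = _matrix(alignment.rows)
    states = _consensus_from_counts(_state_counts(mat))
    consensus = "".join("-" if s == 16 else BITS_TO_IUPAC[int(s)]
                        for s in states)
    dissent = (mat != states[None, :]).sum(axis=0)
    singleton_errors = {int(c): int(dissent[c]) for c in np.flatnonzero(dissent)}
    return AlleleCluster(sorted(alignment.ids), consensus, singleton_errors)


# ---------------------------------------------------------------------------
# chimera detection

def detect_chimeras(alignment: CloneAlignment,
                    clusters: list[AlleleCluster],
                    m: int = 2, d: int = 2) -> list[ChimeraCall]:
    """Screen every clone for a one-breakpoint mosaic of two clusters.

    For each ordered cluster pair (X, Y), diagnostic columns are those
    where the two consensi disagree (both unambiguous). A clone is called
    chimeric if some breakpoint leaves >= ``m`` diagnostic matches to X on
    the left and >= ``m`` to Y on the right, and the mosaic explanation
    has at least ``d`` fewer mismatches than the best single-cluster
    explanation. The clone itself is excluded from its own cluster's
    consensus while testing.

    Whole clusters are screened the same way: two recombinants that share
    a breakpoint region validate each other into a small "allele" cluster,
    so each cluster consensus is also tested as a mosaic of the others and
    a chimeric cluster is excluded member by member.
    """
    if len(clusters) < 2:
        return []
    mat = _matrix(alignment.rows)
    idx = {cid: k for k, cid in enumerate(alignment.ids)}
    member_rows = {ci: [idx[mid] for mid in cl.members if mid in idx]
                   for ci, cl in enumerate(clusters)}
    base_counts = {ci: _state_counts(mat[rows])
                   for ci, rows in member_rows.items() if rows}
    full_cons = {ci: _consensus_from_counts(c)
                 for ci, c in base_counts.items()}
    calls = []
    for clone_id in alignment.ids:
        r = idx[clone_id]
        row = mat[r]
        # candidate parents: clusters with >=1 member besides this clone;
        # the clone is excluded from its own cluster's consensus
        cons: dict[int, np.ndarray] = {}
        for ci, rows in member_rows.items():
            if not rows:
                continue
            if r in rows:
                if len(rows) < 2:
                    continue
                adjusted = base_counts[ci] - (STATES[:, None] == row[None, :])
                cons[ci] = _consensus_from_counts(adjusted)
            else:
                cons[ci] = full_cons[ci]
        if len(cons) < 2:
            continue
        best = _best_mosaic(row, cons, m, d)
        if best is not None:
            parents, b, ls, rs, saved = best
            calls.append(ChimeraCall(clone_id, parents, b, ls, rs, saved))

    # cluster-level screen: a *small* cluster whose consensus is a mosaic
    # of two strictly larger clusters marks every member chimeric (the
    # size constraint stops chimeric singletons from being abused as
    # parents to "explain" genuine allele clusters)
    flagged = {c.clone_id for c in calls}
    sizes = {ci: len(rows) for ci, rows in member_rows.items()}
    for ci, cl in enumerate(clusters):
        if ci not in full_cons:
            continue
        if all(mid in flagged for mid in cl.members):
            continue
        row = full_cons[ci]
        cons = {cj: c for cj, c in full_cons.items()
                if cj != ci and sizes[cj] > sizes[ci]}
        if len(cons) < 2:
            continue
        best = _best_mosaic(row, cons, m, d)
        if best is not None:
            parents, b, ls, rs, saved = best
            for mid in cl.members:
                if mid not in flagged:
                    calls.append(ChimeraCall(mid, parents, b, ls, rs, saved))
                    flagged.add(mid)
    return calls


def _best_mosaic(row: np.ndarray, cons: dict[int, np.ndarray],
                 m: int, d: int
                 ) -> tuple[tuple[int, int], int, int, int, int] | None:
    """Best (parents, breakpoint, supports, saving) mosaic explanation of
    ``row`` over ordered pairs of the given consensi, or None."""
    single_bits = (1, 2, 4, 8)
    best_single = min(
        int(((row != c) & np.isin(c, single_bits)
             & np.isin(row, single_bits)).sum())
        for c in cons.values())
    best_key = best = None
    for xi in sorted(cons):
        for yi in sorted(cons):
            if xi == yi:
                continue
            cx, cy = cons[xi], cons[yi]
            informative = (np.isin(cx, single_bits)
                           & np.isin(cy, single_bits)
                           & np.isin(row, single_bits))
            diag = np.flatnonzero((cx != cy) & informative)
            if diag.size < 2 * m:
                continue
            match_x = row[diag] == cx[diag]
            match_y = row[diag] == cy[diag]
            mmx = ((row != cx) & informative).astype(np.int64)
            mmy = ((row != cy) & informative).astype(np.int64)
            pre_x = np.concatenate([[0], np.cumsum(mmx)])
            pre_y = np.concatenate([[0], np.cumsum(mmy)])
            left_x = np.cumsum(match_x)
            right_y = match_y.sum() - np.cumsum(match_y)
            # breakpoints between consecutive diagnostic columns
            for t in range(1, diag.size):
                ls, rs = int(left_x[t - 1]), int(right_y[t - 1])
                if ls < m or rs < m:
                    continue
                b = (int(diag[t - 1]) + int(diag[t])) // 2 + 1
                mosaic = int(pre_x[b] + pre_y[-1] - pre_y[b])
                saved = best_single - mosaic
                if saved < d:
                    continue
                key = (-saved, mosaic, xi, yi, b)
                if best_key is None or key < best_key:
                    best_key = key
                    best = ((xi, yi), b, ls, rs, saved)
    return best


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class PolishParams:
    nontarget_ceiling: float = 0.25
    chimera_m: int = 2
    chimera_d: int = 2


@dataclass
class ProcessedSet:
    individual: str
    locus: str
    alignment: CloneAlignment
    clusters: list[AlleleCluster]
    consensi: list[tuple[str, str]]       # (name, sequence)
    consensus_members: dict[str, list[str]]
    chimera_calls: list[ChimeraCall]
    nontarget_ids: set[str]
    excluded: set[str]


def process_clone_set(clones: list[CloneRecord],
                      params: PolishParams | None = None) -> ProcessedSet:
    """Full polishing pass: align, screen off-targets, screen chimeras,
    cluster alleles and call one consensus per allele cluster.

    Consensus names follow ``<individual>.t<i>.<n_clones>`` with clusters
    ordered by size (largest first).
    """
    params = params or PolishParams()
    alignment = align_clones(clones)
    nontarget = detect_nontarget(alignment, params.nontarget_ceiling)
    retained = [i for i in alignment.ids if i not in nontarget]
    provisional = cluster_alleles(alignment, exclude=nontarget)
    calls = detect_chimeras(alignment.subset(retained), provisional,
                            m=params.chimera_m, d=params.chimera_d)
    chimeric = {c.clone_id for c in calls}
    excluded = nontarget | chimeric
    final = cluster_alleles(alignment, exclude=excluded)
    consensi = []
    members = {}
    individual = clones[0].individual
    locus = clones[0].locus
    for i, cl in enumerate(final):
        name = f"{individual}.t{i + 1}.{cl.size}"
        consensi.append((name, cl.consensus))
        members[name] = cl.members
    return ProcessedSet(individual, locus, alignment, final, consensi,
                        members, calls, nontarget, excluded)


def group_clone_fasta(records: list[tuple[str, str]],
                      locus: str | None = None
                      ) -> dict[tuple[str, str], list[CloneRecord]]:
    """Group FASTA records by individual x locus.

    Ids follow the grammar ``<individual>|<locus>|<clone#>``.
    """
    out: dict[tuple[str, str], list[CloneRecord]] = {}
    for name, seq in records:
        parts = name.split("|")
        if len(parts) != 3:
            raise ValueError(f"clone id {name!r} does not follow "
                             "'<individual>|<locus>|<clone#>'")
        ind, loc, _ = parts
        if locus is not None and loc != locus:
            continue
        out.setdefault((ind, loc), []).append(
            CloneRecord(name, ind, loc, seq, raw_length=len(seq)))
    return out
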