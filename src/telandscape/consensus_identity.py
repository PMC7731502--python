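"""Copy alignment, consensus reconstruction, identity matrices and clusters.

Identity convention, fixed project-wide and printed in every report header:
identity = matches / aligned columns, with columns gapped in *both*
sequences excluded, times 100. Pairwise alignments are global with affine
gaps (match 1, mismatch -1, gap of length L costs 5 + (L-1)); the multiple
aligner is progressive — single-linkage guide tree on k-mer distance,
profiles merged by aligning their majority consensus strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._sequtils import encode, revcomp

__all__ = [
    "Alignment",
    "ConsensusModel",
    "IdentityMatrix",
    "align_copies",
    "build_consensus",
    "pairwise_identity",
    "identity_matrix",
    "cluster_by_identity",
    "IDENTITY_DEFINITION",
]

IDENTITY_DEFINITION = "identity = 100 * matches / aligned columns (dual-gap columns excluded)"

_BASE_ORDER = "ACGT"  # alphabetical tie-break order for consensus calls


@dataclass
class Alignment:
    """A gapped multiple alignment over A,C,G,T,N,-."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)


@dataclass
class ConsensusModel:
    """Majority-rule consensus with per-column support."""

    sequence: str
    support: list[float]
    n_copies: int
    representative: bool = False  # too few copies for a real consensus


@dataclass
class IdentityMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, percent

    @property
    def mean(self) -> float:
        return float(np.mean(self._offdiag()))

    @property
    def sd(self) -> float:
        return float(np.std(self._offdiag()))

    def _offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]


def _nt_aligner() -> Align.PairwiseAligner:
    # semi-global: end gaps are free, so a clipped or truncated sequence
    # slides to its homologous position instead of smearing across a flank
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    try:  # Biopython >= 1.88 naming
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def global_alignment_score(a: str, b: str) -> float:
    """Score of the optimal global alignment under the project scoring."""
    return float(_nt_aligner().score(a.upper(), b.upper()))


def _pair_align(a: str, b: str) -> tuple[str, str]:
    """One optimal global alignment of two sequences as gapped strings."""
    aln = _nt_aligner().align(a, b)[0]
    # reconstruct gapped strings from the aligned coordinate blocks
    ta, qa = [], []
    t_blocks, q_blocks = aln.aligned
    ti = qi = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ta.append(a[ti:ts] + "-" * (qs - qi))
        qa.append("-" * (ts - ti) + b[qi:qs])
        ta.append(a[ts:te])
        qa.append(b[qs:qe])
        ti, qi = te, qe
    ta.append(a[ti:] + "-" * (len(b) - qi))
    qa.append("-" * (len(a) - ti) + b[qi:])
    return "".join(ta), "".join(qa)


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_set(seq: str, k: int = 6) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    sa, sb = _kmer_set(a, k), _kmer_set(b, k)
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _profile_consensus(rows: list[str]) -> str:
    """Majority non-gap base per column; all-gap columns emit N (kept so
    column count is preserved while merging)."""
    arr = np.array([encode(r.replace("-", "N")) for r in rows])
    gap = np.array([[c == "-" for c in r] for r in rows])
    out = []
    for j in range(arr.shape[1]):
        col = arr[:, j][~gap[:, j]]
        col = col[col < 4]
        if col.size == 0:
            out.append("N")
            continue
        counts = np.bincount(col, minlength=4)
        best = min((b for b in "ACGT" if counts[encode(b)[0]] == counts.max()))
        out.append(best)
    return "".join(out)


def _merge_profiles(p1: list[tuple[str, str]], p2: list[tuple[str, str]]):
    c1 = _profile_consensus([r for _, r in p1])
    c2 = _profile_consensus([r for _, r in p2])
    a1, a2 = _pair_align(c1, c2)
    out = []
    for name, row in p1:
        out.append((name, _project(row, a1)))
    for name, row in p2:
        out.append((name, _project(row, a2)))
    return out


def _project(row: str, gapped_consensus: str) -> str:
    """Insert the gaps the consensus acquired into a member row."""
    out = []
    i = 0
    for c in gapped_consensus:
        if c == "-":
            out.append("-")
        else:
            out.append(row[i])
            i += 1
    assert i == len(row)
    return "".join(out)


def align_copies(seqs: list[str] | dict[str, str] | list[tuple[str, str]]) -> Alignment:
    """Progressive multiple alignment of element copies.

    Guide order comes from single-linkage clustering on k-mer distance;
    profiles are merged by globally aligning their consensus strings and
    projecting the resulting gaps onto every member row. Deterministic.
    """
    if isinstance(seqs, dict):
        named = list(seqs.items())
    elif seqs and isinstance(seqs[0], tuple):
        named = list(seqs)
    else:
        named = [(f"seq{i+1}", s) for i, s in enumerate(seqs)]
    named = [(n, s.upper()) for n, s in named]
    if not named:
        raise ValueError("no sequences to align")
    if len(named) == 1:
        return Alignment(rows=named)

    n = len(named)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(named[i][1], named[j][1])

    # single-linkage agglomeration; ties broken by smallest member index
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [named[i]] for i in range(n)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(profiles)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                u, v = active[ai], active[aj]
                d = min(dist[x, y] for x in members[u] for y in members[v])
                key = (d, min(members[u] + members[v]), u, v)
                if best is None or key < best[0]:
                    best = (key, u, v)
        _, u, v = best
        profiles[u] = _merge_profiles(profiles[u], profiles[v])
        members[u] = sorted(members[u] + members[v])
        del profiles[v], members[v]
        active = sorted(profiles)
    return Alignment(rows=profiles[active[0]])


# ---------------------------------------------------------------------------
# consensus


def build_consensus(
    alignment: Alignment,
    min_support: float = 0.5,
    min_copies: int = 3,
) -> ConsensusModel:
    """Majority-rule consensus of an alignment.

    Per column the most frequent non-gap base among non-gap rows is taken
    (ties alphabetical A<C<G<T); columns where gaps hold the majority are
    dropped. With fewer than ``min_copies`` rows the result is flagged as a
    representative sequence rather than a true consensus.
    """
    if alignment.nrow == 0:
        raise ValueError("empty alignment")
    rows = [r for _, r in alignment.rows]
    seq = []
    support = []
    for j in range(alignment.ncol):
        col = [r[j] for r in rows]
        non_gap = [c for c in col if c != "-"]
        if len(non_gap) * 2 < len(col):
            continue  # gap majority
        counts: dict[str, int] = {}
        for c in non_gap:
            if c != "N":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue
        best = min(counts, key=lambda b: (-counts[b], _BASE_ORDER.find(b)))
        seq.append(best)
        support.append(counts[best] / len(non_gap))
    return ConsensusModel(
        sequence="".join(seq),
        support=support,
        n_copies=alignment.nrow,
        representative=alignment.nrow < min_copies,
    )


# ---------------------------------------------------------------------------
# identity


def _identity_dp(a: str, b: str) -> tuple[int, int]:
    """(matches, aligned columns) of the canonical optimal global alignment.

    Ties between co-optimal alignments are broken by maximising the match
    count, then the number of aligned residue pairs. All three criteria are
    additive, so they fold into one integer objective
    ``score*K1 + matches*K2 + pairs`` and a plain DP maximises it — which
    makes the result exactly symmetric in (a, b) and invariant under
    reverse-complementing both arguments, unlike "first reported optimal
    alignment" conventions.
    """
    ca, cb = encode(a), encode(b)
    n, m = len(ca), len(cb)
    K2 = min(n, m) + 1
    K1 = K2 * K2
    MATCH = K1 + K2 + 1       # score +1, match +1, pair +1
    MISMATCH = -K1 + 1        # score -1, pair +1
    OPEN, EXT = -5 * K1, -1 * K1
    NEG = -(2 ** 60)

    sub_row = np.where((cb[None, :] == ca[:, None]) & (cb[None, :] < 4),
                       MATCH, MISMATCH).astype(np.int64)
    M_prev = np.full(m + 1, NEG, dtype=np.int64)
    X_prev = np.full(m + 1, NEG, dtype=np.int64)
    Y_prev = np.zeros(m + 1, dtype=np.int64)  # free leading gap in a
    M_prev[0] = 0
    Y_prev[0] = NEG
    X_prev[0] = 0
    js = np.arange(1, m + 1, dtype=np.int64)
    best = np.maximum(M_prev, Y_prev).max()  # n == 0 boundary
    for i in range(1, n + 1):
        M = np.full(m + 1, NEG, dtype=np.int64)
        diag = np.maximum(np.maximum(M_prev[:-1], X_prev[:-1]), Y_prev[:-1])
        M[1:] = diag + sub_row[i - 1]
        X = np.maximum(M_prev + OPEN, X_prev + EXT)
        X[0] = 0  # free leading gap in b
        t = M[:-1] + OPEN - EXT * np.arange(1, m + 1, dtype=np.int64)
        Y = np.full(m + 1, NEG, dtype=np.int64)
        Y[1:] = np.maximum.accumulate(t) + EXT * js
        best = max(best, int(max(M[m], X[m], Y[m])))  # free trailing gap in a
        M_prev, X_prev, Y_prev = M, X, Y
    # free trailing gap in b: best over the last row
    best = max(best, int(np.maximum(np.maximum(M_prev, X_prev), Y_prev).max()))
    score, rem = divmod(best, K1)
    matches, pairs = divmod(rem, K2)
    columns = n + m - pairs
    return int(matches), int(columns)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity after global alignment (dual-gap columns excluded)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matches, columns = _identity_dp(a.upper(), b.upper())
    return 100.0 * matches / columns if columns else 0.0


def identity_matrix(seqs: dict[str, str] | list[tuple[str, str]]) -> IdentityMatrix:
    """All-pairs percent identity with summary mean ± SD."""
    named = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(named) < 2:
        raise ValueError("need at least two sequences")
    ids = [n for n, _ in named]
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(named[i][1], named[j][1])
    return IdentityMatrix(ids=ids, matrix=m)


def cluster_by_identity(matrix: IdentityMatrix, threshold: float) -> dict[str, int]:
    """Single-linkage components over edges with identity >= threshold.

    Cluster labels are integers ordered by decreasing size, then by the
    lexicographically smallest member.
    """
    n = len(matrix.ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.matrix[i, j] >= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(matrix.ids[i])
    ordered = sorted(comps.values(), key=lambda ms: (-len(ms), sorted(ms)[0]))
    out = {}
    for label, ms in enumerate(ordered, start=1):
        for mname in ms:
            out[mname] = label
    return out
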