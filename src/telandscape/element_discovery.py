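"""Find copies of a transposon family in a genome and annotate their anatomy.

The search is a k-mer seeded, gapped-extension local homology scan on both
strands, gated by explicit identity and coverage thresholds (defaults 80%
identity, 40% query coverage). Boundary refinement, terminal-inverted-repeat
(TIR) detection, TA target-site-duplication (TSD) checks and the
intact / full_length / truncated status call live here too.

Conventions: all intervals are 0-based half-open on the plus strand; minus
hits carry a strand flag. Identity = matches / aligned columns (dual-gap
columns excluded); coverage = aligned query positions / query length. N
never counts as a match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align

from ._sequtils import encode, revcomp

__all__ = [
    "Hit",
    "TirPair",
    "ElementCopy",
    "homology_search",
    "count_copies",
    "merge_hits",
    "define_boundaries",
    "detect_tirs",
    "detect_tsd",
    "classify_copy",
]


class InputError(ValueError):
    pass


@dataclass
class Hit:
    """One local-alignment hit of the query family in a genome."""

    genome_id: str
    start: int
    end: int
    strand: str
    identity: float  # percent of aligned columns matching
    coverage: float  # percent of query length aligned
    score: float = 0.0

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError("hit interval must satisfy start < end")
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity/coverage must lie in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TirPair:
    """Element-relative intervals of the left TIR and its inverted partner."""

    left: tuple[int, int]
    right: tuple[int, int]
    length: int
    mismatches: int


@dataclass
class ElementCopy:
    """A discovered copy with its structural annotation."""

    hit: Hit
    sequence: str
    tir_pair: TirPair | None = None
    tsd: str | None = None
    status: str = "truncated"
    low_confidence: bool = False
    boundaries_from_tir: bool = False


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(alignment, query: str, target: str) -> tuple[float, float, int, int]:
    """(identity %, coverage %, target_start, target_end) of one local alignment."""
    tcoords, qcoords = alignment.aligned  # target/query coordinate blocks
    matches = 0
    columns = 0
    qaligned = 0
    for (ts, te), (qs, qe) in zip(tcoords, qcoords):
        t_seg = encode(target[ts:te])
        q_seg = encode(query[qs:qe])
        ok = (t_seg == q_seg) & (t_seg < 4)  # N never matches
        matches += int(ok.sum())
        columns += te - ts
        qaligned += qe - qs
    # gap columns between consecutive blocks count toward aligned columns
    for i in range(1, len(tcoords)):
        columns += (tcoords[i][0] - tcoords[i - 1][1]) + (qcoords[i][0] - qcoords[i - 1][1])
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * qaligned / len(query)
    return (identity, coverage, int(tcoords[0][0]), int(tcoords[-1][1]),
            int(qcoords[0][0]), int(qcoords[-1][1]))


def _word_hashes(codes: np.ndarray, word_size: int) -> np.ndarray:
    """Base-4 hash of every word; -1 where the word contains N."""
    if len(codes) < word_size:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, word_size).astype(np.int64)
    powers = 4 ** np.arange(word_size, dtype=np.int64)
    hashes = (np.minimum(windows, 3) * powers).sum(axis=1)
    hashes[(windows > 3).any(axis=1)] = -1
    return hashes


def _seed_windows(genome: str, query: str, word_size: int) -> list[tuple[int, int]]:
    """Candidate genome windows from exact k-mer seed clusters."""
    qlen = len(query)
    q_hashes = _word_hashes(encode(query), word_size)
    g_hashes = _word_hashes(encode(genome), word_size)
    valid = set(q_hashes[q_hashes >= 0].tolist())
    if not valid:
        return []
    mask = np.isin(g_hashes, np.fromiter(valid, dtype=np.int64)) & (g_hashes >= 0)
    hits = np.flatnonzero(mask).tolist()
    if not hits:
        return [], np.empty(0, dtype=np.int64)
    # cluster seed positions separated by < query length into one window
    windows = []
    cur_lo = hits[0]
    cur_hi = hits[0]
    for g in hits[1:]:
        if g - cur_hi < max(word_size, qlen // 2):
            cur_hi = g
        else:
            windows.append((cur_lo, cur_hi))
            cur_lo = cur_hi = g
    windows.append((cur_lo, cur_hi))
    # seeds cover the homologous core; a modest margin absorbs seedless ends
    margin = max(300, qlen // 4)
    out = [
        (max(0, lo - margin), min(len(genome), hi + word_size + margin))
        for lo, hi in windows
    ]
    return out, np.asarray(hits, dtype=np.int64)


def homology_search(
    genome: str | dict[str, str],
    query: str,
    min_identity: float = 80.0,
    min_coverage: float = 40.0,
    word_size: int = 11,
    genome_id: str = "genome",
) -> list[Hit]:
    """k-mer seeded local homology search on both strands.

    Accepts a single sequence or an id -> sequence dict (multi-contig).
    Returns merged hits meeting both gates, sorted by genome position.
    """
    if isinstance(genome, dict):
        out = []
        for gid, seq in genome.items():
            out.extend(
                homology_search(seq, query, min_identity, min_coverage, word_size, gid)
            )
        return out

    query = query.upper()
    genome = genome.upper()
    if len(query) < word_size:
        raise InputError("query shorter than word size")
    frac_acgt = np.mean(encode(query) < 4) if query else 0.0
    if frac_acgt < 0.9:
        raise InputError("query contains too many non-ACGT characters")
    if not genome:
        return []

    aligner = _local_aligner()
    # a window may span several adjacent copies: after accepting the best
    # local hit, recurse into the flanking sub-windows
    min_score = max(20, int(word_size))
    raw: list[Hit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        stack, seeds = _seed_windows(genome, q, word_size)
        while stack:
            lo, hi = stack.pop()
            if hi - lo < word_size:
                continue
            window = genome[lo:hi]
            alignments = aligner.align(window, q)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            if aln.score < min_score:
                continue
            identity, coverage, ts, te, qs, qe = _alignment_stats(aln, q, window)
            if identity >= min_identity and coverage >= min_coverage:
                # local alignment trims mutated query termini; when only a
                # few bases are missing (substitution damage, not a
                # truncated copy) restore the full element boundary
                ext5 = qs if 0 < qs <= 15 else 0
                ext3 = (len(q) - qe) if 0 < len(q) - qe <= 15 else 0
                gstart = max(0, lo + ts - ext5)
                gend = min(len(genome), lo + te + ext3)
                raw.append(
                    Hit(genome_id, gstart, gend, strand, identity, coverage,
                        score=float(aln.score))
                )
            # recurse only into flanking sub-windows that still hold a seed
            for sub_lo, sub_hi in ((lo, lo + ts), (lo + te, hi)):
                if sub_hi - sub_lo >= word_size and np.any(
                        (seeds >= sub_lo) & (seeds < sub_hi - word_size + 1)):
                    stack.append((sub_lo, sub_hi))
    merged = merge_hits(raw)
    merged.sort(key=lambda h: (h.start, h.end))
    return merged


def merge_hits(hits: list[Hit]) -> list[Hit]:
    """Merge hits overlapping by more than 50% of the shorter one.

    The higher-identity interval (score as tie-break) represents the merged
    locus.
    """
    ordered = sorted(hits, key=lambda h: (-h.identity, -h.score, h.start, h.end))
    kept: list[Hit] = []
    for h in ordered:
        redundant = False
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0.5 * min(h.length, k.length):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def count_copies(
    genome: str | dict[str, str],
    consensus: str,
    min_identity: float = 80.0,
    min_coverage: float = 40.0,
    word_size: int = 11,
) -> int:
    """Copy number = non-overlapping merged hits of the consensus."""
    if not consensus:
        raise InputError("consensus must be non-empty")
    return len(homology_search(genome, consensus, min_identity, min_coverage, word_size))


# ---------------------------------------------------------------------------
# boundaries


@dataclass
class Locus:
    """A hit with flanking context extracted for boundary refinement."""

    hit: Hit
    sequence: str  # hit plus flanks, plus-strand of the element
    element_offset: int  # start of the raw hit within `sequence`
    element_length: int
    refined: tuple[int, int] | None = None  # genome coords after refinement
    boundaries_from_tir: bool = False


def define_boundaries(
    hits: list[Hit],
    genome: str | dict[str, str],
    flank: int = 2000,
    min_column_support: float = 0.6,
    pad: int = 50,
) -> list[Locus]:
    """Extract each hit with ±flank context and refine boundaries by MSA.

    For refinement the hits are aligned together with a short ``pad`` of
    flanking sequence (the full ±flank context is kept on the Locus for
    downstream use but would drown the aligner in unrelated sequence);
    element boundaries are set at the maximal run of columns where at least
    ``min_column_support`` of the rows agree on one base — flanking
    sequence is unrelated between insertion sites, so it fails that test.
    0.6 rather than a bare majority because with ~10 rows a random flank
    column passes a 50% same-base test too often. With a single locus no
    alignment is possible and boundary definition is deferred to TIR
    detection (``boundaries_from_tir``).
    """
    from .consensus_identity import align_copies  # local import, cycle-free

    if not hits:
        raise InputError("no hits to define boundaries for")
    genomes = genome if isinstance(genome, dict) else {hits[0].genome_id: genome}
    loci = []
    padded = []  # (pad_lo, pad_hi, oriented subsequence)
    for h in hits:
        contig = genomes[h.genome_id]
        lo = max(0, h.start - flank)
        hi = min(len(contig), h.end + flank)
        seg = contig[lo:hi]
        if h.strand == "-":
            seg = revcomp(seg)
            off = hi - h.end
        else:
            off = h.start - lo
        loci.append(Locus(hit=h, sequence=seg, element_offset=off,
                          element_length=h.length))
        plo = max(0, h.start - pad)
        phi = min(len(contig), h.end + pad)
        pseg = contig[plo:phi]
        if h.strand == "-":
            pseg = revcomp(pseg)
        padded.append((plo, phi, pseg))
    if len(loci) == 1:
        loci[0].boundaries_from_tir = True
        loci[0].refined = (loci[0].hit.start, loci[0].hit.end)
        return loci

    alignment = align_copies([p[2] for p in padded])
    rows = [r for _, r in alignment.rows]
    ncol = alignment.ncol
    arr = np.array([encode(r.replace("-", "N")) for r in rows])
    gap = np.array([[c == "-" for c in r] for r in rows])
    support = np.zeros(ncol)
    nongap_frac = np.zeros(ncol)
    for j in range(ncol):
        nongap_frac[j] = (~gap[:, j]).mean()
        col = arr[:, j][~gap[:, j]]
        col = col[col < 4]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=4)
        support[j] = counts.max() / len(rows)
    # smooth over a short window so isolated alignment-jitter columns do
    # not split the element run, then trim to exact good columns
    w = 9
    kernel = np.ones(w) / w
    smoothed = np.convolve(support, kernel, mode="same")
    good = smoothed >= min_column_support
    best_len = best_start = 0
    run_start = None
    for j in range(ncol + 1):
        if j < ncol and good[j]:
            if run_start is None:
                run_start = j
        else:
            if run_start is not None and j - run_start > best_len:
                best_len, best_start = j - run_start, run_start
            run_start = None
    col_lo, col_hi = best_start, best_start + best_len
    # trim the run ends with a stricter per-column test (near-unanimous and
    # nearly gap-free): the aligner gaps the unrelated flanks so that shared
    # letters stack, which inflates agreement just outside the element
    trim = max(min_column_support, 0.9)
    exact = np.flatnonzero((support[col_lo:col_hi] >= trim)
                           & (nongap_frac[col_lo:col_hi] >= 0.9))
    if exact.size:
        col_lo, col_hi = col_lo + int(exact[0]), col_lo + int(exact[-1]) + 1

    for row, g, lc, (plo, phi, _) in zip(rows, gap, loci, padded):
        ungapped = np.cumsum(~g)  # 1-based count of residues up to column
        seq_lo = int(ungapped[col_lo - 1]) if col_lo > 0 else 0
        seq_hi = int(ungapped[col_hi - 1]) if col_hi > 0 else 0
        if lc.hit.strand == "+":
            lc.refined = (plo + seq_lo, plo + seq_hi)
        else:
            lc.refined = (phi - seq_hi, phi - seq_lo)
    return loci


# ---------------------------------------------------------------------------
# TIR / TSD


def detect_tirs(
    element_seq: str,
    min_len: int = 10,
    max_len: int = 300,
    max_mismatch_frac: float = 0.10,
    jitter: int = 10,
) -> TirPair | None:
    """Best terminal inverted repeat within a ±jitter window at each end.

    Candidate repeats pair a prefix starting at offset a ≤ jitter with a
    suffix ending at offset b ≤ jitter from the terminus. Among lengths
    whose mismatch fraction stays at or below ``max_mismatch_frac`` the
    detector maximises matches − 4·mismatches (so a perfect repeat is never
    over-extended into flanking sequence that merely stays under the
    fraction gate). None when nothing of at least ``min_len`` qualifies.
    """
    seq = element_seq.upper()
    E = len(seq)
    if E < 2 * min_len:
        return None
    codes = encode(seq)
    comp = codes.copy()
    acgt = codes < 4
    comp[acgt] = codes[acgt] ^ 3  # A<->T (0^3=3), G<->C (1^3=2)
    best: TirPair | None = None
    best_key: tuple | None = None
    max_jitter = min(jitter, E // 4)
    for a in range(0, max_jitter + 1):
        for b in range(0, max_jitter + 1):
            span = min(max_len, (E - a - b) // 2)
            if span < min_len:
                continue
            x = codes[a:a + span]
            y = comp[E - b - span:E - b][::-1]
            mism = np.cumsum((x != y) | (x > 3) | (y > 3))
            lengths = np.arange(1, span + 1)
            ok = np.flatnonzero((mism <= max_mismatch_frac * lengths)
                                & (lengths >= min_len))
            if ok.size == 0:
                continue
            scores = (lengths[ok] - mism[ok]) - 4 * mism[ok]
            pick = ok[int(np.flatnonzero(scores == scores.max())[-1])]  # longest on ties
            L = int(pick) + 1
            m = int(mism[pick])
            key = (int(scores.max()), L, -m, -(a + b))
            if best_key is None or key > best_key:
                best_key = key
                best = TirPair(left=(a, a + L), right=(E - b - L, E - b),
                               length=L, mismatches=m)
    return best


def detect_tsd(genome: str, interval: tuple[int, int]) -> str | None:
    """Return "TA" iff the element is flanked by TA on both sides."""
    start, end = interval
    if start < 2 or end + 2 > len(genome):
        warnings.warn("element at contig edge; TSD undeterminable", stacklevel=2)
        return None
    left = genome[start - 2:start].upper()
    right = genome[end:end + 2].upper()
    return "TA" if left == "TA" and right == "TA" else None


def classify_copy(tir_pair: TirPair | None, orf, triad) -> str:
    """Status call: intact (TIRs + complete D,D,E transposase), full_length
    (TIRs, disrupted ORF), truncated (no TIR pair).

    ``orf`` is a motif_scan.OrfAnnotation or None; ``triad`` a
    motif_scan.CatalyticTriad or None.
    """
    if tir_pair is None:
        return "truncated"
    if orf is not None and triad is not None:
        return "intact"
    return "full_length"


def annotate_copy(
    genome: str,
    hit: Hit,
    anchor=None,
    min_orf_aa: int = 300,
) -> ElementCopy:
    """Full structural annotation of one hit: TIRs, TSD, ORF/triad status."""
    from . import motif_scan

    seq = genome[hit.start:hit.end].upper()
    if hit.strand == "-":
        seq = revcomp(seq)
    n_frac = seq.count("N") / max(1, len(seq))
    tirs = detect_tirs(seq)
    tsd = detect_tsd(genome, (hit.start, hit.end))
    orf = motif_scan.find_orf(seq, min_len_aa=min_orf_aa)
    triad = None
    if orf is not None:
        if anchor is None:
            anchor = motif_scan.default_anchor()
        triad = motif_scan.locate_dde_triad(orf.protein, anchor)
    return ElementCopy(
        hit=hit,
        sequence=seq,
        tir_pair=tirs,
        tsd=tsd,
        status=classify_copy(tirs, orf, triad),
        low_confidence=n_frac > 0.10,
    )
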