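"""Horizontal-transfer inference from element vs host-gene distances.

A transposon inherited vertically accumulates divergence between two
species at the same pace as a neutral host gene; a horizontally transferred
element is younger than the species split, so its between-species distance
undercuts the host-gene (e.g. RAG1) distance. For every shared species pair
the test compares d_TE with d_gene and flags the pair when
``margin * d_TE < d_gene`` (strict inequality, margin 1 by default),
optionally gated on a minimum species split time.

Distance methods: ``p`` (proportion of differing sites), ``k2p`` (Kimura
two-parameter), and ``mcl`` — the Tamura–Nei-form composite-likelihood
distance with base frequencies pooled over the whole alignment, the
behaviour MEGA's "maximum composite likelihood" default denotes. All use
pairwise deletion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._sequtils import encode
from .dating import SaturationError, SubstitutionCounts, count_substitutions, k2p_distance

__all__ = [
    "DistanceTable",
    "HtComparison",
    "DistanceSummary",
    "pairwise_distance_table",
    "tn93_mcl_distance",
    "ht_compare",
    "summarize_distances",
    "pair_count",
]

METHODS = ("p", "k2p", "mcl")


@dataclass
class DistanceTable:
    method: str
    ids: list[str]
    entries: dict[frozenset, float]  # undefined pairs absent
    undefined: set[frozenset]

    def get(self, a: str, b: str) -> float | None:
        return self.entries.get(frozenset((a, b)))


@dataclass
class HtComparison:
    species_a: str
    species_b: str
    d_te: float
    d_gene: float
    split_myr: float | None
    ht_flag: bool


@dataclass
class DistanceSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float


# ---------------------------------------------------------------------------
# distances


def _pair_codes(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ca = encode(a.upper().replace("-", "N"))
    cb = encode(b.upper().replace("-", "N"))
    use = (ca < 4) & (cb < 4)
    return ca[use], cb[use]


def tn93_mcl_distance(a: str, b: str, freqs: np.ndarray) -> float:
    """Tamura–Nei composite-likelihood distance for one pair.

    ``freqs`` are base frequencies (A,G,C,T) pooled over the alignment.
    P1/P2 are the purine and pyrimidine transition proportions, Q the
    transversion proportion; saturation raises SaturationError.
    """
    ca, cb = _pair_codes(a, b)
    n = len(ca)
    if n == 0:
        raise ValueError("no compared sites")
    pa, pg, pc, pt = freqs
    gR, gY = pa + pg, pc + pt
    diff = ca != cb
    purine = (ca < 2) & (cb < 2)
    pyrimidine = (ca >= 2) & (cb >= 2)
    P1 = float((diff & purine).sum()) / n
    P2 = float((diff & pyrimidine).sum()) / n
    Q = float((diff & ~purine & ~pyrimidine).sum()) / n
    k1 = 2.0 * pa * pg / gR
    k2 = 2.0 * pc * pt / gY
    k3 = 2.0 * (gR * gY - pa * pg * gY / gR - pc * pt * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("Tamura-Nei correction undefined (saturated)")
    return max(0.0, -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3))


def _pooled_freqs(rows: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for row in rows:
        codes = encode(row.upper().replace("-", "N"))
        codes = codes[codes < 4]
        counts += np.bincount(codes, minlength=4)
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous bases")
    return counts / counts.sum()


def pairwise_distance_table(
    alignment: dict[str, str] | list[tuple[str, str]],
    method: str = "mcl",
) -> DistanceTable:
    """All-pairs distances from a gapless-or-gapped aligned set.

    Pairwise deletion is applied per pair; saturated / undefined pairs are
    recorded in ``undefined`` and excluded from summaries.
    """
    named = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    if len(named) < 2:
        raise ValueError("need at least two aligned sequences")
    if method not in METHODS:
        raise ValueError(f"unsupported method {method!r}; pick from {METHODS}")
    lengths = {len(s) for _, s in named}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    ids = [n for n, _ in named]
    freqs = _pooled_freqs([s for _, s in named]) if method == "mcl" else None
    entries: dict[frozenset, float] = {}
    undefined: set[frozenset] = set()
    for i in range(len(named)):
        for j in range(i + 1, len(named)):
            (na, sa), (nb, sb) = named[i], named[j]
            key = frozenset((na, nb))
            try:
                if method == "p":
                    c = count_substitutions(sa, sb)
                    if c.compared_sites == 0:
                        raise ValueError("no compared sites")
                    d = c.P + c.Q
                elif method == "k2p":
                    d = k2p_distance(count_substitutions(sa, sb))
                else:
                    d = tn93_mcl_distance(sa, sb, freqs)
            except (SaturationError, ValueError):
                undefined.add(key)
                continue
            entries[key] = d
    return DistanceTable(method=method, ids=ids, entries=entries, undefined=undefined)


# ---------------------------------------------------------------------------
# HT test


def ht_compare(
    te_table: DistanceTable,
    gene_table: DistanceTable,
    split_times: dict[frozenset, float] | None = None,
    min_split: float = 0.0,
    margin: float = 1.0,
) -> tuple[list[HtComparison], int, int]:
    """Flag species pairs whose TE distance undercuts the host-gene distance.

    A pair is flagged when ``margin * d_te < d_gene`` (strict) and, if split
    times are supplied, when the species split at least ``min_split`` Myr
    ago. Returns (comparisons, n_flagged, n_total); pairs missing from
    either table are skipped with a warning.
    """
    shared = sorted(set(te_table.ids) & set(gene_table.ids))
    if len(shared) < 2:
        raise ValueError("species sets overlap on fewer than two species")
    comparisons = []
    flagged = 0
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            a, b = shared[i], shared[j]
            key = frozenset((a, b))
            d_te = te_table.entries.get(key)
            d_gene = gene_table.entries.get(key)
            if d_te is None or d_gene is None:
                warnings.warn(f"pair ({a}, {b}) missing/undefined; skipped",
                              stacklevel=2)
                continue
            split = split_times.get(key) if split_times else None
            flag = margin * d_te < d_gene
            if min_split > 0:
                flag = flag and split is not None and split >= min_split
            comparisons.append(HtComparison(a, b, d_te, d_gene, split, flag))
            flagged += int(flag)
    return comparisons, flagged, len(comparisons)


def summarize_distances(table: DistanceTable) -> DistanceSummary:
    """n / mean / population SD / min / max over the defined distances."""
    values = np.array(sorted(table.entries.values()), dtype=float)
    if values.size == 0:
        raise ValueError("no defined distances to summarize")
    return DistanceSummary(
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std()),  # population SD
        min=float(values.min()),
        max=float(values.max()),
    )


def pair_count(cluster_sizes: list[int]) -> int:
    """Total within-cluster unordered pairs: sum of n(n-1)/2."""
    if any(n < 0 for n in cluster_sizes):
        raise ValueError("cluster sizes must be non-negative")
    return sum(n * (n - 1) // 2 for n in cluster_sizes)
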