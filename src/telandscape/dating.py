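"""Kimura two-parameter divergence and insertion-age estimation.

Each element copy is compared with its species consensus under pairwise
deletion (columns with a gap or N in either sequence are excluded). With P
the transition and Q the transversion proportion,

    k = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

and the insertion age follows the neutral-clock relation T = k / (2 r),
with r the lineage-specific neutral substitution rate per site per year.
Distances are flagged saturated when the logarithm's argument is not
positive, in which case no age is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._sequtils import encode, is_transition

__all__ = [
    "SubstitutionCounts",
    "DivergenceRecord",
    "RateTable",
    "Landscape",
    "DEFAULT_RATES",
    "count_substitutions",
    "k2p_distance",
    "insertion_age",
    "date_copy",
    "divergence_landscape",
]

#: neutral substitution rates (substitutions/site/year) by lineage
DEFAULT_RATES: dict[str, float] = {
    "Actinopterygii": 1e-8,
    "Arthropoda": 3.46e-9,
    "Rhinella_marina": 2e-9,
    "Eptatretus_burgeri": 1.9e-9,
    "Anthozoa": 5e-8,
}


class SaturationError(ValueError):
    """Distance undefined: the K2P correction has no real solution."""


@dataclass(frozen=True)
class SubstitutionCounts:
    compared_sites: int
    transitions: int
    transversions: int

    def __post_init__(self):
        if min(self.compared_sites, self.transitions, self.transversions) < 0:
            raise ValueError("counts must be non-negative")
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("more substitutions than compared sites")

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites


@dataclass
class DivergenceRecord:
    copy_id: str
    compared_sites: int
    P: float
    Q: float
    k: float | None
    saturated: bool
    age_years: float | None = None

    @property
    def age_myr(self) -> float | None:
        return None if self.age_years is None else self.age_years / 1e6


class RateTable:
    """lineage label -> neutral rate (substitutions/site/year)."""

    def __init__(self, rates: dict[str, float] | None = None):
        self.rates = dict(DEFAULT_RATES if rates is None else rates)
        for lineage, r in self.rates.items():
            if r <= 0:
                raise ValueError(f"rate for {lineage!r} must be > 0")

    def __getitem__(self, lineage: str) -> float:
        return self.rates[lineage]

    @classmethod
    def from_tsv(cls, path) -> "RateTable":
        rates = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                lineage, r = line.split("\t")[:2]
                if lineage.lower() in ("lineage", "label"):
                    continue
                rates[lineage] = float(r)
        return cls(rates)


@dataclass
class Landscape:
    """Copy counts binned by insertion age (Myr); saturated -> overflow."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow: int  # saturated / undateable copies

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow


# ---------------------------------------------------------------------------


def count_substitutions(aligned_a: str, aligned_b: str) -> SubstitutionCounts:
    """Transition/transversion counts under pairwise deletion.

    Columns with a gap or N in either row are excluded from the comparison;
    A<->G and C<->T are transitions, every other differing pair a
    transversion.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = encode(aligned_a.upper().replace("-", "N"))
    b = encode(aligned_b.upper().replace("-", "N"))
    use = (a < 4) & (b < 4)
    a, b = a[use], b[use]
    ts = int(is_transition(a, b).sum())
    diff = int((a != b).sum())
    return SubstitutionCounts(
        compared_sites=int(use.sum()), transitions=ts, transversions=diff - ts
    )


def k2p_distance(counts: SubstitutionCounts) -> float:
    """Kimura two-parameter distance; raises SaturationError when undefined."""
    if counts.compared_sites == 0:
        raise ValueError("no compared sites: distance undefined")
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f}")
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def insertion_age(k: float, r: float) -> float:
    """Insertion age in years via T = k / (2 r)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if r <= 0:
        raise ValueError("rate must be > 0")
    return k / (2.0 * r)


def date_copy(
    copy_id: str,
    copy_seq: str,
    consensus_seq: str,
    rate: float,
    cpg_adjust: bool = False,
) -> DivergenceRecord:
    """Align one copy to the consensus, estimate k and the insertion age.

    With ``cpg_adjust`` the hypermutable CpG-site columns of the consensus
    are excluded before counting, mirroring the optional CpG-aware mode of
    repeat-landscape tooling (default off).
    """
    from .consensus_identity import _pair_align

    ga, gb = _pair_align(copy_seq.upper(), consensus_seq.upper())
    if cpg_adjust:
        gb_list = list(gb)
        for i, c in enumerate(gb):
            if c == "C":
                # CpG site in the consensus: mask both positions
                j = i + 1
                while j < len(gb) and gb[j] == "-":
                    j += 1
                if j < len(gb) and gb[j] == "G":
                    gb_list[i] = gb_list[j] = "N"
        gb = "".join(gb_list)
    counts = count_substitutions(ga, gb)
    try:
        k = k2p_distance(counts)
    except SaturationError:
        return DivergenceRecord(copy_id, counts.compared_sites,
                                counts.P, counts.Q, None, True)
    return DivergenceRecord(
        copy_id, counts.compared_sites, counts.P, counts.Q, k, False,
        age_years=insertion_age(k, rate),
    )


def divergence_landscape(
    copies: dict[str, str] | list[tuple[str, str]],
    consensus: str,
    rate: float,
    bin_width_myr: float = 0.5,
    max_age_myr: float | None = None,
    cpg_adjust: bool = False,
) -> tuple[Landscape, list[DivergenceRecord]]:
    """Date every copy against the consensus and bin ages into a landscape."""
    named = list(copies.items()) if isinstance(copies, dict) else list(copies)
    if not named:
        raise ValueError("no copies to date")
    records = [
        date_copy(name, seq, consensus, rate, cpg_adjust=cpg_adjust)
        for name, seq in named
    ]
    ages = [r.age_myr for r in records if r.age_myr is not None]
    overflow = sum(1 for r in records if r.saturated)
    if ages:
        top = max_age_myr if max_age_myr is not None else max(max(ages), bin_width_myr)
        n_bins = max(1, int(math.ceil(top / bin_width_myr)))
        edges = np.arange(0, (n_bins + 1) * bin_width_myr, bin_width_myr)[:n_bins + 1]
        counts, _ = np.histogram(ages, bins=edges)
        clipped = sum(1 for a in ages if a > edges[-1])
        counts[-1] += clipped
    else:
        edges = np.array([0.0, bin_width_myr])
        counts = np.zeros(1, dtype=int)
    return Landscape(bin_edges=edges, counts=counts, overflow=overflow), records


def plot_landscape(landscape: Landscape, path, title: str = "Insertion ages"):
    """Bar plot of the age landscape (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    widths = np.diff(landscape.bin_edges)
    ax.bar(landscape.bin_edges[:-1], landscape.counts, width=widths,
           align="edge", edgecolor="black", linewidth=0.3)
    ax.set_xlabel("Insertion age (Myr)")
    ax.set_ylabel("Copies")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
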