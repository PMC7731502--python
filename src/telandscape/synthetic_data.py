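"""Synthetic genomes with planted transposon copies of known age and history.

The generator emulates the structure of a recently expanded Tc1/mariner-like
DNA transposon family: a ~1.6 kb master element with long terminal inverted
repeats (TIRs) and a single transposase ORF carrying a D,D,E catalytic triad
and a GRPR motif; TA target-site duplications at every insertion; a mixture
of intact, ORF-disrupted (full-length) and terminally truncated copies; and,
optionally, horizontal transfer (HT) events that seed a young copy lineage
in a recipient species.

Model of descent
----------------
The master element first evolves *vertically* down the dated species tree
under a Kimura two-parameter (K2P) process at the per-lineage neutral rate,
giving each species its own species-level master. Planted copies then
diverge from that species master by ``planted_k = 2 r T`` substitutions per
site, the inverse of the dating relation ``T = k / (2 r)``. An HT event
(donor, recipient, time) replaces the recipient's copy lineage with copies
descending from the *donor's* species master, each at age equal to the HT
time — which is what makes element distance undercut host-gene distance for
that species pair.

Every random draw flows from a single integer seed, so identical configs
produce byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._sequtils import decode, encode, random_sequence, revcomp, write_fasta
from .tree import SpeciesTree, TreeError

__all__ = [
    "AgePeak",
    "SimulationConfig",
    "TruthRecord",
    "MasterElement",
    "SimulationResult",
    "make_master",
    "mutate_sequence",
    "k2p_event_probabilities",
    "plant_copies",
    "simulate_host_gene",
    "write_simulation",
]

#: neutral substitution rates (substitutions/site/year) per lineage
DEFAULT_RATES: dict[str, float] = {
    "Actinopterygii": 1e-8,
    "Arthropoda": 3.46e-9,
    "Rhinella_marina": 2e-9,
    "Eptatretus_burgeri": 1.9e-9,
    "Anthozoa": 5e-8,
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# aa -> codon list from the standard genetic code (stops excluded)
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class CapacityError(ValueError):
    """Background sequence too short for the requested copies."""


@dataclass(frozen=True)
class AgePeak:
    """One component of the insertion-age mixture (Myr)."""

    mean: float
    sd: float
    weight: float = 1.0


@dataclass(frozen=True)
class HtEvent:
    donor: str
    recipient: str
    time_myr: float


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults mirror the canonical family structure: a 1588 bp element with
    210 bp TIRs and a 341 aa transposase, ~20 copies per genome, and a
    recent (< 5 Myr) insertion burst.
    """

    master_length: int = 1588
    tir_length: int = 210
    orf_span: tuple[int, int] | None = None  # element-relative, stop included
    protein_length: int = 341  # aa, stop excluded
    copies_per_species: int = 20
    age_distribution: tuple[AgePeak, ...] = (AgePeak(mean=2.0, sd=1.0, weight=1.0),)
    truncation_prob: float = 0.3
    kappa: float = 2.0
    rate_table_ref: dict[str, str] | None = None  # leaf -> lineage label
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    ht_events: tuple[HtEvent, ...] = ()
    background_length: int = 50_000
    gc_content: float = 0.41
    seed: int = 0
    # triad / motif placement within the transposase (1-based aa positions)
    d1_pos: int = 160
    d2_pos: int = 200
    triad_spacing: int = 38  # residues strictly between D2 and E
    grpr_pos: int = 20

    def __post_init__(self):
        if self.tir_length <= 0:
            raise ConfigurationError("tir_length must be positive (TIRs required)")
        if self.master_length < 2 * self.tir_length + 3:
            raise ConfigurationError(
                "master_length must be at least 2*tir_length + 3"
            )
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ConfigurationError("truncation_prob must lie in [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must lie in [0, 1]")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")
        orf_nt = 3 * (self.protein_length + 1)
        interior = self.master_length - 2 * self.tir_length
        if orf_nt > interior:
            raise ConfigurationError(
                f"ORF of {orf_nt} nt does not fit the {interior} nt interior"
            )
        if self.orf_span is not None:
            s, e = self.orf_span
            if e - s != orf_nt or s < self.tir_length or e > self.master_length - self.tir_length:
                raise ConfigurationError("orf_span incompatible with master_length/TIRs")
        if not self.age_distribution or any(p.weight < 0 for p in self.age_distribution):
            raise ConfigurationError("age_distribution needs peaks with non-negative weights")

    @property
    def e_pos(self) -> int:
        return self.d2_pos + self.triad_spacing + 1

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        """Build from JSON-style plain types (age peaks / HT events as
        dicts or lists)."""
        d = dict(d)
        if "age_distribution" in d:
            d["age_distribution"] = tuple(
                p if isinstance(p, AgePeak) else AgePeak(**p)
                for p in d["age_distribution"]
            )
        if "ht_events" in d:
            d["ht_events"] = tuple(
                e if isinstance(e, HtEvent)
                else HtEvent(*e) if isinstance(e, (list, tuple)) else HtEvent(**e)
                for e in d["ht_events"]
            )
        if "orf_span" in d and d["orf_span"] is not None:
            d["orf_span"] = tuple(d["orf_span"])
        return cls(**d)


@dataclass(frozen=True)
class MasterElement:
    """The reconstructed-master analogue: sequence plus designed annotation."""

    sequence: str
    tir_length: int
    orf_span: tuple[int, int]  # 0-based half-open, stop codon included
    protein: str
    triad_positions: tuple[int, int, int]  # 1-based aa positions of D, D, E
    grpr_pos: int

    def tir_self_check(self) -> bool:
        L = self.tir_length
        return revcomp(self.sequence[:L]) == self.sequence[-L:]


@dataclass
class TruthRecord:
    """Planted ground truth for one genomic copy (0-based half-open)."""

    species: str
    chrom: str
    start: int
    end: int
    strand: str
    planted_k: float
    planted_age: float  # Myr
    status: str  # intact | full_length | truncated
    via_ht: bool


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: SpeciesTree
    master: MasterElement
    species_masters: dict[str, str]
    genomes: dict[str, str]
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------
# master construction


def _design_protein(config: SimulationConfig, rng: np.random.Generator) -> str:
    """Design the master transposase.

    The protein is random outside the catalytic core, but the neighbourhoods
    of the three catalytic residues are copied from the bundled anchor-set
    consensus so the simulated family is genuinely homologous to the
    reference transposases its triad will later be mapped against — the
    analogue of a real family sharing the conserved DDE domain.
    """
    from .motif_scan import default_anchor

    aa = list(rng.choice(list(_AA20), size=config.protein_length))
    aa[0] = "M"
    g = config.grpr_pos - 1
    d1, d2, e = config.d1_pos - 1, config.d2_pos - 1, config.e_pos - 1
    if not (3 <= g and g + 4 < d1 < d2 < e < config.protein_length):
        raise ConfigurationError("triad/motif positions do not fit the protein")

    anchor = default_anchor()
    cons = anchor.consensus
    c1, c2, c3 = anchor.consensus_triad_positions()
    # conserved blocks around each catalytic residue (clipped to fit)
    for target, source, radius in ((d1, c1, 18), (d2, c2, 12), (e, c3, 18)):
        lo = min(radius, target, source)
        hi = min(radius, config.protein_length - 1 - target, len(cons) - 1 - source)
        for off in range(-lo, hi + 1):
            aa[target + off] = cons[source + off]
    aa[g:g + 4] = list("GRPR")
    # keep the designed triad unambiguous: no other D/E inside the core
    for i in range(d1 + 1, e):
        if aa[i] in "DE" and i not in (d2,):
            aa[i] = "A"
    aa[d1], aa[d2], aa[e] = "D", "D", "E"
    return "".join(aa)


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_BY_AA[a][rng.integers(len(_CODONS_BY_AA[a]))] for a in protein]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def make_master(config: SimulationConfig) -> MasterElement:
    """Build the master element: TIR + spacer + ORF + spacer + TIR'.

    The first ``tir_length`` bases are the exact reverse complement of the
    last ``tir_length`` bases; the ORF is ATG-initiated, stop-terminated and
    in-frame blocked upstream so it is the unique longest plus-strand ORF.
    """
    rng = np.random.default_rng(config.seed)
    protein = _design_protein(config, rng)
    orf = _encode_protein(protein, rng)
    orf_nt = len(orf)
    interior = config.master_length - 2 * config.tir_length
    if config.orf_span is None:
        orf_start = config.tir_length + (interior - orf_nt) // 2
    else:
        orf_start = config.orf_span[0]
    left_pad = orf_start - config.tir_length
    right_pad = interior - orf_nt - left_pad
    if left_pad < 0 or right_pad < 0:
        raise ConfigurationError("orf_span incompatible with master_length")

    tir = random_sequence(config.tir_length, rng, config.gc_content)
    spacer1 = random_sequence(left_pad, rng, config.gc_content)
    if left_pad >= 3:
        spacer1 = spacer1[:-3] + "TAA"  # in-frame block against upstream ATG run-through
    spacer2 = random_sequence(right_pad, rng, config.gc_content)
    seq = tir + spacer1 + orf + spacer2 + revcomp(tir)
    assert len(seq) == config.master_length
    return MasterElement(
        sequence=seq,
        tir_length=config.tir_length,
        orf_span=(orf_start, orf_start + orf_nt),
        protein=protein,
        triad_positions=(config.d1_pos, config.d2_pos, config.e_pos),
        grpr_pos=config.grpr_pos,
    )


# ---------------------------------------------------------------------------
# K2P forward process


def k2p_event_probabilities(k: float, kappa: float) -> tuple[float, float]:
    """Per-site probabilities (transition, each-transversion) after k expected
    substitutions/site under K2P with ts/tv rate ratio kappa.

    Rates are normalised so alpha + 2*beta = 1 per unit branch length.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * k)
    e2 = np.exp(-2.0 * (alpha + beta) * k)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def mutate_sequence(
    seq: str,
    k_target: float,
    kappa: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Evolve ``seq`` for ``k_target`` expected substitutions/site under K2P.

    No indels are introduced; N bases are carried through unchanged. The
    draw is deterministic under a fixed ``seed`` (or caller-supplied RNG).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if k_target == 0:
        return seq
    p_ts, p_tv = k2p_event_probabilities(k_target, kappa)
    codes = encode(seq)
    out = codes.copy()
    acgt = codes < 4
    u = rng.random(len(codes))
    ts = acgt & (u < p_ts)
    tv1 = acgt & (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = acgt & (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = codes[ts] ^ 1
    out[tv1] = codes[tv1] ^ 2
    out[tv2] = codes[tv2] ^ 3
    return decode(out)


def _evolve_down_tree(
    tree: SpeciesTree,
    root_seq: str,
    rate_of_leaf: dict[str, float],
    kappa: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """K2P-evolve a sequence from the root to every leaf.

    Each branch uses the neutral rate of its lexicographically first
    descendant leaf (exact when all leaves share one lineage rate).
    """
    seqs = {id(tree.root): root_seq}
    out: dict[str, str] = {}
    for parent, child, length_myr in tree.preorder_edges():
        leaves = [lf.taxon.label for lf in child.leaf_iter()]
        r = rate_of_leaf[min(leaves)]
        k = 2.0 * 0.5 * r * length_myr * 1e6  # = r * t on one branch
        child_seq = mutate_sequence(seqs[id(parent)], k, kappa, rng=rng)
        seqs[id(child)] = child_seq
        if child.is_leaf():
            out[child.taxon.label] = child_seq
    return out


def _leaf_rates(tree: SpeciesTree, config: SimulationConfig) -> dict[str, float]:
    ref = config.rate_table_ref or {}
    rates = {}
    for leaf in tree.leaf_names:
        lineage = ref.get(leaf, "Actinopterygii")
        if lineage not in config.rates:
            raise ConfigurationError(f"no rate for lineage {lineage!r} (leaf {leaf})")
        rates[leaf] = config.rates[lineage]
    return rates


# ---------------------------------------------------------------------------
# planting


def _sample_ages(peaks: Sequence[AgePeak], n: int, rng: np.random.Generator) -> np.ndarray:
    w = np.array([p.weight for p in peaks], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(peaks), size=n, p=w)
    ages = np.array([rng.normal(peaks[i].mean, peaks[i].sd) for i in idx])
    return np.clip(ages, 0.0, None)


def _orf_intact(copy_seq: str, orf_span: tuple[int, int],
                triad_positions: tuple[int, int, int] | None = None) -> bool:
    """ORF still encodes a working transposase: start retained, no premature
    in-frame stop, and (when triad positions are given) the catalytic D,D,E
    residues unchanged."""
    s, e = orf_span
    orf = copy_seq[s:e]
    if not orf.startswith("ATG"):
        return False
    for i in range(3, len(orf) - 3, 3):
        if orf[i:i + 3] in _STOP_CODONS:
            return False
    if orf[-3:] not in _STOP_CODONS:
        return False
    if triad_positions is not None:
        from Bio.Seq import Seq

        protein = str(Seq(orf[:-3]).translate())
        d1, d2, epos = triad_positions
        if (protein[d1 - 1], protein[d2 - 1], protein[epos - 1]) != ("D", "D", "E"):
            return False
    return True


def plant_copies(tree: SpeciesTree, config: SimulationConfig) -> SimulationResult:
    """Insert mutated element copies into random background genomes.

    Every insertion lands immediately after a TA dinucleotide and the TA is
    duplicated on the 3' flank, reproducing the family's target-site
    duplication. Statuses follow the field's convention: truncated copies
    lost a terminal segment; full-length copies retain both TIRs but carry
    a disrupted transposase ORF; intact copies retain both.
    """
    rng = np.random.default_rng(config.seed)
    master = make_master(config)
    leaf_rates = _leaf_rates(tree, config)
    species_masters = _evolve_down_tree(
        tree, master.sequence, leaf_rates, config.kappa, rng
    )

    ht_by_recipient: dict[str, HtEvent] = {}
    for ev in config.ht_events:
        if ev.donor == ev.recipient:
            raise ConfigurationError("HT donor and recipient must differ")
        for sp in (ev.donor, ev.recipient):
            if sp not in species_masters:
                raise ConfigurationError(f"HT event names unknown leaf {sp!r}")
        if not 0.0 <= ev.time_myr <= tree.depth + 1e-9:
            raise ConfigurationError("HT time exceeds tree depth")
        ht_by_recipient[ev.recipient] = ev

    genomes: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for species in tree.leaf_names:
        background = random_sequence(config.background_length, rng, config.gc_content)
        ta_sites = [
            i for i in range(len(background) - 1)
            if background[i] == "T" and background[i + 1] == "A"
        ]
        n = config.copies_per_species
        if len(ta_sites) < n or config.background_length < n * 2:
            raise CapacityError(
                f"background of {config.background_length} bp has only "
                f"{len(ta_sites)} TA sites for {n} requested copies"
            )
        chosen = sorted(rng.choice(len(ta_sites), size=n, replace=False))
        sites = [ta_sites[i] for i in chosen]

        ht = ht_by_recipient.get(species)
        if ht is not None:
            source = species_masters[ht.donor]
            ages = np.full(n, ht.time_myr)
        else:
            source = species_masters[species]
            ages = _sample_ages(config.age_distribution, n, rng)
        r = leaf_rates[species]

        pieces: list[str] = []
        cursor = 0
        records: list[TruthRecord] = []
        for site, age in zip(sites, ages):
            k = 2.0 * r * age * 1e6
            copy = mutate_sequence(source, k, config.kappa, rng=rng)
            status = ("intact"
                      if _orf_intact(copy, master.orf_span, master.triad_positions)
                      else "full_length")
            if rng.random() < config.truncation_prob:
                frac = rng.uniform(0.1, 0.9)
                cut = max(1, int(round(frac * len(copy))))
                copy = copy[cut:] if rng.random() < 0.5 else copy[:-cut]
                status = "truncated"
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = copy if strand == "+" else revcomp(copy)
            # background[..site+2] | copy | TA | background[site+2..]
            pieces.append(background[cursor:site + 2])
            pieces.append(inserted)
            pieces.append("TA")
            cursor = site + 2
            records.append(
                TruthRecord(
                    species=species,
                    chrom=species,
                    start=-1,  # filled after assembly
                    end=-1,
                    strand=strand,
                    planted_k=float(k),
                    planted_age=float(age),
                    status=status,
                    via_ht=ht is not None,
                )
            )
        pieces.append(background[cursor:])
        genome = "".join(pieces)
        # recover coordinates: pieces alternate background/copy/TA
        pos = 0
        rec_i = 0
        for j, piece in enumerate(pieces[:-1]):
            if j % 3 == 1:  # the inserted copy
                records[rec_i].start = pos
                records[rec_i].end = pos + len(piece)
                rec_i += 1
            pos += len(piece)
        genomes[species] = genome
        truth.extend(records)

    return SimulationResult(
        config=config,
        tree=tree,
        master=master,
        species_masters=species_masters,
        genomes=genomes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# host gene


def simulate_host_gene(
    tree: SpeciesTree,
    gene_length: int,
    rate: float,
    kappa: float = 2.0,
    seed: int | None = None,
) -> dict[str, str]:
    """Evolve one ancestral CDS down the tree under K2P at ``rate``.

    The expected pairwise distance between two leaves is 2*rate*t_split
    (years). Returns a gapless leaf -> sequence alignment (no indels are
    simulated, mirroring a coding ortholog like RAG1).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if not isinstance(tree, SpeciesTree):
        raise TreeError("simulate_host_gene requires a validated SpeciesTree")
    rng = np.random.default_rng(seed)
    n_codons = max(1, gene_length // 3)
    codons = ["ATG"]
    sense = sorted(set(_CODONS_BY_AA_FLAT()))
    for _ in range(n_codons - 1):
        codons.append(sense[rng.integers(len(sense))])
    root = "".join(codons)[:gene_length]
    if len(root) < gene_length:
        root += random_sequence(gene_length - len(root), rng)
    rate_of_leaf = {leaf: rate for leaf in tree.leaf_names}
    return _evolve_down_tree(tree, root, rate_of_leaf, kappa, rng)


def _CODONS_BY_AA_FLAT() -> list[str]:
    return [c for codons in _CODONS_BY_AA.values() for c in codons]


# ---------------------------------------------------------------------------
# output


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write genomes, master, species masters and the truth table to disk.

    All coordinates are 0-based half-open; FASTA is wrapped at 80 columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for species, genome in result.genomes.items():
        p = outdir / f"{species}.genome.fa"
        write_fasta(p, [(species, genome)])
        paths[f"genome:{species}"] = p
    p = outdir / "master.fa"
    write_fasta(p, [("master", result.master.sequence)])
    paths["master"] = p
    p = outdir / "species_masters.fa"
    write_fasta(p, sorted(result.species_masters.items()))
    paths["species_masters"] = p
    p = outdir / "truth.tsv"
    with open(p, "w") as fh:
        fh.write(f"# telandscape simulation; seed={result.config.seed}\n")
        fh.write(
            "species\tchrom\tstart\tend\tstrand\tk\tage_myr\tstatus\tvia_ht\n"
        )
        for t in result.truth:
            fh.write(
                f"{t.species}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.planted_k:.6f}\t{t.planted_age:.4f}\t{t.status}\t{int(t.via_ht)}\n"
            )
    paths["truth"] = p
    return paths
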