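"""Transposase ORF finding and D,D,E catalytic-triad classification.

Tc1/mariner-superfamily transposases carry three acidic residues (Asp, Asp,
Glu) forming the catalytic core; family names such as DD34E or DD38E encode
the spacing between the second D and the E. Here the triad is located by
aligning a candidate protein to an anchored reference alignment whose triad
columns are annotated, then mapping those columns onto the protein.

Spacing convention (fixed project-wide, recorded in output metadata):
``spacing = e_pos - d2_pos - 1`` — the number of residues strictly between
the second aspartate and the glutamate, so a DD38E transposase has its E 39
positions after its second D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "OrfAnnotation",
    "CatalyticTriad",
    "TriadAnchor",
    "find_orf",
    "locate_dde_triad",
    "family_label",
    "find_motif",
    "default_anchor",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfAnnotation:
    """A plus-strand ORF: interval includes the stop codon."""

    start: int
    end: int  # 0-based half-open, stop codon included
    frame: int
    protein: str  # stop excluded

    def __post_init__(self):
        assert self.protein.startswith("M")
        assert (self.end - self.start) // 3 == len(self.protein) + 1

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class CatalyticTriad:
    """1-based protein positions of the D, D, E catalytic residues."""

    d1_pos: int
    d2_pos: int
    e_pos: int

    def __post_init__(self):
        if not self.d1_pos < self.d2_pos < self.e_pos:
            raise ValueError("triad positions must be strictly increasing")

    @property
    def spacing(self) -> int:
        return self.e_pos - self.d2_pos - 1

    @property
    def label(self) -> str:
        return family_label(self)


@dataclass
class TriadAnchor:
    """Reference protein alignment with annotated triad columns (0-based)."""

    rows: list[tuple[str, str]]  # (id, gapped protein)
    triad_columns: tuple[int, int, int]

    def __post_init__(self):
        ncol = {len(r) for _, r in self.rows}
        if len(ncol) != 1:
            raise ValueError("anchor rows must have equal length")
        c1, c2, c3 = self.triad_columns
        for name, row in self.rows:
            if (row[c1], row[c2], row[c3]) != ("D", "D", "E"):
                raise ValueError(f"anchor row {name} lacks D,D,E at triad columns")

    @property
    def consensus(self) -> str:
        """Per-column majority residue over non-gap rows (gap-majority kept
        only if some residue exists; ties broken alphabetically)."""
        ncol = len(self.rows[0][1])
        out = []
        for j in range(ncol):
            col = [row[j] for _, row in self.rows if row[j] != "-"]
            if not col:
                continue
            counts: dict[str, int] = {}
            for a in col:
                counts[a] = counts.get(a, 0) + 1
            out.append(min(counts, key=lambda a: (-counts[a], a)))
        return "".join(out)

    def consensus_triad_positions(self) -> tuple[int, int, int]:
        """Triad positions (0-based) in the ungapped consensus string."""
        ncol = len(self.rows[0][1])
        keep = [j for j in range(ncol)
                if any(row[j] != "-" for _, row in self.rows)]
        index = {j: i for i, j in enumerate(keep)}
        c1, c2, c3 = self.triad_columns
        return index[c1], index[c2], index[c3]

    @classmethod
    def from_files(cls, aligned_fasta: str | Path, sidecar_json: str | Path) -> "TriadAnchor":
        from ._sequtils import read_fasta

        rows = list(read_fasta(aligned_fasta).items())
        meta = json.loads(Path(sidecar_json).read_text())
        return cls(rows=rows, triad_columns=tuple(meta["triad_columns"]))


# ---------------------------------------------------------------------------


def find_orf(nucleotide_seq: str, min_len_aa: int = 300) -> OrfAnnotation | None:
    """Longest ATG-initiated plus-strand ORF across the three frames.

    The reported protein excludes the stop codon; ambiguity codes translate
    to X. Returns None when no ORF reaches ``min_len_aa``.
    """
    seq = nucleotide_seq.upper()
    best: OrfAnnotation | None = None
    n = len(seq)
    for frame in range(3):
        i = frame
        orf_start = None
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in _STOPS:
                aa_len = (i - orf_start) // 3
                if aa_len >= min_len_aa and (best is None or aa_len > best.length_aa):
                    protein = str(Seq(seq[orf_start:i]).translate())
                    best = OrfAnnotation(start=orf_start, end=i + 3,
                                         frame=frame, protein=protein)
                orf_start = None
            i += 3
    return best


def _profile_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    try:  # Biopython >= 1.88 naming
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def locate_dde_triad(
    protein: str,
    anchor: TriadAnchor,
    min_score_per_col: float = 0.0,
) -> CatalyticTriad | None:
    """Map the anchor's annotated D,D,E columns onto ``protein``.

    The protein is globally aligned (affine gaps, BLOSUM62, free end gaps)
    to the anchor's consensus; a triad is reported only when all three
    mapped residues are exactly D, D, E. Returns None for non-homologous
    proteins (score floor) or incomplete triads.
    """
    if len(protein) < 100:
        return None
    protein = protein.upper().replace("*", "X")
    cons = anchor.consensus
    aligner = _profile_aligner()
    alignments = aligner.align(cons.replace("X", "A"), protein.replace("X", "A"))
    aln = alignments[0]
    if aln.score < min_score_per_col * len(cons):
        return None
    c_blocks, p_blocks = aln.aligned
    cpos = anchor.consensus_triad_positions()
    mapped = []
    for target in cpos:
        found = None
        for (cs, ce), (ps, pe) in zip(c_blocks, p_blocks):
            if cs <= target < ce:
                found = ps + (target - cs)
                break
        if found is None:
            return None
        mapped.append(found)
    d1, d2, e = mapped
    if not (d1 < d2 < e):
        return None
    if protein[d1] != "D" or protein[d2] != "D" or protein[e] != "E":
        return None
    return CatalyticTriad(d1_pos=d1 + 1, d2_pos=d2 + 1, e_pos=e + 1)


def family_label(triad: CatalyticTriad) -> str:
    """Family name "DD{spacing}E" from the triad spacing."""
    return f"DD{triad.spacing}E"


def find_motif(protein: str, pattern: str = "GRPR", max_mismatch: int = 0) -> list[int]:
    """1-based positions of (Hamming-tolerant) occurrences of ``pattern``."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    protein = protein.upper()
    pattern = pattern.upper()
    m = len(pattern)
    out = []
    for i in range(len(protein) - m + 1):
        mism = sum(a != b for a, b in zip(protein[i:i + m], pattern))
        if mism <= max_mismatch:
            out.append(i + 1)
    return out


# ---------------------------------------------------------------------------
# bundled anchor set (synthetic)


def default_anchor(seed: int = 2024) -> TriadAnchor:
    """Synthetic Tc1/mariner-style anchor alignment.

    Five reference rows, one per family label (DD34E, DD35E, DD36E, DD37E,
    DD38E), sharing a conserved core with D, D at fixed columns and each
    family's E placed at its own spacing; shorter spacings are padded with
    gap columns so all rows align. Sequences are synthesized (real reference
    accessions are not redistributable); only the triad geometry matters.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    core_len = 320
    d1_col, d2_col = 150, 190
    spacings = {"Tc1_DD34E": 34, "TR_DD35E": 35, "IC_DD36E": 36,
                "TRT_DD37E": 37, "IT_DD38E": 38}
    max_sp = max(spacings.values())
    e_col = d2_col + max_sp + 1
    ncol = core_len + (max_sp - 34)  # room for the widest spacing
    base = rng.choice(aa, size=ncol)
    rows = []
    for name, sp in sorted(spacings.items()):
        row = base.copy()
        # family-specific drift away from the shared core
        drift = rng.random(ncol) < 0.25
        row[drift] = rng.choice(aa, size=int(drift.sum()))
        row = row.tolist()
        pad = max_sp - sp  # gaps placed just after D2 to shrink the spacing
        for j in range(d2_col + 1, d2_col + 1 + pad):
            row[j] = "-"
        row[0] = "M"
        for j in range(d1_col + 1, e_col):
            if row[j] in "DE":
                row[j] = "G"  # keep the designed triad unambiguous
        row[d1_col] = "D"
        row[d2_col] = "D"
        row[e_col] = "E"
        rows.append((name, "".join(row)))
    return TriadAnchor(rows=rows, triad_columns=(d1_col, d2_col, e_col))
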