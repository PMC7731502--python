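"""Small shared sequence helpers: encoding, reverse complement, FASTA I/O.

Nucleotides are handled as uppercase strings over A,C,G,T,N externally and
as uint8 codes internally (A=0, G=1, C=2, T=3, N=4) so that "is transition"
is a cheap integer test: codes 0/1 are purines, 2/3 pyrimidines.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: base order chosen so that ``code ^ 1`` is the transition partner
BASES = "AGCTN"
A, G, C, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (unknown letters -> N)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(code_a: np.ndarray, code_b: np.ndarray) -> np.ndarray:
    """Elementwise transition test (A<->G or C<->T) on encoded arrays."""
    return (code_a != code_b) & ((code_a ^ 1) == code_b)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.41) -> str:
    """I.i.d. background sequence at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A,G,C,T
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    """Write records wrapped at ``width`` columns."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def fasta_string(records: Sequence[tuple[str, str]], width: int = 80) -> str:
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=width)
    writer.write_file([SeqRecord(Seq(s), id=n, description="") for n, s in records])
    return buf.getvalue()
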