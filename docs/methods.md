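# Methods

This note documents the models, conventions and numerical choices behind
telandscape, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not establish about real data.

## The synthetic-data model

The generator emulates a recently expanded Tc1/mariner-style DNA transposon
family.

**Master element.** A single master sequence of 1588 bp by default: a
210 bp terminal inverted repeat (TIR), a spacer, a transposase ORF of
341 aa (1023 coding nt + stop), a second spacer, and the exact reverse
complement of the left TIR. The transposase is random protein sequence
except for three conserved neighbourhoods copied from the bundled anchor
alignment around the catalytic D, D, E residues (defaults: positions 160,
200, 239 — 38 residues strictly between D2 and E, i.e. a DD38E family) and
a GRPR motif near the N-terminus. The conserved blocks make the simulated
transposase genuinely homologous to the anchor references, which is what
the triad-mapping step relies on in real families. An in-frame stop is
placed immediately upstream of the ORF so it is the unique longest
plus-strand ORF.

**Descent.** The master first evolves *vertically* down a dated, ultrametric
species tree under a Kimura two-parameter (K2P) substitution process at the
per-lineage neutral rate, giving each species its own species-level master
(branch rate taken from the branch's first descendant leaf; exact whenever
one lineage rate applies, which is the case in every bundled scenario).
Copies planted in a genome then diverge from the species master by
`planted_k = 2 r T`, the inverse of the dating relation `T = k / 2r`, with
ages drawn from a configurable mixture of Gaussian peaks (default: one peak
at 2 ± 1 Myr, emulating a recent burst). The simulator and the estimator
share only this formula, not code.

**Insertion.** Each copy lands immediately after a TA dinucleotide in an
i.i.d. background (GC 0.41 by default) and the TA is duplicated on the 3′
flank — the family's target-site duplication — on a uniformly random
strand. With probability `truncation_prob` (default 0.3) a copy loses a
uniform 10–90% terminal segment and is recorded `truncated`; otherwise it
is `intact` if its ORF still starts with ATG, contains no premature
in-frame stop, and retains D, D, E at the designed triad positions, else
`full_length`. No within-copy indels are simulated: the K2P dating model
ignores indels, and whole-segment truncation reproduces the truncated-copy
category that matters for discovery.

**Horizontal transfer.** An HT event (donor, recipient, time) replaces the
recipient's copy lineage: its copies descend from the *donor's* tip master,
each at age equal to the transfer time. This is the minimal model that
produces the diagnostic signature — element distance far below host-gene
distance for the donor–recipient pair — without donor-lineage resampling.

**Host gene.** A clean CDS (random sense codons after ATG) evolves down the
same tree under K2P at a supplied rate, gapless; expected pairwise distance
between two leaves is `2 · rate · t_split`, mirroring a slowly evolving
vertically inherited ortholog such as RAG1.

**K2P forward process.** Substitutions are drawn per site from the exact
K2P transition matrix at branch length k (rates normalised so
α + 2β = 1 per unit k; transition:transversion rate ratio κ, default 2).
N bases pass through unchanged. Every draw flows from one integer seed;
identical configs give byte-identical FASTA.

What the generator does **not** emulate: genomic repeat confounders and
compositional heterogeneity, indel evolution, nested insertions,
copy-number feedback or selection, and assembly artifacts. Passing the
benchmark therefore demonstrates correctness of the algorithms under the
stated model, not field performance on repeat-rich assemblies.

## Discovery

Homology search is a k-mer seeded (word size 11), gapped local alignment on
both strands: exact seed matches are clustered into candidate windows
(cluster gap < half the query length, ±300 bp margin), each window is
aligned to the query with an affine-gap Smith–Waterman (match +1, mismatch
−1, gap open −5, extend −1 per additional base), and windows are re-split
around accepted hits so adjacent copies are found individually. Hits pass
when identity ≥ 80% and query coverage ≥ 40% (identity = matches / aligned
columns; coverage = aligned query positions / query length; N never
matches). When a local alignment trims ≤ 15 terminal query bases — the
signature of substitution-damaged termini rather than truncation — the hit
is extended back to the query boundary, which keeps boundary error within
±2 bp at moderate divergence. Hits overlapping by more than half the
shorter one are merged, keeping the higher-identity interval. E-value
statistics are deliberately not used: the explicit identity/coverage gates
are reproducible across database sizes.

**Boundary refinement.** Hits are extracted with ±2 kb context; for
refinement the copies (± 50 bp pad) are multiply aligned and the element is
taken as the longest run of columns whose smoothed (9-column window)
same-base agreement reaches 0.6, trimmed at the ends to columns that are
near-unanimous (≥ 0.9) and nearly gap-free (≥ 0.9 of rows). The stricter
trim exists because the aligner places gaps in the unrelated flanks so that
shared letters stack, inflating apparent agreement just outside the
element; a bare majority rule extends boundaries several bases into flank.
The TA duplication itself is conserved across rows, so alignment-based
boundaries carry an intrinsic ±2 bp ambiguity; single-copy loci fall back
to TIR-defined boundaries.

**TIR detection** pairs a prefix and suffix (each allowed a ±10 bp jitter
from the terminus) and maximises matches − 4·mismatches over lengths 10–300
bp whose mismatch fraction stays ≤ 0.10. Score maximisation (rather than
"longest under the fraction gate") prevents a perfect repeat from being
over-extended into flanking sequence. On random 1.6 kb sequences the
detector fires ≤ 5% of the time. Note that between the two arms of one
copy, each arm carries its own substitutions, so at total copy divergence
above ~10% the full-length TIR pair decays below the mismatch ceiling and
the detector reports the best-preserved terminal repeat, which may be
short — real TIR decay behaves the same way.

**Status call.** intact = TIR pair present and an ORF (≥ 300 aa floor,
plus-strand, ATG-initiated) whose mapped catalytic residues are exactly D,
D, E; full_length = TIR pair but no such transposase; truncated = no TIR
pair.

## Triad classification

The candidate transposase is globally aligned (BLOSUM62, gap open −11,
extend −1, free end gaps) to the consensus of an anchor alignment whose
three triad columns are annotated; the columns are mapped through the
alignment and a triad is reported only when the mapped residues are exactly
D, D, E. The spacing convention is fixed project-wide: residues strictly
between the second D and the E, so DD38E means e − d2 = 39 positions. The
bundled anchor set is synthetic — five rows, one per family label
DD34E/DD35E/DD36E/DD37E/DD38E, sharing a conserved core with each family's
E at its own spacing — because real reference accessions cannot be
redistributed; users can supply their own anchor (aligned FASTA + JSON
sidecar with triad column indices). A profile HMM would be the heavier
alternative; the anchored-alignment substitute is deterministic and
testable.

## Alignment, consensus and identity

The multiple aligner is progressive: single-linkage guide tree on k-mer
(k=6) distance, profiles merged by aligning their majority-consensus
strings (affine gaps as above, end gaps free) and projecting the resulting
gap columns onto every member row. Semi-global (free end-gap) scoring is
used throughout so clipped or truncated sequences slide to their homologous
position instead of smearing across flanks. Pre-computed alignments from
external tools are accepted anywhere an alignment is consumed.

Consensus: per column, the most frequent non-gap base among non-gap rows,
ties broken alphabetically (A<C<G<T); gap-majority columns are dropped.
Fewer than 3 rows yields a "representative" sequence, the conventional
fallback for low-copy species.

Percent identity = 100 · matches / aligned columns, dual-gap columns
excluded — printed in every report header because published identity
matrices rarely state their convention and are otherwise not comparable.
Identity uses a dedicated DP that breaks ties between co-optimal alignments
by maximising matches, then aligned pairs; all three criteria are additive,
so the canonical optimum is exactly symmetric in its arguments and
invariant under reverse-complementing both sequences. Identity clustering
is single linkage over edges at or above the threshold, cluster labels
ordered by size then lexicographically smallest member.

## Dating

Copies are compared with their species consensus (standard repeat-landscape
semantics), under pairwise deletion. Saturated copies (non-positive
logarithm argument) are reported as such, with no age. A `--cpg-adjust`
option excludes consensus CpG-site columns before counting; it defaults off.
Ages are reported in Myr to 3 significant digits (years kept at full
precision internally); the landscape bin width defaults to 0.5 Myr, which
resolves sub-5-Myr burst structure.

## Horizontal-transfer test

Distances: `p` (proportion of differing sites), `k2p`, and `mcl` — the
Tamura–Nei-form composite-likelihood distance with base frequencies pooled
over the whole alignment (the behaviour of MEGA's "maximum composite
likelihood" default), all under pairwise deletion; undefined/saturated
pairs are excluded from both the flag counts and the summaries, and
reported. The flag rule is strict inequality `margin · d_TE < d_gene`
(default margin 1; ties flag neither direction). The margin option exists
because a strict count reproduces published pair counts while "far
smaller" arguments are better served by margin 2, at which vertically
inherited elements (which track the gene in expectation) essentially never
flag and a planted young transfer always does. A minimum split-time gate is
available but defaults to 0: deep-split enrichment is a property of a
dataset, not of the test. Summary statistics use the population SD.

## Pipeline

`telandscape run` executes simulate → discover → classify → consensus →
date → httest with one seed; every output carries a `#` header with
version, seed and parameters, and identical config + seed gives
byte-identical outputs. The default scenario is a shallow four-species tree
(splits at 5 and 10 Myr) — a deep tree at the default vertebrate rate would
saturate the family's vertical divergence, which is also why recently
transferred families are the ones this workflow can find in practice. The
host gene evolves at the same 1e-8/site/year as the elements by default so
that vertical element pairs track the gene, the calibration the HT test
assumes.

## Problem sizes in the bundled benchmarks

The test-suite and acceptance scenarios use 20 copies per 50 kb genome
(10 per 30 kb for the zero-divergence check), 200 replicates per planted
divergence for parameter recovery, 100 random sequences for the TIR
false-positive rate, 30 copies for the burst landscape, and a four-species
100-Myr tree with 10 copies per species for the transfer test — sizes at
which every scenario completes in seconds to tens of seconds while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The seeded search needs at least one exact 11-mer match per copy; at
  divergences far beyond the 80% identity gate, copies are invisible (as
  they are to the analogous published workflows).
- Alignment-based boundaries are ambiguous within ±2 bp around the
  conserved TA duplication, and a few bp more at higher divergence.
- The anchored triad mapping assumes detectable homology to the anchor
  consensus; a family with a diverged catalytic core needs its own anchor.
- The MCL distance uses pooled (not per-pair) base frequencies; on strongly
  compositionally heterogeneous data the two conventions diverge.
- Only plus-strand ORFs are scanned, because elements are strand-normalized
  upstream.
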