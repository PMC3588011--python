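# Methods

This note documents the models, rules and numerical choices behind
`mirnod`, and what the synthetic-data generator does and does not emulate.

## Secondary-structure model

Pre-miRNA candidates are folded with a Nussinov-style dynamic programme
that maximises a weighted count of nested base pairs (GC = 3, AU = 2,
G:U = 1) with a minimum hairpin loop of 3 nt (a steric constraint; loops of
1–2 nt are disallowed).  The novel-miRNA criteria consume only pairing
geometry — arm membership, duplex mismatches, bulges, end stagger — so a
full thermodynamic (free-energy) model is unnecessary; the weighted
objective prefers the stable stems a thermodynamic folder would also find
while staying exactly reproducible and fast (the O(n³) fill is JIT-compiled
with numba; windows of ~190 nt fold in ~10 ms).  No minimum free-energy
threshold is imposed on precursors.  Traceback ties are broken
deterministically: a paired 3′ base with the smallest partner index is
preferred over leaving it unpaired, so identical sequences always give
identical structures.

The *major stem-loop* of a structure is the terminal loop whose enclosing
helix chain (following nested pairs outward through interior loops and
bulges, stopping at bifurcations) contains the most pairs, leftmost on
ties.  Arm classification of an interval is relative to this stem-loop:
`five_prime_arm` / `three_prime_arm` when entirely between the stem's
outermost pair and the terminal loop, `loop` / `spanning` on loop overlap,
`outside` otherwise.

## Duplex statistics and the Dicer signature

Given a folded precursor and a mature interval, the star interval is
derived from the pair table: the partners of the mature's outermost paired
bases are extrapolated to the mature's ends and shifted by the canonical
2-nt stagger of Dicer processing.  A walk along the duplex counts
mismatches (both strands unpaired at a step; G:U is a pair, not a
mismatch) and bulges (asymmetric unpaired runs).  The mature's 3′ overhang
is measured as the number of its 3′-terminal bases whose partners fall
outside the star interval; the acceptance check requires this to be
2 ± 1 nt.  In a continuous-stem hairpin the overhang is a property of the
assumed excision register rather than of unpaired bases, so this check
validates duplex-end regularity; the tolerance is configurable.

## Novel-miRNA calling

Rules are applied in the order used by the published screens this pipeline
re-implements: read support first (≥ 20 reads summed over both libraries —
"total reads" is read as the sum, not per library), then arm placement,
duplex mismatches (≤ 4), bulge size, and the overhang signature.  The
low-abundance prescreen happens before any folding, which keeps the
candidate set small and matches the practice of eliminating rare tags
before structure prediction.  The bulge limit follows the strict reading
of "less than 2 bases" (max bulge ≤ 1 nt); the laxer ≤ 2 nt variant is one
config switch away (`NovelThresholds.max_bulge`).  Star-sequence read
support is *not* required — only that a star region exists on the opposite
arm.  A tag matching the known catalog is never also evaluated as novel.

Precursor windows follow the two asymmetric excisions
`[start−flank, end+20)` and `[start−20, end+flank)` with flank = 150 nt, so
the mature can sit on either arm; both windows of every genome placement
are tried and a call is accepted if any window passes all rules.  The
rejection reason reported for a failed candidate comes from the window that
passed the most leading rules.

## Known matching, families, conservation

Known calls require an exact catalog match or an end-trimmed/extended
variant (total length difference ≤ 2 nt, identical core); internal
substitutions never match.  Families group matures with identical seed
(positions 2–8) and overall edit distance ≤ 3, closed under union-find,
deterministically named by the lexicographically smallest member.

Conservation classing mirrors a nucleotide-BLAST screen at E ≤ 10: local
alignment with match +1, mismatch −3, gap −5; E = K·m·n·e^(−λS) over the
whole catalog search space with λ ≈ 1.374 (solved from the score system at
uniform base frequencies) and K = 0.711.  Because an E cutoff of 10 alone
would accept near-random 21-mer matches, a hit additionally requires a
shared exact word of 11 nt — the implicit seeding step of the BLAST search
being emulated.  Hits in any non-legume plant catalog ⇒ conserved in
plants; only legume catalogs ⇒ legume-specific; none ⇒ species-specific.

## Expression

RPM = count / clean-read total × 10⁶, kept at full float precision
internally and rendered at 2 decimals.  Fold changes are computed on RPM
(that is what the normalisation exists for); the 2-fold threshold is
inclusive (≥ 2 up, ≤ 0.5 down) with a strict-inequality switch.  Exclusive
detection is decided on raw counts to avoid floating-point artifacts.  No
count-model significance test is applied; the classification is
deliberately fold-change-only.

## Target rules

Scanning is ungapped: the reverse complement of the mature slides along
the transcript and each offset gets a per-position penalty vector (WC 0,
G:U 0.5, mismatch 1; the indel penalty 2 exists in the scoring table for
externally supplied gapped alignments but gapped sites are not searched —
a known limitation).  Positional rules use full-penalty mismatches only:
≤ 1 in positions 2–12 with none at 10/11, ≤ 3 additional in 12–21
(position 12 counted once, in the tail window), no run of > 2 consecutive
mismatches, and E = Σ penalties ≤ 3.5 (the largest expectation observed
among reported plant target alignments; half-integer E values arise only
through the 0.5 wobble penalty).  Position 1 is unconstrained positionally
but contributes to E.  Overlapping acceptances are deduplicated keeping
minimum E, leftmost on ties.  Seed-region penalty doubling (used by some
web tools) is not applied.

Cleavage validation places RACE-style reads by exact leftmost substring
match, restricted to ±30 nt of the linked site; the modal 5′ coordinate is
the cut, reported between the two miRNA positions it falls under, with the
modal read count as support.

## The synthetic world

The generator emulates the input side of a two-library nodule experiment
at desk scale: one 60 kb chromosome, 20 criterion-satisfying hairpin loci,
5 decoys per violated rule (excess duplex mismatches, an oversized bulge, a
loop-spanning mature, sub-threshold abundance), 20 known-miRNA loci with a
miRBase-style catalog, ncRNA contaminant intervals (rRNA/tRNA/snoRNA/snRNA
plus an mRNA exon; 20% of reads), and two libraries of 40,000 reads each
with lengths over 18–30 nt peaking at 24 then 21 nt.  Reads are insert +
3′ adapter truncated at 36 cycles; small planted fractions lack an adapter,
are adapter dimers, or carry sub-18-nt inserts, so the cleaning stage has
real work to do.  These sizes keep a full pipeline run in tens of seconds
while leaving ≥ 10× head-room between planted span and genome length.

Precursors are built backward from the desired duplex: the star arm is the
reverse complement of mature + a stem extension, edited to plant mismatches
or bulges, joined by an 8–15 nt all-A loop.  Planted mismatches use an A:A
opposition inside a CAG/GAC context chosen so that no ±1/±2 register slide
can pair — otherwise the maximising folder quietly converts designed
mismatches into bulges.  Every planted locus is then *verified* by folding
its actual discovery windows; flanking sequence is resampled (and, failing
that, the locus redesigned) until the intended verdict — including each
decoy's single violated rule — is reproduced, with a hard attempt limit.
The same verify-and-resample guard realises the designed three-way
conservation split against the generated multi-species catalogs.

Counts per miRNA use one negative-binomial draw (configured mean,
dispersion 0.1) for the lower library, with the planted fold applied
exactly (rounded) to the other library and identical fixed library totals.
The single-draw design is deliberate: with independent per-library draws a
planted fold of exactly 2 straddles the ≥ 2 classification boundary and is
unrecoverable in principle, whereas the shared draw keeps planted ratios
exact while retaining across-miRNA and across-seed overdispersion.
Library-exclusive classes put the whole draw in one library.

What the generator does **not** emulate: sequencing errors beyond optional
uniform substitution (default off), quality-score structure, isomiR
heterogeneity (each miRNA yields one exact tag), multi-chromosome genomes,
and overlapping/nested gene models.  Passing the planted-truth tests
therefore demonstrates correctness of the analysis logic under clean
attribution, not robustness to real-library noise.

## Determinism and accounting

A single integer seed drives every random choice in the generator;
identical configs give byte-identical fixture sets.  The pipeline writes
only sorted plain-text outputs with no timestamps, so repeated runs on the
same inputs are byte-identical, and every stage's read accounting must
balance (input = kept + Σ removed-by-reason) or the run aborts with the
stage name.
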