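"""Perfect-match placement of tags on both genome strands.

A k-mer hash index over the forward strand supports exact placement of
20-24 nt tags (range configurable); a tag is reported wherever the genome
substring equals it exactly, with minus-strand hits found by searching the
tag's reverse complement.  Multi-mapping tags keep all hits, with the total
placement count ``n_hits`` on each alignment.  Coordinates are 0-based
half-open on the forward strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import reverse_complement

LENGTH_OUT_OF_RANGE = "length outside mapping range"


@dataclass(frozen=True)
class GenomeAlignment:
    """One perfect placement of a tag."""

    tag: str
    chrom: str
    start: int          # 0-based
    end: int            # half-open; end - start == len(tag)
    strand: str         # '+' or '-'
    n_hits: int = 1     # total perfect placements of this tag genome-wide


class GenomeIndex:
    """Deterministic k-mer position index over a genome dict.

    Non-ACGT characters are masked: any window containing one is never
    indexed nor matched.
    """

    def __init__(self, genome: dict[str, str], k: int = 18):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        valid = set("ACGT")
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i:i + k]
                if set(kmer) <= valid:
                    self._index[kmer].append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer.upper(), [])

    def _exact_hits(self, seq: str) -> list[tuple[str, int]]:
        """All (chrom, start) where the forward genome equals ``seq``."""
        k = self.k
        if len(seq) < k:
            raise ValueError(f"tag length {len(seq)} < index k {k}")
        hits = []
        for chrom, pos in self.lookup(seq[:k]):
            if self.genome[chrom][pos:pos + len(seq)] == seq:
                hits.append((chrom, pos))
        return hits


def build_index(genome: dict[str, str], k: int = 18) -> GenomeIndex:
    """Build the k-mer index; ``k`` must not exceed the shortest queried tag."""
    return GenomeIndex(genome, k)


def map_tag(tag: str, index: GenomeIndex, min_len: int = 20, max_len: int = 24,
            ) -> tuple[list[GenomeAlignment], str | None]:
    """All perfect placements of ``tag`` on both strands.

    Returns ``(alignments, skip_reason)``; tags outside the configured
    length range are skipped (empty list, reason set), not errors.  Strand
    symmetry holds by construction: mapping revcomp(tag) yields the same
    loci with strands swapped.
    """
    seq = tag.upper().replace("U", "T")
    if not (min_len <= len(seq) <= max_len):
        return [], LENGTH_OUT_OF_RANGE
    fwd = index._exact_hits(seq)
    rev = index._exact_hits(reverse_complement(seq))
    n = len(fwd) + len(rev)
    out = [GenomeAlignment(tag=seq, chrom=c, start=p, end=p + len(seq),
                           strand="+", n_hits=n) for c, p in fwd]
    out += [GenomeAlignment(tag=seq, chrom=c, start=p, end=p + len(seq),
                            strand="-", n_hits=n) for c, p in rev]
    out.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return out, None


def map_tags(tags, index: GenomeIndex, min_len: int = 20, max_len: int = 24,
             ) -> tuple[dict[str, list[GenomeAlignment]], dict[str, str]]:
    """Map a collection of tags; returns (hits by tag sequence, skip reasons)."""
    hits: dict[str, list[GenomeAlignment]] = {}
    skipped: dict[str, str] = {}
    for tag in tags:
        seq = tag.sequence if hasattr(tag, "sequence") else tag
        alns, reason = map_tag(seq, index, min_len, max_len)
        if reason is not None:
            skipped[seq] = reason
        elif alns:
            hits[seq] = alns
    return hits, skipped


def write_alignment_table(hits: dict[str, list[GenomeAlignment]],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tchrom\tstart\tend\tstrand\tn_hits\n")
        for seq in sorted(hits):
            for a in hits[seq]:
                fh.write(f"{a.tag}\t{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t{a.n_hits}\n")
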