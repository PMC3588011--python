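"""Raw-read cleaning and collapsing into unique tags.

The "clean reads" stage: 3' adapter removal, length filtering (inclusive
18-30 nt by default) and collapsing identical inserts into
:class:`SmallRNATag` records carrying per-library counts.  All internal
sequence is DNA alphabet (U normalised to T at ingest); mature-miRNA
renderings elsewhere convert back to U.

Read-count conservation holds at every stage: input reads = kept reads plus
the per-reason removal tallies in :class:`CleaningStats`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

NO_ADAPTER = "no 3' adaptor"
TOO_SHORT = "shorter than min length"
TOO_LONG = "longer than max length"
AMBIGUOUS = "ambiguous base"
EMPTY_INSERT = "empty insert"


@dataclass
class SmallRNATag:
    """A collapsed unique read with per-library counts."""

    sequence: str
    count_by_library: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.count_by_library.values())

    def count(self, library: str) -> int:
        return self.count_by_library.get(library, 0)


@dataclass
class CleaningStats:
    """Per-library accounting of the cleaning stage."""

    library: str
    n_input: int = 0
    n_kept: int = 0
    removed_by_reason: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return self.n_input == self.n_kept + sum(self.removed_by_reason.values())

    def as_dict(self) -> dict:
        return {"library": self.library, "input_reads": self.n_input,
                "clean_reads": self.n_kept,
                "removed": dict(sorted(self.removed_by_reason.items()))}


def normalize_seq(seq: str) -> str:
    """Uppercase and U->T: the single canonical internal alphabet."""
    return seq.upper().replace("U", "T")


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> tuple[str | None, str | None]:
    """Trim the 3' adapter from ``read``.

    Returns ``(insert, None)`` on success or ``(None, reason)`` on
    rejection.  The insert is the prefix preceding the leftmost full adapter
    occurrence; failing that, a terminal adapter *prefix* of at least
    ``min_overlap`` nt at the read's 3' end also counts (the sequencer ran
    out of cycles mid-adapter).  Reads without a detectable adapter are
    rejected as lacking a reliable 3' adaptor; zero-length inserts
    (adapter dimers) are rejected too.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not read:
        return None, NO_ADAPTER
    read = normalize_seq(read)
    adapter = normalize_seq(adapter)
    pos = read.find(adapter)
    if pos == -1:
        # suffix of read == prefix of adapter, longest first
        for k in range(min(len(read), len(adapter) - 1), min_overlap - 1, -1):
            if read.endswith(adapter[:k]):
                pos = len(read) - k
                break
    if pos == -1:
        return None, NO_ADAPTER
    if pos == 0:
        return None, EMPTY_INSERT
    return read[:pos], None


def filter_by_length(tags: Iterable[SmallRNATag], min_len: int = 18,
                     max_len: int = 30) -> tuple[list[SmallRNATag], Counter]:
    """Keep tags with ``min_len <= length <= max_len`` (inclusive bounds).

    The removal log counts *reads* (not tags) removed per reason.
    """
    kept: list[SmallRNATag] = []
    removed: Counter = Counter()
    for tag in tags:
        if tag.length < min_len:
            removed[TOO_SHORT] += tag.total_count
        elif tag.length > max_len:
            removed[TOO_LONG] += tag.total_count
        else:
            kept.append(tag)
    return kept, removed


def collapse(reads_by_library: dict[str, Iterable[str]]) -> list[SmallRNATag]:
    """Collapse cleaned reads into unique tags with per-library counts.

    Counts are exact tallies; the per-library sum over tags equals the
    number of input reads.  Tags are returned sorted by total count
    descending, then sequence, for deterministic output.
    """
    counters = {lib: Counter(normalize_seq(r) for r in reads)
                for lib, reads in reads_by_library.items()}
    seqs = sorted(set().union(*[set(c) for c in counters.values()] or [set()]))
    tags = [SmallRNATag(sequence=s,
                        count_by_library={lib: c[s] for lib, c in counters.items()
                                          if c[s] > 0})
            for s in seqs]
    tags.sort(key=lambda t: (-t.total_count, t.sequence))
    return tags


def clean_library(reads: Iterable[str], library: str, adapter: str | None,
                  min_overlap: int = 6, min_len: int = 18, max_len: int = 30,
                  ) -> tuple[list[str], CleaningStats]:
    """Full cleaning of one library: adapter trim, N filter, length filter.

    ``adapter=None`` skips trimming (reads are already inserts).  Running
    the cleaner again on its own output changes nothing (idempotence).
    """
    stats = CleaningStats(library=library)
    clean: list[str] = []
    for raw in reads:
        stats.n_input += 1
        seq = normalize_seq(str(raw))
        if adapter is not None:
            insert, reason = trim_adapter(seq, adapter, min_overlap)
            if insert is None:
                stats.removed_by_reason[reason] += 1
                continue
            seq = insert
        if set(seq) - set("ACGT"):
            stats.removed_by_reason[AMBIGUOUS] += 1
            continue
        if len(seq) < min_len:
            stats.removed_by_reason[TOO_SHORT] += 1
            continue
        if len(seq) > max_len:
            stats.removed_by_reason[TOO_LONG] += 1
            continue
        clean.append(seq)
        stats.n_kept += 1
    return clean, stats


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


def clean_fastq_libraries(paths: dict[str, str | Path], adapter: str | None,
                          min_overlap: int = 6, min_len: int = 18,
                          max_len: int = 30,
                          ) -> tuple[list[SmallRNATag], dict[str, CleaningStats]]:
    """Clean and collapse a set of FASTQ libraries keyed by library label."""
    cleaned: dict[str, list[str]] = {}
    stats: dict[str, CleaningStats] = {}
    for lib, path in paths.items():
        cleaned[lib], stats[lib] = clean_library(
            read_fastq(path), lib, adapter, min_overlap, min_len, max_len)
    return collapse(cleaned), stats


def write_tag_table(tags: list[SmallRNATag], libraries: list[str],
                    path: str | Path) -> None:
    """Write the tag table as TSV: sequence, length, count_<lib>..."""
    with open(path, "w") as fh:
        fh.write("sequence\tlength\t" + "\t".join(f"count_{l}" for l in libraries) + "\n")
        for t in tags:
            counts = "\t".join(str(t.count(l)) for l in libraries)
            fh.write(f"{t.sequence}\t{t.length}\t{counts}\n")
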