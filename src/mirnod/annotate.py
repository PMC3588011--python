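"""Annotation screen: subtract tags matching known non-miRNA loci.

Mapped tags are intersected with an interval annotation (GFF3) of
rRNA/tRNA/snoRNA/snRNA/scRNA loci, repeats, and mRNA exons/introns; any
overlap of at least 1 nt assigns the class, with a fixed precedence when a
tag (or any of its placements) touches several classes.  Only unannotated
tags proceed to miRNA discovery.

Known-miRNA loci (annotation type ``miRNA``) are protected: a tag whose
only annotation conflict is an exon/intron overlap at a miRNA locus stays
unannotated, since many plant miRNAs reside in introns; the exemption is
logged per tag.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .genome_map import GenomeAlignment

#: final labels, highest precedence first; "unannotated" is the fall-through
PRECEDENCE = ["rRNA", "tRNA", "snoRNA", "snRNA", "scRNA", "repeat",
              "exon", "intron"]
UNANNOTATED = "unannotated"
MIRNA_TYPE = "miRNA"


@dataclass
class Annotation:
    """Per-chromosome interval trees, one per annotation class."""

    trees: dict[str, dict[str, IntervalTree]]   # class -> chrom -> tree
    chroms: set[str]

    @classmethod
    def from_gff3(cls, path: str | Path, genome_chroms: set[str] | None = None
                  ) -> "Annotation":
        """Load GFF3 intervals (1-based inclusive on disk -> 0-based half-open).

        Raises at load if a record references a chromosome absent from
        ``genome_chroms`` (when given).
        """
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["seqid", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"],
                         dtype={"seqid": str, "type": str})
        trees: dict[str, dict[str, IntervalTree]] = defaultdict(
            lambda: defaultdict(IntervalTree))
        chroms: set[str] = set()
        for row in df.itertuples(index=False):
            if genome_chroms is not None and row.seqid not in genome_chroms:
                raise ValueError(f"annotation references unknown chromosome "
                                 f"{row.seqid!r}")
            chroms.add(row.seqid)
            trees[row.type][row.seqid].addi(int(row.start) - 1, int(row.end),
                                            row.attributes)
        return cls(trees={k: dict(v) for k, v in trees.items()}, chroms=chroms)

    def classes_at(self, chrom: str, start: int, end: int) -> set[str]:
        """Annotation types overlapping [start, end) by >= 1 nt."""
        found = set()
        for cls_name, per_chrom in self.trees.items():
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlap(start, end):
                found.add(cls_name)
        return found


def classify_tag(alignments: list[GenomeAlignment], annotation: Annotation,
                 ) -> tuple[str, bool]:
    """Final class of a tag given all its genome placements.

    Any >=1 nt overlap of any placement with an annotated interval counts;
    the highest-precedence class wins (rRNA > tRNA > snoRNA > snRNA > scRNA
    > repeat > exon > intron > unannotated).  Returns ``(label,
    mirna_protected)`` where the flag marks tags rescued from exon/intron
    subtraction because they coincide with an annotated miRNA locus.
    Precedence makes the result independent of annotation record order.
    """
    found: set[str] = set()
    touches_mirna = False
    for aln in alignments:
        classes = annotation.classes_at(aln.chrom, aln.start, aln.end)
        if MIRNA_TYPE in classes:
            touches_mirna = True
            classes = classes - {MIRNA_TYPE}
        found |= classes
    for label in PRECEDENCE:
        if label in found:
            if label in ("exon", "intron") and touches_mirna:
                return UNANNOTATED, True
            return label, False
    return UNANNOTATED, False


def classify_tags(hits: dict[str, list[GenomeAlignment]], annotation: Annotation,
                  ) -> tuple[dict[str, str], list[str]]:
    """Classify every mapped tag; returns (label by tag, protected tags)."""
    labels: dict[str, str] = {}
    protected: list[str] = []
    for seq in sorted(hits):
        label, prot = classify_tag(hits[seq], annotation)
        labels[seq] = label
        if prot:
            protected.append(seq)
    return labels, protected


def class_summary(tags, labels: dict[str, str], libraries: list[str],
                  ) -> pd.DataFrame:
    """Per-class read totals per library; totals conserve classified reads.

    ``tags`` is the tag list; tags absent from ``labels`` (unmapped or
    length-skipped) are reported under ``unplaced`` so the summary
    partitions the clean-read totals exactly.
    """
    rows: dict[str, Counter] = defaultdict(Counter)
    for tag in tags:
        label = labels.get(tag.sequence, "unplaced")
        for lib in libraries:
            rows[label][lib] += tag.count(lib)
    order = PRECEDENCE + [UNANNOTATED, "unplaced"]
    data = [{"class": label, **{lib: rows[label][lib] for lib in libraries}}
            for label in order if label in rows]
    return pd.DataFrame(data)
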