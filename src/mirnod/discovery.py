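"""Known and novel miRNA calling.

Known miRNAs are matched against a mature catalog (miRBase-style headers);
remaining unannotated tags are evaluated as novel miRNA candidates by
folding precursor windows around each genome placement and applying the
plant miRNA annotation criteria to the hairpin:

* enough read support (default >= 20 reads summed over libraries);
* the mature lies entirely within one hairpin arm;
* a star sequence on the opposite arm forms a duplex with <= 4 mismatches;
* every duplex bulge is smaller than 2 nt (strict: <= 1, configurable);
* the duplex carries the 2-nt 3' overhang Dicer signature (tolerance +-1).

Read support is checked first — low-abundance tags are eliminated before
any folding, mirroring how such screens are run in practice — and a
rejected candidate carries the first failing rule, so planted single-rule
decoys report exactly their violated rule.

Accepted calls are grouped into families (identical seed, positions 2-8,
plus overall edit distance <= 3) and novel calls are classed for
cross-species conservation with a seeded local-alignment screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .fold import SecondaryStructure, arm_of, fold, pair_weight
from .genome_map import GenomeAlignment
from .preprocess import SmallRNATag, normalize_seq

# rejection reasons (also the planted decoy labels of the simulator)
RULE_READS = "low abundance"
RULE_ARM = "not within arm"
RULE_MISMATCH = "duplex mismatches > 4"
RULE_BULGE = "oversized bulge"
RULE_OVERHANG = "no 2-nt 3' overhang"
RULE_ORDER = [RULE_READS, RULE_ARM, RULE_MISMATCH, RULE_BULGE, RULE_OVERHANG]


@dataclass
class DuplexStats:
    """Pairing statistics of a mature::star duplex inside a hairpin."""

    n_mismatches: int
    bulge_sizes: list[int]
    overhang_3p: int            # mature 3'-end stagger; 2 = canonical Dicer cut
    star_interval: tuple[int, int]

    @property
    def max_bulge(self) -> int:
        return max(self.bulge_sizes, default=0)


@dataclass
class CriteriaReport:
    """Per-rule outcome of one candidate evaluation."""

    checks: dict[str, tuple[bool, object]] = field(default_factory=dict)
    failed: str | None = None

    @property
    def accepted(self) -> bool:
        return self.failed is None

    @property
    def progress(self) -> int:
        """Number of leading rules passed before the first failure."""
        n = 0
        for rule in RULE_ORDER:
            if rule in self.checks and self.checks[rule][0]:
                n += 1
            else:
                break
        return n


@dataclass
class MiRNACall:
    """A final known or novel miRNA call."""

    id: str
    mature: str                              # DNA alphabet
    provenance: str                          # 'known' | 'novel'
    read_support: int
    count_by_library: dict[str, int] = field(default_factory=dict)
    star: str | None = None
    precursor: tuple[str, int, int, str] | None = None   # chrom,start,end,strand
    family: str | None = None
    report: CriteriaReport | None = None

    @property
    def mature_rna(self) -> str:
        return self.mature.replace("T", "U")


# ---------------------------------------------------------------------------
# known-miRNA matching


def load_catalog(path: str | Path) -> dict[str, str]:
    """Load a mature catalog FASTA into {name: DNA sequence}.

    Headers are miRBase style, e.g. ``>gma-miR166a``; a malformed (empty)
    header fails at load.
    """
    catalog: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"malformed catalog header in {path}")
        catalog[rec.id] = normalize_seq(str(rec.seq))
    return catalog


def mirna_family_name(name: str) -> str:
    """Family from a miRBase-style name: gma-miR166a-5p -> miR166."""
    core = name.split("-miR")[-1] if "-miR" in name else name
    digits = ""
    for ch in core:
        if ch.isdigit():
            digits += ch
        elif digits:
            break
    return f"miR{digits}" if digits else name


def match_known(tag: str, catalog: dict[str, str], end_tolerance: int = 2,
                ) -> tuple[str, str] | None:
    """Match a tag against catalog matures.

    A match is an identical sequence, or an end-trimmed/extended variant:
    one sequence contained in the other with a total length difference of at
    most ``end_tolerance`` nt and an identical core.  Internal substitutions
    never match.  Returns ``(catalog name, family)`` or ``None``; ties go to
    the lexicographically smallest catalog name.
    """
    seq = normalize_seq(tag)
    best: str | None = None
    for name in sorted(catalog):
        mat = catalog[name]
        if seq == mat:
            return name, mirna_family_name(name)
        delta = abs(len(seq) - len(mat))
        if delta <= end_tolerance and (seq in mat or mat in seq):
            if best is None:
                best = name
    if best is not None:
        return best, mirna_family_name(best)
    return None


# ---------------------------------------------------------------------------
# precursor windows and duplex geometry


def extract_precursor_windows(aln: GenomeAlignment, genome: dict[str, str],
                              flank: int = 150,
                              ) -> list[tuple[str, tuple[int, int], tuple[int, int]]]:
    """Candidate precursor windows around one placement.

    Two asymmetric windows are taken — ``[start-flank, end+20)`` and
    ``[start-20, end+flank)`` — clipped at chromosome bounds, so the mature
    may sit on either hairpin arm.  Each entry is ``(sequence 5'->3' on the
    tag's strand, (window_start, window_end) on the forward genome,
    (mature_start, mature_end) within the window sequence)``.  Windows that
    would not contain the full mature are skipped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    chrom_seq = genome[aln.chrom]
    n = len(chrom_seq)
    out = []
    for ws, we in ((aln.start - flank, aln.end + 20),
                   (aln.start - 20, aln.end + flank)):
        ws, we = max(0, ws), min(n, we)
        if ws > aln.start or we < aln.end:
            continue
        seq = chrom_seq[ws:we].upper()
        if aln.strand == "+":
            m = (aln.start - ws, aln.end - ws)
        else:
            seq = reverse_complement(seq)
            m = (we - aln.end, we - aln.start)
        out.append((seq, (ws, we), m))
    return out


def duplex_stats(structure: SecondaryStructure, mature: tuple[int, int],
                 ) -> DuplexStats | None:
    """Mature::star duplex statistics from a folded precursor.

    The star interval is derived from the pair table assuming canonical
    staggered processing: it spans the partners of the mature's outermost
    paired bases, extrapolated to the mature's ends and shifted by the 2-nt
    3' overhang.  Mismatches are counted along a walk of the duplex
    (simultaneous unpaired positions on both strands count 1 each step;
    G:U wobbles are pairs, not mismatches); asymmetric unpaired runs are
    bulges.  ``overhang_3p`` is the measured stagger at the mature's 3' end.
    Returns None when the mature has no partners outside itself.
    """
    pt = structure.pair_table
    ms, me = mature
    paired = [i for i in range(ms, me)
              if pt[i] != -1 and not (ms <= pt[i] < me)]
    if not paired:
        return None
    a, b = paired[0], paired[-1]
    # extrapolate the partners of the mature's ends and add the 2-nt stagger;
    # nesting makes partners decrease as the mature position increases, so the
    # same formulas hold on either arm
    star_s = pt[b] - ((me - 1) - b) + 2
    star_e = pt[a] + (a - ms) + 3
    star_s = max(0, star_s)
    star_e = min(len(pt), star_e)
    if star_e - star_s < 5:
        return None
    # the mature's 3'-terminal bases whose partners fall outside the star
    # (or are unpaired) are its 3' overhang; 2 nt is the Dicer signature
    duplexed = [i for i in range(ms, me)
                if pt[i] != -1 and star_s <= pt[i] < star_e]
    overhang = (me - 1) - max(duplexed) if duplexed else me - ms

    # walk the duplex from the mature 5' paired end towards its 3' end
    mismatches = a - ms                      # unpaired mature 5'-terminal run
    bulges: list[int] = []
    i, j = a, pt[a]
    dj = -1          # partners decrease as the mature position increases
    run = 0

    def in_star(x: int) -> bool:
        return star_s <= x < star_e

    while i <= b and in_star(j):
        if pt[i] == j:
            if run:
                bulges.append(run)
                run = 0
            i += 1
            j += dj
        elif pt[i] == -1 and pt[j] == -1:
            if run:
                bulges.append(run)
                run = 0
            mismatches += 1
            i += 1
            j += dj
        elif pt[i] == -1:
            run += 1                          # bulged base on the mature side
            i += 1
        elif pt[j] == -1 or not (ms <= pt[j] < me):
            run += 1                          # bulged base on the star side
            j += dj
        else:
            mismatches += 1
            i += 1
            j += dj
    if run:
        bulges.append(run)
    return DuplexStats(n_mismatches=mismatches, bulge_sizes=bulges,
                       overhang_3p=overhang, star_interval=(star_s, star_e))


# ---------------------------------------------------------------------------
# novel calling


@dataclass
class NovelThresholds:
    """Thresholds of the novel-miRNA criteria."""

    min_reads: int = 20
    max_duplex_mismatches: int = 4
    max_bulge: int = 1          # strict reading of "bulges < 2 bases"
    overhang: int = 2
    overhang_tolerance: int = 1
    min_loop: int = 3


def evaluate_window(window_seq: str, mature: tuple[int, int],
                    thresholds: NovelThresholds,
                    ) -> tuple[CriteriaReport, DuplexStats | None, SecondaryStructure]:
    """Apply the structural criteria to one precursor window."""
    report = CriteriaReport()
    structure = fold(window_seq, min_loop=thresholds.min_loop)
    arm = arm_of(structure, mature)
    ok = arm in ("five_prime_arm", "three_prime_arm")
    report.checks[RULE_ARM] = (ok, arm)
    if not ok:
        report.failed = RULE_ARM
        return report, None, structure
    stats = duplex_stats(structure, mature)
    if stats is None:
        report.checks[RULE_ARM] = (False, "no duplex partner")
        report.failed = RULE_ARM
        return report, None, structure
    ok = stats.n_mismatches <= thresholds.max_duplex_mismatches
    report.checks[RULE_MISMATCH] = (ok, stats.n_mismatches)
    if not ok:
        report.failed = RULE_MISMATCH
        return report, stats, structure
    ok = stats.max_bulge <= thresholds.max_bulge
    report.checks[RULE_BULGE] = (ok, stats.max_bulge)
    if not ok:
        report.failed = RULE_BULGE
        return report, stats, structure
    ok = abs(stats.overhang_3p - thresholds.overhang) <= thresholds.overhang_tolerance
    report.checks[RULE_OVERHANG] = (ok, stats.overhang_3p)
    if not ok:
        report.failed = RULE_OVERHANG
    return report, stats, structure


def call_novel(tag: SmallRNATag, alignments: list[GenomeAlignment],
               genome: dict[str, str], flank: int = 150,
               thresholds: NovelThresholds | None = None,
               ) -> MiRNACall | tuple[None, CriteriaReport]:
    """Evaluate an unannotated tag as a novel miRNA.

    Read support is checked first (cheap, and low-abundance tags are
    eliminated before folding); then every precursor window of every
    placement is folded and judged.  The call is accepted if any window
    passes all criteria; otherwise the rejection report comes from the
    window that passed the most leading rules (first window on ties), so a
    single-rule violation is reported as exactly that rule.
    """
    th = thresholds or NovelThresholds()
    support = tag.total_count
    reads_ok = support >= th.min_reads
    if not reads_ok:
        report = CriteriaReport(checks={RULE_READS: (False, support)},
                                failed=RULE_READS)
        return None, report

    best_report: CriteriaReport | None = None
    for aln in alignments:
        for window_seq, span, mature in extract_precursor_windows(
                aln, genome, flank):
            report, stats, structure = evaluate_window(window_seq, mature, th)
            report.checks[RULE_READS] = (True, support)
            if report.accepted:
                ss, se = stats.star_interval
                star = window_seq[ss:se]
                if aln.strand == "+":
                    pre = (aln.chrom, span[0], span[1], "+")
                else:
                    pre = (aln.chrom, span[0], span[1], "-")
                return MiRNACall(
                    id="", mature=tag.sequence, provenance="novel",
                    read_support=support,
                    count_by_library=dict(tag.count_by_library),
                    star=star, precursor=pre, report=report)
            if best_report is None or report.progress > best_report.progress:
                best_report = report
    if best_report is None:   # no window at all (e.g. tag at a contig edge)
        best_report = CriteriaReport(
            checks={RULE_READS: (True, support), RULE_ARM: (False, "no window")},
            failed=RULE_ARM)
    return None, best_report


# ---------------------------------------------------------------------------
# families


def seed_region(seq: str) -> str:
    """Seed nucleotides, positions 2-8 (1-based) from the 5' end."""
    return normalize_seq(seq)[1:8]


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def assign_families(calls: list[MiRNACall], max_edit: int = 3,
                    prefix: str = "FAM") -> dict[str, str]:
    """Group calls into families by identical seed and edit distance <= 3.

    Two matures are directly related iff their positions 2-8 are identical
    and their overall edit distance is <= ``max_edit``; families are the
    union-find closure.  Naming is deterministic: families are numbered by
    their lexicographically smallest mature.  Returns {mature: family id}
    and sets ``family`` on each call (known calls keep their catalog family
    when present).
    """
    seqs = sorted({normalize_seq(c.mature) for c in calls})
    parent = {s: s for s in seqs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, s1 in enumerate(seqs):
        for s2 in seqs[i + 1:]:
            if seed_region(s1) == seed_region(s2) and \
                    edit_distance(s1, s2) <= max_edit:
                r1, r2 = find(s1), find(s2)
                if r1 != r2:
                    parent[max(r1, r2)] = min(r1, r2)

    roots = sorted({find(s) for s in seqs})
    fam_of_root = {r: f"{prefix}{i + 1:03d}" for i, r in enumerate(roots)}
    fam = {s: fam_of_root[find(s)] for s in seqs}
    for call in calls:
        if call.family is None:
            call.family = fam[normalize_seq(call.mature)]
    return fam


# ---------------------------------------------------------------------------
# conservation


#: local-alignment score system mirroring a nucleotide BLAST search
SW_MATCH, SW_MISMATCH, SW_GAP = 1, -3, -5
#: Karlin-Altschul parameters for the +1/-3 system at uniform base frequencies
KA_LAMBDA = 1.374
KA_K = 0.711
DEFAULT_WORD_SIZE = 11

CONSERVED = "conserved_plants"
LEGUME = "legume_specific"
SPECIES = "species_specific"


def smith_waterman_score(a: str, b: str) -> int:
    """Best local alignment score (match +1, mismatch -3, gap -5)."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = prev[j - 1] + (SW_MATCH if ai == b[j - 1] else SW_MISMATCH)
            s = max(s, prev[j] + SW_GAP, cur[j - 1] + SW_GAP, 0)
            cur[j] = s
            if s > best:
                best = s
        prev = cur
    return best


def _shares_word(a: str, b: str, w: int) -> bool:
    if len(a) < w or len(b) < w:
        return False
    words = {a[i:i + w] for i in range(len(a) - w + 1)}
    return any(b[i:i + w] in words for i in range(len(b) - w + 1))


def evalue(score: int, query_len: int, search_space: int) -> float:
    """Karlin-Altschul expectation for a local score over a catalog search."""
    return KA_K * query_len * search_space * math.exp(-KA_LAMBDA * score)


def hits_catalog(mature: str, catalog: dict[str, str], max_evalue: float = 10.0,
                 word_size: int = DEFAULT_WORD_SIZE) -> bool:
    """Whether the mature hits any catalog entry at E <= ``max_evalue``.

    A hit requires a shared exact word of ``word_size`` nt (the seeding step
    of a nucleotide BLAST search, without which an E cutoff of 10 would
    accept near-random matches) and a local alignment with expectation at or
    below the cutoff over the whole catalog's search space.
    """
    seq = normalize_seq(mature)
    space = sum(len(s) for s in catalog.values())
    if space == 0:
        return False
    for target in catalog.values():
        if not _shares_word(seq, target, word_size):
            continue
        score = smith_waterman_score(seq, target)
        if evalue(score, len(seq), space) <= max_evalue:
            return True
    return False


def classify_conservation(novel_calls: list[MiRNACall],
                          catalogs: dict[str, tuple[dict[str, str], bool]],
                          max_evalue: float = 10.0,
                          word_size: int = DEFAULT_WORD_SIZE) -> dict[str, str]:
    """Three-way conservation class per novel mature.

    ``catalogs`` maps species label to ``(catalog, is_legume)``.  A mature
    hitting any non-legume plant catalog is ``conserved_plants``; hitting
    only legume catalogs is ``legume_specific``; hitting none is
    ``species_specific``.  An empty catalog set yields all
    ``species_specific``.
    """
    out: dict[str, str] = {}
    for call in novel_calls:
        seq = normalize_seq(call.mature)
        if seq in out:
            continue
        hit_nonlegume = hit_legume = False
        for species in sorted(catalogs):
            catalog, is_legume = catalogs[species]
            if hits_catalog(seq, catalog, max_evalue, word_size):
                if is_legume:
                    hit_legume = True
                else:
                    hit_nonlegume = True
        out[seq] = (CONSERVED if hit_nonlegume
                    else LEGUME if hit_legume else SPECIES)
    return out
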