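"""Plant miRNA target prediction and cleavage-site validation.

Sites are found by sliding the reverse complement of the mature miRNA
along each transcript and scoring every offset with a per-position penalty
vector (Watson-Crick 0, G:U wobble 0.5, mismatch 1, indel 2); the
expectation E of a site is the penalty sum.  Position numbering is 1-based
from the miRNA 5' end.  A site is accepted iff

* at most one mismatch in positions 2-12, and none at positions 10 or 11
  (the slicing site);
* at most three further mismatches in positions 12-21;
* no run of more than two consecutive mismatches;
* E <= ``max_E`` (default 3.5).

A mismatch here is a full-penalty position (>= 1); G:U wobbles count 0.5
towards E but are not positional mismatches.  Scanning is ungapped — the
indel penalty exists in the scoring table for externally supplied gapped
alignments but gapped sites are not searched.

Cleavage validation tallies the 5' ends of RACE-style reads on the
transcript; the modal coordinate is the cut, expressed between two miRNA
positions (canonical slicing falls between positions 10 and 11).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import reverse_complement

from .preprocess import normalize_seq

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}   # miRNA G : target U, miRNA U : target G

PENALTY_WC = 0.0
PENALTY_WOBBLE = 0.5
PENALTY_MISMATCH = 1.0
PENALTY_INDEL = 2.0


def score_position(mirna_base: str, target_base: str) -> float:
    """Penalty of pairing one miRNA base with one target base."""
    a = normalize_seq(mirna_base)
    b = normalize_seq(target_base)
    if (a, b) in WC:
        return PENALTY_WC
    if (a, b) in WOBBLE:
        return PENALTY_WOBBLE
    return PENALTY_MISMATCH


@dataclass
class TargetSite:
    """One accepted (or evaluated) miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int                       # 0-based half-open on the transcript
    end: int
    penalties: list[float]           # indexed by miRNA position - 1
    expectation: float
    n_mismatches_2_12: int
    n_mismatches_12_21: int
    max_consecutive_mismatches: int

    def mirna_position_of(self, transcript_coord: int) -> int:
        """1-based miRNA position aligned to a transcript base in the site."""
        return self.end - transcript_coord


# ordered positional rules; a rejected offset reports the first failure
RULE_SEED_MISMATCHES = "more than one mismatch in positions 2-12"
RULE_POS_10_11 = "mismatch at position 10 or 11"
RULE_TAIL_MISMATCHES = "more than three mismatches in positions 12-21"
RULE_RUN = "more than two consecutive mismatches"
RULE_EXPECTATION = "expectation above threshold"


def evaluate_offset(mirna: str, transcript: str, offset: int,
                    max_e: float = 3.5) -> tuple[TargetSite, str | None]:
    """Score one ungapped placement of the miRNA site at ``offset``.

    The site occupies ``transcript[offset : offset + len(mirna)]`` and the
    miRNA 5' end faces the site's 3' end.  Returns the evaluated site and
    the first failing rule (None if accepted).
    """
    seq = normalize_seq(mirna)
    L = len(seq)
    window = normalize_seq(transcript)[offset:offset + L]
    if len(window) < L:
        raise ValueError("offset window exceeds transcript")
    # miRNA position p (1-based) pairs the transcript base at offset+L-p
    penalties = [score_position(seq[p - 1], window[L - p]) for p in range(1, L + 1)]
    mm = [p >= PENALTY_MISMATCH for p in penalties]
    mm_2_12 = sum(mm[1:12])
    mm_12_21 = sum(mm[11:21])
    run = best_run = 0
    for flag in mm:
        run = run + 1 if flag else 0
        best_run = max(best_run, run)
    site = TargetSite(
        mirna_id="", transcript_id="", start=offset, end=offset + L,
        penalties=penalties, expectation=float(sum(penalties)),
        n_mismatches_2_12=mm_2_12, n_mismatches_12_21=mm_12_21,
        max_consecutive_mismatches=best_run)
    if mm_2_12 > 1:
        return site, RULE_SEED_MISMATCHES
    if mm[9] or mm[10]:
        return site, RULE_POS_10_11
    if mm_12_21 > 3:
        return site, RULE_TAIL_MISMATCHES
    if best_run > 2:
        return site, RULE_RUN
    if site.expectation > max_e:
        return site, RULE_EXPECTATION
    return site, None


def scan_transcript(mirna: str, transcript: str, max_e: float = 3.5,
                    mirna_id: str = "", transcript_id: str = "",
                    ) -> list[TargetSite]:
    """All accepted sites of one miRNA on one transcript.

    Overlapping acceptances are deduplicated keeping the minimum-E site
    (ties: leftmost).  Transcripts shorter than the miRNA yield no sites.
    Lowering ``max_e`` never adds a site (monotonicity).
    """
    seq = normalize_seq(mirna)
    if not 19 <= len(seq) <= 24:
        raise ValueError(f"miRNA length {len(seq)} outside 19-24 nt")
    tx = normalize_seq(transcript)
    accepted: list[TargetSite] = []
    for offset in range(0, len(tx) - len(seq) + 1):
        site, failure = evaluate_offset(seq, tx, offset, max_e)
        if failure is None:
            site.mirna_id = mirna_id
            site.transcript_id = transcript_id
            accepted.append(site)
    # deduplicate overlapping sites
    accepted.sort(key=lambda s: (s.expectation, s.start))
    kept: list[TargetSite] = []
    for site in accepted:
        if all(site.end <= k.start or site.start >= k.end for k in kept):
            kept.append(site)
    kept.sort(key=lambda s: s.start)
    return kept


def render_alignment(mirna: str, transcript: str, site: TargetSite) -> str:
    """Text rendering: target 5'->3' on top, miRNA 3'->5' below."""
    seq = normalize_seq(mirna)
    window = normalize_seq(transcript)[site.start:site.end]
    mir_rev = seq[::-1]   # 3'->5', aligned with the target window
    marks = "".join(
        "|" if site.penalties[len(seq) - 1 - k] == 0
        else "o" if site.penalties[len(seq) - 1 - k] == PENALTY_WOBBLE
        else " "
        for k in range(len(seq)))
    return (f"target 5' {window} 3'\n"
            f"          {marks}\n"
            f"miRNA  3' {mir_rev.replace('T', 'U')} 5'   E={site.expectation:g}")


# ---------------------------------------------------------------------------
# cleavage validation


@dataclass
class CleavageEvent:
    """A mapped cleavage position supported by RACE-style reads."""

    transcript_id: str
    cut_coordinate: int          # downstream fragment starts here (0-based)
    support: int                 # reads sharing the modal 5' coordinate
    n_reads: int
    between_positions: tuple[int, int] | None   # miRNA positions p | p+1


def tally_cleavage(race_reads: list[str], transcript: str,
                   site: TargetSite | None = None,
                   window: int = 30) -> CleavageEvent | None:
    """Map RACE read 5' ends onto the transcript and call the cut.

    Each read is placed by exact leftmost substring match; the modal 5'
    coordinate is the cut, supported by the reads sharing it.  When a
    ``site`` is given, only reads within ``window`` nt of it count and the
    cut is expressed relative to the miRNA 5' end; returns None ("no
    supported cleavage") when no read maps near the site.
    """
    tx = normalize_seq(transcript)
    starts: Counter = Counter()
    for read in race_reads:
        pos = tx.find(normalize_seq(str(read)))
        if pos == -1:
            continue
        if site is not None and not (site.start - window <= pos <= site.end + window):
            continue
        starts[pos] += 1
    if not starts:
        return None
    cut, support = min(starts.items(), key=lambda kv: (-kv[1], kv[0]))
    between = None
    if site is not None:
        p = site.end - cut           # base at cut pairs miRNA position p
        between = (p, p + 1)
    return CleavageEvent(
        transcript_id=site.transcript_id if site else "",
        cut_coordinate=cut, support=support,
        n_reads=sum(starts.values()), between_positions=between)
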