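"""Synthetic small-RNA world with recorded ground truth.

Emulates the inputs of a two-condition (non-stressed vs salt-stressed
nodule) small-RNA sequencing experiment: a genome carrying planted
pre-miRNA hairpins that satisfy the novel-miRNA criteria, decoy hairpins
each violating exactly one criterion, known-miRNA loci with a mature
catalog, contaminant ncRNA loci, two read libraries with planted
two-condition count profiles, transcripts carrying target sites with
controlled mismatch patterns, and RACE-style cleaved-transcript reads.

Planted precursors are built backward from the desired mature::miRNA*
duplex: the star arm is the complement of the mature with controlled
mismatches or bulges, joined by an 8-15 nt all-A loop, so criterion
satisfaction holds by construction; every planted locus is then verified
by actually folding its discovery windows, and flanking sequence is
resampled (or the locus redesigned) until the intended verdict — including
each decoy's single violated rule — is reproduced.  Identical seeds give
byte-identical fixture sets.

Two-condition counts use one negative-binomial draw per miRNA (mean from
the config, dispersion 0.1) with the planted fold applied exactly to the
second library, so a planted fold of 2 is recoverable at the 2-fold
classification boundary; both libraries have identical fixed read totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from . import discovery
from .discovery import NovelThresholds, evaluate_window
from .fold import pair_weight
from .preprocess import trim_adapter

BASES = np.array(list("ACGT"))

#: star base guaranteed to pair neither Watson-Crick nor G:U with the key
NON_PAIRING = {"A": "C", "C": "A", "G": "A", "T": "C"}
#: target-strand base that is a full mismatch (not a wobble) with the key
TARGET_MISMATCH = {"A": "C", "C": "A", "G": "A", "T": "C"}
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

DECOY_RULES = [discovery.RULE_MISMATCH, discovery.RULE_BULGE,
               discovery.RULE_ARM, discovery.RULE_READS]

#: planted target-site patterns: (name, {1-based miRNA position: kind}, verdict)
TARGET_PATTERNS = [
    ("perfect", {}, "accept"),
    ("wobble_15", {15: "wobble"}, "accept"),
    ("mm_5", {5: "mismatch"}, "accept"),
    ("mm_17", {17: "mismatch"}, "accept"),
    ("mm_10", {10: "mismatch"}, "reject"),
    ("mm_11", {11: "mismatch"}, "reject"),
    ("seed_two_mm", {4: "mismatch", 7: "mismatch"}, "reject"),
    ("tail_four_mm", {13: "mismatch", 15: "mismatch", 17: "mismatch",
                      19: "mismatch"}, "reject"),
    ("run_of_three", {14: "mismatch", 15: "mismatch", 16: "mismatch"},
     "reject"),
]


@dataclass
class CountModel:
    """Per-miRNA abundance model: NB(mean, dispersion) with exact fold."""

    mean_known: float = 300.0
    mean_novel: float = 150.0
    mean_decoy: float = 60.0
    dispersion: float = 0.1
    #: cycled over planted miRNAs; numbers are SSN/NSN folds, strings are
    #: the library-exclusive classes
    fold_classes: tuple = (4.0, 2.0, 1.5, 1.0, 0.5, 0.25,
                           "NSN_only", "SSN_only")


def default_length_weights() -> dict[int, float]:
    """Read-length distribution over 18-30 nt, modes at 24 then 21."""
    return {18: 0.02, 19: 0.03, 20: 0.08, 21: 0.25, 22: 0.10, 23: 0.07,
            24: 0.30, 25: 0.05, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.015,
            30: 0.015}


@dataclass
class SimulationConfig:
    seed: int = 1
    genome_length: int = 60_000
    n_true_hairpins: int = 20
    n_decoys_per_rule: int = 5
    n_known_mirnas: int = 20
    ncRNA_fraction: float = 0.20
    total_reads: int = 40_000
    libraries: tuple[str, str] = ("NSN", "SSN")
    adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    read_length: int = 36
    mature_length: int = 21
    loop_range: tuple[int, int] = (8, 15)
    minus_strand_fraction: float = 0.25
    no_adapter_fraction: float = 0.02
    dimer_fraction: float = 0.01
    short_insert_fraction: float = 0.01
    error_rate: float = 0.0
    count_model: CountModel = field(default_factory=CountModel)
    read_length_weights: dict[int, float] = field(
        default_factory=default_length_weights)
    flank: int = 150
    min_reads: int = 20
    n_target_mirnas: int = 6
    transcript_length: int = 300
    verify_attempts: int = 40


@dataclass
class PlantedLocus:
    """One planted genomic locus with its intended downstream fate."""

    name: str
    kind: str                       # 'true' | 'decoy' | 'known'
    chrom: str
    start: int                      # 0-based half-open, forward genome
    end: int
    strand: str
    mature: str                     # 5'->3' on the locus strand
    star: str | None = None
    violated_rule: str | None = None
    fold_class: object = 1.0
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class PlantedTarget:
    """One planted target site on a synthetic transcript."""

    mirna: str                      # mature sequence
    mirna_name: str
    transcript_id: str
    offset: int                     # 0-based site start on the transcript
    pattern: str
    verdict: str                    # 'accept' | 'reject'
    cleavage_cut: int | None = None   # transcript coordinate of the cut


@dataclass
class GroundTruth:
    loci: list[PlantedLocus] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)
    conservation: dict[str, str] = field(default_factory=dict)
    ncRNA_read_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    read_class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def loci_of(self, kind: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.kind == kind]


@dataclass
class World:
    config: SimulationConfig
    genome: dict[str, str]
    annotation_rows: list[tuple]
    known_catalog: dict[str, str]
    conservation_catalogs: dict[str, tuple[dict[str, str], bool]]
    reads: dict[str, list[tuple[str, str]]]     # library -> [(id, seq)]
    transcripts: dict[str, str]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Serialise the fixture set; identical configs give identical bytes."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "genome.fa", self.genome.items())
        _write_fasta(out / "known_mature.fa", self.known_catalog.items())
        _write_fasta(out / "transcripts.fa", self.transcripts.items())
        (out / "catalogs").mkdir(exist_ok=True)
        legume_flags = {}
        for sp in sorted(self.conservation_catalogs):
            catalog, is_legume = self.conservation_catalogs[sp]
            _write_fasta(out / "catalogs" / f"{sp}.fa", catalog.items())
            legume_flags[sp] = is_legume
        (out / "catalogs" / "legume_flags.json").write_text(
            json.dumps(legume_flags, indent=1, sort_keys=True) + "\n")
        with open(out / "annotation.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.annotation_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        for lib in self.config.libraries:
            with open(out / f"reads_{lib}.fastq", "w") as fh:
                for rid, seq in self.reads[lib]:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        (out / "truth.json").write_text(
            json.dumps({
                "loci": [asdict(l) for l in self.truth.loci],
                "targets": [asdict(t) for t in self.truth.targets],
                "conservation": self.truth.conservation,
                "read_class_counts": self.truth.read_class_counts,
            }, indent=1, sort_keys=True) + "\n")


def _write_fasta(path: Path, items) -> None:
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def draw_count_pair(rng: np.random.Generator, mean: float, fold_class,
                    dispersion: float = 0.1, min_total: int = 0,
                    ) -> tuple[int, int]:
    """(NSN, SSN) counts for one miRNA under the planted fold class.

    One NB draw sets the lower-abundance library; the fold is applied
    exactly (rounded) to the other, so the planted ratio survives the
    sampling noise.  ``min_total`` clamps the base draw from below (used
    for loci whose downstream fate requires minimum read support).
    """
    base = max(_nb_draw(rng, mean, dispersion), min_total)
    if fold_class == "NSN_only":
        return base, 0
    if fold_class == "SSN_only":
        return 0, base
    f = float(fold_class)
    if f >= 1.0:
        return base, int(round(base * f))
    return int(round(base / f)), base


# ---------------------------------------------------------------------------
# hairpin construction


def _design_hairpin(rng: np.random.Generator, cfg: SimulationConfig,
                    rule: str | None) -> dict:
    """Backward construction of a precursor from a desired duplex.

    ``rule`` is None for a criterion-satisfying hairpin, or the single
    criterion the decoy must violate.  Returns the precursor pieces and the
    mature/star intervals relative to the precursor.
    """
    L = cfg.mature_length
    loop_len = int(rng.integers(cfg.loop_range[0], cfg.loop_range[1] + 1))
    arm = "5p" if rng.random() >= 0.5 else "3p"

    if rule == discovery.RULE_ARM:
        # mature overlaps the terminal loop of an otherwise clean hairpin
        stem = _random_seq(rng, 25)
        loop = "A" * loop_len
        right = "".join(COMPLEMENT[b] for b in reversed(stem))
        precursor = stem + loop + right
        m_start = 25 - max(4, L - loop_len - 4)
        mature = precursor[m_start:m_start + L]
        return {"precursor": precursor, "mature": mature,
                "mature_rel": (m_start, m_start + L), "star": None,
                "arm": "spanning"}

    mature = _random_seq(rng, L)
    n_mm = 0
    if rule == discovery.RULE_MISMATCH:
        n_mm = 5
    elif rule is None and rng.random() < 0.5:
        n_mm = 1
    mm_pos: list[int] = []
    if n_mm:
        # mismatches are planted as A:A oppositions inside a CAG/GAC context:
        # neither the A:A pair nor any +-1/+-2 register slide can pair, so
        # the maximising folder keeps the mismatch where it was designed
        mm_pos = sorted(int(x) for x in rng.choice(
            np.array([3, 6, 9, 12, 15]), size=n_mm, replace=False))
        chars = list(mature)
        for p in mm_pos:
            motif = "CAG" if rng.random() < 0.5 else "GAC"
            chars[p - 1:p + 2] = motif
        mature = "".join(chars)
    ext = _random_seq(rng, int(rng.integers(8, 13)))   # stem beyond the duplex
    loop = "A" * loop_len
    # one arm is mature+extension (the extension loop-proximal); the other is
    # its full reverse complement, edited to plant mismatches or bulges, so
    # the mature's last two bases pair just outside the 2-nt-shifted star --
    # the excised duplex has canonical 2-nt 3' overhangs by construction
    if arm == "5p":
        arm_seg = mature + ext           # mature 5'-terminal in the precursor
    else:
        arm_seg = ext + mature           # mature 3'-terminal in the precursor
    comp = [COMPLEMENT[b] for b in reversed(arm_seg)]

    def comp_index(p: int) -> int:
        """Index in ``comp`` pairing mature position p (0-based)."""
        seg_pos = p if arm == "5p" else len(ext) + p
        return len(arm_seg) - 1 - seg_pos

    for p in mm_pos:
        comp[comp_index(p)] = "A"          # A:A opposition to mature[p]
    if rule == discovery.RULE_BULGE:
        at = int(rng.integers(6, L - 8))
        ins = NON_PAIRING[mature[at]] * 2
        k = comp_index(at)
        comp = comp[:k] + list(ins) + comp[k:]
    comp_seq = "".join(comp)

    if arm == "5p":
        # dangling star 3'-overhang bases must not tie with the designed
        # partners of the mature's first bases
        cands = [b for b in "CGA"
                 if pair_weight(b, mature[0]) == 0
                 and pair_weight(b, mature[1]) == 0]
        tail = (cands[0] if cands else "A") * 2
        precursor = arm_seg + loop + comp_seq + tail
        m_rel = (0, L)
        star = precursor[-L:]
    else:
        precursor = comp_seq + loop + arm_seg
        m_rel = (len(precursor) - L, len(precursor))
        star = precursor[2:2 + L]
    return {"precursor": precursor, "mature": mature, "mature_rel": m_rel,
            "star": star, "arm": arm}


# ---------------------------------------------------------------------------
# world assembly


def _window_verdict(genome: str, locus_start: int, locus_end: int,
                    mature_abs: tuple[int, int], strand: str,
                    cfg: SimulationConfig) -> str | None:
    """Structural verdict for a planted locus: None = accepted, else rule."""
    th = NovelThresholds(min_reads=cfg.min_reads)
    n = len(genome)
    ms, me = mature_abs
    best: discovery.CriteriaReport | None = None
    for ws, we in ((ms - cfg.flank, me + 20), (ms - 20, me + cfg.flank)):
        ws, we = max(0, ws), min(n, we)
        seq = genome[ws:we]
        if strand == "+":
            m = (ms - ws, me - ws)
        else:
            seq = reverse_complement(seq)
            m = (we - me, we - ms)
        report, _, _ = evaluate_window(seq, m, th)
        if report.accepted:
            return None
        if best is None or report.progress > best.progress:
            best = report
    return best.failed if best else discovery.RULE_ARM


def generate_world(config: SimulationConfig) -> World:
    """Build the full fixture world; see the module docstring.

    Raises
    ------
    ValueError
        If the planted loci cannot be packed into the genome (the genome
        must be at least 10x the total planted span) or a planted locus
        cannot be made to reproduce its intended verdict.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"

    # --- design hairpin loci -------------------------------------------------
    designs: list[tuple[str, str | None, dict]] = []   # (name, rule, design)
    for i in range(cfg.n_true_hairpins):
        designs.append((f"gly_nov{i + 1}", None,
                        _design_hairpin(rng, cfg, None)))
    for rule in DECOY_RULES:
        for j in range(cfg.n_decoys_per_rule):
            label = rule.replace(" ", "_").replace("'", "").replace(">", "gt")
            structural = None if rule == discovery.RULE_READS else rule
            designs.append((f"decoy_{label}_{j + 1}", rule,
                            _design_hairpin(rng, cfg, structural)))

    slot_width = max((len(d["precursor"]) for _, _, d in designs), default=80) + 6
    slot_pitch = slot_width + 2 * (cfg.flank + 30)

    known_names = [f"gma-miR{1500 + i}" for i in range(cfg.n_known_mirnas)]
    known_matures = {}
    for name in known_names:
        seq = _random_seq(rng, cfg.mature_length)
        while seq[-1] == "T":
            seq = _random_seq(rng, cfg.mature_length)
        known_matures[name] = seq

    nc_classes = [("rRNA", 0.50), ("tRNA", 0.20), ("snoRNA", 0.10),
                  ("snRNA", 0.10), ("exon", 0.10)]
    nc_interval_len = 160

    hairpin_zone = 300 + len(designs) * slot_pitch
    known_zone = hairpin_zone + cfg.n_known_mirnas * 60
    nc_zone = known_zone + len(nc_classes) * (nc_interval_len + 60)
    required = nc_zone + 500
    planted_span = (sum(len(d["precursor"]) for _, _, d in designs)
                    + cfg.n_known_mirnas * cfg.mature_length
                    + len(nc_classes) * nc_interval_len)
    if cfg.genome_length < 10 * planted_span:
        raise ValueError(f"genome_length {cfg.genome_length} < 10x planted "
                         f"span {planted_span}")
    if required > cfg.genome_length:
        raise ValueError(f"cannot pack loci: need {required} nt, genome is "
                         f"{cfg.genome_length} nt")

    genome_arr = list(_random_seq(rng, cfg.genome_length))
    planted_mask = np.zeros(cfg.genome_length, dtype=bool)
    truth = GroundTruth()
    annotation_rows: list[tuple] = []

    def plant(seq: str, start: int) -> None:
        genome_arr[start:start + len(seq)] = list(seq)
        planted_mask[start:start + len(seq)] = True

    # hairpin loci: fixed pitch keeps every discovery window private
    loci_meta = []
    for idx, (name, rule, design) in enumerate(designs):
        start = 300 + idx * slot_pitch
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        loci_meta.append({"name": name, "rule": rule, "design": design,
                          "start": start, "strand": strand})

    for meta in loci_meta:
        design = meta["design"]
        pre = design["precursor"]
        placed = pre if meta["strand"] == "+" else reverse_complement(pre)
        plant(placed, meta["start"])

    # verify every planted hairpin reproduces its intended verdict,
    # resampling flanks (then redesigning the locus) until it does
    genome = "".join(genome_arr)
    for meta in loci_meta:
        intended = (None if meta["rule"] in (None, discovery.RULE_READS)
                    else meta["rule"])
        for attempt in range(cfg.verify_attempts):
            design = meta["design"]
            pre = design["precursor"]
            start = meta["start"]
            mrs, mre = design["mature_rel"]
            if meta["strand"] == "+":
                mature_abs = (start + mrs, start + mre)
            else:
                mature_abs = (start + len(pre) - mre, start + len(pre) - mrs)
            verdict = _window_verdict(genome, start, start + len(pre),
                                      mature_abs, meta["strand"], cfg)
            if verdict == intended:
                break
            if attempt >= cfg.verify_attempts // 2:
                structural = (None if meta["rule"] in (None, discovery.RULE_READS)
                              else meta["rule"])
                meta["design"] = _design_hairpin(rng, cfg, structural)
                design = meta["design"]
                pre = design["precursor"]
            # resample the locus slot and its private flanks
            lo = max(0, start - cfg.flank - 25)
            hi = min(cfg.genome_length, start + slot_width + cfg.flank + 25)
            genome_arr[lo:hi] = list(_random_seq(rng, hi - lo))
            placed = (pre if meta["strand"] == "+"
                      else reverse_complement(pre))
            genome_arr[start:start + len(pre)] = list(placed)
            genome = "".join(genome_arr)
        else:
            raise ValueError(f"could not realise planted locus {meta['name']}")

    # record hairpin loci and counts
    cm = cfg.count_model
    low_read_i = 0
    for i, meta in enumerate(loci_meta):
        design = meta["design"]
        pre = design["precursor"]
        start = meta["start"]
        kind = "true" if meta["rule"] is None else "decoy"
        if meta["rule"] == discovery.RULE_READS:
            total = int(rng.integers(5, cfg.min_reads))
            nsn = int(rng.integers(0, total + 1))
            counts = {"NSN": nsn, "SSN": total - nsn}
            fold_class = "low"
            low_read_i += 1
        elif kind == "decoy":
            base = max(_nb_draw(rng, cm.mean_decoy, cm.dispersion),
                       cfg.min_reads + 5)
            counts = {"NSN": base, "SSN": base}
            fold_class = 1.0
        else:
            fold_class = cm.fold_classes[i % len(cm.fold_classes)]
            nsn, ssn = draw_count_pair(rng, cm.mean_novel, fold_class,
                                       cm.dispersion,
                                       min_total=cfg.min_reads + 5)
            counts = {"NSN": nsn, "SSN": ssn}
        counts = {cfg.libraries[0]: counts["NSN"],
                  cfg.libraries[1]: counts["SSN"]}
        truth.loci.append(PlantedLocus(
            name=meta["name"], kind=kind, chrom=chrom, start=start,
            end=start + len(pre), strand=meta["strand"],
            mature=design["mature"], star=design["star"],
            violated_rule=meta["rule"], fold_class=fold_class, counts=counts))

    # known-miRNA loci
    for i, name in enumerate(known_names):
        start = hairpin_zone + i * 60
        seq = known_matures[name]
        plant(seq, start)
        fold_class = cm.fold_classes[i % len(cm.fold_classes)]
        nsn, ssn = draw_count_pair(rng, cm.mean_known, fold_class,
                                   cm.dispersion, min_total=1)
        truth.loci.append(PlantedLocus(
            name=name, kind="known", chrom=chrom, start=start,
            end=start + len(seq), strand="+", mature=seq,
            fold_class=fold_class,
            counts={cfg.libraries[0]: nsn, cfg.libraries[1]: ssn}))
        annotation_rows.append((chrom, "mirnod_sim", "miRNA", start + 1,
                                start + len(seq), ".", "+", ".", f"ID={name}"))

    genome = "".join(genome_arr)

    # ncRNA / mRNA contaminant intervals
    nc_intervals: dict[str, tuple[int, int]] = {}
    for i, (nc_class, _) in enumerate(nc_classes):
        start = known_zone + i * (nc_interval_len + 60)
        nc_intervals[nc_class] = (start, start + nc_interval_len)
        planted_mask[start:start + nc_interval_len] = True
        annotation_rows.append((chrom, "mirnod_sim", nc_class, start + 1,
                                start + nc_interval_len, ".", "+", ".",
                                f"ID={nc_class}_1"))

    # --- reads ---------------------------------------------------------------
    lengths = np.array(sorted(cfg.read_length_weights))
    weights = np.array([cfg.read_length_weights[int(l)] for l in lengths])
    weights = weights / weights.sum()

    free = [(s, e) for s, e in _free_intervals(planted_mask) if e - s >= 60]
    free_len = np.array([e - s for s, e in free], dtype=float)
    free_p = free_len / free_len.sum()

    def random_insert(length: int) -> str:
        block = free[int(rng.choice(len(free), p=free_p))]
        pos = int(rng.integers(block[0], block[1] - length + 1))
        return genome[pos:pos + length]

    def nc_insert(nc_class: str, length: int) -> str:
        s, e = nc_intervals[nc_class]
        pos = int(rng.integers(s, e - length + 1))
        return genome[pos:pos + length]

    def finish_read(insert: str) -> str:
        if cfg.error_rate > 0:
            chars = list(insert)
            for k in range(len(chars)):
                if rng.random() < cfg.error_rate:
                    chars[k] = str(rng.choice(BASES))
            insert = "".join(chars)
        return (insert + cfg.adapter)[:cfg.read_length]

    reads: dict[str, list[tuple[str, str]]] = {lib: [] for lib in cfg.libraries}
    class_counts: dict[str, dict[str, int]] = {
        lib: {} for lib in cfg.libraries}

    def emit(lib: str, cls: str, seq: str) -> None:
        n = len(reads[lib])
        reads[lib].append((f"{cls}:{lib}:{n}", seq))
        class_counts[lib][cls] = class_counts[lib].get(cls, 0) + 1

    n_nc_total = int(round(cfg.ncRNA_fraction * cfg.total_reads))
    n_noad = int(round(cfg.no_adapter_fraction * cfg.total_reads))
    n_dimer = int(round(cfg.dimer_fraction * cfg.total_reads))
    n_short = int(round(cfg.short_insert_fraction * cfg.total_reads))

    for lib in cfg.libraries:
        planted_total = sum(l.counts[lib] for l in truth.loci)
        n_bg = (cfg.total_reads - planted_total - n_nc_total - n_noad
                - n_dimer - n_short)
        if n_bg < 0:
            raise ValueError("planted read counts exceed total_reads")
        for locus in truth.loci:
            read = finish_read(locus.mature)
            for _ in range(locus.counts[lib]):
                emit(lib, f"mir|{locus.name}", read)
        nc_alloc = _allocate(n_nc_total, [w for _, w in nc_classes])
        for (nc_class, _), n_cls in zip(nc_classes, nc_alloc):
            for _ in range(n_cls):
                length = int(rng.choice(lengths, p=weights))
                emit(lib, f"nc|{nc_class}", finish_read(nc_insert(nc_class,
                                                                  length)))
        for _ in range(n_noad):
            while True:
                seq = _random_seq(rng, cfg.read_length)
                if trim_adapter(seq, cfg.adapter)[0] is None:
                    break
            emit(lib, "noadapter", seq)
        for _ in range(n_dimer):
            emit(lib, "dimer", (cfg.adapter + cfg.adapter)[:cfg.read_length])
        for _ in range(n_short):
            emit(lib, "short", finish_read(random_insert(
                int(rng.integers(10, 18)))))
        for _ in range(n_bg):
            length = int(rng.choice(lengths, p=weights))
            emit(lib, "background", finish_read(random_insert(length)))
        assert len(reads[lib]) == cfg.total_reads

    truth.read_class_counts = class_counts

    # --- transcripts and target sites ---------------------------------------
    transcripts: dict[str, str] = {}
    tx_i = 0
    target_mirnas = [l for l in truth.loci if l.kind == "true"][:cfg.n_target_mirnas]
    for locus in target_mirnas:
        for pattern, mutations, verdict in TARGET_PATTERNS:
            tx_i += 1
            tx_id = f"TX{tx_i:04d}"
            seq, offset = _plant_site(rng, locus.mature, mutations,
                                      cfg.transcript_length)
            transcripts[tx_id] = seq
            cut = None
            if pattern == "perfect":
                cut = offset + len(locus.mature) - 10    # between pos 10|11
            truth.targets.append(PlantedTarget(
                mirna=locus.mature, mirna_name=locus.name, transcript_id=tx_id,
                offset=offset, pattern=pattern, verdict=verdict,
                cleavage_cut=cut))

    # --- conservation catalogs ----------------------------------------------
    species = [("ath", False), ("osa", False), ("mtr", True), ("pvu", True)]
    true_loci = truth.loci_of("true")
    n_cons = max(1, len(true_loci) // 3)
    n_leg = max(1, len(true_loci) // 4)
    catalogs: dict[str, tuple[dict[str, str], bool]] = {}
    intended: dict[str, str] = {}
    for i, locus in enumerate(true_loci):
        if i < n_cons:
            intended[locus.mature] = discovery.CONSERVED
        elif i < n_cons + n_leg:
            intended[locus.mature] = discovery.LEGUME
        else:
            intended[locus.mature] = discovery.SPECIES
    for attempt in range(cfg.verify_attempts):
        catalogs = {}
        for sp, is_legume in species:
            entries: dict[str, str] = {}
            k = 0
            for i, locus in enumerate(true_loci):
                copy_here = (intended[locus.mature] == discovery.CONSERVED
                             and sp in ("ath", "osa")) or \
                            (intended[locus.mature] == discovery.LEGUME
                             and sp in ("mtr", "pvu"))
                if copy_here:
                    k += 1
                    variant = _end_variant(rng, locus.mature)
                    entries[f"{sp}-miR{9000 + i}"] = variant
            for j in range(8):    # filler matures pad the search space
                entries[f"{sp}-miR{9500 + j}"] = _random_seq(
                    rng, cfg.mature_length)
            catalogs[sp] = (entries, is_legume)
        observed = {
            m: _conservation_of(m, catalogs) for m in intended}
        if observed == intended:
            break
    else:
        raise ValueError("could not realise planted conservation classes")
    truth.conservation = intended

    world = World(config=cfg, genome={chrom: genome},
                  annotation_rows=sorted(annotation_rows,
                                         key=lambda r: (r[0], r[3], r[2])),
                  known_catalog=known_matures,
                  conservation_catalogs=catalogs, reads=reads,
                  transcripts=transcripts, truth=truth)
    return world


def _conservation_of(mature: str,
                     catalogs: dict[str, tuple[dict[str, str], bool]]) -> str:
    hit_nl = any(discovery.hits_catalog(mature, cat)
                 for sp, (cat, leg) in catalogs.items() if not leg)
    hit_l = any(discovery.hits_catalog(mature, cat)
                for sp, (cat, leg) in catalogs.items() if leg)
    return (discovery.CONSERVED if hit_nl
            else discovery.LEGUME if hit_l else discovery.SPECIES)


def _end_variant(rng: np.random.Generator, mature: str) -> str:
    """A cross-species copy: up to 2 nt of end trimming/extension."""
    mode = int(rng.integers(0, 3))
    if mode == 0:
        return mature
    if mode == 1:
        return mature[1:]
    return mature + str(rng.choice(BASES))


def _allocate(total: int, weights: list[float]) -> list[int]:
    """Deterministic integer allocation of ``total`` by ``weights``."""
    w = np.array(weights, dtype=float)
    w = w / w.sum()
    alloc = np.floor(w * total).astype(int)
    rest = total - alloc.sum()
    order = np.argsort(-(w * total - alloc), kind="stable")
    for i in range(int(rest)):
        alloc[order[i % len(alloc)]] += 1
    return [int(x) for x in alloc]


def _free_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    free = ~mask
    out = []
    start = None
    for i, f in enumerate(free):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def _plant_site(rng: np.random.Generator, mature: str, mutations: dict,
                tx_len: int) -> tuple[str, int]:
    """Transcript with one planted site for ``mature`` at a random offset.

    The site is the reverse complement of the mature with per-position
    edits: ``mismatch`` plants a full (non-wobble) mismatch at the given
    1-based miRNA position, ``wobble`` a G:U pair where constructible.
    """
    L = len(mature)
    site = list(reverse_complement(mature))
    for pos, kind in mutations.items():
        m_base = mature[pos - 1]
        idx = L - pos                   # transcript index within the site
        if kind == "mismatch":
            site[idx] = TARGET_MISMATCH[m_base]
        elif kind == "wobble":
            if m_base == "G":
                site[idx] = "T"
            elif m_base == "T":
                site[idx] = "G"
            # other bases cannot wobble; leave Watson-Crick
    site_seq = "".join(site)
    offset = int(rng.integers(40, tx_len - L - 40))
    tx = _random_seq(rng, tx_len)
    tx = tx[:offset] + site_seq + tx[offset + L:]
    return tx, offset


# ---------------------------------------------------------------------------
# read simulation helpers exposed separately


def simulate_race_reads(transcript: str, site_start: int, site_end: int,
                        cut: int, n_reads: int, noise_fraction: float = 0.0,
                        read_length: int = 40,
                        rng: np.random.Generator | None = None,
                        ) -> list[tuple[str, str]]:
    """RACE-style reads: 5' ends of the cleaved transcript's 3' fragment.

    Every signal read starts exactly at ``cut``; a ``noise_fraction`` of
    reads starts at a nearby non-cut position.  The cut must lie within the
    site span.
    """
    if not (site_start <= cut <= site_end):
        raise ValueError(f"cleavage position {cut} outside site "
                         f"[{site_start}, {site_end}]")
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n_reads):
        start = cut
        if noise_fraction > 0 and rng.random() < noise_fraction:
            while start == cut:
                start = cut + int(rng.integers(-15, 16))
            start = min(max(start, 0), len(transcript) - 15)
        seq = transcript[start:start + read_length]
        out.append((f"race_{i}:{start}", seq))
    return out
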