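"""End-to-end orchestration: reads in, report bundle out.

Runs the whole analysis — cleaning, perfect-match genome placement,
annotation subtraction, known/novel miRNA calling, family grouping,
conservation classing, RPM expression categories, target scanning and
optional RACE cleavage validation — from a single config, writing a
deterministic plain-text report bundle (TSV + JSON, sorted rows, no
timestamps) plus a run manifest with every threshold echoed and input
checksums.  Two runs on the same inputs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from Bio import SeqIO

from . import __version__
from . import annotate as annotate_mod
from . import discovery, expression, genome_map, preprocess, targets
from .discovery import MiRNACall, NovelThresholds


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    Library labels default to the two nodule conditions (NSN = non-stressed,
    SSN = salt-stressed); the first label is the control in fold changes.
    """

    genome: str = ""
    annotation: str = ""
    known_catalog: str = ""
    libraries: dict[str, str] = field(default_factory=dict)
    transcripts: str | None = None
    catalogs_dir: str | None = None         # per-species conservation FASTAs
    adapter: str | None = "TCGTATGCCGTCTTCTGCTTG"
    min_len: int = 18
    max_len: int = 30
    min_overlap: int = 6
    map_min: int = 20
    map_max: int = 24
    index_k: int = 18
    flank: int = 150
    max_duplex_mismatch: int = 4
    max_bulge: int = 1
    min_reads: int = 20
    fold_threshold: float = 2.0
    max_e: float = 3.5
    conservation_e: float = 10.0
    seed: int = 0
    control: str = "NSN"
    treated: str = "SSN"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @classmethod
    def for_world_dir(cls, world_dir: str | Path, **overrides) -> "PipelineConfig":
        """Config pointing at a directory written by ``World.write``."""
        d = Path(world_dir)
        libs = {p.stem.split("reads_")[1]: str(p)
                for p in sorted(d.glob("reads_*.fastq"))}
        cfg = cls(genome=str(d / "genome.fa"),
                  annotation=str(d / "annotation.gff3"),
                  known_catalog=str(d / "known_mature.fa"),
                  libraries=libs,
                  transcripts=str(d / "transcripts.fa")
                  if (d / "transcripts.fa").exists() else None,
                  catalogs_dir=str(d / "catalogs")
                  if (d / "catalogs").exists() else None)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


class PipelineError(RuntimeError):
    """A stage failure: carries the stage name and reason."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


@dataclass
class PipelineResult:
    tags: list
    cleaning_stats: dict
    hits: dict
    skipped: dict
    labels: dict
    known_calls: list[MiRNACall]
    novel_calls: list[MiRNACall]
    rejections: dict
    records: list
    summary: dict
    conservation: dict
    target_sites: list
    cleavage: list
    ledger: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_conservation_catalogs(catalogs_dir: str | Path,
                               ) -> dict[str, tuple[dict[str, str], bool]]:
    d = Path(catalogs_dir)
    flags = json.loads((d / "legume_flags.json").read_text()) \
        if (d / "legume_flags.json").exists() else {}
    out = {}
    for fa in sorted(d.glob("*.fa")):
        out[fa.stem] = (discovery.load_catalog(fa), bool(flags.get(fa.stem)))
    return out


def run(config: PipelineConfig, outdir: str | Path | None = None,
        ) -> PipelineResult:
    """Execute all stages; write the report bundle when ``outdir`` is given."""
    cfg = config
    ledger: dict = {"thresholds": {k: v for k, v in asdict(cfg).items()
                                   if not isinstance(v, dict)}}

    # --- load inputs
    try:
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(cfg.genome, "fasta")}
        annotation = annotate_mod.Annotation.from_gff3(
            cfg.annotation, genome_chroms=set(genome))
        catalog = discovery.load_catalog(cfg.known_catalog)
    except Exception as exc:           # noqa: BLE001 - stage boundary
        raise PipelineError("load_inputs", str(exc)) from exc

    libraries = sorted(cfg.libraries)

    # --- clean + collapse
    tags, stats = preprocess.clean_fastq_libraries(
        {lib: cfg.libraries[lib] for lib in libraries}, cfg.adapter,
        cfg.min_overlap, cfg.min_len, cfg.max_len)
    clean_totals = {lib: stats[lib].n_kept for lib in libraries}
    for lib in libraries:
        if not stats[lib].conserved():
            raise PipelineError("clean", f"read accounting broken in {lib}")
    ledger["clean"] = {lib: stats[lib].as_dict() for lib in libraries}

    # --- map
    index = genome_map.build_index(genome, k=min(cfg.index_k, cfg.map_min))
    hits, skipped = genome_map.map_tags(tags, index, cfg.map_min, cfg.map_max)
    ledger["map"] = {
        "tags_total": len(tags),
        "tags_mapped": len(hits),
        "tags_skipped_length": len(skipped),
        "tags_unmapped": len(tags) - len(hits) - len(skipped)}

    # --- annotate
    labels, protected = annotate_mod.classify_tags(hits, annotation)
    summary_df = annotate_mod.class_summary(tags, labels, libraries)
    unannotated = [t for t in tags
                   if labels.get(t.sequence) == annotate_mod.UNANNOTATED]
    ledger["annotate"] = {
        "unannotated_tags": len(unannotated),
        "mirna_protected_tags": len(protected)}

    # --- known calls (known-before-novel precedence)
    known_calls: dict[str, MiRNACall] = {}
    still_unknown: list = []
    for tag in unannotated:
        match = discovery.match_known(tag.sequence, catalog)
        if match is None:
            still_unknown.append(tag)
            continue
        name, family = match
        if name in known_calls:
            call = known_calls[name]
            call.read_support += tag.total_count
            for lib, c in tag.count_by_library.items():
                call.count_by_library[lib] = call.count_by_library.get(lib, 0) + c
        else:
            known_calls[name] = MiRNACall(
                id=name, mature=catalog[name], provenance="known",
                read_support=tag.total_count,
                count_by_library=dict(tag.count_by_library), family=family)

    # --- novel calls
    thresholds = NovelThresholds(min_reads=cfg.min_reads,
                                 max_duplex_mismatches=cfg.max_duplex_mismatch,
                                 max_bulge=cfg.max_bulge)
    novel_calls: list[MiRNACall] = []
    rejections: dict[str, discovery.CriteriaReport] = {}
    for tag in still_unknown:
        result = discovery.call_novel(tag, hits[tag.sequence], genome,
                                      cfg.flank, thresholds)
        if isinstance(result, MiRNACall):
            novel_calls.append(result)
        else:
            rejections[tag.sequence] = result[1]
    novel_calls.sort(key=lambda c: (-c.read_support, c.mature))
    for i, call in enumerate(novel_calls):
        call.id = f"nov_{i + 1:03d}"
    ledger["discover"] = {"known": len(known_calls), "novel": len(novel_calls),
                          "rejected": len(rejections)}

    # --- families
    all_calls = sorted(known_calls.values(), key=lambda c: c.id) + novel_calls
    discovery.assign_families(novel_calls, prefix="novFAM")

    # --- expression
    counts = {c.id: dict(c.count_by_library) for c in all_calls}
    provenance = {c.id: c.provenance for c in all_calls}
    records, dropped = expression.build_records(
        counts, clean_totals, cfg.control, cfg.treated,
        cfg.fold_threshold, provenance=provenance)
    summary = expression.summarize(records)
    ledger["express"] = {"records": len(records), "dropped": len(dropped),
                         **summary["categories"]}

    # --- conservation
    conservation: dict[str, str] = {}
    if cfg.catalogs_dir:
        catalogs = load_conservation_catalogs(cfg.catalogs_dir)
        by_mature = discovery.classify_conservation(
            novel_calls, catalogs, max_evalue=cfg.conservation_e)
        conservation = {c.id: by_mature[discovery.normalize_seq(c.mature)]
                        for c in novel_calls}

    # --- targets
    target_sites: list = []
    if cfg.transcripts:
        txs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(cfg.transcripts, "fasta")}
        for call in all_calls:
            for tx_id in sorted(txs):
                target_sites.extend(targets.scan_transcript(
                    call.mature, txs[tx_id], cfg.max_e,
                    mirna_id=call.id, transcript_id=tx_id))
        ledger["target"] = {"sites": len(target_sites)}

    result = PipelineResult(
        tags=tags, cleaning_stats=ledger["clean"], hits=hits, skipped=skipped,
        labels=labels, known_calls=sorted(known_calls.values(),
                                          key=lambda c: c.id),
        novel_calls=novel_calls, rejections=rejections, records=records,
        summary=summary, conservation=conservation,
        target_sites=target_sites, cleavage=[], ledger=ledger)

    if outdir is not None:
        _write_bundle(result, summary_df, cfg, libraries, Path(outdir))
    return result


def _write_bundle(res: PipelineResult, class_df, cfg: PipelineConfig,
                  libraries: list[str], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    preprocess.write_tag_table(res.tags, libraries, out / "tag_table.tsv")
    genome_map.write_alignment_table(res.hits, out / "alignments.tsv")
    class_df.to_csv(out / "class_summary.tsv", sep="\t", index=False)

    with open(out / "mirna_calls.tsv", "w") as fh:
        fh.write("id\tprovenance\tmature\tstar\tfamily\tchrom\tstart\tend\t"
                 "strand\tread_support\n")
        for c in res.known_calls + res.novel_calls:
            pre = c.precursor or ("", "", "", "")
            fh.write(f"{c.id}\t{c.provenance}\t{c.mature_rna}\t"
                     f"{(c.star or '').replace('T', 'U')}\t{c.family or ''}\t"
                     f"{pre[0]}\t{pre[1]}\t{pre[2]}\t{pre[3]}\t"
                     f"{c.read_support}\n")

    with open(out / "rejections.tsv", "w") as fh:
        fh.write("tag\treason\n")
        for seq in sorted(res.rejections):
            fh.write(f"{seq}\t{res.rejections[seq].failed}\n")

    expression.to_frame(res.records, libraries).to_csv(
        out / "expression.tsv", sep="\t", index=False)
    (out / "expression_summary.json").write_text(
        json.dumps(res.summary, indent=1, sort_keys=True) + "\n")

    with open(out / "conservation.tsv", "w") as fh:
        fh.write("id\tclass\n")
        for mid in sorted(res.conservation):
            fh.write(f"{mid}\t{res.conservation[mid]}\n")

    with open(out / "target_sites.tsv", "w") as fh:
        fh.write("mirna\ttranscript\tstart\tend\texpectation\tpenalties\n")
        for s in sorted(res.target_sites,
                        key=lambda s: (s.mirna_id, s.transcript_id, s.start)):
            pens = ",".join(f"{p:g}" for p in s.penalties)
            fh.write(f"{s.mirna_id}\t{s.transcript_id}\t{s.start}\t{s.end}\t"
                     f"{s.expectation:g}\t{pens}\n")

    inputs = {"genome": cfg.genome, "annotation": cfg.annotation,
              "known_catalog": cfg.known_catalog,
              **{f"reads_{l}": p for l, p in sorted(cfg.libraries.items())}}
    if cfg.transcripts:
        inputs["transcripts"] = cfg.transcripts
    manifest = {"version": __version__,
                "thresholds": res.ledger["thresholds"],
                "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
                "stages": {k: v for k, v in res.ledger.items()
                           if k != "thresholds"}}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
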