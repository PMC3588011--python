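"""Generate a ground-truthed synthetic small-RNA world.

Builds a genome with planted pre-miRNA hairpins (plus single-rule decoys),
known-miRNA loci, ncRNA contaminant intervals, and two read libraries with
planted salt-response fold changes, then prints what was planted.  Every
downstream example starts from a world like this one.
"""

from collections import Counter

from mirnod import SimulationConfig, generate_world

config = SimulationConfig(seed=7)
world = generate_world(config)

truth = world.truth
print(f"genome: {len(world.genome['chr1']):,} nt, "
      f"{config.total_reads:,} reads per library")
print(f"planted loci: {len(truth.loci_of('true'))} true hairpins, "
      f"{len(truth.loci_of('decoy'))} decoys, "
      f"{len(truth.loci_of('known'))} known miRNAs")
print("decoy rules:", dict(Counter(l.violated_rule
                                   for l in truth.loci_of('decoy'))))
print("fold classes:", dict(Counter(str(l.fold_class)
                                    for l in truth.loci if l.kind != 'decoy')))
example = truth.loci_of("true")[0]
print(f"\nfirst planted hairpin {example.name}: "
      f"{example.chrom}:{example.start}-{example.end} ({example.strand})")
print("mature:", example.mature.replace("T", "U"))
print("counts:", example.counts, "-> planted fold", example.fold_class)
# The printed counts are the per-library read numbers the simulator wrote
# into the FASTQ files; the fold class is the planted SSN/NSN ratio.
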