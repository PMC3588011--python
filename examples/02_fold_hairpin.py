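"""Fold a pre-miRNA candidate and judge the mature::star duplex.

Folds a planted precursor with the weighted maximum-pairing DP, prints the
dot-bracket structure, locates the mature on a hairpin arm and reports the
duplex statistics the novel-miRNA criteria consume.
"""

from Bio.Seq import reverse_complement

from mirnod import SimulationConfig, arm_of, duplex_stats, fold, generate_world

world = generate_world(SimulationConfig(seed=7))
locus = world.truth.loci_of("true")[0]
pre = world.genome[locus.chrom][locus.start:locus.end]
if locus.strand == "-":
    pre = reverse_complement(pre)

structure = fold(pre)
m0 = pre.find(locus.mature)
mature = (m0, m0 + len(locus.mature))

print(structure.to_vienna(locus.name), end="")
print("mature interval:", mature, "->", arm_of(structure, mature))
stats = duplex_stats(structure, mature)
print(f"duplex: {stats.n_mismatches} mismatches, bulges {stats.bulge_sizes}, "
      f"3' overhang {stats.overhang_3p} nt")
# A call requires: mature fully in one arm, <= 4 duplex mismatches, every
# bulge < 2 nt, and the ~2-nt 3' overhang left by staggered Dicer cuts.
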