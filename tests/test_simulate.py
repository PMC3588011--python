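"""Synthetic-world generator: determinism, ground-truth bookkeeping."""

import numpy as np
import pytest

from mirnod.simulate import (SimulationConfig, draw_count_pair,
                             generate_world)


def test_same_seed_byte_identical(tmp_path, world7):
    """Regeneration with the same config reproduces identical bytes."""
    w2 = generate_world(SimulationConfig(seed=7))
    d1, d2 = tmp_path / "a", tmp_path / "b"
    world7.write(d1)
    w2.write(d2)
    files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel


def test_zero_hairpins_world():
    cfg = SimulationConfig(seed=1, n_true_hairpins=0, n_decoys_per_rule=0,
                           n_known_mirnas=2, total_reads=2000,
                           genome_length=20_000, n_target_mirnas=0)
    w = generate_world(cfg)
    assert w.truth.loci_of("true") == [] and w.truth.loci_of("decoy") == []


def test_infeasible_packing_raises():
    with pytest.raises(ValueError):
        generate_world(SimulationConfig(seed=1, genome_length=3_000))


def test_read_totals_exact(world7):
    for lib in world7.config.libraries:
        assert len(world7.reads[lib]) == world7.config.total_reads


def test_every_read_attributed_to_one_class(world7):
    for lib in world7.config.libraries:
        assert sum(world7.truth.read_class_counts[lib].values()) == \
            world7.config.total_reads


def test_library_exclusive_mirnas_have_zero_reads(world7):
    nsn, ssn = world7.config.libraries
    seen = 0
    for locus in world7.truth.loci:
        if locus.fold_class == "SSN_only":
            assert locus.counts[nsn] == 0 and locus.counts[ssn] > 0
            seen += 1
        elif locus.fold_class == "NSN_only":
            assert locus.counts[ssn] == 0 and locus.counts[nsn] > 0
            seen += 1
    assert seen >= 4


def test_fold_classes_cover_required_spectrum(world7):
    fcs = {l.fold_class for l in world7.truth.loci if l.kind != "decoy"}
    assert {4.0, 2.0, 1.5, 0.5, 0.25, "NSN_only", "SSN_only"} <= fcs


def test_decoys_labelled_one_rule_each(world7):
    from collections import Counter
    rules = Counter(l.violated_rule for l in world7.truth.loci_of("decoy"))
    assert all(n == world7.config.n_decoys_per_rule for n in rules.values())
    assert len(rules) == 4


def test_planted_fold_ratio_near_target(world7):
    """A planted fold of 4 shows a ~4x read-count ratio by direct tally."""
    nsn, ssn = world7.config.libraries
    for locus in world7.truth.loci:
        if locus.fold_class == 4.0 and locus.kind == "known":
            ratio = locus.counts[ssn] / locus.counts[nsn]
            assert ratio == pytest.approx(4.0, abs=0.05)
            # and the FASTQ itself carries exactly the drawn counts
            for lib in (nsn, ssn):
                n = sum(1 for rid, _ in world7.reads[lib]
                        if rid.startswith(f"mir|{locus.name}:"))
                assert n == locus.counts[lib]
            break
    else:
        pytest.fail("no known locus with fold 4")


def test_draw_count_pair_fold_applied_exactly():
    rng = np.random.default_rng(0)
    nsn, ssn = draw_count_pair(rng, 500, 2.0)
    assert ssn == 2 * nsn
    nsn, ssn = draw_count_pair(rng, 500, 0.25)
    assert nsn == 4 * ssn
    assert draw_count_pair(rng, 500, "NSN_only")[1] == 0


def test_reads_carry_adapter_suffix(world7):
    cfg = world7.config
    lib = cfg.libraries[0]
    mir_reads = [seq for rid, seq in world7.reads[lib]
                 if rid.startswith("mir|")]
    read = mir_reads[0]
    insert_len = cfg.read_length - len(read.lstrip())  # no-op, length fixed
    assert len(read) == cfg.read_length
    # the read is insert + adapter truncated at the machine read length
    assert any(read.endswith(cfg.adapter[:k])
               for k in range(5, len(cfg.adapter)))


def test_world_dir_layout(world7_dir):
    for name in ("genome.fa", "annotation.gff3", "known_mature.fa",
                 "transcripts.fa", "truth.json", "reads_NSN.fastq",
                 "reads_SSN.fastq", "catalogs/legume_flags.json"):
        assert (world7_dir / name).exists(), name
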