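"""Read cleaning: adapter trimming, length filter, collapsing, conservation."""

import pytest

from mirnod import preprocess as pp


ADAPTER = "TCGTATGCCGTCTTCTGCTTG"


def brute_force_trim(read: str, adapter: str, min_overlap: int):
    """Independent oracle: leftmost full match, else longest terminal
    adapter prefix of >= min_overlap nt, by naive substring scan."""
    for pos in range(len(read)):
        if read[pos:pos + len(adapter)] == adapter and \
                pos + len(adapter) <= len(read):
            return read[:pos] or None
    for k in range(len(adapter) - 1, min_overlap - 1, -1):
        if len(read) >= k and read[-k:] == adapter[:k]:
            return read[:-k] or None
    return None


class TestTrimAdapter:
    def test_full_adapter(self):
        insert = "ACGTACGTACGTACGTACGTA"
        assert pp.trim_adapter(insert + ADAPTER, ADAPTER)[0] == insert

    def test_no_adapter_rejected(self):
        seq, reason = pp.trim_adapter("ACGT" * 9, ADAPTER, min_overlap=6)
        assert seq is None
        assert reason == pp.NO_ADAPTER

    def test_partial_adapter_at_read_end(self):
        insert = "GTCAGTCAGTCAGTCAGTCAG"
        read = insert + ADAPTER[:5]
        assert pp.trim_adapter(read, ADAPTER, min_overlap=5)[0] == insert
        assert pp.trim_adapter(read, ADAPTER, min_overlap=6)[0] is None

    def test_adapter_dimer_rejected(self):
        seq, reason = pp.trim_adapter(ADAPTER + ADAPTER[:10], ADAPTER)
        assert seq is None
        assert reason == pp.EMPTY_INSERT

    def test_empty_read(self):
        assert pp.trim_adapter("", ADAPTER)[1] == pp.NO_ADAPTER

    def test_empty_adapter_raises(self):
        with pytest.raises(ValueError):
            pp.trim_adapter("ACGT", "")

    def test_matches_brute_force_oracle(self, rng):
        from conftest import random_seq
        for _ in range(300):
            n = int(rng.integers(10, 40))
            read = random_seq(rng, n)
            if rng.random() < 0.5:   # plant an adapter suffix
                keep = int(rng.integers(5, min(n, 22)))
                read = read[:n - keep] + ADAPTER[:keep]
            got, _ = pp.trim_adapter(read, ADAPTER, 6)
            assert got == brute_force_trim(read, ADAPTER, 6)


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [
        (17, False), (18, True), (21, True), (30, True), (31, False)])
    def test_inclusive_bounds(self, length, kept):
        tag = pp.SmallRNATag("A" * length, {"NSN": 3})
        result, removed = pp.filter_by_length([tag])
        assert (len(result) == 1) is kept
        if not kept:
            assert sum(removed.values()) == 3   # read-level accounting


class TestCollapse:
    def test_identical_reads_collapse(self):
        tags = pp.collapse({"NSN": ["ACGTACGTACGTACGTACGTA"] * 3})
        assert len(tags) == 1
        assert tags[0].count_by_library == {"NSN": 3}

    def test_shared_sequence_across_libraries(self):
        seq = "ACGTACGTACGTACGTACGTA"
        tags = pp.collapse({"NSN": [seq, seq], "SSN": [seq]})
        assert len(tags) == 1
        assert tags[0].count_by_library == {"NSN": 2, "SSN": 1}

    def test_u_normalised_to_t(self):
        tags = pp.collapse({"NSN": ["ACGU", "ACGT"]})
        assert len(tags) == 1
        assert tags[0].total_count == 2


class TestCleanLibrary:
    def test_conservation_and_idempotence(self, rng):
        from conftest import random_seq
        reads = [random_seq(rng, int(rng.integers(14, 34))) + ADAPTER
                 for _ in range(200)]
        clean, stats = pp.clean_library(reads, "NSN", ADAPTER)
        assert stats.conserved()
        assert stats.n_input == 200
        # idempotence: cleaning the already-clean inserts changes nothing
        again, stats2 = pp.clean_library(clean, "NSN", adapter=None)
        assert again == clean
        assert stats2.n_kept == len(clean)

    def test_ambiguous_base_removed(self):
        clean, stats = pp.clean_library(["ACGTNACGTACGTACGTACGT"], "x", None)
        assert clean == []
        assert stats.removed_by_reason[pp.AMBIGUOUS] == 1


def test_simulated_library_counts_conserved(world7):
    """Collapsed tag counts reproduce the simulator's per-class tallies."""
    cfg = world7.config
    lib = cfg.libraries[0]
    reads = [seq for _, seq in world7.reads[lib]]
    clean, stats = pp.clean_library(reads, lib, cfg.adapter)
    assert stats.conserved()
    assert stats.n_input == cfg.total_reads
    # every planted miRNA read survives cleaning with its exact insert
    tags = pp.collapse({lib: clean})
    by_seq = {t.sequence: t.count(lib) for t in tags}
    for locus in world7.truth.loci:
        want = locus.counts[lib]
        if want:
            assert by_seq.get(locus.mature, 0) >= want
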