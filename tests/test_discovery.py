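"""miRNA calling: known matches, novel criteria, families, conservation."""

import numpy as np
import pytest

from mirnod import discovery as D
from mirnod.discovery import (NovelThresholds, assign_families,
                              classify_conservation, evaluate_window,
                              hits_catalog, match_known, MiRNACall,
                              extract_precursor_windows, smith_waterman_score)
from mirnod.genome_map import GenomeAlignment
from mirnod.simulate import SimulationConfig, _design_hairpin

from conftest import random_seq


class TestMatchKnown:
    CATALOG = {"gma-miR166a": "TCGGACCAGGCTTCATTCCCC",
               "gma-miR393i": "TCCAAAGGGATCGCATTGATC"}

    def test_exact_match(self):
        assert match_known("TCGGACCAGGCTTCATTCCCC", self.CATALOG) == \
            ("gma-miR166a", "miR166")

    def test_internal_substitution_no_match(self):
        assert match_known("TCGGACCAGGCATCATTCCCC", self.CATALOG) is None

    def test_end_trim_within_tolerance(self):
        assert match_known("CGGACCAGGCTTCATTCCCC", self.CATALOG) is not None
        assert match_known("GGACCAGGCTTCATTCCC", self.CATALOG) is None  # -3 nt

    def test_u_t_normalisation(self):
        assert match_known("UCGGACCAGGCUUCAUUCCCC", self.CATALOG) is not None

    def test_planted_known_set_recovered(self, world7, pipeline7):
        res, _ = pipeline7
        called = {c.id for c in res.known_calls}
        assert called == set(world7.known_catalog)


class TestPrecursorWindows:
    def test_two_windows_mid_chromosome(self, rng):
        genome = {"c": random_seq(rng, 2000)}
        a = GenomeAlignment("t", "c", 1000, 1021, "+")
        wins = extract_precursor_windows(a, genome, flank=150)
        assert len(wins) == 2
        (s1, span1, m1), (s2, span2, m2) = wins
        assert span1 == (850, 1041) and span2 == (980, 1171)
        for seq, span, m in wins:
            assert seq[m[0]:m[1]] == genome["c"][1000:1021]

    def test_clipped_at_chromosome_start(self, rng):
        genome = {"c": random_seq(rng, 500)}
        a = GenomeAlignment("t", "c", 5, 26, "+")
        wins = extract_precursor_windows(a, genome, flank=150)
        assert wins and wins[0][1][0] == 0

    def test_minus_strand_window_contains_mature(self, rng):
        from Bio.Seq import reverse_complement
        genome = {"c": random_seq(rng, 1000)}
        a = GenomeAlignment("t", "c", 400, 421, "-")
        for seq, span, m in extract_precursor_windows(a, genome, 100):
            assert seq[m[0]:m[1]] == reverse_complement(genome["c"][400:421])

    def test_planted_precursor_inside_a_window(self, world7):
        genome = world7.genome
        for locus in world7.truth.loci_of("true")[:6]:
            a = GenomeAlignment(locus.mature, locus.chrom, 0, 0, locus.strand)
            # mature absolute coordinates from the recorded locus
            pre = genome[locus.chrom][locus.start:locus.end]
            from Bio.Seq import reverse_complement
            fwd = pre if locus.strand == "+" else reverse_complement(pre)
            m0 = fwd.find(locus.mature)
            if locus.strand == "+":
                start = locus.start + m0
            else:
                start = locus.end - m0 - len(locus.mature)
            a = GenomeAlignment(locus.mature, locus.chrom, start,
                                start + len(locus.mature), locus.strand)
            wins = extract_precursor_windows(a, genome, 150)
            assert any(fwd in seq for seq, _, _ in wins)


class TestNovelCriteria:
    def test_rejection_reasons_match_planted_decoys(self, world7, pipeline7):
        res, _ = pipeline7
        for locus in world7.truth.loci_of("decoy"):
            report = res.rejections[locus.mature]
            assert report.failed == locus.violated_rule, locus.name

    def test_all_true_hairpins_called(self, world7, pipeline7):
        res, _ = pipeline7
        called = {c.mature for c in res.novel_calls}
        assert {l.mature for l in world7.truth.loci_of("true")} <= called

    def test_known_never_also_novel(self, pipeline7):
        res, _ = pipeline7
        known = {c.mature for c in res.known_calls}
        novel = {c.mature for c in res.novel_calls}
        assert not (known & novel)

    def test_accepted_reports_show_all_rules_passing(self, pipeline7):
        res, _ = pipeline7
        for call in res.novel_calls:
            assert call.report is not None and call.report.accepted
            assert all(ok for ok, _ in call.report.checks.values())

    def test_criteria_monotonic_in_thresholds(self, world7):
        """Tightening mismatch or read thresholds never adds a call."""
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(seed=1)
        loose = NovelThresholds(max_duplex_mismatches=4)
        tight = NovelThresholds(max_duplex_mismatches=2)
        added = 0
        for _ in range(25):
            d = _design_hairpin(rng, cfg, None)
            rl, _, _ = evaluate_window(d["precursor"], d["mature_rel"], loose)
            rt, _, _ = evaluate_window(d["precursor"], d["mature_rel"], tight)
            if rt.accepted and not rl.accepted:
                added += 1
        assert added == 0

    def test_low_abundance_rejected_without_structure(self, world7):
        from mirnod.discovery import call_novel
        from mirnod.preprocess import SmallRNATag
        tag = SmallRNATag("ACGT" * 5 + "A", {"NSN": 10, "SSN": 9})
        result = call_novel(tag, [], world7.genome)
        assert result[0] is None
        assert result[1].failed == D.RULE_READS


class TestFamilies:
    def brute_force_families(self, seqs, max_edit=3):
        """Pairwise closure with a naive DP edit distance (oracle)."""
        def edit(a, b):
            m, n = len(a), len(b)
            dp = list(range(n + 1))
            for i in range(1, m + 1):
                prev, dp[0] = dp[0], i
                for j in range(1, n + 1):
                    cur = min(dp[j] + 1, dp[j - 1] + 1,
                              prev + (a[i - 1] != b[j - 1]))
                    prev, dp[j] = dp[j], cur
            return dp[n]

        groups = {s: {s} for s in seqs}
        for a in seqs:
            for b in seqs:
                if a < b and a[1:8] == b[1:8] and edit(a, b) <= max_edit:
                    merged = groups[a] | groups[b]
                    for s in merged:
                        groups[s] = merged
        return {frozenset(g) for g in groups.values()}

    def test_identical_matures_share_family(self):
        calls = [MiRNACall(id=str(i), mature="ACGTACGTACGTACGTACGTA",
                           provenance="novel", read_support=30)
                 for i in range(2)]
        fam = assign_families(calls)
        assert len(set(fam.values())) == 1

    def test_position_one_difference_same_family(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = "TCGTACGTACGTACGTACGTA"
        calls = [MiRNACall(id="a", mature=a, provenance="novel", read_support=1),
                 MiRNACall(id="b", mature=b, provenance="novel", read_support=1)]
        fam = assign_families(calls)
        assert fam[a] == fam[b]

    def test_designed_families_recovered(self, rng):
        """30 matures in 10 designed families match the brute-force closure."""
        seqs = []
        for _ in range(10):
            base = random_seq(rng, 21)
            seqs.append(base)
            for _ in range(2):
                var = list(base)
                # vary outside the seed (positions 2-8 -> indices 1..7)
                for p in rng.choice([0, 9, 12, 15, 18, 20], size=2,
                                    replace=False):
                    var[int(p)] = "ACGT"[int(rng.integers(0, 4))]
                seqs.append("".join(var))
        calls = [MiRNACall(id=str(i), mature=s, provenance="novel",
                           read_support=1) for i, s in enumerate(seqs)]
        fam = assign_families(calls)
        got = {}
        for s, f in fam.items():
            got.setdefault(f, set()).add(s)
        assert {frozenset(g) for g in got.values()} == \
            self.brute_force_families(sorted(set(seqs)))


class TestConservation:
    def sw_oracle(self, a, b):
        """Exhaustive local-alignment DP, written independently."""
        best = 0
        H = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
        for i in range(1, len(a) + 1):
            for j in range(1, len(b) + 1):
                H[i][j] = max(0,
                              H[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1]
                                                 else -3),
                              H[i - 1][j] - 5, H[i][j - 1] - 5)
                best = max(best, H[i][j])
        return best

    def test_sw_matches_oracle(self, rng):
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(15, 25)))
            b = random_seq(rng, int(rng.integers(15, 60)))
            assert smith_waterman_score(a, b) == self.sw_oracle(a, b)

    def test_verbatim_copy_is_conserved(self):
        mature = "TCGGACCAGGCTTCATTCCCC"
        calls = [MiRNACall(id="x", mature=mature, provenance="novel",
                           read_support=1)]
        catalogs = {"ath": ({"ath-miR1": mature}, False)}
        assert classify_conservation(calls, catalogs)[mature] == D.CONSERVED

    def test_no_match_is_species_specific(self, rng):
        mature = random_seq(rng, 21)
        calls = [MiRNACall(id="x", mature=mature, provenance="novel",
                           read_support=1)]
        catalogs = {"ath": ({"ath-miR1": random_seq(rng, 21)}, False)}
        assert classify_conservation(calls, catalogs)[mature] == D.SPECIES

    def test_empty_catalogs_all_species_specific(self, rng):
        mature = random_seq(rng, 21)
        calls = [MiRNACall(id="x", mature=mature, provenance="novel",
                           read_support=1)]
        assert classify_conservation(calls, {})[mature] == D.SPECIES

    def test_legume_only_copy_is_legume_specific(self):
        mature = "TCGGACCAGGCTTCATTCCCC"
        calls = [MiRNACall(id="x", mature=mature, provenance="novel",
                           read_support=1)]
        catalogs = {"mtr": ({"mtr-miR1": mature}, True),
                    "ath": ({"ath-miR1": "GGGGGGGGGGGGGGGGGGGGG"}, False)}
        assert classify_conservation(calls, catalogs)[mature] == D.LEGUME

    def test_planted_three_way_classing(self, world7, pipeline7):
        res, _ = pipeline7
        by_id = {c.id: c.mature for c in res.novel_calls}
        for cid, got in res.conservation.items():
            assert got == world7.truth.conservation[by_id[cid]]
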