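"""Hairpin folding, locus evaluation, novelty, families, clusters."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

from stressmir import mirna_discovery as md
from stressmir._util import can_pair, revcomp


# ---------------------------------------------------------------------------
# independent oracle: exhaustive maximum matching over nested structures


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration of nested structures (for short windows)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                best = max(best, rec(i, k - 1) + 1 + rec(k + 1, j - 1)) if k > i else max(
                    best, 1 + rec(k + 1, j - 1)
                )
        return best

    return rec(0, len(seq) - 1) if seq else 0


class TestFoldHairpin:
    def test_simple_stem(self):
        cand = md.fold_hairpin("GGGAAACCC")
        assert cand.max_pairs == 3
        assert cand.pairing == [(0, 8), (1, 7), (2, 6)]

    def test_unpairable(self):
        assert md.fold_hairpin("AAAAAAAAA").max_pairs == 0

    def test_min_loop_respected(self):
        cand = md.fold_hairpin("GGGAAACCC")
        for i, j in cand.pairing:
            assert j - i > 3

    def test_perfect_planted_hairpin_fully_paired(self):
        mature = "ACGGATGCCATGCAACGGATC"
        hairpin = mature + "TTTTTTTTCTTTTTT" + revcomp(mature)
        cand = md.fold_hairpin(hairpin)
        partner = cand.partner_map()
        assert all(i in partner for i in range(len(mature)))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.text("ACGU", min_size=1, max_size=12))
    def test_matches_exhaustive_enumeration(self, seq):
        assert md.fold_hairpin(seq).max_pairs == brute_force_max_pairs(
            seq.replace("U", "T")
        )

    def test_pairing_is_nested(self):
        cand = md.fold_hairpin("GCGCGCAAAGCGCGCTTTGGCC" * 3)
        pairs = sorted(cand.pairing)
        for a in pairs:
            for b in pairs:
                if a[0] < b[0]:
                    assert b[1] < a[1] or a[1] < b[0]  # nested or disjoint

    def test_window_cap(self):
        with pytest.raises(ValueError):
            md.fold_hairpin("A" * 401)


class TestEvaluateLocus:
    MATURE = "ACGGATGCCATGCAACGGATC"
    LOOP = "TCTAGAAAGCTTCAG"

    def hairpin_window(self, mismatches=0):
        arm = list(revcomp(self.MATURE))
        for k in range(mismatches):
            pos = 5 + 3 * k
            arm[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm[pos]]
        return self.MATURE + self.LOOP + "".join(arm) + "GT"

    def test_perfect_duplex_star_geometry(self):
        window = self.hairpin_window()
        cand = md.fold_hairpin(window)
        locus = md.evaluate_locus(self.MATURE, cand, 0)
        assert locus is not None
        L = len(self.MATURE)
        start = L + len(self.LOOP) + 2
        assert locus.star == window[start : start + L]
        assert locus.arm == "5p"

    def test_mature_spanning_loop_rejected(self):
        window = self.hairpin_window()
        # offset the "mature" so it straddles arm and loop
        read = window[12 : 12 + 21]
        cand = md.fold_hairpin(window)
        assert md.evaluate_locus(read, cand, 12) is None

    def test_underpaired_mature_rejected(self):
        # mature against a window with no complementary arm
        window = self.MATURE + "T" * 40
        cand = md.fold_hairpin(window)
        assert md.evaluate_locus(self.MATURE, cand, 0) is None

    def test_paired_fraction_boundary(self):
        window = self.hairpin_window()
        cand = md.fold_hairpin(window)
        # demanding more pairing than exists must reject
        assert md.evaluate_locus(self.MATURE, cand, 0, min_paired_frac=1.01) is None


class TestCandidateReads:
    def make(self, counts, category="unannotated", matched=True):
        r = md.CollapsedRead("ACGT" * 5 + "A", dict(counts))
        r.category = category
        r.matched_reference["A"] = matched
        return r

    def test_threshold_boundary(self):
        low = self.make({"c": 2, "d": 2, "s": 2})
        edge = self.make({"c": 0, "d": 0, "s": 3})
        assert md.candidate_reads([low, edge]) == [edge]

    def test_contaminants_and_unmatched_excluded(self):
        trna = self.make({"c": 99}, category="tRNA")
        unmatched = self.make({"c": 99}, matched=False)
        assert md.candidate_reads([trna, unmatched]) == []


class TestCallNovel:
    def locus(self, mature, counts, star_counts):
        cand = md.HairpinCandidate("c1", 1, len(mature), mature, [], 0)
        return md.MiRNALocus(
            "x", mature, "T" * 21, "5p", cand, (1, 21),
            counts=counts, star_counts=star_counts,
        )

    CATALOG = {"mir-a": "ACGTACGTACGTACGTACGTA"}

    def test_conserved_kept_without_star(self):
        l = self.locus(self.CATALOG["mir-a"], {"c": 5}, {"c": 0})
        kept = md.call_novel([l], self.CATALOG)
        assert kept == [l] and not l.novel

    def test_unsupported_novel_dropped(self):
        l = self.locus("TTGCATGCAATGCATCGGATC", {"c": 5}, {"c": 0})
        assert md.call_novel([l], self.CATALOG) == []

    def test_star_in_one_library_suffices(self):
        l = self.locus("TTGCATGCAATGCATCGGATC", {"c": 0, "s": 2}, {"c": 0, "s": 1})
        kept = md.call_novel([l], self.CATALOG)
        assert kept == [l] and l.novel

    def test_same_library_flag(self):
        l = self.locus("TTGCATGCAATGCATCGGATC", {"c": 5, "s": 0}, {"c": 0, "s": 1})
        assert md.call_novel([l], self.CATALOG, same_library=True) == []
        l2 = self.locus("TTGCATGCAATGCATCGGATC", {"c": 5, "s": 0}, {"c": 0, "s": 1})
        kept = md.call_novel([l2], self.CATALOG, same_library=False)
        assert kept and kept[0].novel


class TestDedupe:
    def locus(self, seq, contig="c1", start=1, count=10):
        cand = md.HairpinCandidate(contig, start, start + len(seq) - 1, seq, [], 0)
        return md.MiRNALocus("x", seq[:21], None, "5p", cand, (start, start + 20),
                             counts={"c": count})

    def test_identical_precursors_merge(self):
        seq = "ACGT" * 15
        a = self.locus(seq, start=1, count=10)
        b = self.locus(seq, contig="c2", start=500, count=3)
        survivors = md.dedupe_precursors([a, b])
        assert survivors == [a]

    def test_distant_precursors_kept(self):
        a = self.locus("ACGT" * 15)
        b = self.locus("AATTGGCCAATTGGCCAATTGGCCAATTGGCCAATTGGCCAATTGGCCAATTGGCCAAT",
                       contig="c2")
        assert len(md.dedupe_precursors([a, b])) == 2

    def test_idempotent(self, pipeline):
        once = md.dedupe_precursors(pipeline.loci)
        twice = md.dedupe_precursors(once)
        assert [l.mirna_id for l in once] == [l.mirna_id for l in twice]


class TestHomology:
    def test_embedded_and_boundary(self):
        pre = "ACGGATGCCATGCAACGGATCTCTAGAAAGCTTCAGGATCCGTT"
        cand = md.HairpinCandidate("c", 1, len(pre), pre, [], 0)
        locus = md.MiRNALocus("m1", pre[:21], None, "5p", cand, (1, 21))
        ref_exact = "TTTT" + pre + "GGGG"
        # 2 mutations in 44 nt -> 95.45% identity (>= 95, inclusive)
        mutated = list(pre)
        mutated[10] = "A" if mutated[10] != "A" else "C"
        mutated[30] = "A" if mutated[30] != "A" else "C"
        ref_close = "TTTT" + "".join(mutated) + "GGGG"
        # 5 mutations -> 88.6%
        for p in (3, 9, 15, 21, 33):
            mutated[p] = "A" if mutated[p] != "A" else "C"
        ref_far = "TTTT" + "".join(mutated) + "GGGG"
        assert md.cross_genome_homology([locus], [ref_exact])["m1"]
        assert md.cross_genome_homology([locus], [ref_close])["m1"]
        assert not md.cross_genome_homology([locus], [ref_far])["m1"]


class TestFamilies:
    def locus(self, mature, novel=True, hit=None):
        cand = md.HairpinCandidate("c", 1, 60, mature + "T" * 39, [], 0)
        l = md.MiRNALocus("x", mature, None, "5p", cand, (1, 21), novel=novel)
        l.known_hit = hit
        return l

    def test_single_linkage_families(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = a[:-2] + "GG"  # 2 mismatches from a
        c = "TTTTGGGGCCCCAAAATTTTG"  # unrelated
        loci = [self.locus(x) for x in (a, b, c)]
        md.assign_family(loci, {})
        assert loci[0].family == loci[1].family
        assert loci[2].family != loci[0].family

    def test_conserved_inherit_catalog_family(self):
        l = self.locus("ACGTACGTACGTACGTACGTA", novel=False, hit=("mir-9", 0))
        md.assign_family([l], {"mir-9": "miR156"})
        assert l.family == "miR156"

    def test_five_member_planted_family(self):
        base = "ACGTACGTACGTACGTACGTA"
        variants = [base]
        for k in range(1, 5):
            v = list(base)
            v[k] = "C" if v[k] != "C" else "G"
            variants.append("".join(v))
        loci = [self.locus(v) for v in variants]
        md.assign_family(loci, {})
        assert len({l.family for l in loci}) == 1

    def test_permutation_invariant_partition(self):
        seqs = ["ACGTACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGGG",
                "TTTTGGGGCCCCAAAATTTTG", "GATCGATCGATCGATCGATCG"]
        loci1 = [self.locus(s) for s in seqs]
        loci2 = [self.locus(s) for s in reversed(seqs)]
        md.assign_family(loci1, {})
        md.assign_family(loci2, {})
        part1 = {frozenset(l.mature for l in loci1 if l.family == f)
                 for f in {l.family for l in loci1}}
        part2 = {frozenset(l.mature for l in loci2 if l.family == f)
                 for f in {l.family for l in loci2}}
        assert part1 == part2


class TestClusters:
    def locus(self, contig, start):
        cand = md.HairpinCandidate(contig, start, start + 59, "A" * 60, [], 0)
        return md.MiRNALocus(f"{contig}:{start}", "A" * 21, None, "5p", cand,
                             (start, start + 20))

    def test_nearby_loci_cluster(self):
        a, b = self.locus("c1", 1000), self.locus("c1", 2000)
        clusters = md.find_clusters([a, b], cluster_distance=10_000)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_different_contigs_never_cluster(self):
        a, b = self.locus("c1", 1000), self.locus("c2", 1000)
        assert md.find_clusters([a, b], cluster_distance=10_000) == []

    def test_planted_three_locus_cluster_recovered(self):
        loci = [self.locus("c1", s) for s in (100, 1200, 2500)] + [
            self.locus("c1", 50_000)
        ]
        clusters = md.find_clusters(loci, cluster_distance=10_000)
        assert len(clusters) == 1
        assert [l.precursor.start for l in clusters[0].members] == [100, 1200, 2500]


class TestEndToEndRecovery:
    def test_planted_loci_recovered(self, pipeline):
        """Every planted locus is discovered with its exact star."""
        truth = pipeline.reference.truth
        by_mature = {l.mature: l for l in pipeline.loci}
        for planted in truth.mirna_loci:
            assert planted.mature in by_mature, planted.mirna_id
            assert by_mature[planted.mature].star == planted.star

    def test_planted_novel_called_novel(self, pipeline):
        """Novel miRNAs with >= 3 mature reads and a sequenced star are called."""
        truth = pipeline.reference.truth
        called = {l.mature for l in pipeline.loci if l.novel}
        for planted in truth.mirna_loci:
            if not planted.novel:
                continue
            supported = any(
                c.get("mature", 0) >= 3 and c.get("star", 0) >= 1
                for c in planted.realized_counts.values()
            )
            if supported:
                assert planted.mature in called, planted.mirna_id

    def test_no_contaminant_yields_a_locus(self, pipeline):
        contaminants = {
            r.sequence
            for r in pipeline.reads
            if r.category in md.CONTAMINANT_PRIORITY
        }
        assert all(l.mature not in contaminants for l in pipeline.loci)
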