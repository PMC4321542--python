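"""Generator contracts: determinism, planted structure, count conservation."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from stressmir import synthetic
from stressmir.config import SyntheticConfig, CONDITIONS
from stressmir.mirna_discovery import fold_hairpin
from stressmir._util import revcomp
from tests.conftest import small_config


class TestGenerateReference:
    def test_empty_plan(self):
        cfg = small_config(n_known_mirnas=0, n_novel_mirnas=0)
        ref = synthetic.generate_reference(cfg)
        assert ref.truth.mirna_loci == []
        assert len(ref.contigs) == cfg.n_contigs
        assert ref.known_catalog == {}

    def test_planted_hairpin_geometry(self, reference):
        """Arms reverse-complementary up to the planted mismatch budget."""
        for locus in reference.truth.mirna_loci:
            contig = reference.contigs[locus.contig]
            p0, p1 = locus.precursor_span
            precursor = contig[p0 - 1 : p1]
            L = len(locus.mature)
            assert precursor[:L] == locus.mature
            arm = precursor[-L:]
            mm = sum(a != b for a, b in zip(arm, revcomp(locus.mature)))
            assert mm <= 2
            loop = len(precursor) - 2 * L
            assert loop >= 8
            s0, s1 = locus.star_span
            assert contig[s0 - 1 : s1] == locus.star

    def test_perfect_precursor_fully_pairs_mature(self):
        cfg = small_config(precursor_mismatches=0, n_known_mirnas=3, n_novel_mirnas=1)
        ref = synthetic.generate_reference(cfg)
        locus = ref.truth.mirna_loci[0]
        contig = ref.contigs[locus.contig]
        p0, p1 = locus.precursor_span
        cand = fold_hairpin(contig[p0 - 1 : p1])
        partner = cand.partner_map()
        assert all(i in partner for i in range(len(locus.mature)))

    def test_deterministic_outputs(self):
        cfg = small_config(seed=7)
        a = synthetic.generate_reference(cfg)
        b = synthetic.generate_reference(small_config(seed=7))
        assert a.contigs == b.contigs
        assert a.known_catalog == b.known_catalog
        assert a.transcripts == b.transcripts

    def test_sizing_error_names_locus(self):
        cfg = small_config(n_contigs=1, contig_length=100, n_known_mirnas=5)
        with pytest.raises(ValueError, match="mir-"):
            synthetic.generate_reference(cfg)

    def test_cleavage_sites_inside_transcripts(self, reference):
        for c in reference.truth.cleavage_sites:
            t = reference.transcripts[c.transcript_id]
            assert 1 <= c.position <= len(t)
            s0, s1 = c.site_span
            mature = next(
                l.mature for l in reference.truth.mirna_loci if l.mirna_id == c.mirna_id
            )
            assert t[s0 - 1 : s1] == revcomp(mature)
            assert c.position == s1 - 9


class TestSimulateLibraries:
    def test_fastq_bytes_deterministic(self):
        cfg = small_config(seed=9)
        ref = synthetic.generate_reference(cfg)
        a = synthetic.simulate_libraries(cfg, ref)
        ref2 = synthetic.generate_reference(small_config(seed=9))
        b = synthetic.simulate_libraries(small_config(seed=9), ref2)
        assert a == b

    def test_expected_counts_sum_to_library_size(self, config, reference):
        from stressmir.synthetic import _source_table

        for cond in CONDITIONS:
            _labels, expected = _source_table(config, reference.truth, cond)
            assert expected.sum() == pytest.approx(config.library_sizes[cond])

    def test_zero_library_size_warns_and_empties(self):
        cfg = small_config(
            library_sizes={"control": 0, "drought": 5000, "salt": 5000}
        )
        ref = synthetic.generate_reference(cfg)
        with pytest.warns(UserWarning, match="library size 0"):
            libs = synthetic.simulate_libraries(cfg, ref)
        assert libs["control"] == []
        assert len(libs["drought"]) == 5000

    def test_null_plan_count_ratios_near_one(self):
        cfg = small_config(
            seed=42,
            planted_log2_fc={},
            library_sizes={"control": 100_000, "drought": 100_000, "salt": 100_000},
        )
        counts, _totals = synthetic.simulate_count_matrix(cfg)
        strong = counts[counts["control"] >= 200]
        ratios = strong["drought"] / strong["control"]
        assert np.all((ratios > 0.8) & (ratios < 1.25))

    def test_planted_truth_round_trip(self):
        """Error-free reads, once trimmed and collapsed, recover every
        planted mature that was actually sequenced."""
        from stressmir import read_processing as rp

        cfg = small_config(seed=3, sequencing_error_rate=0.0)
        ref = synthetic.generate_reference(cfg)
        libs = synthetic.simulate_libraries(cfg, ref)
        cleaned = {
            lib: rp.clean_reads(iter(records), adapter=cfg.adapter)[0]
            for lib, records in libs.items()
        }
        reads, _stats = rp.collapse(cleaned)
        seen = {r.sequence: r.counts for r in reads}
        for locus in ref.truth.mirna_loci:
            for cond, realized in locus.realized_counts.items():
                assert seen.get(locus.mature, {}).get(cond, 0) == realized["mature"]

    def test_contaminant_reads_are_catalog_substrings(self):
        cfg = small_config(seed=4, sequencing_error_rate=0.0)
        ref = synthetic.generate_reference(cfg)
        libs = synthetic.simulate_libraries(cfg, ref)
        from stressmir import read_processing as rp

        cleaned, _ = rp.clean_reads(iter(libs["control"]), adapter=cfg.adapter)
        texts = {
            cls: "\n".join(seqs) for cls, seqs in ref.contaminant_catalog.items()
        }
        planted = {l.mature for l in ref.truth.mirna_loci} | {
            l.star for l in ref.truth.mirna_loci
        } | set(ref.truth.background)
        contaminant_reads = [s for s in cleaned if s not in planted]
        hits = sum(
            any(s in t for t in texts.values()) for s in contaminant_reads
        )
        assert hits == len(contaminant_reads)


class TestSimulateDegradome:
    def test_signal_fraction_one_concentrates_tags(self):
        cfg = small_config(degradome_signal_fraction=1.0)
        ref = synthetic.generate_reference(cfg)
        profiles = synthetic.simulate_degradome(cfg, ref)
        sites = {c.transcript_id: c.position for c in ref.truth.cleavage_sites}
        for tid, pos in sites.items():
            counts = profiles[tid]
            assert counts[pos - 1] == counts.sum() == cfg.degradome_tags_per_transcript

    def test_decoys_uniformish(self, config, reference):
        profiles = synthetic.simulate_degradome(config, reference)
        decoys = [t for t in profiles if t.startswith("decoy")]
        assert decoys
        for t in decoys:
            assert profiles[t].max() < 0.5 * profiles[t].sum()


class TestSimulateCorpus:
    def test_empty_corpus(self):
        from stressmir.citation_rank import build_matrix, citation_rank, cluster_homologs

        cfg = small_config(corpus_n_documents=0)
        truth = synthetic.PlantedTruth()
        docs, sim = synthetic.simulate_corpus(cfg, truth)
        assert docs == []
        clusters = cluster_homologs([], sim, 0.5)
        res = citation_rank(build_matrix(docs, clusters))
        assert res.scores == {}

    def test_all_offtarget_filtered_away(self):
        from stressmir.citation_rank import filter_species

        cfg = small_config(corpus_offtarget_species_fraction=1.0)
        truth = synthetic.PlantedTruth()
        docs, _sim = synthetic.simulate_corpus(cfg, truth)
        plant_only = filter_species(docs, {"plant"})
        # the hub-coverage documents are pinned to plant species by design
        assert all(int(d.doc_id[3:]) <= cfg.corpus_n_gene_families - 1 for d in plant_only)

    def test_hub_co_occurs_with_every_cluster(self, config):
        truth = synthetic.PlantedTruth()
        docs, _sim = synthetic.simulate_corpus(config, truth)
        hub = truth.expected_top_gene
        clusters = set(truth.corpus_clusters.values()) - {hub}
        seen = set()
        for d in docs:
            mentioned = {truth.corpus_clusters[g] for g in d.genes}
            if hub in mentioned:
                seen |= mentioned - {hub}
        assert seen == clusters


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(planted_log2_fc={"mir-001": (2.0, 0.0)})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = SyntheticConfig.from_yaml(path)
        assert loaded == cfg

    @pytest.mark.parametrize(
        "overrides",
        [
            {"star_fraction": 1.5},
            {"adapter": ""},
            {"library_sizes": {"control": 10}},
            {"planted_log2_fc": {"m": (float("inf"), 0.0)}},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        cfg = small_config()
        for k, v in overrides.items():
            setattr(cfg, k, v)
        with pytest.raises(ValueError):
            cfg.validate()
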