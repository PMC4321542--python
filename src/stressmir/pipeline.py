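"""End-to-end convenience driver over the synthetic study design.

Chains the full analysis: simulate (or accept) three libraries, clean
and collapse, categorize, match references, discover miRNA loci, test
differential expression, predict and validate targets, and rank
literature gene clusters.  Each stage is available individually from
its own module; this driver wires the default study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import (
    differential_expression as de,
    mirna_discovery as md,
    read_processing as rp,
    synthetic,
    target_analysis as ta,
)
from .citation_rank import (
    RankResult,
    build_matrix,
    citation_rank,
    cluster_homologs,
    filter_species,
)
from .config import SyntheticConfig, CONDITIONS


@dataclass
class PipelineResult:
    config: SyntheticConfig
    reference: synthetic.SyntheticReference
    reads: list[rp.CollapsedRead]
    stats: dict[str, rp.LibraryStats]
    drop_log: dict[str, dict[str, int]]
    jaccard: dict[tuple[str, str], float]
    loci: list[md.MiRNALocus]
    clusters: list[md.MiRNACluster]
    counts: pd.DataFrame
    comparisons: pd.DataFrame
    venn: dict
    sites: list[ta.TargetSite]
    validations: list[ta.DegradomeValidation]
    rank: RankResult
    extras: dict[str, Any] = field(default_factory=dict)


def run_pipeline(config: SyntheticConfig) -> PipelineResult:
    """Simulate the study and run every stage on the synthetic data."""
    reference = synthetic.generate_reference(config)
    libraries = synthetic.simulate_libraries(config, reference)

    cleaned: dict[str, list[str]] = {}
    drop_log: dict[str, dict[str, int]] = {}
    for lib in CONDITIONS:
        records = ((rid, seq, qual) for rid, seq, qual in libraries[lib])
        cleaned[lib], drop_log[lib] = rp.clean_reads(records, adapter=config.adapter)

    reads, stats = rp.collapse(cleaned)
    rp.annotate_category(
        reads, reference.contaminant_catalog, reference.known_catalog
    )
    genome = rp.ReferenceSet("G", list(reference.contigs.values()), both_strands=True)
    est = rp.ReferenceSet("E/G", list(reference.transcripts.values()), both_strands=False)
    rp.match_reference(reads, [est, genome])

    lib_counts = {
        lib: {r.sequence: r.counts[lib] for r in reads if r.counts.get(lib, 0) > 0}
        for lib in CONDITIONS
    }
    jaccard = {}
    for i, a in enumerate(CONDITIONS):
        for b in CONDITIONS[i + 1 :]:
            jaccard[(a, b)] = rp.jaccard_top(lib_counts[a], lib_counts[b]).jaccard_percent

    loci = md.discover_loci(reads, reference.contigs)
    loci = md.call_novel(loci, reference.known_catalog)
    loci = md.dedupe_precursors(loci)
    md.assign_family(loci, reference.known_families)
    clusters = md.find_clusters(loci)

    counts = pd.DataFrame(
        {lib: {l.mirna_id: l.counts.get(lib, 0) for l in loci} for lib in CONDITIONS}
    ).fillna(0).astype(int)
    # name loci by their planted/known identity where recoverable
    totals = {lib: stats[lib].total_redundant for lib in CONDITIONS}
    comparisons = de.compare_all(counts, totals)
    venn = de.venn_partition(counts)

    mirna_seqs = {l.mirna_id: l.mature for l in loci}
    sites = ta.scan_targets(mirna_seqs, reference.transcripts)
    profiles = {
        tid: ta.DegradomeProfile(tid, arr)
        for tid, arr in synthetic.simulate_degradome(config, reference).items()
    }
    validations = [
        ta.validate_site(site, profiles[site.transcript_id])
        for site in sites
        if site.transcript_id in profiles
    ]

    documents, similarity = synthetic.simulate_corpus(config, reference.truth)
    plant_docs = filter_species(documents, {"plant"})
    genes = sorted({g for d in plant_docs for g in d.genes})
    gene_clusters = cluster_homologs(genes, similarity, threshold=0.5)
    matrix = build_matrix(plant_docs, gene_clusters)
    rank = citation_rank(matrix)

    return PipelineResult(
        config=config,
        reference=reference,
        reads=reads,
        stats=stats,
        drop_log=drop_log,
        jaccard=jaccard,
        loci=loci,
        clusters=clusters,
        counts=counts,
        comparisons=comparisons,
        venn=venn,
        sites=sites,
        validations=validations,
        rank=rank,
    )
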