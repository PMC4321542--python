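"""Simulate a three-condition small-RNA study with planted ground truth.

Builds reference contigs hosting hairpin precursors, catalogs, and three
FASTQ libraries (control / drought / salt) with planted per-condition
fold changes, then prints what was planted.
"""

from stressmir import SyntheticConfig, generate_reference, simulate_libraries

config = SyntheticConfig(
    seed=11,
    library_sizes={"control": 20_000, "drought": 20_000, "salt": 20_000},
    n_known_mirnas=6,
    n_novel_mirnas=2,
    n_contigs=8,
)
reference = generate_reference(config)
libraries = simulate_libraries(config, reference)

print(f"contigs: {len(reference.contigs)} x {config.contig_length} nt")
print(f"known-miRNA catalog: {len(reference.known_catalog)} entries")
for lib, reads in libraries.items():
    print(f"{lib}: {len(reads)} reads of {config.machine_read_length} nt")

print("\nplanted loci (id, condition fold changes, expected control reads):")
for locus in reference.truth.mirna_loci:
    fc_d, fc_s = locus.log2_fc
    print(
        f"  {locus.mirna_id:9s} {'novel' if locus.novel else 'known'}  "
        f"log2FC drought={fc_d:+.0f} salt={fc_s:+.0f}  "
        f"control expectation ~{locus.control_weight:.0f} reads"
    )
# Each locus is a hairpin embedded in a contig; reads for its mature (and,
# for most loci, its star) are drawn multinomially around these expectations.
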