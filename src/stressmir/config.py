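"""Configuration for the synthetic three-library study design.

The defaults emulate a desk-scale version of a three-condition
(control / drought / salt) small-RNA sequencing experiment: 18-30 nt
reads dominated by the 21 and 24 nt classes, a known-miRNA catalog,
planted novel hairpin loci with miRNA* strands, rRNA/tRNA/snRNA/snoRNA
contaminants, per-condition log2 fold changes, degradome tag libraries
peaked at cleavage sites, and a gene-document literature corpus with
homologous gene families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

CONDITIONS = ("control", "drought", "salt")

#: 3' sequencing adapter appended to every simulated insert (TruSeq small RNA).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Read-length weights over 18-30 nt, dominated by the 21/24 nt classes
#: as observed in plant small-RNA libraries.
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.30, 22: 0.08, 23: 0.06,
    24: 0.32, 25: 0.05, 26: 0.03, 27: 0.02, 28: 0.01, 29: 0.01, 30: 0.01,
}

#: Redundant-read fractions for the structural-RNA contaminant classes,
#: matching the magnitudes reported for plant seedling libraries
#: (rRNA a few percent, tRNA ~1%, snRNA/snoRNA trace).
DEFAULT_CONTAMINANT_FRACTIONS = {
    "rRNA": 0.066, "tRNA": 0.010, "snRNA": 0.0005, "snoRNA": 0.0002,
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic-data generator.

    Same seed => byte-identical outputs.  Counts must be positive and
    probabilities lie in [0, 1]; :meth:`validate` enforces this.
    """

    seed: int = 0

    # reference
    n_contigs: int = 30
    contig_length: int = 2000

    # miRNA plan
    n_known_mirnas: int = 24
    n_novel_mirnas: int = 8
    mature_length: int = 21
    loop_length: int = 15
    precursor_mismatches: int = 2
    star_fraction: float = 0.75
    #: resample a planted mature whose own base-pair-maximal fold exceeds
    #: this (real mature miRNAs are essentially unstructured)
    max_mature_self_pairs: int = 6
    mirna_read_fraction: float = 0.24
    star_relative_abundance: float = 0.15

    # contaminants: catalog entries per class and read fractions
    n_contaminants: dict[str, int] = field(
        default_factory=lambda: {"rRNA": 5, "tRNA": 5, "snRNA": 3, "snoRNA": 3}
    )
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_FRACTIONS)
    )

    # libraries
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 100_000, "drought": 100_000, "salt": 100_000}
    )
    #: miRNA id -> (drought, salt) log2 fold change vs control.  When None
    #: the generator assigns a deterministic plan: a quarter of the loci
    #: up in drought (+2), a quarter up in salt (+2), one in eight down in
    #: both (-2), the remainder null.
    planted_log2_fc: dict[str, tuple[float, float]] | None = None
    read_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    adapter: str = DEFAULT_ADAPTER
    machine_read_length: int = 36
    sequencing_error_rate: float = 0.001
    n_background: int = 400
    background_mappable_fraction: float = 0.45

    # degradome
    n_target_transcripts: int = 8
    n_decoy_transcripts: int = 4
    transcript_length: int = 500
    degradome_tags_per_transcript: int = 200
    degradome_signal_fraction: float = 0.8

    # literature corpus
    corpus_n_documents: int = 120
    corpus_n_gene_families: int = 12
    corpus_genes_per_family: int = 3
    corpus_offtarget_species_fraction: float = 0.2

    def validate(self) -> None:
        counts = {
            "n_contigs": self.n_contigs,
            "contig_length": self.contig_length,
            "n_known_mirnas": self.n_known_mirnas,
            "n_novel_mirnas": self.n_novel_mirnas,
            "mature_length": self.mature_length,
            "loop_length": self.loop_length,
            "corpus_n_gene_families": self.corpus_n_gene_families,
            "corpus_genes_per_family": self.corpus_genes_per_family,
        }
        for name, value in counts.items():
            if value < 0 or (value == 0 and name in ("n_contigs", "contig_length")):
                raise ValueError(f"{name} must be positive, got {value}")
        probs = {
            "star_fraction": self.star_fraction,
            "sequencing_error_rate": self.sequencing_error_rate,
            "degradome_signal_fraction": self.degradome_signal_fraction,
            "corpus_offtarget_species_fraction": self.corpus_offtarget_species_fraction,
            "background_mappable_fraction": self.background_mappable_fraction,
            "mirna_read_fraction": self.mirna_read_fraction,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.planted_log2_fc is not None:
            import math

            for mid, (fc_d, fc_s) in self.planted_log2_fc.items():
                if not (math.isfinite(fc_d) and math.isfinite(fc_s)):
                    raise ValueError(f"planted_log2_fc[{mid!r}] must be finite")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if set(self.library_sizes) != set(CONDITIONS):
            raise ValueError(f"library_sizes must have keys {CONDITIONS}")
        if any(w < 0 for w in self.read_length_distribution.values()):
            raise ValueError("read_length_distribution weights must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["planted_log2_fc"] is not None:
            data["planted_log2_fc"] = {
                k: list(v) for k, v in data["planted_log2_fc"].items()
            }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("planted_log2_fc"):
            data["planted_log2_fc"] = {
                k: tuple(v) for k, v in data["planted_log2_fc"].items()
            }
        if "read_length_distribution" in data:
            data["read_length_distribution"] = {
                int(k): float(v) for k, v in data["read_length_distribution"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg
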