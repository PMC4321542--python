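"""File I/O: FASTA/FASTQ/TSV readers and writers used across the pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .read_processing import CollapsedRead
from .target_analysis import DegradomeProfile


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_collapsed_fasta(
    reads: Sequence[CollapsedRead],
    path: str | Path,
    libraries: Sequence[str] = ("control", "drought", "salt"),
) -> None:
    """Collapsed reads as FASTA with per-library counts in the header:
    ``>seq{i}_x{control}_{drought}_{salt}``."""
    seqs = {}
    for i, r in enumerate(reads):
        counts = "_".join(str(r.counts.get(l, 0)) for l in libraries)
        seqs[f"seq{i + 1}_x{counts}"] = r.sequence
    write_fasta(seqs, path)


def write_degradome_tsv(profiles: Mapping[str, "np.ndarray"], path: str | Path) -> None:
    """Degradome tags as TSV: transcript_id, position_1based, count."""
    rows = []
    for tid in sorted(profiles):
        counts = profiles[tid]
        for pos in range(len(counts)):
            if counts[pos] > 0:
                rows.append((tid, pos + 1, int(counts[pos])))
    pd.DataFrame(rows, columns=["transcript_id", "position_1based", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_degradome_tsv(
    path: str | Path, transcript_lengths: Mapping[str, int]
) -> dict[str, DegradomeProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for tid, group in df.groupby("transcript_id"):
        profiles[str(tid)] = DegradomeProfile.from_table(
            str(tid),
            transcript_lengths[str(tid)],
            list(zip(group["position_1based"], group["count"])),
        )
    return profiles


def write_loci_gff3(loci, path: str | Path) -> None:
    """miRNA loci as GFF3 (1-based inclusive, type miRNA_primary_transcript
    for the precursor window and miRNA for the mature)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            pre = locus.precursor
            fh.write(
                f"{pre.contig}\tstressmir\tmiRNA_primary_transcript\t{pre.start}\t{pre.end}"
                f"\t.\t+\t.\tID={locus.mirna_id}\n"
            )
            m0, m1 = locus.mature_span
            fh.write(
                f"{pre.contig}\tstressmir\tmiRNA\t{m0}\t{m1}\t.\t+\t.\t"
                f"ID={locus.mirna_id}.mature;Parent={locus.mirna_id}\n"
            )


def write_corpus_tsv(documents, path: str | Path) -> None:
    rows = [(d.doc_id, d.species, ",".join(sorted(d.genes))) for d in documents]
    pd.DataFrame(rows, columns=["document_id", "species", "genes"]).to_csv(
        path, sep="\t", index=False
    )


def read_corpus_tsv(path: str | Path):
    from .citation_rank import Document

    df = pd.read_csv(path, sep="\t")
    return [
        Document(doc_id=str(r.document_id), species=str(r.species),
                 genes=set(str(r.genes).split(",")) if pd.notna(r.genes) else set())
        for r in df.itertuples()
    ]


def write_similarity_tsv(similarity: Mapping[tuple[str, str], float], path: str | Path) -> None:
    rows = [(a, b, s) for (a, b), s in sorted(similarity.items())]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"]).to_csv(
        path, sep="\t", index=False
    )


def read_similarity_tsv(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {(str(r.gene_a), str(r.gene_b)): float(r.similarity) for r in df.itertuples()}
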