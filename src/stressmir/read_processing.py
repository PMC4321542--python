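"""Small-RNA library processing: cleaning, collapsing, categorization.

Implements the front end of the pipeline: 3' adapter trimming with
quality/length filters, collapsing to unique reads with per-library
counts, exclusion of structural-RNA contaminants before known-miRNA
assignment, exact-substring reference matching, per-length size
distributions, and the top-N Jaccard similarity between libraries.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import revcomp

#: Contaminant classes in exclusion priority order (ties resolved
#: toward the earlier class).
CONTAMINANT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")

CATEGORIES = ("miRNA",) + CONTAMINANT_PRIORITY[:-1] + ("repeat", "unannotated")


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int]
    category: str = "unannotated"
    known_hit: tuple[str, int] | None = None  # (catalog id, mismatch distance)
    matched_reference: dict[str, bool] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def max_count(self) -> int:
        return max(self.counts.values())


@dataclass
class LibraryStats:
    """Unique/redundant totals and the per-length histogram of one library."""

    library: str
    total_redundant: int
    total_unique: int
    size_histogram: dict[int, tuple[int, int]]  # length -> (unique, redundant)


@dataclass
class SimilarityResult:
    jaccard_percent: float
    n_top: int


@dataclass
class ReferenceSet:
    """A FASTA reference; genome-style sets are searched on both strands."""

    name: str
    sequences: Sequence[str]
    both_strands: bool = False

    def __post_init__(self) -> None:
        text = "\n".join(s.upper().replace("U", "T") for s in self.sequences)
        self._text = text
        # newline separators are preserved by reverse-complementation
        self._rc_text = revcomp(text) if self.both_strands else ""

    def contains(self, read: str) -> bool:
        return read in self._text or (self.both_strands and read in self._rc_text)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# cleaning


def clean_reads(
    records: Iterable[tuple[str, str, str]] | str | Path,
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    quality_floor: int = 20,
    min_partial: int = 6,
) -> tuple[list[str], dict[str, int]]:
    """Trim the 3' adapter and filter reads; return kept inserts + drop log.

    The adapter is removed at its leftmost full occurrence, or at a
    terminal partial match of at least ``min_partial`` nt.  After
    trimming, reads outside ``[min_len, max_len]``, containing an N, or
    with any base below ``quality_floor`` (Phred+33) are dropped; the
    returned log counts drops by reason.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = _normalize(adapter)
    if isinstance(records, (str, Path)):
        records = read_fastq(records)

    kept: list[str] = []
    dropped: Counter[str] = Counter()
    for _id, seq, qual in records:
        seq = _normalize(seq)
        idx = seq.find(adapter)
        if idx >= 0:
            insert, q = seq[:idx], qual[:idx]
        else:
            k = _terminal_partial(seq, adapter, min_partial)
            if k:
                insert, q = seq[:-k], qual[:-k]
            else:
                insert, q = seq, qual
        if not min_len <= len(insert) <= max_len:
            dropped["length"] += 1
        elif "N" in insert:
            dropped["ambiguous_base"] += 1
        elif any(ord(c) - 33 < quality_floor for c in q):
            dropped["low_quality"] += 1
        else:
            kept.append(insert)
    return kept, dict(dropped)


def _terminal_partial(seq: str, adapter: str, min_partial: int) -> int:
    """Longest adapter prefix (>= min_partial) ending the read; 0 if none."""
    for k in range(min(len(adapter) - 1, len(seq)), min_partial - 1, -1):
        if seq.endswith(adapter[:k]):
            return k
    return 0


def read_fastq(path: str | Path):
    """Yield (id, sequence, quality) triples; report malformed records."""
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                record = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
            yield record
            index += 1


# ---------------------------------------------------------------------------
# collapsing


def collapse(
    libraries: Mapping[str, Sequence[str]],
) -> tuple[list[CollapsedRead], dict[str, LibraryStats]]:
    """Collapse cleaned libraries to unique reads with per-library counts."""
    lib_names = list(libraries)
    per_seq: dict[str, dict[str, int]] = defaultdict(lambda: {n: 0 for n in lib_names})
    for name, seqs in libraries.items():
        for seq in seqs:
            per_seq[_normalize(seq)][name] += 1

    reads = [CollapsedRead(seq, counts) for seq, counts in sorted(per_seq.items())]
    stats = {name: _library_stats(name, reads) for name in lib_names}
    return reads, stats


def _library_stats(name: str, reads: Sequence[CollapsedRead]) -> LibraryStats:
    hist: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    unique = redundant = 0
    for r in reads:
        c = r.counts.get(name, 0)
        if c > 0:
            unique += 1
            redundant += c
            hist[len(r.sequence)][0] += 1
            hist[len(r.sequence)][1] += c
    return LibraryStats(
        library=name,
        total_redundant=redundant,
        total_unique=unique,
        size_histogram={k: tuple(v) for k, v in sorted(hist.items())},
    )


# ---------------------------------------------------------------------------
# categorization


def assign_known(
    read: str,
    known_catalog: Mapping[str, str],
    max_mismatch: int = 3,
) -> tuple[str, int] | None:
    """Best known-miRNA hit within ``max_mismatch`` ungapped mismatches.

    Distance is the Hamming distance over the best ungapped offset
    alignment of the read against a catalog entry, with read positions
    hanging over either end counted as mismatches.  Ties break toward
    the lower distance, then the lexicographically smaller catalog id.
    Only offsets whose overhang alone cannot exceed the budget are
    scanned (an exhaustive scan gives identical results).
    """
    read = _normalize(read)
    n = len(read)
    best: tuple[int, str] | None = None
    for cid in sorted(known_catalog):
        entry = _normalize(known_catalog[cid])
        m = len(entry)
        # overhang = n - overlap; require overlap >= n - max_mismatch
        min_overlap = max(1, n - max_mismatch)
        for offset in range(-(n - min_overlap), m - min_overlap + 1):
            dist = 0
            overlap = 0
            for i in range(n):
                j = offset + i
                if 0 <= j < m:
                    overlap += 1
                    if read[i] != entry[j]:
                        dist += 1
                        if dist > max_mismatch:
                            break
            else:
                dist += n - overlap
                if dist <= max_mismatch and (best is None or (dist, cid) < best):
                    best = (dist, cid)
    if best is None:
        return None
    return best[1], best[0]


def annotate_category(
    reads: Iterable[CollapsedRead],
    contaminant_catalog: Mapping[str, Sequence[str]],
    known_mirna_catalog: Mapping[str, str],
    max_mismatch: int = 3,
) -> None:
    """Assign each read one category, excluding contaminants first.

    A read exactly contained in any contaminant entry takes that class
    (priority rRNA > tRNA > snRNA > snoRNA > repeat); remaining reads
    within ``max_mismatch`` of a known miRNA are miRNA; the rest are
    unannotated.  Contaminant exclusion always precedes miRNA
    assignment, so no read carries both labels.
    """
    texts = {
        cls: "\n".join(_normalize(s) for s in contaminant_catalog.get(cls, ()))
        for cls in CONTAMINANT_PRIORITY
    }
    for read in reads:
        seq = read.sequence
        for cls in CONTAMINANT_PRIORITY:
            if texts[cls] and seq in texts[cls]:
                read.category = cls
                break
        else:
            hit = assign_known(seq, known_mirna_catalog, max_mismatch)
            if hit is not None:
                read.category = "miRNA"
                read.known_hit = hit
            else:
                read.category = "unannotated"


# ---------------------------------------------------------------------------
# reference matching & summaries


def match_reference(
    reads: Iterable[CollapsedRead],
    reference_sets: Sequence[ReferenceSet],
    union_name: str = "A",
) -> None:
    """Flag exact full-length substring matches against each reference set.

    Genome-style sets are searched on both strands; transcript sets
    sense-only.  The union flag (default ``"A"``) is the OR over all
    individual sets.
    """
    for read in reads:
        any_hit = False
        for ref in reference_sets:
            hit = ref.contains(read.sequence)
            read.matched_reference[ref.name] = hit
            any_hit = any_hit or hit
        read.matched_reference[union_name] = any_hit


def category_table(
    reads: Sequence[CollapsedRead],
    stats: Mapping[str, LibraryStats],
) -> pd.DataFrame:
    """Per-library unique/redundant counts and percentages by category.

    Mirrors the published categorization-table layout: one row per
    reference-match flag and per annotation category plus a total row.
    """
    libs = list(stats)
    flags = sorted({k for r in reads for k in r.matched_reference})
    rows = {}
    for flag in flags:
        rows[f"Matched ({flag})"] = {
            lib: _count_pair(reads, lib, lambda r: r.matched_reference.get(flag, False))
            for lib in libs
        }
    for cat in CATEGORIES:
        rows[cat] = {
            lib: _count_pair(reads, lib, lambda r: r.category == cat) for lib in libs
        }
    rows["Total"] = {
        lib: (stats[lib].total_unique, stats[lib].total_redundant) for lib in libs
    }

    out = {}
    for lib in libs:
        tu, tr = stats[lib].total_unique, stats[lib].total_redundant
        out[f"unique_{lib}"] = {k: v[lib][0] for k, v in rows.items()}
        out[f"unique_{lib}_pct"] = {
            k: 100.0 * v[lib][0] / tu if tu else 0.0 for k, v in rows.items()
        }
        out[f"redundant_{lib}"] = {k: v[lib][1] for k, v in rows.items()}
        out[f"redundant_{lib}_pct"] = {
            k: 100.0 * v[lib][1] / tr if tr else 0.0 for k, v in rows.items()
        }
    return pd.DataFrame(out)


def _count_pair(reads, lib, pred) -> tuple[int, int]:
    unique = redundant = 0
    for r in reads:
        c = r.counts.get(lib, 0)
        if c > 0 and pred(r):
            unique += 1
            redundant += c
    return unique, redundant


def jaccard_top(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    n_top: int = 5000,
) -> SimilarityResult:
    """Jaccard index (percent) over the top-N most abundant unique reads.

    Ties in abundance break lexicographically on the sequence so the
    top set is deterministic.
    """
    top_a = _top_set(counts_a, n_top)
    top_b = _top_set(counts_b, n_top)
    union = top_a | top_b
    if not union:
        return SimilarityResult(0.0, n_top)
    j = 100.0 * len(top_a & top_b) / len(union)
    return SimilarityResult(j, n_top)


def _top_set(counts: Mapping[str, int], n_top: int) -> set[str]:
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {seq for seq, c in ranked[:n_top] if c > 0}


def size_distribution(
    reads: Sequence[CollapsedRead],
    libraries: Sequence[str],
    matched_flag: str | None = None,
    lengths: Sequence[int] = range(18, 31),
) -> pd.DataFrame:
    """Per-length unique/redundant counts per library, for plotting.

    With ``matched_flag`` set, only reads matching that reference flag
    are counted (the matched-reads panels of a size-distribution figure).
    """
    data = {}
    for lib in libraries:
        u = Counter()
        r = Counter()
        for read in reads:
            c = read.counts.get(lib, 0)
            if c == 0:
                continue
            if matched_flag is not None and not read.matched_reference.get(matched_flag):
                continue
            u[len(read.sequence)] += 1
            r[len(read.sequence)] += c
        data[f"unique_{lib}"] = {n: u.get(n, 0) for n in lengths}
        data[f"redundant_{lib}"] = {n: r.get(n, 0) for n in lengths}
    df = pd.DataFrame(data)
    df.index.name = "length"
    return df
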