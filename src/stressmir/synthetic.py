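"""Synthetic three-library study generator with planted ground truth.

Generates every input the pipeline consumes: reference contigs hosting
planted hairpin precursors (known and novel, with miRNA* strands under
the 2-nt 3' overhang geometry), a known-miRNA catalog, structural-RNA
contaminant catalogs, three FASTQ libraries (control / drought / salt)
with per-condition planted log2 fold changes, adapters and sequencing
errors, target transcripts with degradome tag tables peaked at the
planted cleavage sites, and a gene-document literature corpus with
homologous gene families and a designated hub cluster.

Determinism contract: the same :class:`~stressmir.config.SyntheticConfig`
(including seed) yields byte-identical outputs.  Per-library multinomial
draws use generators seeded ``seed + {0, 1, 2}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import json
import numpy as np

from ._util import revcomp, random_seq, BASES
from .config import SyntheticConfig, CONDITIONS
from .citation_rank import Document


@dataclass
class PlantedLocus:
    """Ground truth for one planted miRNA precursor."""

    mirna_id: str
    mature: str
    star: str
    contig: str
    precursor_span: tuple[int, int]  # 1-based inclusive
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    arm: str
    novel: bool
    sequenced_star: bool
    control_weight: float
    log2_fc: tuple[float, float]  # (drought, salt) vs control
    expected_counts: dict = field(default_factory=dict)
    realized_counts: dict = field(default_factory=dict)


@dataclass
class CleavageSite:
    mirna_id: str
    transcript_id: str
    position: int  # 1-based, first nucleotide of the 3' cleavage fragment
    site_span: tuple[int, int]


@dataclass
class PlantedTruth:
    mirna_loci: list[PlantedLocus] = field(default_factory=list)
    cleavage_sites: list[CleavageSite] = field(default_factory=list)
    corpus_clusters: dict[str, str] = field(default_factory=dict)
    expected_top_gene: str | None = None
    background: dict[str, float] = field(default_factory=dict)  # seq -> weight
    background_mappable: dict[str, bool] = field(default_factory=dict)

    def locus(self, mirna_id: str) -> PlantedLocus:
        for l in self.mirna_loci:
            if l.mirna_id == mirna_id:
                return l
        raise KeyError(mirna_id)

    def to_json(self, path: str | Path) -> None:
        data = {
            "mirna_loci": [asdict(l) for l in self.mirna_loci],
            "cleavage_sites": [asdict(c) for c in self.cleavage_sites],
            "corpus_clusters": self.corpus_clusters,
            "expected_top_gene": self.expected_top_gene,
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


@dataclass
class SyntheticReference:
    """Everything generate_reference produces besides the truth ledger."""

    contigs: dict[str, str]
    known_catalog: dict[str, str]
    known_families: dict[str, str]
    contaminant_catalog: dict[str, list[str]]
    transcripts: dict[str, str]
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# expression plan shared by library and count-matrix simulation


def expression_plan(config: SyntheticConfig) -> tuple[list[str], np.ndarray, dict[str, tuple[float, float]]]:
    """Planted miRNA ids, control weights (reads) and fold-change map.

    Control weights follow a Zipf profile over a deterministic
    permutation of the loci so high- and low-expressed miRNAs occur in
    both the known and novel groups; they sum to
    ``mirna_read_fraction x control library size``.
    """
    ids = [f"mir-{i + 1:03d}" for i in range(config.n_known_mirnas)]
    ids += [f"nov-{i + 1:03d}" for i in range(config.n_novel_mirnas)]
    rng = np.random.default_rng(config.seed + 17)
    order = rng.permutation(len(ids))
    raw = np.zeros(len(ids))
    for rank, idx in enumerate(order):
        raw[idx] = 1.0 / (rank + 1)
    weights = raw / raw.sum() * config.mirna_read_fraction * config.library_sizes["control"]

    if config.planted_log2_fc is not None:
        fc = {mid: config.planted_log2_fc.get(mid, (0.0, 0.0)) for mid in ids}
    else:
        fc = {}
        for i, mid in enumerate(ids):
            k = i % 8
            if k in (0, 1):
                fc[mid] = (2.0, 0.0)
            elif k in (2, 3):
                fc[mid] = (0.0, 2.0)
            elif k == 4:
                fc[mid] = (-2.0, -2.0)
            else:
                fc[mid] = (0.0, 0.0)
    return ids, weights, fc


def _fc_factor(fc: tuple[float, float], condition: str) -> float:
    if condition == "control":
        return 1.0
    return 2.0 ** fc[0] if condition == "drought" else 2.0 ** fc[1]


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(config: SyntheticConfig) -> SyntheticReference:
    """Build contigs with planted hairpins, catalogs, transcripts, truth.

    Each precursor is mature + loop + star arm, the star arm reverse-
    complementary to the mature except for at most
    ``precursor_mismatches`` interior substitutions; the planted star
    sequence follows the 2-nt 3' overhang rule (so it extends two
    nucleotides past the precursor into the contig).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, weights, fc = expression_plan(config)

    # known catalog: the planted known matures themselves
    known_catalog: dict[str, str] = {}
    known_families: dict[str, str] = {}
    matures: dict[str, str] = {}
    from .mirna_discovery import fold_hairpin

    for mid in ids:
        while True:
            m = random_seq(rng, config.mature_length)
            if any(_mm_distance(m, other) <= 3 for other in matures.values()):
                continue
            # real matures are unstructured; reject self-folding draws
            if fold_hairpin(m).max_pairs > config.max_mature_self_pairs:
                continue
            break
        matures[mid] = m
        if mid.startswith("mir-"):
            known_catalog[mid] = m
            known_families[mid] = f"miR{100 + len(known_families) + 1}"

    contigs = {
        f"contig{i + 1:03d}": list(random_seq(rng, config.contig_length))
        for i in range(config.n_contigs)
    }
    contig_ids = sorted(contigs)

    truth = PlantedTruth()
    star_cut = int(round(config.star_fraction * len(ids)))
    pre_len = 2 * config.mature_length + config.loop_length
    slot = pre_len + 250  # precursors well separated so fold windows stay distinct
    per_contig = -(-len(ids) // len(contig_ids)) if ids else 0  # ceil
    # last slot must leave room for max jitter (29) + precursor + 2 nt star overhang
    headroom = config.contig_length - pre_len - 32
    capacity = headroom // slot + 1 if headroom >= 0 else 0
    if per_contig > capacity:
        first_bad = ids[capacity * len(contig_ids)]
        raise ValueError(
            f"contig_length {config.contig_length} too small to host the requested "
            f"loci; first unplaceable locus: {first_bad}"
        )

    for i, mid in enumerate(ids):
        contig_id = contig_ids[i % len(contig_ids)]
        slot_idx = i // len(contig_ids)
        jitter = int(rng.integers(0, 30))
        p0 = slot_idx * slot + jitter  # 0-based precursor start
        mature = matures[mid]
        L = config.mature_length
        star_arm = list(revcomp(mature))
        n_mm = int(rng.integers(0, config.precursor_mismatches + 1))
        mm_positions = rng.choice(np.arange(3, L - 4), size=n_mm, replace=False) if n_mm else []
        for pos in mm_positions:
            old = star_arm[pos]
            star_arm[pos] = rng.choice([b for b in BASES if b != old])
        precursor = mature + random_seq(rng, config.loop_length) + "".join(star_arm)
        seq = contigs[contig_id]
        seq[p0 : p0 + pre_len] = list(precursor)
        # star under the 2-nt 3' overhang rule: revcomp arm shifted by 2,
        # including two contig nucleotides past the precursor
        s0 = p0 + L + config.loop_length + 2
        star = "".join(seq[s0 : s0 + L])
        truth.mirna_loci.append(
            PlantedLocus(
                mirna_id=mid,
                mature=mature,
                star=star,
                contig=contig_id,
                precursor_span=(p0 + 1, p0 + pre_len),
                mature_span=(p0 + 1, p0 + L),
                star_span=(s0 + 1, s0 + L),
                arm="5p",
                novel=mid.startswith("nov-"),
                sequenced_star=i < star_cut or mid.startswith("nov-"),
                control_weight=float(weights[i]),
                log2_fc=fc[mid],
            )
        )

    contigs_str = {k: "".join(v) for k, v in contigs.items()}

    contaminant_catalog = {
        cls: [random_seq(rng, int(rng.integers(70, 130))) for _ in range(n)]
        for cls, n in sorted(config.n_contaminants.items())
    }

    # background small-RNA complement (library complexity)
    lengths = sorted(config.read_length_distribution)
    lweights = np.array([config.read_length_distribution[l] for l in lengths], dtype=float)
    lweights /= lweights.sum()
    n_mappable = int(round(config.background_mappable_fraction * config.n_background))
    # keep background reads off the planted hairpins so their abundance
    # cannot masquerade as mature or star expression
    planted_spans: dict[str, list[tuple[int, int]]] = {}
    for locus in truth.mirna_loci:
        planted_spans.setdefault(locus.contig, []).append(
            (locus.precursor_span[0] - 1, locus.star_span[1])
        )
    bg_rank = 0
    while len(truth.background) < config.n_background:
        length = int(rng.choice(lengths, p=lweights))
        if len(truth.background) < n_mappable:
            cid = contig_ids[int(rng.integers(len(contig_ids)))]
            start = int(rng.integers(0, config.contig_length - length))
            if any(
                start < hi and start + length > lo
                for lo, hi in planted_spans.get(cid, ())
            ):
                continue
            seq = contigs_str[cid][start : start + length]
            mappable = True
        else:
            seq = random_seq(rng, length)
            mappable = False
        if seq in truth.background or seq in matures.values():
            continue
        bg_rank += 1
        truth.background[seq] = 1.0 / bg_rank
        truth.background_mappable[seq] = mappable

    # target transcripts with planted cleavage sites + decoys
    transcripts: dict[str, str] = {}
    targeted = truth.mirna_loci[: config.n_target_transcripts]
    for t, locus in enumerate(targeted):
        tid = f"transcript{t + 1:03d}"
        body = list(random_seq(rng, config.transcript_length))
        site = revcomp(locus.mature)
        pos = int(rng.integers(30, config.transcript_length - len(site) - 30))
        body[pos : pos + len(site)] = list(site)
        transcripts[tid] = "".join(body)
        start, end = pos + 1, pos + len(site)
        truth.cleavage_sites.append(
            CleavageSite(
                mirna_id=locus.mirna_id,
                transcript_id=tid,
                position=end - 9,
                site_span=(start, end),
            )
        )
    for d in range(config.n_decoy_transcripts):
        transcripts[f"decoy{d + 1:03d}"] = random_seq(rng, config.transcript_length)

    return SyntheticReference(
        contigs=contigs_str,
        known_catalog=known_catalog,
        known_families=known_families,
        contaminant_catalog=contaminant_catalog,
        transcripts=transcripts,
        truth=truth,
    )


def _mm_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        return 99
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# library simulation


def _source_table(config: SyntheticConfig, truth: PlantedTruth, condition: str):
    """(labels, sequences-or-class, expected counts) for one library."""
    lib_size = config.library_sizes[condition]
    labels: list[tuple[str, str]] = []  # (kind, key)
    expected: list[float] = []
    for locus in truth.mirna_loci:
        e = locus.control_weight * _fc_factor(locus.log2_fc, condition)
        labels.append(("mature", locus.mirna_id))
        expected.append(e)
        if locus.sequenced_star:
            labels.append(("star", locus.mirna_id))
            expected.append(e * config.star_relative_abundance)
    for cls in sorted(config.contaminant_fractions):
        labels.append(("contaminant", cls))
        expected.append(config.contaminant_fractions[cls] * lib_size)

    bg_weights = np.array(list(truth.background.values()), dtype=float)
    remainder = lib_size - sum(expected)
    if remainder < 0:
        raise ValueError(
            f"planted expectations exceed the {condition} library size; "
            "lower mirna_read_fraction or fold changes"
        )
    bg_expected = bg_weights / bg_weights.sum() * remainder
    for seq in truth.background:
        labels.append(("background", seq))
    expected = np.concatenate([np.array(expected, dtype=float), bg_expected])
    return labels, expected


def simulate_libraries(
    config: SyntheticConfig,
    reference: SyntheticReference,
) -> dict[str, list[tuple[str, str, str]]]:
    """Draw the three FASTQ libraries; returns (id, seq, qual) per library.

    Expected counts per source sum exactly to the configured library
    size before the multinomial draw.  Reads are insert + 3' adapter
    truncated to the machine read length, with substitution errors at
    the configured rate; error bases carry Q10 ('+'), everything else
    Q40 ('I').  Realized per-source counts are recorded in the truth
    ledger.
    """
    truth = reference.truth
    matures = {l.mirna_id: l.mature for l in truth.mirna_loci}
    stars = {l.mirna_id: l.star for l in truth.mirna_loci}
    lengths = sorted(config.read_length_distribution)
    lweights = np.array([config.read_length_distribution[l] for l in lengths], dtype=float)
    lweights /= lweights.sum()

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for k, condition in enumerate(CONDITIONS):
        rng = np.random.default_rng(config.seed + k)
        lib_size = config.library_sizes[condition]
        reads: list[tuple[str, str, str]] = []
        if lib_size == 0:
            import warnings

            warnings.warn(f"library size 0 for {condition}: writing empty FASTQ")
            libraries[condition] = reads
            continue
        labels, expected = _source_table(config, truth, condition)
        counts = rng.multinomial(lib_size, expected / expected.sum())

        inserts: list[str] = []
        for src_idx, ((kind, key), n) in enumerate(zip(labels, counts)):
            # record realized/expected counts for planted loci (even zeros)
            if kind in ("mature", "star"):
                locus = truth.locus(key)
                locus.realized_counts.setdefault(condition, {})[kind] = int(n)
                locus.expected_counts.setdefault(condition, {})[kind] = float(expected[src_idx])
            if n == 0:
                continue
            if kind == "mature":
                inserts.extend([matures[key]] * n)
            elif kind == "star":
                inserts.extend([stars[key]] * n)
            elif kind == "background":
                inserts.extend([key] * n)
            else:  # contaminant class: exact substrings of catalog entries
                entries = reference.contaminant_catalog[key]
                picks = rng.integers(0, len(entries), size=n)
                ls = rng.choice(lengths, p=lweights, size=n)
                for e_idx, length in zip(picks, ls):
                    entry = entries[e_idx]
                    length = min(int(length), len(entry))
                    off = int(rng.integers(0, len(entry) - length + 1))
                    inserts.append(entry[off : off + length])

        R = config.machine_read_length
        raw = [(ins + config.adapter)[:R] for ins in inserts]
        if config.sequencing_error_rate > 0:
            err = rng.random((len(raw), R)) < config.sequencing_error_rate
            shifts = rng.integers(1, 4, size=int(err.sum()))
            e_rows, e_cols = np.nonzero(err)
        else:
            e_rows = np.array([], dtype=int)

        quals = ["I" * R] * len(raw)
        if len(e_rows):
            raw = [list(r) for r in raw]
            quals = [list(q) for q in quals]
            for (row, col), shift in zip(zip(e_rows, e_cols), shifts):
                base = raw[row][col]
                raw[row][col] = BASES[(BASES.index(base) + shift) % 4]
                quals[row][col] = "+"  # Q10
            raw = ["".join(r) for r in raw]
            quals = ["".join(q) for q in quals]

        for i, (r, q) in enumerate(zip(raw, quals)):
            reads.append((f"{condition}_{i + 1}", r, q))
        libraries[condition] = reads
    return libraries


def simulate_count_matrix(config: SyntheticConfig, seed: int | None = None):
    """Per-miRNA counts per library drawn from the expectation model.

    Fast path for calibration and recovery experiments: the same Zipf
    weights, fold-change plan and multinomial sampling as the full
    read simulation, without materializing reads.  Returns
    (counts DataFrame [miRNA x condition], library totals dict).
    """
    import pandas as pd

    ids, weights, fc = expression_plan(config)
    base_seed = config.seed if seed is None else seed
    data = {}
    for k, condition in enumerate(CONDITIONS):
        rng = np.random.default_rng(base_seed + k)
        lib_size = config.library_sizes[condition]
        expected = np.array(
            [w * _fc_factor(fc[mid], condition) for mid, w in zip(ids, weights)]
        )
        rest = lib_size - expected.sum()
        if rest < 0:
            raise ValueError("planted expectations exceed library size")
        p = np.concatenate([expected, [rest]]) / lib_size
        counts = rng.multinomial(lib_size, p)
        data[condition] = counts[:-1]
    df = pd.DataFrame(data, index=ids)
    return df, dict(config.library_sizes)


# ---------------------------------------------------------------------------
# degradome simulation


def simulate_degradome(
    config: SyntheticConfig,
    reference: SyntheticReference,
) -> dict[str, np.ndarray]:
    """Degradome 5'-end tag counts per transcript.

    A ``degradome_signal_fraction`` of each targeted transcript's tags
    falls exactly on the planted cleavage position; the remainder is
    uniform over the transcript.  Decoy transcripts receive uniform
    tags only.
    """
    rng = np.random.default_rng(config.seed + 5)
    sites = {c.transcript_id: c.position for c in reference.truth.cleavage_sites}
    profiles: dict[str, np.ndarray] = {}
    for tid in sorted(reference.transcripts):
        T = len(reference.transcripts[tid])
        counts = np.zeros(T, dtype=np.int64)
        n_tags = config.degradome_tags_per_transcript
        if tid in sites:
            n_signal = int(round(config.degradome_signal_fraction * n_tags))
            counts[sites[tid] - 1] += n_signal
            n_noise = n_tags - n_signal
        else:
            n_noise = n_tags
        if n_noise > 0:
            positions = rng.integers(0, T, size=n_noise)
            np.add.at(counts, positions, 1)
        profiles[tid] = counts
    return profiles


# ---------------------------------------------------------------------------
# literature corpus


def simulate_corpus(
    config: SyntheticConfig,
    truth: PlantedTruth,
) -> tuple[list[Document], dict[tuple[str, str], float]]:
    """Documents with species labels plus a pairwise gene-similarity table.

    Gene families are fully connected above the clustering threshold
    (within-family similarity 0.9) and unconnected across families
    (0.1).  Cluster 0 is the hub: it co-occurs with every other
    cluster in at least one plant document and has the highest document
    frequency, so it is the expected top-ranked cluster.
    """
    rng = np.random.default_rng(config.seed + 9)
    F = config.corpus_n_gene_families
    G = config.corpus_genes_per_family
    families = {
        f: [f"g{f:02d}_{k}" for k in range(G)] for f in range(F)
    }
    truth.corpus_clusters = {
        g: min(families[f]) for f in families for g in families[f]
    }
    hub = min(families[0]) if F else None
    truth.expected_top_gene = hub

    similarity: dict[tuple[str, str], float] = {}
    for f, members in families.items():
        for i in range(G):
            for j in range(i + 1, G):
                similarity[(members[i], members[j])] = 0.9
    all_genes = sorted(truth.corpus_clusters)
    for _ in range(2 * F):
        a, b = rng.choice(all_genes, size=2, replace=False)
        if truth.corpus_clusters[a] != truth.corpus_clusters[b]:
            similarity.setdefault((a, b), 0.1)

    non_plant = ("human", "mouse", "yeast")
    documents: list[Document] = []
    for d in range(config.corpus_n_documents):
        if rng.random() < config.corpus_offtarget_species_fraction:
            species = str(rng.choice(non_plant))
        else:
            species = "plant"
        if F == 0:
            continue
        if d < F - 1:
            chosen = [0, d + 1]  # hub co-occurs with every other cluster
            species = "plant"
        elif rng.random() < 0.5 and F > 1:
            chosen = [0, int(rng.integers(1, F))]
        else:
            k = int(rng.integers(1, min(3, F) + 1))
            chosen = sorted(rng.choice(F, size=k, replace=False).tolist())
        genes: set[str] = set()
        for f in chosen:
            take = 1 + int(rng.integers(0, min(2, G)))
            genes.update(rng.choice(families[f], size=take, replace=False).tolist())
        documents.append(Document(doc_id=f"doc{d + 1:04d}", genes=genes, species=species))
    return documents, similarity
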