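"""Literature-based gene-cluster ranking (CitationRank).

A gene frequently mentioned in documents about a stress context is
likely important for that context, and genes co-mentioned with
frequent genes inherit importance.  Documents from non-plant species
are excluded; homologous genes are merged into clusters (single
linkage over a pairwise similarity table); a cluster-by-cluster
co-existence matrix is accumulated from co-mentions; and a damped
power iteration over the column-normalized co-existence matrix, with
the document-frequency vector as teleportation prior, yields the
ranking.  Top clusters are finally linked back to predicted miRNA
targets by sequence similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class Document:
    doc_id: str
    genes: set[str]
    species: str


@dataclass
class GeneCluster:
    cluster_id: str
    members: set[str]
    document_frequency: int = 0


@dataclass
class CoexistenceMatrix:
    clusters: list[str]
    matrix: np.ndarray  # symmetric; diagonal = document frequency

    def index(self, cluster_id: str) -> int:
        return self.clusters.index(cluster_id)


@dataclass
class RankResult:
    scores: dict[str, float] = field(default_factory=dict)
    iterations_run: int = 0
    final_delta: float = float("inf")

    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda c: (-self.scores[c], c))


def filter_species(
    documents: Sequence[Document],
    allowed_species: set[str],
) -> list[Document]:
    """Drop documents from disallowed species (and their orphaned genes)."""
    return [d for d in documents if d.species in allowed_species]


def cluster_homologs(
    genes: Sequence[str],
    similarity: Mapping[tuple[str, str], float],
    threshold: float,
) -> list[GeneCluster]:
    """Single-linkage clusters over the similarity graph.

    Genes joined by any chain of pairwise similarities >= ``threshold``
    form one cluster (connected components); cluster ids are named
    after the smallest member gene id, so the output is deterministic
    and permutation-invariant.
    """
    genes = sorted(set(genes))
    index = {g: i for i, g in enumerate(genes)}
    parent = list(range(len(genes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), s in similarity.items():
        if a in index and b in index and s >= threshold:
            ra, rb = find(index[a]), find(index[b])
            if ra != rb:
                parent[rb] = ra

    groups: dict[int, set[str]] = {}
    for g in genes:
        groups.setdefault(find(index[g]), set()).add(g)
    return [
        GeneCluster(cluster_id=min(members), members=members)
        for members in sorted(groups.values(), key=min)
    ]


def build_matrix(
    documents: Sequence[Document],
    clusters: Sequence[GeneCluster],
) -> CoexistenceMatrix:
    """Cluster co-existence counts over the document set.

    Off-diagonal entry (i, j) counts documents mentioning members of
    both clusters; the diagonal holds each cluster's document
    frequency.  Documents touching a single cluster contribute only to
    its diagonal.
    """
    gene_to_cluster = {}
    for c in clusters:
        for g in c.members:
            gene_to_cluster[g] = c.cluster_id
    ids = [c.cluster_id for c in clusters]
    pos = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    mat = np.zeros((n, n), dtype=float)
    for doc in documents:
        mentioned = sorted({gene_to_cluster[g] for g in doc.genes if g in gene_to_cluster})
        for cid in mentioned:
            mat[pos[cid], pos[cid]] += 1
        for i, a in enumerate(mentioned):
            for b in mentioned[i + 1 :]:
                mat[pos[a], pos[b]] += 1
                mat[pos[b], pos[a]] += 1
    for c in clusters:
        c.document_frequency = int(mat[pos[c.cluster_id], pos[c.cluster_id]])
    return CoexistenceMatrix(clusters=ids, matrix=mat)


def citation_rank(
    coexistence: CoexistenceMatrix,
    iterations: int = 1000,
    damping: float = 0.85,
    tol: float = 1e-12,
) -> RankResult:
    """Damped power iteration over the co-existence matrix.

    The starting vector (and teleportation prior) is the document-
    frequency vector normalized to sum 1.  The transition matrix is
    the column-normalized off-diagonal co-existence matrix; columns
    with zero sum teleport to the prior.  Runs ``iterations`` steps,
    stopping early once the L1 change drops below ``tol``.
    """
    n = len(coexistence.clusters)
    if n == 0:
        return RankResult(scores={}, iterations_run=0, final_delta=0.0)
    A = coexistence.matrix.astype(float).copy()
    freq = np.diag(A).copy()
    np.fill_diagonal(A, 0.0)
    if freq.sum() > 0:
        prior = freq / freq.sum()
    else:
        prior = np.full(n, 1.0 / n)

    colsum = A.sum(axis=0)
    T = np.where(colsum > 0, A / np.where(colsum > 0, colsum, 1.0), prior[:, None])

    r = prior.copy()
    delta = float("inf")
    it = 0
    for it in range(1, iterations + 1):
        r_new = damping * (T @ r) + (1.0 - damping) * prior
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        if delta < tol:
            break
    return RankResult(
        scores={cid: float(r[i]) for i, cid in enumerate(coexistence.clusters)},
        iterations_run=it,
        final_delta=delta,
    )


# ---------------------------------------------------------------------------
# linking top clusters to miRNA targets


def kmer_identity(a: str, b: str, k: int = 8) -> float:
    """Fraction of shared k-mers (Jaccard) between two sequences.

    Default pluggable similarity for homolog clustering and target
    linkage; any callable (a, b) -> [0, 1] may replace it.
    """
    if len(a) < k or len(b) < k:
        return 1.0 if a == b else 0.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    union = ka | kb
    return len(ka & kb) / len(union) if union else 0.0


def link_targets(
    ranked: RankResult,
    cluster_sequences: Mapping[str, Mapping[str, str]],
    target_sequences: Mapping[str, Mapping[str, str]],
    similarity: Callable[[str, str], float] = kmer_identity,
    threshold: float = 0.5,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Edges between miRNAs and (top-ranked) clusters via target similarity.

    ``cluster_sequences`` maps cluster id -> {gene id: sequence};
    ``target_sequences`` maps miRNA id -> {target id: sequence}.  An
    edge appears when any predicted target of the miRNA is similar to
    any member of the cluster above ``threshold``; edges carry the
    cluster's rank.
    """
    order = ranked.ranking()
    if top_n is not None:
        order = order[:top_n]
    rank_of = {cid: i + 1 for i, cid in enumerate(ranked.ranking())}
    rows = []
    for cid in order:
        members = cluster_sequences.get(cid, {})
        for mirna_id in sorted(target_sequences):
            hit = None
            for tid, tseq in sorted(target_sequences[mirna_id].items()):
                for gid, gseq in sorted(members.items()):
                    if similarity(tseq, gseq) >= threshold:
                        hit = (tid, gid)
                        break
                if hit:
                    break
            if hit:
                rows.append(
                    {
                        "mirna": mirna_id,
                        "cluster": cid,
                        "cluster_rank": rank_of[cid],
                        "target": hit[0],
                        "cluster_gene": hit[1],
                        "score": ranked.scores[cid],
                    }
                )
    return pd.DataFrame(rows, columns=["mirna", "cluster", "cluster_rank", "target", "cluster_gene", "score"])
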