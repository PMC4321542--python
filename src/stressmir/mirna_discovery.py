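"""miRNA precursor and novel-miRNA identification.

Hairpin structure is assessed by base-pair maximization (Watson-Crick
plus G:U, nested, minimum loop 3 nt) via the classic O(n^3) dynamic
program, not by thermodynamic folding; a candidate read becomes a
miRNA locus when it sits on one arm of the hairpin, is sufficiently
paired, and its duplex partner (the star) obeys the 2-nt 3' overhang
geometry.  Novel loci additionally require the star to be sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import revcomp
from .read_processing import CollapsedRead, CONTAMINANT_PRIORITY, assign_known

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# Watson-Crick + G:U wobble (T stands for U)
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for _x, _y in ("AT", "TA", "GC", "CG", "GT", "TG"):
    _PAIRABLE["ACGT".index(_x), "ACGT".index(_y)] = True
_WC = np.zeros((4, 4), dtype=bool)
for _x, _y in ("AT", "TA", "GC", "CG"):
    _WC["ACGT".index(_x), "ACGT".index(_y)] = True


@dataclass
class HairpinCandidate:
    """A folded window with its maximum-pairing nested structure."""

    contig: str
    start: int  # 1-based inclusive, window position on the contig
    end: int
    sequence: str
    pairing: list[tuple[int, int]]  # 0-based position pairs within the window
    max_pairs: int

    def partner_map(self) -> dict[int, int]:
        d = {}
        for i, j in self.pairing:
            d[i] = j
            d[j] = i
        return d


@dataclass
class MiRNALocus:
    mirna_id: str
    mature: str
    star: str | None
    arm: str  # "5p" | "3p"
    precursor: HairpinCandidate
    mature_span: tuple[int, int]  # 1-based inclusive on the contig
    family: str | None = None
    novel: bool = False
    duplex_pairs: int = 0
    duplex_wc: int = 0  # Watson-Crick (non-wobble) pairs within the duplex
    counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)
    known_hit: tuple[str, int] | None = None


@dataclass
class MiRNACluster:
    contig: str
    members: list[MiRNALocus]
    span: int


# ---------------------------------------------------------------------------
# candidate selection


def candidate_reads(
    reads: Sequence[CollapsedRead],
    min_reads: int = 3,
    matched_flag: str = "A",
) -> list[CollapsedRead]:
    """Reads usable for precursor search.

    Keeps reads with at least ``min_reads`` copies in one library that
    match the reference and are not contaminant-classed; this guards
    the precursor search against sequencing errors.
    """
    out = []
    for r in reads:
        if r.category in CONTAMINANT_PRIORITY:
            continue
        if not r.matched_reference.get(matched_flag, False):
            continue
        if max(r.counts.values(), default=0) >= min_reads:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# folding


def fold_hairpin(
    window: str,
    min_loop: int = 3,
    contig: str = "",
    start: int = 1,
    pair_mask: np.ndarray | None = None,
) -> HairpinCandidate:
    """Maximum base-pair nested structure of a window (<= 400 nt).

    Dynamic program over Watson-Crick and G:U pairs with a minimum
    hairpin loop of ``min_loop`` unpaired bases.  Among equal-pair-count
    structures, contiguous helices (stacked pairs) are preferred, and
    among optimal bifurcations the split point closest to the window
    center is taken, so the traceback is deterministic.  ``pair_mask``
    (boolean, window x window) optionally restricts which position
    pairs may form, e.g. to hold a candidate mature on its duplex
    diagonal.
    """
    window = window.upper().replace("U", "T")
    n = len(window)
    if n > 400:
        raise ValueError("fold window longer than 400 nt")
    if n == 0:
        return HairpinCandidate(contig, start, start - 1, window, [], 0)
    codes = _CODE[np.frombuffer(window.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("window contains non-ACGT characters")
    pairable = _PAIRABLE[codes[:, None], codes[None, :]]
    if pair_mask is not None:
        pairable = pairable & pair_mask

    # score = 1000 * pairs + stacked pairs (the stacking term breaks
    # ties only: it never reaches 1000).  P[i, j] is the best score
    # with (i, j) paired; M[i, j] the best overall.
    PAIR = 1000
    NEG = np.iinfo(np.int64).min // 4
    M = np.zeros((n, n), dtype=np.int64)
    P = np.full((n, n), NEG, dtype=np.int64)
    for l in range(min_loop + 1, n):
        i = np.arange(n - l)
        j = i + l
        inner = np.maximum(M[i + 1, j - 1], P[i + 1, j - 1] + 1)
        closing = np.where(pairable[i, j], PAIR + inner, NEG)
        P[i, j] = closing
        best = M[i, j - 1].copy()  # j unpaired (split at d = l-1)
        for d in range(l - 1):
            np.maximum(best, M[i, i + d] + M[i + d + 1, j], out=best)
        np.maximum(best, closing, out=best)
        M[i, j] = best

    pairing: list[tuple[int, int]] = []
    center = (n - 1) / 2.0
    stack: list[tuple[int, int, bool]] = [(0, n - 1, False)]
    while stack:
        i, j, in_pair = stack.pop()
        if j - i <= min_loop:
            continue
        if in_pair:
            pairing.append((i, j))
            inner_target = P[i, j] - PAIR
            if P[i + 1, j - 1] + 1 == inner_target:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        target = M[i, j]
        if target <= 0:
            continue
        if P[i, j] == target:
            stack.append((i, j, True))
            continue
        # choose the optimal split closest to the window center
        best_d = None
        best_key = None
        for d in range(j - i):
            if M[i, i + d] + M[i + d + 1, j] == target:
                key = abs(i + d + 0.5 - center)
                if best_key is None or key < best_key:
                    best_key, best_d = key, d
        assert best_d is not None
        stack.append((i, i + best_d, False))
        stack.append((i + best_d + 1, j, False))

    pairing.sort()
    return HairpinCandidate(
        contig=contig,
        start=start,
        end=start + n - 1,
        sequence=window,
        pairing=pairing,
        max_pairs=int(M[0, n - 1]) // PAIR,
    )


# ---------------------------------------------------------------------------
# locus evaluation


def evaluate_locus(
    read: str,
    candidate: HairpinCandidate,
    read_offset: int,
    min_paired_frac: float = 0.6,
    max_bulge: int = 4,
    mirna_id: str | None = None,
) -> MiRNALocus | None:
    """Accept or reject a mature candidate against a folded window.

    Acceptance requires (a) at least ``min_paired_frac`` of mature
    positions paired, (b) the mature wholly on one arm (all partners on
    one side, none internal), (c) a star computable under the 2-nt 3'
    overhang duplex geometry within the window, and (d) total duplex
    bulge asymmetry at most ``max_bulge`` nt.
    """
    L = len(read)
    m0, m1 = read_offset, read_offset + L - 1
    if m0 < 0 or m1 >= len(candidate.sequence):
        return None
    partner = candidate.partner_map()
    paired_all = [i for i in range(m0, m1 + 1) if i in partner]
    if any(m0 <= partner[i] <= m1 for i in paired_all):
        return None  # mature folds onto itself / spans the loop

    # Base-pair maximization can report degenerate optima with a few
    # stray pairs; the duplex is read off the majority arm and the
    # longest run of pairs whose step-wise bulge stays within budget.
    up = [i for i in paired_all if partner[i] > m1]
    down = [i for i in paired_all if partner[i] < m0]
    arm_pairs = up if len(up) >= len(down) else down
    arm = "5p" if arm_pairs is up else "3p"

    paired, asym = _duplex_segment(arm_pairs, partner, max_bulge)
    if len(paired) < min_paired_frac * L:
        return None
    if asym > max_bulge:
        return None

    # star under the 2-nt 3' overhang rule.  On an antiparallel duplex
    # i + partner(i) is constant; the median diagonal is robust to a
    # single slipped pair at the duplex ends.
    diag = int(np.median([i + partner[i] for i in paired]))
    p_ext_m0 = diag - m0
    p_ext_m1m2 = diag - (m1 - 2)
    lo, hi = sorted((p_ext_m1m2, p_ext_m0 + 2))
    if lo < 0 or hi >= len(candidate.sequence):
        return None
    star = candidate.sequence[lo : hi + 1]

    # trim the precursor to the hairpin extent (duplex arms + loop) so
    # downstream redundancy removal compares precursors, not windows
    ext0, ext1 = min(m0, lo), max(m1, hi)
    kept_pairs = sorted(
        (i - ext0, j - ext0)
        for i, j in candidate.pairing
        if ext0 <= i <= ext1 and ext0 <= j <= ext1
    )
    precursor = HairpinCandidate(
        contig=candidate.contig,
        start=candidate.start + ext0,
        end=candidate.start + ext1,
        sequence=candidate.sequence[ext0 : ext1 + 1],
        pairing=kept_pairs,
        max_pairs=len(kept_pairs),
    )
    return MiRNALocus(
        mirna_id=mirna_id or f"{candidate.contig}:{candidate.start + m0}",
        mature=read,
        star=star,
        arm=arm,
        precursor=precursor,
        mature_span=(candidate.start + m0, candidate.start + m1),
        duplex_pairs=len(paired),
        duplex_wc=sum(
            1
            for i in paired
            if _WC["ACGT".index(candidate.sequence[i]),
                   "ACGT".index(candidate.sequence[partner[i]])]
        ),
    )


def _duplex_segment(
    positions: list[int],
    partner: dict[int, int],
    max_bulge: int,
) -> tuple[list[int], int]:
    """Longest run of same-arm pairs with per-step bulge within budget.

    Consecutive paired mature positions must have antiparallel partners
    (strictly decreasing) and a step asymmetry |gap_mature - gap_star|
    of at most ``max_bulge``; returns (segment positions, total
    asymmetry within the segment).
    """
    if not positions:
        return [], 0
    best: list[int] = []
    best_asym = 0
    seg = [positions[0]]
    asym = 0
    for a, b in zip(positions, positions[1:]):
        gap_m = b - a - 1
        gap_s = partner[a] - partner[b] - 1  # antiparallel: partner decreasing
        step = abs(gap_m - gap_s)
        if gap_s < 0 or step > max_bulge or asym + step > max_bulge:
            if len(seg) > len(best):
                best, best_asym = seg, asym
            seg, asym = [b], 0
        else:
            seg.append(b)
            asym += step
    if len(seg) > len(best):
        best, best_asym = seg, asym
    return best, best_asym


def anchored_windows(
    read: str,
    contig_seq: str,
    position: int,
    min_loop: int = 3,
    max_loop: int = 120,
    n_best: int = 2,
) -> list[tuple[str, int, int, int]]:
    """Duplex-anchored minimal windows for one read occurrence.

    Scans every antiparallel diagonal on which the read could pair an
    arm up- or downstream (loop length between ``min_loop`` and
    ``max_loop``), ranks diagonals by pairable positions, and returns
    (window, window start, read offset, window-local diagonal) tuples
    of minimal windows spanning read + loop + implied star arm for the
    best diagonals.  Windows this tight, folded with the matching
    duplex-band mask, leave base-pair maximization no room to trade
    the stem away against flanking structure.
    """
    L = len(read)
    n = len(contig_seq)
    codes = _CODE[np.frombuffer(contig_seq.encode(), dtype=np.uint8)]
    m = _CODE[np.frombuffer(read.encode(), dtype=np.uint8)]
    if (m < 0).any():
        return []
    m0, m1 = position, position + L - 1
    idx = np.arange(L)

    diags = []
    # star downstream (read on the 5' arm): partner(m0) in (m1+min_loop, m1+max_loop+L]
    lo = m0 + m1 + min_loop + 1
    hi = m0 + m1 + max_loop + L
    diags.extend(range(lo, hi + 1))
    # star upstream (read on the 3' arm)
    lo = m0 + m1 - max_loop - L
    hi = m0 + m1 - min_loop - 1
    diags.extend(range(lo, hi + 1))

    scored = []
    for diag in diags:
        partner = diag - (m0 + idx)
        if partner.min() < 0 or partner.max() >= n:
            continue
        count = int(_PAIRABLE[m, codes[partner]].sum())
        scored.append((count, diag))
    scored.sort(key=lambda t: (-t[0], t[1]))

    windows = []
    for count, diag in scored[:n_best]:
        partner_lo = diag - m1
        partner_hi = diag - m0
        w0 = max(0, min(m0, partner_lo) - 3)
        w1 = min(n, max(m1, partner_hi) + 3 + 1)
        windows.append((contig_seq[w0:w1], w0, m0 - w0, diag - 2 * w0))
    return windows


def duplex_band_mask(
    window_len: int,
    read_offset: int,
    read_len: int,
    diag: int,
    slack: int = 4,
) -> np.ndarray:
    """Pair mask holding the mature on its anchored duplex diagonal.

    Positions inside the mature may pair only partners with
    |i + j - diag| <= ``slack`` outside the mature (no mature-internal
    pairs); all other positions pair freely.
    """
    mask = np.ones((window_len, window_len), dtype=bool)
    m0, m1 = read_offset, read_offset + read_len - 1
    idx = np.arange(window_len)
    in_mature = (idx >= m0) & (idx <= m1)
    on_band = np.abs(idx[:, None] + idx[None, :] - diag) <= slack
    involves_mature = in_mature[:, None] | in_mature[None, :]
    both_mature = in_mature[:, None] & in_mature[None, :]
    mask &= ~involves_mature | (on_band & ~both_mature)
    return mask


def fold_windows_for_read(
    read: str,
    contig_seq: str,
    position: int,
    window_size: int = 200,
    flank: int = 20,
) -> list[tuple[str, int, int]]:
    """Candidate windows around one read occurrence (0-based position).

    Two placements are tried: the read near the window 5' end (its own
    5' flank ``flank`` nt, remainder 3') and the mirrored placement;
    returns (window sequence, window start 0-based, read offset) tuples.
    """
    L = len(read)
    windows = []
    for lead in (flank, window_size - L - flank):
        w0 = max(0, position - lead)
        w1 = min(len(contig_seq), w0 + window_size)
        w0 = max(0, w1 - window_size)
        if w1 - w0 >= L + 10:
            windows.append((contig_seq[w0:w1], w0, position - w0))
    return windows


# ---------------------------------------------------------------------------
# novelty, dedup, families, clusters


def call_novel(
    loci: Sequence[MiRNALocus],
    known_catalog: Mapping[str, str],
    max_mismatch: int = 3,
    same_library: bool = True,
) -> list[MiRNALocus]:
    """Label loci conserved/novel; drop unsupported candidates.

    A locus whose mature is within ``max_mismatch`` of a known miRNA is
    conserved and kept even without star reads (well-known miRNAs often
    lack a sequenced star).  Otherwise it is novel only when mature and
    star co-exist in a sequencing library (``same_library=True``
    requires both in the same library; otherwise a star anywhere
    suffices).
    """
    kept = []
    for locus in loci:
        hit = assign_known(locus.mature, known_catalog, max_mismatch)
        if hit is not None:
            locus.novel = False
            locus.known_hit = hit
            kept.append(locus)
            continue
        libs = set(locus.counts) | set(locus.star_counts)
        if same_library:
            ok = any(
                locus.counts.get(l, 0) >= 1 and locus.star_counts.get(l, 0) >= 1
                for l in libs
            )
        else:
            ok = any(c >= 1 for c in locus.star_counts.values())
        if ok:
            locus.novel = True
            kept.append(locus)
    return kept


def ungapped_identity(a: str, b: str) -> float:
    """Best sliding ungapped percent identity over the shorter sequence."""
    if len(a) > len(b):
        a, b = b, a
    la = len(a)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    best = 0
    for s in range(len(b) - la + 1):
        m = int(np.count_nonzero(arr_a == arr_b[s : s + la]))
        if m > best:
            best = m
            if best == la:
                break
    return 100.0 * best / la if la else 0.0


def dedupe_precursors(
    loci: Sequence[MiRNALocus],
    min_identity: float = 95.0,
) -> list[MiRNALocus]:
    """Merge loci with near-identical precursors (all-to-all alignment).

    Precursors at least ``min_identity`` percent identical over the
    shorter length collapse to one survivor: the locus with the highest
    summed mature count, ties broken by (contig, start).  Idempotent.
    """
    n = len(loci)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if ungapped_identity(loci[i].precursor.sequence, loci[j].precursor.sequence) >= min_identity:
                parent[find(j)] = find(i)

    groups: dict[int, list[MiRNALocus]] = {}
    for i, locus in enumerate(loci):
        groups.setdefault(find(i), []).append(locus)

    survivors = []
    for members in groups.values():
        members.sort(
            key=lambda l: (-sum(l.counts.values()), l.precursor.contig, l.precursor.start)
        )
        survivors.append(members[0])
    survivors.sort(key=lambda l: (l.precursor.contig, l.precursor.start))
    return survivors


def cross_genome_homology(
    precursors: Sequence[MiRNALocus],
    reference: Sequence[str],
    min_identity: float = 95.0,
) -> dict[str, bool]:
    """Homology of each precursor to another reference set.

    A precursor is homologous when an ungapped sliding alignment to any
    reference sequence reaches ``min_identity`` percent identity over
    the full precursor length (inclusive boundary).
    """
    refs = [r.upper().replace("U", "T") for r in reference]
    out = {}
    for locus in precursors:
        pre = locus.precursor.sequence
        hit = any(pre in r for r in refs)
        if not hit:
            for r in refs:
                if len(r) >= len(pre) and ungapped_identity(pre, r) >= min_identity:
                    hit = True
                    break
        out[locus.mirna_id] = hit
    return out


def _mature_distance(a: str, b: str, cap: int) -> int:
    """Offset-Hamming distance between two matures (overhang = mismatch)."""
    hit = assign_known(a, {"x": b}, max_mismatch=cap)
    return hit[1] if hit else cap + 1


def assign_family(
    loci: Sequence[MiRNALocus],
    known_families: Mapping[str, str],
    max_mismatch: int = 3,
    novel_prefix: str = "ghr-n",
) -> None:
    """Assign catalog families to conserved loci, single-linkage to novel.

    Novel matures within ``max_mismatch`` (offset Hamming) link into one
    family; novel families are named ``ghr-n1, ghr-n2, ...`` in
    discovery order.  Invariant under permutation of the input up to
    the naming.
    """
    novel = [l for l in loci if l.novel]
    for locus in loci:
        if not locus.novel and locus.known_hit is not None:
            cid = locus.known_hit[0]
            locus.family = known_families.get(cid, cid)

    n = len(novel)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _mature_distance(novel[i].mature, novel[j].mature, max_mismatch) <= max_mismatch:
                parent[find(j)] = find(i)

    names: dict[int, str] = {}
    k = 0
    for i, locus in enumerate(novel):
        root = find(i)
        if root not in names:
            k += 1
            names[root] = f"{novel_prefix}{k}"
        locus.family = names[root]


def find_clusters(
    loci: Sequence[MiRNALocus],
    cluster_distance: int = 10_000,
) -> list[MiRNACluster]:
    """Maximal runs of >= 2 loci on one contig with start gaps <= distance."""
    by_contig: dict[str, list[MiRNALocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.precursor.contig, []).append(locus)

    clusters = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda l: l.precursor.start)
        run = [members[0]]
        for locus in members[1:]:
            if locus.precursor.start - run[-1].precursor.start <= cluster_distance:
                run.append(locus)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(contig, run))
                run = [locus]
        if len(run) >= 2:
            clusters.append(_make_cluster(contig, run))
    return clusters


def _make_cluster(contig: str, run: list[MiRNALocus]) -> MiRNACluster:
    span = run[-1].precursor.end - run[0].precursor.start + 1
    return MiRNACluster(contig=contig, members=list(run), span=span)


# ---------------------------------------------------------------------------
# end-to-end discovery over contigs


def discover_loci(
    reads: Sequence[CollapsedRead],
    contigs: Mapping[str, str],
    min_reads: int = 3,
    window_size: int = 200,
    flank: int = 20,
    min_paired_frac: float = 0.6,
    max_bulge: int = 4,
    max_occurrences: int = 4,
    matched_flag: str = "A",
) -> list[MiRNALocus]:
    """Search contigs for hairpin loci seeded by candidate reads.

    Each sense-strand occurrence of a candidate read is folded in two
    fixed-size window placements and in duplex-anchored minimal
    windows (which rescue hairpins whose stem the wide-window fold
    trades away against flanking structure); among accepted geometries
    the one with the largest mature/star duplex wins.  Mature and
    exact-star counts are looked up in the collapsed read table.
    """
    contigs = {k: v.upper().replace("U", "T") for k, v in contigs.items()}
    count_index = {r.sequence: r.counts for r in reads}
    libs: list[str] = list(next(iter(count_index.values()), {}).keys()) if count_index else []

    loci: list[MiRNALocus] = []
    for read in candidate_reads(reads, min_reads=min_reads, matched_flag=matched_flag):
        seq = read.sequence
        for contig_id in sorted(contigs):
            contig_seq = contigs[contig_id]
            pos = contig_seq.find(seq)
            seen = 0
            while pos >= 0 and seen < max_occurrences:
                best: MiRNALocus | None = None
                windows: list[tuple[str, int, int, int | None]] = [
                    (w, s, o, None)
                    for w, s, o in fold_windows_for_read(
                        seq, contig_seq, pos, window_size=window_size, flank=flank
                    )
                ] + anchored_windows(seq, contig_seq, pos)
                for window, w0, offset, diag in windows:
                    # cheap screen: a usable hairpin needs an ungapped
                    # reverse-complement echo of the mature in the window
                    if ungapped_identity(revcomp(seq), window) < 100.0 * min_paired_frac:
                        continue
                    mask = (
                        duplex_band_mask(len(window), offset, len(seq), diag, max_bulge)
                        if diag is not None
                        else None
                    )
                    candidate = fold_hairpin(
                        window, contig=contig_id, start=w0 + 1, pair_mask=mask
                    )
                    locus = evaluate_locus(
                        seq, candidate, offset,
                        min_paired_frac=min_paired_frac, max_bulge=max_bulge,
                    )
                    if locus is not None and (
                        best is None
                        or (locus.duplex_pairs, locus.duplex_wc, locus.precursor.max_pairs)
                        > (best.duplex_pairs, best.duplex_wc, best.precursor.max_pairs)
                    ):
                        best = locus
                if best is not None:
                    best.counts = dict(read.counts)
                    star_counts = count_index.get(best.star or "", None)
                    best.star_counts = dict(star_counts) if star_counts else {l: 0 for l in libs}
                    loci.append(best)
                seen += 1
                pos = contig_seq.find(seq, pos + 1)
    return loci
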