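"""Plant miRNA target prediction and degradome (PARE) validation.

Targets are scored by ungapped complementarity penalties: a Watson-
Crick pair costs 0, a G:U wobble 0.5 and a mismatch 1, with penalties
doubled over miRNA positions 2-13 (seed-proximal region).  Candidate
sites pass with total score <= 4.0, at most two consecutive mismatches
and at most one mismatch inside positions 2-13.

Degradome validation tests the 5'-end tag pile-up at the cleavage
position (the transcript nucleotide opposite the miRNA 10/11 boundary)
against a uniform binomial null over the transcript, and additionally
requires perfect matches at miRNA positions 10 and 11.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import revcomp

#: miRNA positions (1-based) whose penalties are doubled.
WEIGHTED_REGION = (2, 13)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    alignment: str  # one code per miRNA position 1..L: m(atch) / w(obble) / x(mismatch)
    score: float


@dataclass
class DegradomeProfile:
    """Per-position degradome 5'-end tag counts of one transcript."""

    transcript_id: str
    five_prime_counts: np.ndarray  # length = transcript length; index = position-1

    @property
    def total_tags(self) -> int:
        return int(self.five_prime_counts.sum())

    @classmethod
    def from_table(cls, transcript_id: str, length: int, rows: Sequence[tuple[int, int]]):
        counts = np.zeros(length, dtype=np.int64)
        for pos, count in rows:
            if not 1 <= pos <= length:
                raise ValueError(f"tag position {pos} outside transcript of length {length}")
            counts[pos - 1] += count
        return cls(transcript_id, counts)


@dataclass
class DegradomeValidation:
    site: TargetSite
    cleavage_position: int
    tags_at_site: int
    total_tags: int
    p_value: float
    validated: bool


# ---------------------------------------------------------------------------
# scoring

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# penalty[mirna base, revcomp(target) base]: 0 match, 0.5 wobble, 1 mismatch.
# After reverse-complementing the site, a Watson-Crick pair is equality;
# G:U wobble appears as (G, A) or (T, C).
_PENALTY = np.ones((4, 4), dtype=float)
np.fill_diagonal(_PENALTY, 0.0)
_PENALTY["ACGT".index("G"), "ACGT".index("A")] = 0.5
_PENALTY["ACGT".index("T"), "ACGT".index("C")] = 0.5

_CODE_CHAR = {0.0: "m", 0.5: "w", 1.0: "x"}


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGTU characters")
    return arr


def position_weights(length: int) -> np.ndarray:
    w = np.ones(length)
    lo, hi = WEIGHTED_REGION
    w[lo - 1 : hi] = 2.0
    return w


def score_duplex(mirna: str, window: str) -> tuple[str, float]:
    """Alignment codes (miRNA 5'->3') and penalty score for one window.

    The window is the transcript site in sense orientation with the
    same length as the miRNA; no gaps are considered.
    """
    if len(window) != len(mirna):
        raise ValueError("window length must equal miRNA length")
    m = _encode(mirna)
    t = _encode(revcomp(window))
    pen = _PENALTY[m, t]
    codes = "".join(_CODE_CHAR[p] for p in pen)
    score = float((pen * position_weights(len(mirna))).sum())
    return codes, score


def _site_ok(pen: np.ndarray, max_consecutive_mismatch: int, max_core_mismatch: int) -> bool:
    mism = pen == 1.0
    run = best = 0
    for x in mism:
        run = run + 1 if x else 0
        best = max(best, run)
    lo, hi = WEIGHTED_REGION
    return best <= max_consecutive_mismatch and int(mism[lo - 1 : hi].sum()) <= max_core_mismatch


def scan_targets(
    mirnas: Mapping[str, str],
    transcriptome: Mapping[str, str],
    max_score: float = 4.0,
    max_consecutive_mismatch: int = 2,
    max_core_mismatch: int = 1,
) -> list[TargetSite]:
    """All passing target sites, ordered by (miRNA, transcript, position)."""
    sites: list[TargetSite] = []
    weights_cache: dict[int, np.ndarray] = {}
    for mid in sorted(mirnas):
        m = _encode(mirnas[mid])[::-1]  # reversed miRNA aligns with the sense window
        L = len(m)
        w = weights_cache.setdefault(L, position_weights(L)[::-1])
        for tid in sorted(transcriptome):
            t_arr = _encode(transcriptome[tid])
            T = len(t_arr)
            if T < L:
                continue
            # complement of transcript base, so WC pair becomes equality
            t_comp = np.array([3, 2, 1, 0], dtype=np.int8)[t_arr]
            windows = np.lib.stride_tricks.sliding_window_view(t_comp, L)
            pen = _PENALTY[np.broadcast_to(m, windows.shape), windows]
            scores = pen @ w
            for s in np.flatnonzero(scores <= max_score):
                pen_site = pen[s][::-1]  # back to miRNA 5'->3' orientation
                if not _site_ok(pen_site, max_consecutive_mismatch, max_core_mismatch):
                    continue
                codes = "".join(_CODE_CHAR[p] for p in pen_site)
                sites.append(
                    TargetSite(
                        mirna_id=mid,
                        transcript_id=tid,
                        start=int(s) + 1,
                        end=int(s) + L,
                        alignment=codes,
                        score=float(scores[s]),
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# degradome validation


def cleavage_position(site: TargetSite) -> int:
    """Transcript coordinate opposite the miRNA 10/11 boundary.

    The nucleotide paired to miRNA position 10 (1-based from the miRNA
    5' end) is the first nucleotide of the 3' cleavage fragment.
    """
    return site.end - 9


def validate_site(
    site: TargetSite,
    profile: DegradomeProfile,
    alpha: float = 0.05,
) -> DegradomeValidation:
    """Binomial test of the tag pile-up at the predicted cleavage site.

    Under the null, each of the ``total_tags`` tags falls uniformly on
    one of the transcript's positions; the p-value is the upper-tail
    binomial probability of observing at least the seen count at the
    cleavage position.  Validation additionally requires Watson-Crick
    matches at miRNA positions 10 and 11.
    """
    T = len(profile.five_prime_counts)
    pos = cleavage_position(site)
    if not 1 <= pos <= T:
        raise ValueError("cleavage position outside the degradome profile")
    k = int(profile.five_prime_counts[pos - 1])
    total = profile.total_tags
    if total == 0:
        p = 1.0
    else:
        p = float(stats.binom.sf(k - 1, total, 1.0 / T))
    matches_1011 = site.alignment[9] == "m" and site.alignment[10] == "m"
    return DegradomeValidation(
        site=site,
        cleavage_position=pos,
        tags_at_site=k,
        total_tags=total,
        p_value=p,
        validated=bool(p <= alpha and matches_1011),
    )


def tplot_data(profile: DegradomeProfile, site: TargetSite) -> pd.DataFrame:
    """Per-position tag counts with the cleavage position marked (T-plot)."""
    if profile.total_tags == 0:
        return pd.DataFrame(columns=["position", "count", "cleavage_site"])
    pos = cleavage_position(site)
    nz = np.flatnonzero(profile.five_prime_counts)
    positions = sorted(set(nz + 1) | {pos})
    return pd.DataFrame(
        {
            "position": positions,
            "count": [int(profile.five_prime_counts[p - 1]) for p in positions],
            "cleavage_site": [p == pos for p in positions],
        }
    )
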