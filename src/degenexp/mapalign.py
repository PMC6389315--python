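"""Pairwise ordered-label map alignment and indel/overhang calling.

Dynamic-programming alignment of two label maps under a declared scoring
model: each matched label pair earns a fixed bonus minus a truncated squared
sizing error of the flanked inter-label intervals (in units of the sizing
standard deviation), each internally skipped label costs a penalty, and at
most ``max_skip`` labels may be skipped per step on either map.  End gaps
are free, which lets unaligned "overhangs" flank the alignment.  The sizing
cost is capped so that a single large indel (a huge interval discrepancy)
does not break the alignment chain in two.

Calls: for each pair of consecutive matched intervals whose lengths differ
by at least ``min_size`` (default 3 kb) one indel call is emitted — an
insertion if the query (b) interval is longer, a deletion if shorter.  The
call is localized to the flanking matched interval on the reference (B)
map; optical resolution does not localize breakpoints within intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labelmaps import LabelMap

__all__ = [
    "AlignParams",
    "MapAlignment",
    "IndelCall",
    "OverhangRecord",
    "align_label_maps",
    "score_matching",
    "call_indels",
    "call_overhangs",
    "reciprocal_consistency",
    "calls_to_frame",
    "overhangs_to_frame",
    "write_calls",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring model for label-map alignment.

    sizing_sd_bp
        Expected Gaussian sizing error of one inter-label interval.
    match_bonus
        Score earned per matched label pair (in squared-sd units).
    miss_penalty
        Cost per internally skipped label.
    cost_cap
        Upper bound on the squared sizing error of one matched interval;
        spanning a large indel costs at most this much.
    max_skip
        Maximum labels skipped per step on either map.
    """

    sizing_sd_bp: float = 150.0
    match_bonus: float = 6.0
    miss_penalty: float = 3.0
    cost_cap: float = 12.0
    max_skip: int = 3

    def __post_init__(self) -> None:
        if self.sizing_sd_bp <= 0 or self.max_skip < 0:
            raise ValueError("invalid alignment parameters")


@dataclass(frozen=True)
class MapAlignment:
    """A monotone, non-crossing matching between two label maps."""

    map_a: str
    map_b: str
    matched_pairs: tuple[tuple[int, int], ...]
    score: float
    unaligned_prefix_a: int = 0
    unaligned_suffix_a: int = 0
    unaligned_prefix_b: int = 0
    unaligned_suffix_b: int = 0

    def __post_init__(self) -> None:
        pairs = tuple(self.matched_pairs)
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            if not (i2 > i1 and j2 > j1):
                raise ValueError("matched pairs must strictly increase in both maps")
        if not np.isfinite(self.score):
            raise ValueError("alignment score must be finite")

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


@dataclass(frozen=True)
class IndelCall:
    chromosome: str
    start: int  # flanking matched interval on the reference (B) map, 0-based
    end: int  # half-open
    type: str  # "INS" | "DEL", relative to the reference sample
    size: int
    sample_pair: str = "b_vs_B"
    ref_labels: tuple[int, int] = (0, 0)  # flanking label indices, reference map
    qry_labels: tuple[int, int] = (0, 0)  # flanking label indices, query map

    def __post_init__(self) -> None:
        if self.type not in ("INS", "DEL"):
            raise ValueError("type must be INS or DEL")
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.size <= 0:
            raise ValueError("size must be positive")


@dataclass(frozen=True)
class OverhangRecord:
    chromosome: str
    alignment_id: str
    side: str  # "left" | "right"
    length: int  # bp
    sample: str  # sample carrying the excess: "B" | "b"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be left or right")
        if self.length <= 0:
            raise ValueError("overhang length must be positive")


def _interval_cost(delta: float, params: AlignParams) -> float:
    return min((delta / params.sizing_sd_bp) ** 2, params.cost_cap)


def score_matching(
    pairs: list[tuple[int, int]],
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    params: AlignParams,
) -> float:
    """Score of an explicit monotone matching under the declared model.

    Used both by the aligner's traceback check and by brute-force
    enumeration oracles.  Returns ``-inf`` if a step skips more than
    ``max_skip`` labels on either map.
    """
    if not pairs:
        return 0.0
    score = params.match_bonus
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 - i1 - 1 > params.max_skip or j2 - j1 - 1 > params.max_skip:
            return float("-inf")
        delta = (pos_b[j2] - pos_b[j1]) - (pos_a[i2] - pos_a[i1])
        score += (
            params.match_bonus
            - _interval_cost(float(delta), params)
            - params.miss_penalty * ((i2 - i1 - 1) + (j2 - j1 - 1))
        )
    return float(score)


def align_label_maps(
    map_a: LabelMap, map_b: LabelMap, params: AlignParams | None = None
) -> MapAlignment:
    """Globally optimal DP alignment with free end gaps.

    ``S[i, j]`` is the best score of any matching whose last matched pair is
    ``(i, j)``; predecessors range over a ``(max_skip+1)``-square window.
    Ties are broken toward fewer skipped labels, then toward the nearer
    (larger-index) predecessor — the first candidate encountered wins.
    """
    params = params or AlignParams()
    if map_a.n_labels < 2 or map_b.n_labels < 2:
        raise ValueError("maps need at least 2 labels to align")
    A = map_a.positions.astype(float)
    B = map_b.positions.astype(float)
    n, m = A.size, B.size
    w = params.max_skip + 1
    inv_sd2 = 1.0 / params.sizing_sd_bp**2

    S = np.full((n, m), params.match_bonus)
    back = np.full((n, m, 2), -1, dtype=np.int32)

    steps = sorted(
        ((di, dj) for di in range(1, w + 1) for dj in range(1, w + 1)),
        key=lambda t: (t[0] + t[1] - 2, t[0], t[1]),
    )
    for i in range(1, n):
        row = S[i]
        for di, dj in steps:
            pi = i - di
            if pi < 0 or m <= dj:
                continue
            dA = A[i] - A[pi]
            dB = B[dj:] - B[:-dj]  # length m-dj, query interval ending at j
            cost = np.minimum((dB - dA) ** 2 * inv_sd2, params.cost_cap)
            cand = (
                S[pi, : m - dj]
                + params.match_bonus
                - cost
                - params.miss_penalty * (di - 1 + dj - 1)
            )
            cur = row[dj:]
            better = cand > cur
            if better.any():
                idx = np.flatnonzero(better) + dj
                row[idx] = cand[better]
                back[i, idx, 0] = pi
                back[i, idx, 1] = idx - dj

    end = np.unravel_index(np.argmax(S), S.shape)
    pairs = []
    i, j = int(end[0]), int(end[1])
    while i >= 0:
        pairs.append((i, j))
        i, j = int(back[i, j, 0]), int(back[i, j, 1])
    pairs.reverse()

    (fi, fj), (li, lj) = pairs[0], pairs[-1]
    return MapAlignment(
        map_a=map_a.map_id,
        map_b=map_b.map_id,
        matched_pairs=tuple(pairs),
        score=float(S[end]),
        unaligned_prefix_a=int(A[fi]),
        unaligned_suffix_a=int(map_a.length - A[li]),
        unaligned_prefix_b=int(B[fj]),
        unaligned_suffix_b=int(map_b.length - B[lj]),
    )


def call_indels(
    alignment: MapAlignment,
    map_a: LabelMap,
    map_b: LabelMap,
    min_size: int = 3000,
    sample_pair: str = "b_vs_B",
) -> list[IndelCall]:
    """Indel calls from matched-interval length differences.

    ``map_a`` is the reference (B sample), ``map_b`` the query (b sample).
    Adjacent calls between consecutive matched pairs are not merged.
    """
    A, B = map_a.positions, map_b.positions
    calls = []
    pairs = alignment.matched_pairs
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        delta = int(B[j2] - B[j1]) - int(A[i2] - A[i1])
        if abs(delta) >= min_size:
            calls.append(
                IndelCall(
                    chromosome=map_a.chromosome,
                    start=int(A[i1]),
                    end=int(A[i2]),
                    type="INS" if delta > 0 else "DEL",
                    size=abs(delta),
                    sample_pair=sample_pair,
                    ref_labels=(i1, i2),
                    qry_labels=(j1, j2),
                )
            )
    return calls


def call_overhangs(
    alignment: MapAlignment,
    map_a: LabelMap,
    map_b: LabelMap,
    sample_a: str = "B",
    sample_b: str = "b",
    min_length: int = 1000,
) -> list[OverhangRecord]:
    """One record per unaligned flank (bp beyond the outermost matched label).

    Flanks shorter than ``min_length`` are below optical resolution and are
    not reported.
    """
    aln_id = f"{alignment.map_a}|{alignment.map_b}"
    spec = [
        ("left", alignment.unaligned_prefix_a, sample_a, map_a.chromosome),
        ("right", alignment.unaligned_suffix_a, sample_a, map_a.chromosome),
        ("left", alignment.unaligned_prefix_b, sample_b, map_b.chromosome),
        ("right", alignment.unaligned_suffix_b, sample_b, map_b.chromosome),
    ]
    return [
        OverhangRecord(chromosome=chrom, alignment_id=aln_id, side=side,
                       length=int(length), sample=sample)
        for side, length, sample, chrom in spec
        if length >= min_length
    ]


def _label_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def reciprocal_consistency(
    calls_ab: list[IndelCall], calls_ba: list[IndelCall]
) -> float:
    """Fraction of indel sites recovered in both alignment directions.

    ``calls_ab`` and ``calls_ba`` come from the same map pair with roles
    swapped.  A site is recovered when a call of opposite type in the other
    direction flanks an overlapping label interval on the shared map (the
    swap converts insertions into deletions).  Returns the fraction of all
    calls (both directions pooled) that are recovered.
    """
    if not calls_ab and not calls_ba:
        warnings.warn("both call sets empty; consistency defined as 1.0")
        return 1.0
    opposite = {"INS": "DEL", "DEL": "INS"}
    hit_ab = [
        any(
            c2.type == opposite[c1.type]
            and _label_overlap(c1.ref_labels, c2.qry_labels)
            for c2 in calls_ba
        )
        for c1 in calls_ab
    ]
    hit_ba = [
        any(
            c1.type == opposite[c2.type]
            and _label_overlap(c2.ref_labels, c1.qry_labels)
            for c1 in calls_ab
        )
        for c2 in calls_ba
    ]
    return (sum(hit_ab) + sum(hit_ba)) / (len(calls_ab) + len(calls_ba))


# -- tabular output ------------------------------------------------------

def calls_to_frame(calls: list[IndelCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chromosome, c.start, c.end, c.type, c.size, c.sample_pair)
            for c in calls
        ],
        columns=["chrom", "start", "end", "type", "size_bp", "sample"],
    )


def overhangs_to_frame(records: list[OverhangRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chromosome, r.alignment_id, r.side, r.length, r.sample) for r in records],
        columns=["chrom", "alignment_id", "side", "length_bp", "sample"],
    )


def write_calls(calls: list[IndelCall], path) -> None:
    """BED-like TSV; header comment names the 0-based half-open convention."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open, on the reference (B) map\n")
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)
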