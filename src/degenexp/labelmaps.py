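"""Ordered-label maps: a minimal stand-in for optical restriction maps.

A :class:`LabelMap` is an ordered list of label coordinates (bp) on one
contig or chromosome, plus the contig length.  Labels come either from exact
motif matches on a sequence (``digest_to_label_map``) or from a per-bp label
density when no sequence is materialised.  The noise model is the minimal
standard one for optical maps: Gaussian perturbation of inter-label
intervals, plus independent Bernoulli label loss and Poisson false labels.

Coordinates are 0-based, half-open.  TSV layout (one row per label):
``map_id  chromosome  label_index  position_bp  map_length_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabelMap",
    "digest_to_label_map",
    "labels_by_density",
    "noisy_copy",
    "transform_positions",
    "write_label_maps",
    "read_label_maps",
]


@dataclass(frozen=True)
class LabelMap:
    map_id: str
    chromosome: str  # chromosome id, or "unplaced"
    positions: np.ndarray  # strictly increasing, int bp
    length: int  # bp, >= last position + 1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size and (np.any(np.diff(pos) <= 0)):
            raise ValueError("label positions must be strictly increasing")
        if pos.size and (pos[0] < 0 or pos[-1] >= self.length):
            raise ValueError("label positions must lie in [0, length)")
        if self.length <= 0:
            raise ValueError("map length must be positive")

    @property
    def n_labels(self) -> int:
        return int(self.positions.size)


def _find_motif_positions(seq: str, motif: str) -> np.ndarray:
    """All (overlapping) start positions of ``motif`` in ``seq``."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return np.asarray(out, dtype=np.int64)


def digest_to_label_map(
    seq: str,
    motif: str,
    map_id: str = "map",
    chromosome: str = "unplaced",
    sizing_sd_bp: float = 0.0,
    miss_rate: float = 0.0,
    false_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> LabelMap:
    """In-silico labelling: exact motif matches, then optional map noise.

    With all noise parameters zero this returns the exact motif match
    positions.  Noise is applied by :func:`noisy_copy`.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    positions = _find_motif_positions(seq, motif)
    lmap = LabelMap(map_id, chromosome, positions, len(seq))
    if sizing_sd_bp == 0 and miss_rate == 0 and false_rate == 0:
        return lmap
    noisy, _ = noisy_copy(
        lmap, sizing_sd_bp=sizing_sd_bp, miss_rate=miss_rate,
        false_rate=false_rate, seed=seed,
    )
    return noisy


def labels_by_density(
    length: int,
    density: float,
    map_id: str = "map",
    chromosome: str = "unplaced",
    rng: np.random.Generator | int | None = None,
) -> LabelMap:
    """Uniform random labels at ``density`` labels per bp (Poisson count)."""
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(rng)
    n = rng.poisson(density * length)
    pos = np.unique(rng.integers(0, length, size=n))
    return LabelMap(map_id, chromosome, pos, length)


def noisy_copy(
    lmap: LabelMap,
    sizing_sd_bp: float = 0.0,
    miss_rate: float = 0.0,
    false_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    map_id: str | None = None,
) -> tuple[LabelMap, np.ndarray]:
    """Apply the three-parameter optical noise model to a map.

    Inter-label intervals (including the two flanks to the map ends) receive
    i.i.d. Gaussian perturbations of ``sizing_sd_bp``; each true label is
    lost independently with ``miss_rate``; false labels arrive as a Poisson
    count of mean ``false_rate`` x n_labels at uniform positions.

    Returns
    -------
    (noisy_map, origin)
        ``origin[i]`` is the index of the true label that produced noisy
        label ``i``, or -1 for a false label.  This is the truth pairing used
        by alignment-recovery tests.
    """
    for name, r in (("miss_rate", miss_rate), ("false_rate", false_rate)):
        if not 0 <= r <= 1 and name == "miss_rate":
            raise ValueError(f"{name} outside [0, 1]")
    if miss_rate < 0 or miss_rate > 1 or false_rate < 0:
        raise ValueError("rates outside valid range")
    rng = np.random.default_rng(seed)
    pos = lmap.positions.astype(float)
    n = pos.size

    keep = rng.random(n) >= miss_rate
    kept_idx = np.flatnonzero(keep)
    pos = pos[keep]

    # Perturb intervals between consecutive kept labels and to the map ends.
    if sizing_sd_bp > 0 and pos.size:
        bounds = np.concatenate([[0.0], pos, [float(lmap.length)]])
        ivals = np.diff(bounds)
        ivals = np.maximum(1.0, ivals + rng.normal(0.0, sizing_sd_bp, ivals.size))
        new_len = ivals.sum()
        pos = np.cumsum(ivals)[:-1]
        length = int(round(new_len))
    else:
        length = lmap.length

    origin = kept_idx.astype(np.int64)

    n_false = rng.poisson(false_rate * n)
    if n_false:
        fpos = rng.uniform(0, length, size=n_false)
        pos = np.concatenate([pos, fpos])
        origin = np.concatenate([origin, np.full(n_false, -1, dtype=np.int64)])

    order = np.argsort(pos, kind="stable")
    pos, origin = pos[order], origin[order]
    ipos = np.round(pos).astype(np.int64)
    # enforce strict monotonicity after rounding
    for i in range(1, ipos.size):
        if ipos[i] <= ipos[i - 1]:
            ipos[i] = ipos[i - 1] + 1
    length = max(length, (int(ipos[-1]) + 1) if ipos.size else 1)
    noisy = LabelMap(
        map_id or f"{lmap.map_id}.noisy", lmap.chromosome, ipos, length
    )
    return noisy, origin


def transform_positions(
    positions: np.ndarray, truth: pd.DataFrame, chromosome: str, length: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map reference-coordinate label positions through a set of indel edits.

    ``truth`` is a truth table with columns ``chromosome, start, end, type,
    size`` in reference (B) coordinates: insertions are zero-width anchors
    (``start == end``) gaining ``size`` bp in the edited genome; deletions
    remove ``[start, end)``.  Labels inside deleted spans are dropped;
    surviving labels are shifted by the net offset of edits to their left.

    Returns the transformed positions, the surviving original indices, and
    the edited chromosome length.
    """
    sub = truth[truth["chromosome"] == chromosome]
    pos = np.asarray(positions, dtype=np.int64)
    offset = np.zeros(pos.size, dtype=np.int64)
    keep = np.ones(pos.size, dtype=bool)
    net = 0
    for row in sub.itertuples():
        size = int(row.size)
        if row.type == "INS":
            offset[pos >= row.start] += size
            net += size
        else:
            inside = (pos >= row.start) & (pos < row.end)
            keep &= ~inside
            offset[pos >= row.end] -= size
            net -= size
    new_pos = (pos + offset)[keep]
    idx = np.flatnonzero(keep)
    order = np.argsort(new_pos, kind="stable")
    return new_pos[order], idx[order], length + net


# -- TSV round trip ------------------------------------------------------

def write_label_maps(maps: list[LabelMap], path) -> None:
    """Write maps as TSV; coordinates 0-based half-open."""
    rows = []
    for m in maps:
        for i, p in enumerate(m.positions):
            rows.append((m.map_id, m.chromosome, i, int(p), m.length))
        if m.n_labels == 0:  # keep empty maps representable
            rows.append((m.map_id, m.chromosome, -1, -1, m.length))
    df = pd.DataFrame(
        rows,
        columns=["map_id", "chromosome", "label_index", "position_bp", "map_length_bp"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_label_maps(path) -> list[LabelMap]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (map_id, chrom, length), grp in df.groupby(
        ["map_id", "chromosome", "map_length_bp"], sort=False
    ):
        pos = grp.loc[grp["label_index"] >= 0, "position_bp"].to_numpy(np.int64)
        out.append(LabelMap(str(map_id), str(chrom), np.sort(pos), int(length)))
    return out
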