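"""Presence/absence indel matrices, distances, and neighbor-joining trees.

Six haploid individuals (three species, one B and one b variant each) are
scored for presence or absence of large indels.  A locus is retained only
if it is present in at least two individuals and covered (informative) in
all individuals.  Loci are split into a background partition (chromosomes
1-15 plus the non-supergene part of the social chromosome) and a supergene
partition; trees are inferred separately for each.  The expected pattern
under a single shared origin of the supergene: background trees group
samples by species, supergene trees group them by variant.

Tree inference is neighbor joining (scikit-bio); grouping is assessed with
an unrooted "clan" test — a set of leaves is a clan if one edge separates
it from all other leaves (the unrooted analogue of monophyly; no outgroup
is available in-system).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .chromosomes import ChromosomeTable

__all__ = [
    "IndelMatrix",
    "TreeResult",
    "build_matrix",
    "apply_coverage",
    "filter_matrix",
    "split_partitions",
    "distance_matrix",
    "infer_tree",
    "is_clan",
    "grouping_test",
]


@dataclass(frozen=True)
class IndelMatrix:
    """Presence/absence matrix plus locus metadata.

    values: sample x locus, entries in {0, 1} (after filtering) or -1 for
    missing coverage (before filtering).  loci: per-locus metadata with at
    least ``locus, chromosome, start, end``.
    """

    values: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.loci["locus"]):
            raise ValueError("values columns must match loci order")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TreeResult:
    newick: str
    partition: str  # "background" | "supergene"
    tree: TreeNode
    grouping: dict[str, bool | None]  # group label -> clan?


def _merge_intervals(
    frames: dict[str, pd.DataFrame], min_reciprocal_overlap: float
) -> pd.DataFrame:
    """Cluster per-individual calls into loci by reciprocal overlap.

    Calls of the same type on the same chromosome are merged transitively
    when each covers at least ``min_reciprocal_overlap`` of the other.
    Returns one row per (individual call) with its assigned locus id.
    """
    rows = []
    for sample, df in frames.items():
        col = "chromosome" if "chromosome" in df.columns else "chrom"
        for r in df.itertuples():
            rows.append((sample, getattr(r, col), int(r.start), int(r.end), r.type))
    calls = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "type"])
    calls = calls.sort_values(["chromosome", "type", "start"], kind="stable").reset_index(drop=True)

    locus_ids = np.full(len(calls), -1, dtype=int)
    next_id = 0
    for (_, _), grp in calls.groupby(["chromosome", "type"], sort=False):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cluster_start, cluster_end = None, None
        for k, i in enumerate(idx):
            s, e = starts[k], ends[k]
            if cluster_start is not None:
                ov = min(e, cluster_end) - max(s, cluster_start)
                ok = (
                    ov > 0
                    and ov >= min_reciprocal_overlap * (e - s)
                    and ov >= min_reciprocal_overlap * (cluster_end - cluster_start)
                )
            else:
                ok = False
            if not ok:
                next_id += 1
                cluster_start, cluster_end = s, e
            else:
                cluster_start = min(cluster_start, s)
                cluster_end = max(cluster_end, e)
            locus_ids[i] = next_id - 1
    calls["locus_id"] = locus_ids
    return calls


def build_matrix(
    call_sets: dict[str, pd.DataFrame],
    coverage_masks: dict[str, pd.DataFrame] | None,
    chrom_table: ChromosomeTable,
    min_reciprocal_overlap: float = 0.5,
) -> IndelMatrix:
    """Merge per-individual calls into loci and score presence/absence.

    ``coverage_masks`` maps each sample to a BED-like frame of covered
    intervals (``chromosome, start, end``); a locus is missing (-1) for a
    sample whose coverage does not span the locus interval.  With ``None``
    every locus is treated as covered everywhere.  The result is unfiltered;
    apply :func:`filter_matrix` for the shared-in->=2 / covered-in-all rule.
    """
    if len(call_sets) < 2:
        raise ValueError("need calls from at least two individuals")
    samples = list(call_sets)
    assigned = _merge_intervals(call_sets, min_reciprocal_overlap)
    loci_rows = []
    for lid, grp in assigned.groupby("locus_id", sort=True):
        loci_rows.append(
            (
                f"locus{lid:05d}",
                grp["chromosome"].iloc[0],
                int(grp["start"].min()),
                int(grp["end"].max()),
                grp["type"].iloc[0],
            )
        )
    loci = pd.DataFrame(loci_rows, columns=["locus", "chromosome", "start", "end", "type"])

    values = pd.DataFrame(
        0, index=samples, columns=loci["locus"], dtype=np.int8
    )
    for (sample, lid) in assigned[["sample", "locus_id"]].itertuples(index=False):
        values.loc[sample, f"locus{lid:05d}"] = 1

    if coverage_masks is not None:
        for sample in samples:
            cov = coverage_masks[sample]
            col = "chromosome" if "chromosome" in cov.columns else "chrom"
            for li, locus in loci.iterrows():
                sub = cov[(cov[col] == locus["chromosome"])
                          & (cov["start"] <= locus["start"])
                          & (cov["end"] >= locus["end"])]
                if sub.empty and values.loc[sample, locus["locus"]] == 0:
                    values.loc[sample, locus["locus"]] = -1
    return IndelMatrix(values=values, loci=loci)


def filter_matrix(matrix: IndelMatrix) -> IndelMatrix:
    """Retain loci present in >=2 individuals and covered in all individuals.

    Idempotent.  Returns an explicit empty matrix when nothing survives.
    """
    v = matrix.values
    covered_all = (v >= 0).all(axis=0)
    shared = (v == 1).sum(axis=0) >= 2
    keep = covered_all & shared
    kept = v.loc[:, keep]
    loci = matrix.loci[matrix.loci["locus"].isin(kept.columns)].reset_index(drop=True)
    return IndelMatrix(values=kept, loci=loci)


def apply_coverage(values: pd.DataFrame, covered: pd.DataFrame) -> pd.DataFrame:
    """Mark uncovered cells as missing (-1) in a planted matrix."""
    out = values.astype(np.int8).copy()
    out[~covered] = -1
    return out


def split_partitions(
    matrix: IndelMatrix, chrom_table: ChromosomeTable
) -> tuple[IndelMatrix, IndelMatrix]:
    """Split loci into (background, supergene) by the supergene interval.

    A locus belongs to the supergene partition iff it lies on the social
    chromosome and overlaps the supergene interval.
    """
    s, e = chrom_table.supergene_interval
    in_sg = (
        (matrix.loci["chromosome"] == chrom_table.social)
        & (matrix.loci["start"] < e)
        & (matrix.loci["end"] > s)
    ).to_numpy()
    bg_loci = matrix.loci[~in_sg].reset_index(drop=True)
    sg_loci = matrix.loci[in_sg].reset_index(drop=True)
    return (
        IndelMatrix(matrix.values.loc[:, bg_loci["locus"]], bg_loci),
        IndelMatrix(matrix.values.loc[:, sg_loci["locus"]], sg_loci),
    )


def distance_matrix(matrix: IndelMatrix, metric: str = "hamming") -> DistanceMatrix:
    """Pairwise sample distances over loci (no missing values allowed).

    ``hamming``: count of differing loci (absence is informative because
    coverage is guaranteed by the filter).  ``jaccard``: 1 - shared-presence
    over union-presence.
    """
    v = matrix.values.to_numpy()
    if (v < 0).any():
        raise ValueError("missing values present; filter the matrix first")
    n = v.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "hamming":
                dij = float(np.sum(v[i] != v[j]))
            elif metric == "jaccard":
                union = np.sum((v[i] == 1) | (v[j] == 1))
                inter = np.sum((v[i] == 1) & (v[j] == 1))
                dij = 0.0 if union == 0 else 1.0 - inter / union
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids=matrix.samples)


def is_clan(tree: TreeNode, tips: set[str]) -> bool:
    """True if one edge of the unrooted tree separates ``tips`` from the rest."""
    all_tips = {t.name for t in tree.tips()}
    if not tips <= all_tips:
        raise ValueError("tips not all present in tree")
    if len(tips) in (0, len(all_tips)):
        return True
    if len(tips) == 1 or len(all_tips) - len(tips) == 1:
        return True  # single leaves always hang off one edge
    for node in tree.non_tips(include_self=True):
        sub = {t.name for t in node.tips()}
        if sub == tips or (all_tips - sub) == tips:
            return True
    return False


def grouping_test(tree: TreeNode, groups: dict[str, set[str]]) -> dict[str, bool | None]:
    """Clan status per named leaf group; None when distances were degenerate."""
    out: dict[str, bool | None] = {}
    for name, tips in groups.items():
        out[name] = is_clan(tree, tips)
    return out


def infer_tree(
    dm: DistanceMatrix,
    partition: str = "background",
    groups: dict[str, set[str]] | None = None,
) -> TreeResult:
    """Neighbor-joining tree plus clan tests for the given leaf groups.

    Degenerate all-zero distances yield a star tree and indeterminate
    (``None``) grouping outcomes.
    """
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    ids = list(dm.ids)
    if np.allclose(dm.data, 0):
        newick = "(" + ",".join(f"{i}:0.0" for i in ids) + ");"
        tree = TreeNode.read([newick])
        grouping = {name: None for name in (groups or {})}
        return TreeResult(newick=newick, partition=partition, tree=tree,
                          grouping=grouping)
    tree = nj(dm)
    newick = str(tree).strip()
    grouping = grouping_test(tree, groups or {})
    return TreeResult(newick=newick, partition=partition, tree=tree, grouping=grouping)
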