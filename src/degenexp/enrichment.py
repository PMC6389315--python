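"""Enrichment and length-accounting statistics for large indels.

Given per-chromosome indel counts and a chromosome table, this module tests
homogeneity of the counts against expectations proportional to chromosome
length (Pearson chi-square, df = n_chromosomes - 1), standardizes each
chromosome's excess as the Pearson residual Z = (O - E)/sqrt(E) with a
one-sided upper-tail normal p-value and Bonferroni correction, accounts for
cumulative indel length shares, nets out overhang-based length differences,
and converts variant-length pairs into percent expansion estimates.

The Pearson identity chi2 = sum(Z_i^2) holds exactly and is tested to 1e-9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chromosomes import ChromosomeTable

__all__ = [
    "EnrichmentResult",
    "ExpansionEstimate",
    "counts_by_chromosome",
    "chisq_homogeneity",
    "enrichment_zscores",
    "cumulative_length_shares",
    "net_overhang_difference",
    "expansion_from_lengths",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Chi-square homogeneity plus per-chromosome standardized residuals."""

    chromosomes: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    z: np.ndarray
    p_raw: np.ndarray  # one-sided upper-tail normal
    p_bonferroni: np.ndarray
    n_total: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        """Chromosomes enriched at Bonferroni-corrected ``alpha``."""
        return [
            c for c, p in zip(self.chromosomes, self.p_bonferroni) if p < alpha
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosomes,
                "observed": self.observed,
                "expected": self.expected,
                "z": self.z,
                "p_raw": self.p_raw,
                "p_bonferroni": self.p_bonferroni,
            }
        )


@dataclass(frozen=True)
class ExpansionEstimate:
    """Percent size increase of the b supergene variant over the B variant."""

    sb_length: float  # B-variant length, bp (or the normalizing quantity)
    sbvariant_length: float  # b-variant length, bp
    percent_increase: float
    method: str  # lengths | overhangs | genome_size | repeats
    ci95: tuple[float, float] | None = None

    @property
    def rounded(self) -> float:
        return round(self.percent_increase, 1)


def counts_by_chromosome(
    calls: pd.DataFrame, table: ChromosomeTable, indel_type: str | None = None
) -> np.ndarray:
    """Per-chromosome call counts in table order; unplaced calls excluded."""
    df = calls
    if indel_type is not None:
        df = df[df["type"] == indel_type]
    col = "chromosome" if "chromosome" in df.columns else "chrom"
    vc = df[col].value_counts()
    return np.array([int(vc.get(c, 0)) for c in table.names])


def _expected(counts: np.ndarray, table: ChromosomeTable) -> np.ndarray:
    n_total = counts.sum()
    lengths = table.lengths_array()
    E = n_total * lengths / lengths.sum()
    if np.any(E == 0):
        raise ValueError("zero expected count: empty chromosome in table")
    if np.any(E < 5):
        warnings.warn(
            "expected counts < 5; chi-square approximation is rough",
            stacklevel=3,
        )
    return E


def chisq_homogeneity(
    counts: np.ndarray | list[int], table: ChromosomeTable
) -> EnrichmentResult:
    """Pearson chi-square of counts against length-proportional expectation."""
    return enrichment_zscores(counts, table)


def enrichment_zscores(
    counts: np.ndarray | list[int],
    table: ChromosomeTable,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Chi-square homogeneity and per-chromosome enrichment Z-scores.

    Z_i = (O_i - E_i)/sqrt(E_i) with E_i proportional to chromosome length;
    chi2 = sum(Z_i^2) with df = n_chromosomes - 1; one-sided upper-tail
    normal p per chromosome, Bonferroni-corrected by the chromosome count.
    """
    O = np.asarray(counts, dtype=float)
    if O.size != len(table):
        raise ValueError("counts length != number of chromosomes")
    if O.sum() <= 0:
        raise ValueError("no calls to test")
    E = _expected(O, table)
    z = (O - E) / np.sqrt(E)
    chi2 = float(np.sum(z**2))
    df = len(table) - 1
    p = float(stats.chi2.sf(chi2, df))
    p_raw = stats.norm.sf(z)
    p_bonf = np.minimum(1.0, p_raw * len(table))
    return EnrichmentResult(
        chromosomes=table.names,
        observed=O.astype(int),
        expected=E,
        chi2=chi2,
        df=df,
        p=p,
        z=z,
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        n_total=int(O.sum()),
    )


def cumulative_length_shares(
    calls: pd.DataFrame, table: ChromosomeTable
) -> pd.DataFrame:
    """Per-chromosome count, cumulative bp, and % of total bp, per indel type.

    Shares sum to 100% across chromosomes within each type.  Calls on
    chromosomes absent from the table (unplaced maps) are excluded.
    """
    col = "chromosome" if "chromosome" in calls.columns else "chrom"
    size_col = "size" if "size" in calls.columns else "size_bp"
    placed = calls[calls[col].isin(table.names)]
    out = []
    for t, grp in placed.groupby("type"):
        agg = grp.groupby(col)[size_col].agg(["count", "sum"])
        total = agg["sum"].sum()
        for chrom in table.names:
            cnt = int(agg["count"].get(chrom, 0))
            bp = int(agg["sum"].get(chrom, 0))
            out.append(
                (chrom, t, cnt, bp, 100.0 * bp / total if total else 0.0)
            )
    return pd.DataFrame(
        out, columns=["chromosome", "type", "count", "cum_bp", "share_pct"]
    )


def net_overhang_difference(
    overhangs: pd.DataFrame,
    table: ChromosomeTable,
    sample_b: str = "b",
    sample_B: str = "B",
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome net overhang excess in the b sample, plus a test.

    ``net_i = sum(b overhang bp) - sum(B overhang bp)`` per chromosome.  As
    a homogeneity test we use a 2 x n_chromosomes contingency chi-square on
    the per-sample overhang bp totals (net values can be negative and cannot
    enter a plain chi-square directly).

    Returns ``(frame, chi2, p)`` where the frame has one row per chromosome.
    """
    col = "chromosome" if "chromosome" in overhangs.columns else "chrom"
    len_col = "length_bp" if "length_bp" in overhangs.columns else "length"
    rows = []
    for chrom in table.names:
        sub = overhangs[overhangs[col] == chrom]
        b_bp = int(sub.loc[sub["sample"] == sample_b, len_col].sum())
        B_bp = int(sub.loc[sub["sample"] == sample_B, len_col].sum())
        rows.append((chrom, b_bp, B_bp, b_bp - B_bp))
    frame = pd.DataFrame(rows, columns=["chromosome", "b_bp", "B_bp", "net_bp"])
    tab = frame[["b_bp", "B_bp"]].to_numpy().T
    keep = tab.sum(axis=0) > 0
    if keep.sum() >= 2 and (tab.sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tab[:, keep])
    else:
        chi2, p = 0.0, 1.0
    return frame, float(chi2), float(p)


def expansion_from_lengths(len_sb: float, len_sbvariant: float) -> ExpansionEstimate:
    """Percent increase of the b-variant length over the B-variant length."""
    if len_sb <= 0 or len_sbvariant <= 0:
        raise ValueError("lengths must be positive")
    pct = 100.0 * (len_sbvariant / len_sb - 1.0)
    return ExpansionEstimate(
        sb_length=float(len_sb),
        sbvariant_length=float(len_sbvariant),
        percent_increase=pct,
        method="lengths",
    )
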