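"""K-mer spectra, genome-size and repeat-fraction estimation, B/b pairing.

The estimator is the standard peak-normalized k-mer-mass method for haploid
samples: canonical 21-mers are counted from reads; multiplicities at or
below the first local minimum of the histogram are treated as sequencing
errors; the sequencing depth ``lambda`` is the count-weighted mean
multiplicity in a window around the histogram mode above that cutoff; and

    genome_size = (sum of m * count_m over m > cutoff) / lambda.

The repeat fraction is the share of that k-mer mass lying above
``r * lambda`` (default r = 1.5): in a haploid sample single-copy sequence
sits at the depth peak, so mass well above it comes from multi-copy
(repetitive) sequence.  Haploid males have no heterozygosity mixture, so no
multi-peak model fitting is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ExpansionEstimate
from .synthetic import ReadSet

__all__ = [
    "KmerHistogram",
    "GenomeSizeEstimate",
    "PairedDifference",
    "count_kmers",
    "build_histogram",
    "estimate_genome_size",
    "paired_comparison",
    "expansion_from_genome_diff",
    "expansion_from_repeat_excess",
    "write_histogram",
    "read_histogram",
]


@dataclass(frozen=True)
class KmerHistogram:
    """Multiplicity spectrum: distinct-k-mer counts per multiplicity."""

    k: int
    multiplicity: np.ndarray  # >= 1, increasing
    count: np.ndarray  # distinct k-mers at that multiplicity
    n_skipped: int = 0  # k-mers dropped for non-ACGT characters

    def __post_init__(self) -> None:
        m = np.asarray(self.multiplicity, dtype=np.int64)
        c = np.asarray(self.count, dtype=np.int64)
        object.__setattr__(self, "multiplicity", m)
        object.__setattr__(self, "count", c)
        if np.any(c < 0) or np.any(m < 1):
            raise ValueError("invalid histogram")

    @property
    def total_kmers(self) -> int:
        """Total k-mer mass: sum of multiplicity x count."""
        return int(np.sum(self.multiplicity * self.count))

    def dense(self) -> np.ndarray:
        """counts indexed by multiplicity (index 0 unused)."""
        out = np.zeros(int(self.multiplicity.max()) + 1 if self.multiplicity.size else 1,
                       dtype=np.int64)
        out[self.multiplicity] = self.count
        return out


@dataclass(frozen=True)
class GenomeSizeEstimate:
    genome_size: float  # bp
    coverage_peak: int  # modal multiplicity of the homozygous peak
    depth: float  # refined lambda used as the normalizer
    error_cutoff: int  # multiplicities <= cutoff treated as errors
    repeat_fraction: float
    sample: str = ""
    variant: str = ""  # "B" | "b"

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if not 0 <= self.repeat_fraction <= 1:
            raise ValueError("repeat_fraction outside [0, 1]")
        if self.error_cutoff >= self.coverage_peak:
            raise ValueError("error_cutoff must be below the coverage peak")


@dataclass(frozen=True)
class PairedDifference:
    """Paired b-vs-B percent differences with t-based CI and one-sided test."""

    per_pair_pct: np.ndarray
    mean_pct: float
    ci95: tuple[float, float]
    t_stat: float
    p_one_sided: float
    n_pairs: int


# -- counting ------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def count_kmers(seqs: list[str], k: int = 21) -> tuple[np.ndarray, np.ndarray, int]:
    """Canonical k-mer codes and their counts across a list of sequences.

    Sequences are concatenated with an invalid separator so windows never
    cross read boundaries; windows containing non-ACGT characters are
    skipped.  Canonicalization takes the lexicographic minimum of the 2-bit
    encoding of the forward k-mer and its reverse complement (k <= 31).

    Returns ``(codes, counts, n_skipped)`` for distinct canonical k-mers.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    if not seqs:
        return np.empty(0, np.uint64), np.empty(0, np.int64), 0
    blob = ("\x00".join(seqs)).encode("latin1")
    arr = _CODE[np.frombuffer(blob, dtype=np.uint8)]
    n = arr.size
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, np.int64), 0

    bad = (arr > 3).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0  # window [i, i+k) has no bad base

    a = np.where(arr > 3, 0, arr).astype(np.uint64)
    nw = n - k + 1
    fwd = np.zeros(nw, dtype=np.uint64)
    rev = np.zeros(nw, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | a[j : j + nw]
        # complement base appended in reverse order builds the rc code
        rev = (rev << two) | (np.uint64(3) - a[k - 1 - j : k - 1 - j + nw])
    canon = np.minimum(fwd, rev)[valid]
    # skipped = within-read windows lost to non-ACGT characters (separator
    # windows between reads are not within any read and do not count)
    expected = sum(max(0, len(s) - k + 1) for s in seqs)
    n_skipped = expected - int(valid.sum())
    codes, counts = np.unique(canon, return_counts=True)
    return codes, counts.astype(np.int64), n_skipped


def build_histogram(reads: ReadSet | list[str], k: int = 21,
                    max_multiplicity: int = 10_000) -> KmerHistogram:
    """Multiplicity histogram of canonical k-mers from a read set.

    Multiplicities above ``max_multiplicity`` are pooled into the top bin.
    When reads are pure ACGT, total mass equals
    ``sum(len(read) - k + 1)`` exactly.
    """
    seqs = reads.reads if isinstance(reads, ReadSet) else reads
    _, counts, n_skipped = count_kmers(seqs, k)
    if counts.size == 0:
        return KmerHistogram(k, np.empty(0, np.int64), np.empty(0, np.int64), n_skipped)
    # k-mers above the cap are pooled into the top bin (their mass is then
    # accounted at the cap; conservation is exact whenever nothing is capped)
    capped = np.minimum(counts, max_multiplicity)
    hist = np.bincount(capped)
    mult = np.flatnonzero(hist[1:]) + 1
    return KmerHistogram(k, mult, hist[mult], n_skipped)


# -- estimation ----------------------------------------------------------

def _first_local_minimum(dense: np.ndarray) -> int:
    """Smallest multiplicity m with count(m) <= count(m+1): the error valley.

    Returns 0 when the histogram starts rising (no error component).
    """
    nz = np.flatnonzero(dense[1:]) + 1
    if nz.size == 0:
        return 0
    start = nz[0]
    for m in range(start, len(dense) - 1):
        if dense[m] <= dense[m + 1]:
            return m if m > start or dense[m] < dense[m - 1] or True else 0
    return 0


def estimate_genome_size(
    hist: KmerHistogram,
    repeat_threshold: float = 1.5,
    sample: str = "",
    variant: str = "",
) -> GenomeSizeEstimate:
    """Peak-normalized genome size and repeat fraction from a k-mer spectrum.

    error_cutoff: bottom of the initial descent of the histogram (0 when
    there is no error component).  The normalizing depth is the
    count-weighted mean multiplicity of the single-copy peak — all mass
    between the cutoff and 1.5 x the modal multiplicity.  genome_size is
    the k-mer mass above the cutoff divided by the depth; repeat_fraction
    is the mass share above ``repeat_threshold * depth``.
    """
    dense = hist.dense()
    if dense.sum() == 0:
        raise ValueError("empty histogram")
    nz = np.flatnonzero(dense[1:]) + 1
    start = int(nz[0])
    # Error component: a cluster starting at multiplicity 1-2.  Walk down its
    # initial descent; the bottom is the error cutoff.  A spectrum that never
    # rises again has no detectable coverage peak.
    if start <= 2:
        m = start
        while m + 1 < len(dense) and dense[m + 1] < dense[m]:
            m += 1
        cutoff = m
        if m + 1 >= len(dense) or dense[cutoff + 1 :].max() == 0:
            raise ValueError(
                "no coverage peak detectable above the error component; "
                "deeper coverage needed"
            )
    else:
        cutoff = 0
    mult = np.arange(len(dense))
    above = mult > cutoff
    if not np.any(above & (dense > 0)):
        raise ValueError("no k-mer mass above the error cutoff")
    mode = int(np.argmax(np.where(above, dense, 0)))
    # depth = count-weighted mean multiplicity of the single-copy peak:
    # all mass between the error cutoff and 1.5 x mode (multi-copy k-mers
    # sit at >= 2x depth and are excluded; robust to the +-1 mode jitter)
    hi = min(len(dense) - 1, int(np.ceil(1.5 * mode)))
    win = slice(cutoff + 1, hi + 1)
    wc = dense[win].astype(float)
    if wc.sum() == 0:
        raise ValueError("degenerate histogram peak")
    depth = float(np.sum(mult[win] * wc) / wc.sum())
    mass = float(np.sum(mult[above] * dense[above]))
    genome_size = mass / depth
    rep_mask = mult > repeat_threshold * depth
    repeat_mass = float(np.sum(mult[rep_mask & above] * dense[rep_mask & above]))
    return GenomeSizeEstimate(
        genome_size=genome_size,
        coverage_peak=mode,
        depth=depth,
        error_cutoff=cutoff,
        repeat_fraction=repeat_mass / mass,
        sample=sample,
        variant=variant,
    )


# -- paired comparison and propagation ----------------------------------

def paired_comparison(pairs: list[tuple[float, float]]) -> PairedDifference:
    """Paired b-vs-B percent differences: mean, 95% t-CI, one-sided t-test.

    Each pair is ``(B_value, b_value)``; the per-pair statistic is
    ``100 * (b - B)/B``.  The test alternative is b > B.  Degenerate
    zero-variance input: the CI collapses to the mean and p is 0.5 at mean 0
    (boundary), 0 for a positive mean, 1 for a negative mean.
    """
    clean = [(b0, b1) for b0, b1 in pairs if np.isfinite(b0) and np.isfinite(b1)]
    if len(clean) < len(pairs):
        import warnings

        warnings.warn(f"dropped {len(pairs) - len(clean)} incomplete pairs")
    if len(clean) < 2:
        raise ValueError("need >= 2 complete pairs")
    arr = np.asarray(clean, dtype=float)
    pct = 100.0 * (arr[:, 1] - arr[:, 0]) / arr[:, 0]
    n = pct.size
    mean = float(pct.mean())
    sd = float(pct.std(ddof=1))
    if sd == 0.0:
        p = 0.5 if mean == 0 else (0.0 if mean > 0 else 1.0)
        return PairedDifference(pct, mean, (mean, mean), 0.0, p, n)
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    t_stat = mean / sem
    p = float(stats.t.sf(t_stat, n - 1))
    return PairedDifference(
        per_pair_pct=pct,
        mean_pct=mean,
        ci95=(mean - tcrit * sem, mean + tcrit * sem),
        t_stat=float(t_stat),
        p_one_sided=p,
        n_pairs=n,
    )


def expansion_from_genome_diff(
    mean_pct: float,
    ci: tuple[float, float] | None = None,
    supergene_fraction: float = 0.045,
) -> ExpansionEstimate:
    """Propagate a whole-genome percent difference to supergene expansion.

    Assumes the entire genome-size difference lies in the supergene, which
    occupies ``supergene_fraction`` of the B genome; the same transform
    (division by the fraction) applies to the CI bounds.
    """
    if not 0 < supergene_fraction < 1:
        raise ValueError("supergene_fraction must be in (0, 1)")
    pct = mean_pct / supergene_fraction
    ci_out = None
    if ci is not None:
        ci_out = (ci[0] / supergene_fraction, ci[1] / supergene_fraction)
    return ExpansionEstimate(
        sb_length=supergene_fraction,
        sbvariant_length=supergene_fraction * (1 + pct / 100.0),
        percent_increase=pct,
        method="genome_size",
        ci95=ci_out,
    )


def expansion_from_repeat_excess(
    excess_bp: float, supergene_len_bp: float = 20.9e6
) -> ExpansionEstimate:
    """Supergene expansion implied by excess repeat content in b samples."""
    if supergene_len_bp <= 0:
        raise ValueError("supergene length must be positive")
    pct = 100.0 * excess_bp / supergene_len_bp
    return ExpansionEstimate(
        sb_length=supergene_len_bp,
        sbvariant_length=supergene_len_bp + excess_bp,
        percent_increase=pct,
        method="repeats",
    )


# -- histogram TSV (two columns: multiplicity, count) --------------------

def write_histogram(hist: KmerHistogram, path) -> None:
    pd.DataFrame(
        {"multiplicity": hist.multiplicity, "count": hist.count}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_histogram(path, k: int = 21) -> KmerHistogram:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["multiplicity", "count"])
    return KmerHistogram(
        k, df["multiplicity"].to_numpy(np.int64), df["count"].to_numpy(np.int64)
    )
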