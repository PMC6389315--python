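"""Synthetic inputs with the statistical structure the analyses assume.

This module fabricates every input the pipeline consumes: paired B/b genomes
that differ by planted large indels (with insertions biased into a supergene
interval), tandem-repeat families whose copy number differs between the two
samples, short-read sets for k-mer spectra, and six-individual
presence/absence indel matrices in which supergene loci cluster by variant
and background loci cluster by species.

All coordinates are 0-based half-open; all generators are deterministic
under a fixed seed; every planted indel respects a 3 kb size floor (the
detection threshold used downstream).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromosomes import ChromosomeTable, fire_ant_table

__all__ = [
    "RepeatFamily",
    "SyntheticGenomeSpec",
    "ReadSet",
    "plan_indels",
    "generate_genome_pair",
    "apply_truth_table",
    "simulate_reads",
    "generate_indel_matrix",
    "default_insertion_bias",
    "write_fasta",
    "write_fastq",
    "write_truth_table",
]

MIN_INDEL_BP = 3000  # detection floor for large structural differences

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def default_insertion_bias(table: ChromosomeTable, social_share: float = 0.337) -> float:
    """Supergene placement bias matching an observed social-chromosome share.

    With bias ``b`` an insertion is forced into the supergene interval;
    otherwise it falls length-uniformly anywhere.  The expected fraction on
    the social chromosome is ``b + (1 - b) * social_len/total``; solving for
    the observed share (default 33.7%) gives the bias.
    """
    f = table.social_share()
    return (social_share - f) / (1.0 - f)


@dataclass(frozen=True)
class RepeatFamily:
    """A tandem array with per-sample copy number.

    The B genome carries ``copies_B`` adjacent copies of a random unit; the b
    genome carries ``copies_b``.  Copy-number differences are recorded in the
    truth table as indels at the array locus, so B/b genome-size differences
    are concentrated in repeats.
    """

    unit_length: int
    copies_B: int
    copies_b: int
    chromosome: str | None = None  # None: random placement by length

    def __post_init__(self) -> None:
        if self.unit_length <= 0 or self.copies_B < 0 or self.copies_b < 0:
            raise ValueError("invalid repeat family")
        delta = abs(self.copies_b - self.copies_B) * self.unit_length
        if 0 < delta < MIN_INDEL_BP:
            raise ValueError(
                f"repeat copy-number difference {delta} bp below the "
                f"{MIN_INDEL_BP} bp indel floor"
            )


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a planted B/b genome pair.

    ``insertion_bias`` is the fraction of planted insertions forced inside
    the supergene interval; the remainder (and all deletions) are placed
    length-uniformly across chromosomes.  Indel sizes are log-uniform on
    ``indel_size_range`` (the empirical size law is unknown; this default is
    configurable).
    """

    chrom_table: ChromosomeTable
    n_insertions: int = 163
    n_deletions: int = 187
    insertion_bias: float | None = None  # None: matched to a 33.7% social share
    indel_size_range: tuple[int, int] = (MIN_INDEL_BP, 100_000)
    repeat_families: tuple[RepeatFamily, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.indel_size_range
        if lo < MIN_INDEL_BP:
            raise ValueError(f"indel sizes must be >= {MIN_INDEL_BP} bp")
        if hi < lo:
            raise ValueError("empty indel size range")
        if self.insertion_bias is not None and not 0 <= self.insertion_bias <= 1:
            raise ValueError("insertion_bias outside [0, 1]")
        if self.n_insertions < 0 or self.n_deletions < 0:
            raise ValueError("negative indel counts")

    @property
    def bias(self) -> float:
        if self.insertion_bias is not None:
            return self.insertion_bias
        return default_insertion_bias(self.chrom_table)


@dataclass(frozen=True)
class ReadSet:
    """Substitution-error short reads at uniform start positions."""

    reads: list[str]
    coverage: float
    error_rate: float
    read_length: int

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate outside [0, 1)")


def _sample_sizes(rng: np.random.Generator, n: int, size_range: tuple[int, int]) -> np.ndarray:
    lo, hi = size_range
    if lo == hi:
        return np.full(n, lo, dtype=np.int64)
    return np.round(
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    ).astype(np.int64).clip(lo, hi)


def plan_indels(
    table: ChromosomeTable,
    n_insertions: int,
    n_deletions: int,
    insertion_bias: float,
    rng: np.random.Generator | int | None = None,
    size_range: tuple[int, int] = (MIN_INDEL_BP, 100_000),
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Plant indel coordinates on a chromosome table (no sequence needed).

    Insertions are zero-width anchors in reference (B) coordinates; with
    probability ``insertion_bias`` the anchor is uniform inside the supergene
    interval, otherwise uniform genome-wide by length.  Deletions are
    ``[start, start+size)`` spans placed length-uniformly.  Spans and anchors
    are rejection-sampled to be mutually non-overlapping.
    """
    if n_insertions and table.supergene_length < n_insertions:
        raise ValueError("supergene interval too small to host requested insertions")
    rng = np.random.default_rng(rng)
    lengths = table.lengths_array()
    probs = lengths / lengths.sum()
    sg_start, sg_end = table.supergene_interval

    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in table.names}

    def free(chrom: str, s: int, e: int) -> bool:
        return all(e <= a or s >= b for a, b in taken[chrom])

    rows = []
    ins_sizes = _sample_sizes(rng, n_insertions, size_range)

    for i in range(n_insertions):
        in_sg = rng.random() < insertion_bias
        for _ in range(max_tries):
            if in_sg:
                chrom = table.social
                pos = int(rng.integers(sg_start, sg_end))
            else:
                chrom = table.names[rng.choice(len(lengths), p=probs)]
                pos = int(rng.integers(0, table.length_of(chrom)))
            if free(chrom, pos, pos + 1):
                break
        else:
            raise RuntimeError("could not place insertion without overlap")
        taken[chrom].append((pos, pos + 1))
        rows.append((chrom, pos, pos, "INS", int(ins_sizes[i]), in_sg))

    for _ in range(n_deletions):
        # size redrawn per attempt so spans always fit the drawn chromosome
        for _ in range(max_tries):
            size = int(_sample_sizes(rng, 1, size_range)[0])
            chrom = table.names[rng.choice(len(lengths), p=probs)]
            L = table.length_of(chrom)
            if L <= size + 1:
                continue
            s = int(rng.integers(0, L - size))
            if free(chrom, s, s + size):
                break
        else:
            raise RuntimeError("could not place deletion without overlap")
        taken[chrom].append((s, s + size))
        rows.append((chrom, s, s + size, "DEL", size, False))

    df = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "type", "size", "in_supergene"]
    )
    return df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)


def add_query_coordinates(truth: pd.DataFrame) -> pd.DataFrame:
    """Annotate a planned truth table with b-genome coordinates.

    Pure coordinate arithmetic (no sequences): insertions occupy
    ``[start_b, start_b + size)`` in b; deletions collapse to an anchor.
    """
    truth = truth.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    start_b = np.zeros(len(truth), dtype=np.int64)
    end_b = np.zeros(len(truth), dtype=np.int64)
    for _, idx in truth.groupby("chromosome", sort=False).groups.items():
        off = 0
        for i in idx:
            r = truth.iloc[i]
            if r["type"] == "INS":
                start_b[i] = r["start"] + off
                end_b[i] = r["start"] + off + r["size"]
                off += int(r["size"])
            else:
                start_b[i] = end_b[i] = r["start"] + off
                off -= int(r["size"])
    out = truth.copy()
    out["start_b"] = start_b
    out["end_b"] = end_b
    return out


def generate_genome_pair(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Build genome_B, genome_b and the exhaustive truth table.

    genome_b differs from genome_B by exactly the truth-table edits: planted
    random-sequence indels plus tandem-repeat copy-number differences.  The
    truth table carries coordinates in both genomes (``start``/``end`` in B,
    ``start_b``/``end_b`` in b) and the inserted sequence, so applying all
    edits to genome_B reconstructs genome_b byte-for-byte.
    """
    rng = np.random.default_rng(spec.seed)
    table = spec.chrom_table

    genome_B = {name: random_dna(rng, table.length_of(name)) for name in table.names}

    # Embed shared tandem arrays (copies_B) into genome_B; copy-number deltas
    # become truth-table indels anchored at the array edge.
    extra_rows = []
    for fam in spec.repeat_families:
        unit = random_dna(rng, fam.unit_length)
        if fam.chromosome is None:
            lengths = table.lengths_array()
            chrom = table.names[rng.choice(len(lengths), p=lengths / lengths.sum())]
        else:
            chrom = fam.chromosome
        seq = genome_B[chrom]
        pos = int(rng.integers(0, len(seq)))
        genome_B[chrom] = seq[:pos] + unit * fam.copies_B + seq[pos:]
        delta = fam.copies_b - fam.copies_B
        if delta > 0:
            extra_rows.append(
                (chrom, pos, pos, "INS", delta * fam.unit_length, unit * delta, True)
            )
        elif delta < 0:
            d = -delta * fam.unit_length
            extra_rows.append((chrom, pos, pos + d, "DEL", d, "", True))

    # Actual lengths after array embedding drive indel placement.
    actual = ChromosomeTable(
        names=table.names,
        lengths=tuple(len(genome_B[n]) for n in table.names),
        social=table.social,
        supergene_interval=table.supergene_interval,
    )
    plan = plan_indels(
        actual, spec.n_insertions, spec.n_deletions, spec.bias, rng,
        size_range=spec.indel_size_range,
    )
    plan["seq"] = [
        random_dna(rng, int(r.size)) if r.type == "INS" else ""
        for r in plan.itertuples()
    ]
    plan["is_repeat"] = False
    if extra_rows:
        extra = pd.DataFrame(
            extra_rows,
            columns=["chromosome", "start", "end", "type", "size", "seq", "is_repeat"],
        )
        extra["in_supergene"] = False
        plan = pd.concat([plan, extra], ignore_index=True)
    plan = plan.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)

    genome_b, truth = apply_truth_table(genome_B, plan)
    return genome_B, genome_b, truth


def apply_truth_table(
    genome_B: dict[str, str], truth: pd.DataFrame
) -> tuple[dict[str, str], pd.DataFrame]:
    """Apply truth-table edits to genome_B; annotate b-genome coordinates."""
    truth = truth.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    genome_b = {}
    start_b = np.zeros(len(truth), dtype=np.int64)
    end_b = np.zeros(len(truth), dtype=np.int64)
    for chrom, seq in genome_B.items():
        parts = []
        cursor = 0
        offset = 0
        for row in truth.itertuples():
            if row.chromosome != chrom:
                continue
            if row.start < cursor:
                raise ValueError("overlapping truth-table edits")
            parts.append(seq[cursor:row.start])
            if row.type == "INS":
                if len(row.seq) != row.size:
                    raise ValueError("insertion sequence length != size")
                parts.append(row.seq)
                start_b[row.Index] = row.start + offset
                end_b[row.Index] = row.start + offset + row.size
                offset += row.size
                cursor = row.start
            else:
                start_b[row.Index] = row.start + offset
                end_b[row.Index] = row.start + offset
                offset -= row.size
                cursor = row.end
        parts.append(seq[cursor:])
        genome_b[chrom] = "".join(parts)
    truth = truth.copy()
    truth["start_b"] = start_b
    truth["end_b"] = end_b
    return genome_b, truth


def simulate_reads(
    genome: dict[str, str] | str,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ReadSet:
    """Uniform-start substitution-error reads at the requested fold coverage.

    The read count is ``round(coverage * genome_length / read_length)``;
    start positions are uniform per chromosome chosen by length, so per-base
    depth is Poisson(coverage) away from contig ends.  Errors are i.i.d.
    substitutions to one of the three other bases.
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    enc = {c: np.frombuffer(genome[c].encode(), dtype=np.uint8) for c in chroms}
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("C")], lut[ord("G")], lut[ord("T")] = 1, 2, 3
    lens = np.array([len(genome[c]) for c in chroms])
    if read_length > lens.min():
        raise ValueError("read_length exceeds a contig length")
    total = int(lens.sum())
    n_reads = int(round(coverage * total / read_length))
    which = rng.choice(len(chroms), size=n_reads, p=lens / lens.sum())
    reads: list[str] = []
    for ci, c in enumerate(chroms):
        n = int((which == ci).sum())
        if n == 0:
            continue
        starts = rng.integers(0, lens[ci] - read_length + 1, size=n)
        mat = lut[enc[c][starts[:, None] + np.arange(read_length)]]
        if error_rate > 0:
            mask = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4
        chars = _BASES[mat]
        reads.extend(
            chars[i].tobytes().decode() for i in range(n)
        )
    return ReadSet(reads=reads, coverage=coverage, error_rate=error_rate,
                   read_length=read_length)


def generate_indel_matrix(
    n_species: int = 3,
    n_per_species: int = 2,
    n_background_loci: int = 200,
    n_supergene_loci: int = 50,
    noise: float = 0.05,
    missing_rate: float = 0.05,
    seed: int | np.random.Generator | None = None,
    chrom_table: ChromosomeTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planted presence/absence indel matrix for 3 species x B/b variants.

    Background loci are species markers: each is present in both individuals
    of one randomly chosen species.  Supergene loci are variant markers:
    present in every individual of one variant class (polarity random), the
    pattern the shared-origin supergene predicts.  ``noise`` flips each cell
    independently; ``missing_rate`` marks cells as lacking coverage.

    Returns ``(values, covered, loci)``: two sample x locus DataFrames (0/1
    presence; boolean coverage) plus per-locus metadata with coordinates and
    partition labels.
    """
    if n_per_species != 2:
        raise ValueError("one B and one b individual per species required")
    rng = np.random.default_rng(seed)
    table = chrom_table or fire_ant_table()
    species = [f"sp{i+1}" for i in range(n_species)]
    samples = [f"{s}_{v}" for s in species for v in ("B", "b")]
    sp_of = np.repeat(np.arange(n_species), 2)
    variant_b = np.tile([False, True], n_species)

    n_loci = n_background_loci + n_supergene_loci
    values = np.zeros((len(samples), n_loci), dtype=np.int8)

    for j in range(n_background_loci):
        sp = rng.integers(0, n_species)
        values[sp_of == sp, j] = 1
    for j in range(n_background_loci, n_loci):
        carrier_is_b = bool(rng.random() < 0.5)
        values[variant_b == carrier_is_b, j] = 1

    if noise > 0:
        flips = rng.random(values.shape) < noise
        values = np.where(flips, 1 - values, values)
    covered = rng.random(values.shape) >= missing_rate

    # Locus coordinates: background on chromosomes 1..n-1 by length,
    # supergene loci inside the supergene interval.
    bg_chroms = [n for n in table.names if n != table.social]
    bg_lens = np.array([table.length_of(c) for c in bg_chroms], dtype=float)
    rows = []
    for j in range(n_loci):
        if j < n_background_loci:
            c = bg_chroms[rng.choice(len(bg_chroms), p=bg_lens / bg_lens.sum())]
            s = int(rng.integers(0, table.length_of(c) - 10_000))
            part = "background"
        else:
            c = table.social
            a, b = table.supergene_interval
            s = int(rng.integers(a, b - 10_000))
            part = "supergene"
        rows.append((f"locus{j:05d}", c, s, s + int(rng.integers(MIN_INDEL_BP, 10_000)), part))
    loci = pd.DataFrame(rows, columns=["locus", "chromosome", "start", "end", "partition"])

    values_df = pd.DataFrame(values, index=samples, columns=loci["locus"])
    covered_df = pd.DataFrame(covered, index=samples, columns=loci["locus"])
    return values_df, covered_df, loci


# -- writers (plain-text formats only) ----------------------------------

def write_fasta(genome: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: ReadSet, path, prefix: str = "read") -> None:
    # fixed Q40 qualities; byte-identical output under a fixed seed upstream
    with open(path, "w") as fh:
        for i, seq in enumerate(reads.reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_table(truth: pd.DataFrame, path, sample: str = "b_vs_B") -> None:
    """BED-like TSV (0-based half-open): chrom, start, end, type, size_bp, sample."""
    out = truth[["chromosome", "start", "end", "type", "size"]].copy()
    out.columns = ["chrom", "start", "end", "type", "size_bp"]
    out["sample"] = sample
    out.to_csv(path, sep="\t", index=False)
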