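#!/usr/bin/env python
"""Generate the synthetic study inputs and record their planted structure.

Builds one paired B/b genome (with supergene-biased insertions and a
tandem-repeat family whose copy number differs between variants), simulates
a read set for each variant, digests both genomes into label maps, and
writes a planted six-individual indel matrix.  Small summary tables go to
results/; bulky sequence files (FASTA/FASTQ) go to scratch/.
"""

from pathlib import Path

import numpy as np

from degenexp.chromosomes import ChromosomeTable
from degenexp.labelmaps import digest_to_label_map, write_label_maps
from degenexp.synthetic import (
    RepeatFamily,
    SyntheticGenomeSpec,
    generate_genome_pair,
    generate_indel_matrix,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_truth_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 20_260_928

def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    table = ChromosomeTable(
        names=("chr1", "chr2"),
        lengths=(150_000, 100_000),
        social="chr2",
        supergene_interval=(20_000, 90_000),
    )
    spec = SyntheticGenomeSpec(
        chrom_table=table,
        n_insertions=12,
        n_deletions=8,
        insertion_bias=0.6,
        indel_size_range=(3000, 15_000),
        repeat_families=(RepeatFamily(600, 10, 20, chromosome="chr2"),),
        seed=SEED,
    )
    genome_B, genome_b, truth = generate_genome_pair(spec)
    write_fasta(genome_B, SCRATCH / "genome_B.fasta")
    write_fasta(genome_b, SCRATCH / "genome_b.fasta")
    write_truth_table(truth, RESULTS / "truth_table.tsv")
    sizes = truth.groupby("type")["size"].agg(["count", "sum"])
    print("planted indels:\n", sizes)
    print(
        "genome sizes: B",
        sum(map(len, genome_B.values())),
        "b",
        sum(map(len, genome_b.values())),
    )

    for name, genome in (("B", genome_B), ("b", genome_b)):
        reads = simulate_reads(genome, coverage=30, read_length=100,
                               error_rate=0.001, seed=SEED + hash(name) % 1000)
        write_fastq(reads, SCRATCH / f"reads_{name}.fastq")
        maps = [
            digest_to_label_map(seq, "GCTCTT", f"{name}.{chrom}", chrom,
                                sizing_sd_bp=150, miss_rate=0.05,
                                false_rate=0.02, seed=SEED)
            for chrom, seq in genome.items()
        ]
        write_label_maps(maps, RESULTS / f"label_maps_{name}.tsv")
        print(name, "reads:", len(reads.reads),
              "labels:", [m.n_labels for m in maps])

    values, covered, loci = generate_indel_matrix(seed=SEED)
    values.to_csv(RESULTS / "indel_matrix.tsv", sep="\t")
    covered.astype(int).to_csv(RESULTS / "indel_matrix_coverage.tsv", sep="\t")
    loci.to_csv(RESULTS / "indel_matrix_loci.tsv", sep="\t", index=False)
    print("indel matrix:", values.shape, "loci partitions:",
          loci.partition.value_counts().to_dict())


if __name__ == "__main__":
    main()
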