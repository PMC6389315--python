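"""End-to-end study procedures over the synthetic inputs.

Each function runs one self-contained study at a configurable scale and
seed: enrichment flagging across planted genomes, genome-size recovery from
simulated reads, paired-CI coverage, the optical-map indel pipeline with its
reciprocal-consistency check, indel-phylogeny recovery, and the simulator
regimes.  The analysis drivers and the acceptance script are thin wrappers
around these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chromosomes import ChromosomeTable, fire_ant_table
from .enrichment import (
    counts_by_chromosome,
    cumulative_length_shares,
    enrichment_zscores,
    expansion_from_lengths,
    net_overhang_difference,
)
from .kmer import (
    build_histogram,
    estimate_genome_size,
    expansion_from_genome_diff,
    expansion_from_repeat_excess,
    paired_comparison,
)
from .labelmaps import LabelMap, labels_by_density, noisy_copy, transform_positions
from .mapalign import (
    AlignParams,
    align_label_maps,
    call_indels,
    call_overhangs,
    overhangs_to_frame,
    reciprocal_consistency,
)
from .phylogeny import (
    IndelMatrix,
    apply_coverage,
    distance_matrix,
    filter_matrix,
    infer_tree,
    split_partitions,
)
from .synthetic import (
    SyntheticGenomeSpec,
    add_query_coordinates,
    default_insertion_bias,
    generate_genome_pair,
    generate_indel_matrix,
    plan_indels,
    simulate_reads,
)

__all__ = [
    "published_arithmetic",
    "enrichment_flagging_study",
    "genome_size_recovery_study",
    "paired_ci_coverage_study",
    "map_pipeline_study",
    "reciprocal_recovery_study",
    "phylogeny_recovery_study",
]


def published_arithmetic() -> dict[str, float]:
    """Recompute the summary statistics printed for the fire-ant system.

    Inputs are the published per-chromosome and per-variant figures (counts,
    lengths, percent differences); every output is computed by the package's
    statistics, rounded to the printed precision.
    """
    table = fire_ant_table()
    counts = np.zeros(16, dtype=int)
    counts[-1] = 55  # insertions observed on the social chromosome
    rest = 163 - 55  # remaining insertions spread over chromosomes 1-15
    counts[:15] = np.diff(np.linspace(0, rest, 16)).astype(int)
    counts[0] += 163 - counts.sum()
    enr = enrichment_zscores(counts, table)

    lengths = expansion_from_lengths(20.9e6, 27.52e6)
    kmer = expansion_from_genome_diff(3.59, (2.02, 5.16), supergene_fraction=0.045)
    repeats = expansion_from_repeat_excess(10.02e6, 20.9e6)

    return {
        "social_z": round(float(enr.z[-1]), 1),
        "chi2_df": enr.df,
        "insertion_share_pct": round(100 * 55 / 163, 1),
        "social_genome_share_pct": round(100 * table.social_share(), 1),
        "cumulative_share_pct": round(100 * 1.43 / 2.44, 1),
        "expansion_lengths_pct": lengths.rounded,
        "expansion_kmer_pct": round(kmer.percent_increase, 1),
        "expansion_kmer_ci_low": round(kmer.ci95[0], 1),
        "expansion_kmer_ci_high": round(kmer.ci95[1], 1),
        "expansion_repeats_pct": round(repeats.percent_increase, 2),
    }


def enrichment_flagging_study(
    n_seeds: int = 100,
    seed: int = 0,
    n_insertions: int = 163,
    n_deletions: int = 187,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Plant paper-scale indels repeatedly; ask which chromosomes get flagged.

    Insertions carry the default supergene bias (expected social-chromosome
    share 33.7%); deletions are length-uniform.  Reports how often exactly
    the social chromosome is Bonferroni-significant for insertions, and how
    often any chromosome is (spuriously) flagged for deletions.
    """
    table = fire_ant_table()
    bias = default_insertion_bias(table)
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    exact = 0
    del_flagged = 0
    for s in ss:
        rng = np.random.default_rng(s)
        plan = plan_indels(table, n_insertions, n_deletions, bias, rng)
        res_i = enrichment_zscores(counts_by_chromosome(plan, table, "INS"), table)
        exact += res_i.significant(alpha) == [table.social]
        res_d = enrichment_zscores(counts_by_chromosome(plan, table, "DEL"), table)
        del_flagged += len(res_d.significant(alpha)) > 0
    return {
        "social_flag_rate": exact / n_seeds,
        "deletion_false_flag_rate": del_flagged / n_seeds,
        "n_seeds": n_seeds,
    }


def _two_chrom_table() -> ChromosomeTable:
    return ChromosomeTable(
        names=("chr1", "chr2"),
        lengths=(150_000, 100_000),
        social="chr2",
        supergene_interval=(20_000, 90_000),
    )


def genome_size_recovery_study(
    n_seeds: int = 20,
    seed: int = 0,
    coverage: float = 30.0,
    error_rate: float = 0.001,
    read_length: int = 100,
) -> dict[str, float]:
    """Estimate synthetic genome sizes from reads; report the percent bias.

    Each seed builds a fresh ~250 kb two-chromosome genome, simulates reads
    at the requested coverage and error rate, and runs the k-mer estimator.
    """
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    biases = []
    for s in ss:
        child = np.random.default_rng(s)
        g_seed, r_seed = child.integers(0, 2**31, size=2)
        spec = SyntheticGenomeSpec(
            chrom_table=_two_chrom_table(), n_insertions=0, n_deletions=0,
            insertion_bias=0.0, seed=int(g_seed),
        )
        genome, _, _ = generate_genome_pair(spec)
        true_size = sum(len(v) for v in genome.values())
        reads = simulate_reads(genome, coverage, read_length, error_rate,
                               seed=int(r_seed))
        est = estimate_genome_size(build_histogram(reads, 21))
        biases.append(100.0 * (est.genome_size / true_size - 1.0))
    biases = np.asarray(biases)
    return {
        "median_abs_bias_pct": float(np.median(np.abs(biases))),
        "mean_bias_pct": float(biases.mean()),
        "n_seeds": n_seeds,
    }


def paired_ci_coverage_study(
    n_replicates: int = 100,
    seed: int = 0,
    true_diff_pct: float = 3.6,
    pair_sd_pct: float = 1.0,
    n_pairs: int = 5,
) -> dict[str, float]:
    """Coverage of the paired 95% t-CI for a planted B/b size difference.

    Five pairs per replicate, each with a true +3.6% difference plus 1%
    between-pair scatter, matching the study design of five wild-caught
    B/b pairs.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    sig = 0
    for _ in range(n_replicates):
        pairs = []
        for _ in range(n_pairs):
            B = 380e6 * (1 + rng.normal(0, 0.02))
            b = B * (1 + (true_diff_pct + rng.normal(0, pair_sd_pct)) / 100)
            pairs.append((B, b))
        res = paired_comparison(pairs)
        covered += res.ci95[0] <= true_diff_pct <= res.ci95[1]
        sig += res.p_one_sided < 0.05
    return {
        "ci_coverage": covered / n_replicates,
        "power_at_005": sig / n_replicates,
        "n_replicates": n_replicates,
    }


def map_pipeline_study(
    seed: int = 0,
    chrom_bp: int = 2_000_000,
    n_insertions: int = 15,
    n_deletions: int = 10,
    label_density: float = 1 / 8000,
    sizing_sd_bp: float = 150.0,
    miss_rate: float = 0.05,
    false_rate: float = 0.02,
    size_range: tuple[int, int] = (5000, 30_000),
    tail_excess_bp: int = 0,
    params: AlignParams | None = None,
) -> dict[str, object]:
    """One synthetic optical-map comparison on a single chromosome.

    Plants indels (all inside a supergene spanning most of the chromosome),
    builds B and b label maps with the three-parameter noise model, aligns
    in both directions, calls indels and overhangs, and scores reciprocal
    consistency plus sensitivity against the planted truth.  An optional
    unlabeled ``tail_excess_bp`` on the b map emulates net overhang excess.
    """
    rng = np.random.default_rng(seed)
    table = ChromosomeTable(
        ("chr1",), (chrom_bp,), "chr1", (chrom_bp // 20, chrom_bp * 19 // 20)
    )
    truth = add_query_coordinates(
        plan_indels(table, n_insertions, n_deletions, 1.0, rng, size_range=size_range)
    )
    base = labels_by_density(chrom_bp, label_density, "B", "chr1", rng)
    bpos, _, blen = transform_positions(base.positions, truth, "chr1", base.length)
    # labels arise inside inserted spans at the same density
    extra = []
    for r in truth[truth.type == "INS"].itertuples():
        n = rng.poisson(r.size * label_density)
        if n:
            extra.append(rng.integers(r.start_b, r.end_b, size=n))
    if extra:
        bpos = np.unique(np.concatenate([bpos] + extra))
    map_b0 = LabelMap("b", "chr1", bpos, blen + tail_excess_bp)
    map_B, _ = noisy_copy(base, sizing_sd_bp, miss_rate, false_rate, seed=rng,
                          map_id="B")
    map_b, _ = noisy_copy(map_b0, sizing_sd_bp, miss_rate, false_rate, seed=rng,
                          map_id="b")

    params = params or AlignParams(sizing_sd_bp=sizing_sd_bp)
    aln_fwd = align_label_maps(map_B, map_b, params)
    calls_fwd = call_indels(aln_fwd, map_B, map_b)
    aln_rev = align_label_maps(map_b, map_B, params)
    calls_rev = call_indels(aln_rev, map_b, map_B)
    recip = reciprocal_consistency(calls_fwd, calls_rev)

    overhangs = call_overhangs(aln_fwd, map_B, map_b)
    net_b = sum(r.length for r in overhangs if r.sample == "b") - sum(
        r.length for r in overhangs if r.sample == "B"
    )

    hits = 0
    for r in truth.itertuples():
        lo, hi = r.start - 20_000, r.start + 20_000
        if any(c.type == r.type and c.start < hi and c.end > lo for c in calls_fwd):
            hits += 1
    return {
        "reciprocal": recip,
        "sensitivity": hits / len(truth),
        "n_calls_fwd": len(calls_fwd),
        "n_calls_rev": len(calls_rev),
        "net_overhang_bp": net_b,
        "truth": truth,
        "calls_fwd": calls_fwd,
        "overhangs": overhangs,
    }


def reciprocal_recovery_study(n_seeds: int = 10, seed: int = 0, **kwargs) -> dict[str, float]:
    """Mean reciprocal indel-site recovery across map-pipeline seeds."""
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    recips, sens = [], []
    for s in ss:
        out = map_pipeline_study(seed=int(s.generate_state(1)[0] % 2**31), **kwargs)
        recips.append(out["reciprocal"])
        sens.append(out["sensitivity"])
    return {
        "mean_reciprocal": float(np.mean(recips)),
        "min_reciprocal": float(np.min(recips)),
        "mean_sensitivity": float(np.mean(sens)),
        "n_seeds": n_seeds,
    }


def phylogeny_recovery_study(n_seeds: int = 100, seed: int = 0, **matrix_kwargs) -> dict[str, float]:
    """Planted-matrix recovery: species clans on background loci, variant
    clans on supergene loci, across independent seeds."""
    table = fire_ant_table()
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    ok_bg = ok_sg = 0
    species = {f"sp{i}": {f"sp{i}_B", f"sp{i}_b"} for i in (1, 2, 3)}
    for s in ss:
        values, covered, loci = generate_indel_matrix(
            seed=np.random.default_rng(s), **matrix_kwargs
        )
        m = filter_matrix(IndelMatrix(apply_coverage(values, covered), loci))
        bg, sg = split_partitions(m, table)
        variants = {
            "B": {x for x in m.samples if x.endswith("_B")},
            "b": {x for x in m.samples if x.endswith("_b")},
        }
        tb = infer_tree(distance_matrix(bg), "background", species)
        ts = infer_tree(distance_matrix(sg), "supergene", variants)
        ok_bg += all(tb.grouping.values())
        ok_sg += all(ts.grouping.values())
    return {
        "background_species_rate": ok_bg / n_seeds,
        "supergene_variant_rate": ok_sg / n_seeds,
        "n_seeds": n_seeds,
    }
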