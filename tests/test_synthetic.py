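"""Planted-genome, read-simulation and label-map generator behaviour."""

import numpy as np
import pandas as pd
import pytest

from degenexp.chromosomes import ChromosomeTable
from degenexp.labelmaps import (
    digest_to_label_map,
    labels_by_density,
    noisy_copy,
    read_label_maps,
    transform_positions,
    write_label_maps,
)
from degenexp.mapalign import align_label_maps
from degenexp.synthetic import (
    MIN_INDEL_BP,
    ReadSet,
    RepeatFamily,
    SyntheticGenomeSpec,
    add_query_coordinates,
    generate_genome_pair,
    generate_indel_matrix,
    plan_indels,
    simulate_reads,
    write_fastq,
)


def splice(seq: str, truth: pd.DataFrame, chrom: str) -> str:
    """Independent reconstruction oracle: apply truth edits by string splicing."""
    out, cur = [], 0
    for r in truth[truth.chromosome == chrom].itertuples():
        out.append(seq[cur:r.start])
        if r.type == "INS":
            out.append(r.seq)
            cur = r.start
        else:
            cur = r.end
    out.append(seq[cur:])
    return "".join(out)


class TestGenomePair:
    def test_truth_table_reconstructs_genome_b(self, small_table):
        spec = SyntheticGenomeSpec(
            chrom_table=small_table, n_insertions=8, n_deletions=5,
            insertion_bias=0.5, indel_size_range=(3000, 10_000), seed=3,
            repeat_families=(RepeatFamily(500, 20, 40, chromosome="chr2"),),
        )
        gB, gb, truth = generate_genome_pair(spec)
        for chrom in gB:
            assert splice(gB[chrom], truth, chrom) == gb[chrom]

    def test_bias_one_places_all_insertions_in_supergene(self, small_table):
        spec = SyntheticGenomeSpec(
            chrom_table=small_table, n_insertions=10, n_deletions=0,
            insertion_bias=1.0, seed=1,
        )
        _, _, truth = generate_genome_pair(spec)
        ins = truth[truth.type == "INS"]
        assert len(ins) == 10
        s, e = small_table.supergene_interval
        assert (ins.chromosome == "chr2").all()
        assert ((ins.start >= s) & (ins.start < e)).all()

    def test_no_indels_yields_identical_genomes(self, small_table):
        spec = SyntheticGenomeSpec(
            chrom_table=small_table, n_insertions=0, n_deletions=0,
            insertion_bias=0.0, seed=2,
        )
        gB, gb, truth = generate_genome_pair(spec)
        assert truth.empty
        assert gB == gb

    def test_all_planted_indels_respect_floor(self, ant_table, rng):
        plan = plan_indels(ant_table, 60, 60, 0.3, rng)
        assert (plan["size"] >= MIN_INDEL_BP).all()

    def test_generators_deterministic_under_seed(self, small_table):
        spec = SyntheticGenomeSpec(
            chrom_table=small_table, n_insertions=5, n_deletions=5,
            insertion_bias=0.5, seed=11,
        )
        a = generate_genome_pair(spec)
        b = generate_genome_pair(spec)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_size_floor_enforced_in_spec(self, small_table):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(
                chrom_table=small_table, indel_size_range=(1000, 5000)
            )

    def test_supergene_too_small_raises(self):
        tiny = ChromosomeTable(("c1",), (10_000,), "c1", (100, 150))
        with pytest.raises(ValueError, match="too small"):
            plan_indels(tiny, 100, 0, 1.0, rng=0)

    def test_query_coordinates_consistent_with_sequence_path(self, small_table):
        spec = SyntheticGenomeSpec(
            chrom_table=small_table, n_insertions=6, n_deletions=4,
            insertion_bias=0.5, seed=5,
        )
        _, _, truth = generate_genome_pair(spec)
        redo = add_query_coordinates(truth.drop(columns=["start_b", "end_b"]))
        assert (redo["start_b"] == truth["start_b"]).all()
        assert (redo["end_b"] == truth["end_b"]).all()


class TestReads:
    def test_total_bases_match_coverage(self, small_table):
        spec = SyntheticGenomeSpec(
            chrom_table=small_table, n_insertions=0, n_deletions=0,
            insertion_bias=0.0, seed=4,
        )
        gB, _, _ = generate_genome_pair(spec)
        rs = simulate_reads(gB, coverage=30, read_length=100, seed=0)
        total = sum(len(r) for r in rs.reads)
        expect = 30 * sum(len(v) for v in gB.values())
        assert abs(total - expect) / expect < 0.03

    def test_error_free_reads_are_exact_substrings(self):
        genome = {"c": "ACGTACGGTTCA" * 500}
        rs = simulate_reads(genome, coverage=2, read_length=50, seed=1)
        for read in rs.reads[:200]:
            assert read in genome["c"]

    def test_read_longer_than_contig_raises(self):
        with pytest.raises(ValueError):
            simulate_reads({"c": "ACGT" * 10}, coverage=1, read_length=100, seed=0)

    def test_fastq_byte_identical_on_rerun(self, tmp_path):
        genome = {"c": "ACGT" * 2000}
        paths = []
        for tag in ("a", "b"):
            rs = simulate_reads(genome, coverage=5, read_length=60,
                                error_rate=0.01, seed=99)
            p = tmp_path / f"{tag}.fastq"
            write_fastq(rs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_readset_params_rejected(self):
        with pytest.raises(ValueError):
            ReadSet(reads=["ACGT"], coverage=0, error_rate=0.0, read_length=4)
        with pytest.raises(ValueError):
            ReadSet(reads=["ACGT"], coverage=1, error_rate=1.0, read_length=4)


class TestLabelMaps:
    def test_motif_digest_finds_overlapping_matches(self):
        lmap = digest_to_label_map("AAGCTAGCTT", "GCT")
        assert list(lmap.positions) == [2, 6]

    def test_miss_rate_one_drops_all_labels(self):
        lmap = digest_to_label_map("GCT" * 50, "GCT", miss_rate=1.0, seed=0)
        assert lmap.n_labels == 0

    def test_label_map_tsv_round_trip(self, tmp_path, rng):
        maps = [labels_by_density(500_000, 1 / 10_000, f"m{i}", "chr1", rng)
                for i in range(3)]
        path = tmp_path / "maps.tsv"
        write_label_maps(maps, path)
        back = read_label_maps(path)
        for a, b in zip(maps, back):
            assert a.map_id == b.map_id and a.length == b.length
            assert np.array_equal(a.positions, b.positions)

    def test_alignment_recovers_noisy_label_pairs(self, rng):
        """1 Mb map at 1 label/10 kb, 150 bp sizing noise: aligning a map to
        its re-noised copy recovers >= 95% of the true label pairs."""
        base = labels_by_density(1_000_000, 1 / 10_000, "t", "chr1", rng)
        noisy, origin = noisy_copy(base, sizing_sd_bp=150, miss_rate=0.02,
                                   false_rate=0.02, seed=rng)
        aln = align_label_maps(base, noisy)
        truth_pairs = {(int(o), j) for j, o in enumerate(origin) if o >= 0}
        matched = set(aln.matched_pairs)
        recovered = len(truth_pairs & {(i, j) for i, j in matched})
        assert recovered / len(truth_pairs) >= 0.95

    def test_transform_positions_shifts_and_drops(self):
        truth = pd.DataFrame(
            {
                "chromosome": ["c", "c"],
                "start": [100, 500],
                "end": [100, 700],
                "type": ["INS", "DEL"],
                "size": [50, 200],
            }
        )
        pos = np.array([50, 150, 600, 800])
        new, idx, new_len = transform_positions(pos, truth, "c", 1000)
        # 50 unmoved; 150 shifted +50; 600 deleted; 800 shifted +50-200
        assert list(new) == [50, 200, 650]
        assert list(idx) == [0, 1, 3]
        assert new_len == 1000 + 50 - 200


class TestIndelMatrix:
    def test_noise_free_background_conspecifics_identical(self):
        values, _, loci = generate_indel_matrix(noise=0.0, missing_rate=0.0, seed=0)
        bg = loci.loc[loci.partition == "background", "locus"]
        for sp in ("sp1", "sp2", "sp3"):
            a = values.loc[f"{sp}_B", bg].to_numpy()
            b = values.loc[f"{sp}_b", bg].to_numpy()
            assert np.array_equal(a, b)

    def test_noise_free_supergene_variants_identical(self):
        values, _, loci = generate_indel_matrix(noise=0.0, missing_rate=0.0, seed=1)
        sg = loci.loc[loci.partition == "supergene", "locus"]
        b_rows = [s for s in values.index if s.endswith("_b")]
        arrs = [values.loc[s, sg].to_numpy() for s in b_rows]
        assert all(np.array_equal(arrs[0], a) for a in arrs[1:])
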