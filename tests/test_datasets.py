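"""Supermatrix construction, codon-position filtering, translation and
partition-file round-tripping."""

import random

import pytest

from mitocomp.datasets import (
    GENE_ORDER,
    Supermatrix,
    build_dataset,
    codon_positions,
    concatenate,
    read_nexus_sets,
    read_raxml_partitions,
    translate_alignment,
    write_dataset,
)


def test_codon_positions_examples():
    assert codon_positions({"t": "ATGAAA"}, {1, 2}) == {"t": "ATAA"}
    assert codon_positions({"t": "ATGAAA"}, {1, 2, 3}) == {"t": "ATGAAA"}
    with pytest.raises(ValueError):
        codon_positions({"t": "ATGA"}, {1, 2})


def test_codon_positions_index_mapping():
    """Every output column maps back to a kept input column."""
    rng = random.Random(3)
    seq = "".join(rng.choice("ACGT") for _ in range(60))
    out = codon_positions({"t": seq}, {1, 3})["t"]
    kept = [i for i in range(60) if i % 3 in (0, 2)]
    assert out == "".join(seq[i] for i in kept)


def test_translate_alignment_table5():
    assert translate_alignment({"t": "ATAAGATGA"}) == {"t": "MSW"}
    assert translate_alignment({"t": "---"}) == {"t": "-"}
    assert translate_alignment({"t": "AT-NNN"}) == {"t": "XX"}


def test_translate_internal_stop_warns(caplog):
    with caplog.at_level("WARNING"):
        out = translate_alignment({"t": "ATGTAAAAA"})
    assert out == {"t": "M*K"}
    assert "internal stop" in caplog.text


class TestConcatenate:
    def test_bookkeeping_two_genes(self):
        sm = concatenate({
            "atp6": {"a": "ATGATG", "b": "ATGATA"},
            "atp8": {"a": "ATGAAAGGG", "b": "ATGAAAGGA"},
        })
        assert sm.length == 15
        assert sm.partitions == [("atp6", 1, 6), ("atp8", 7, 15)]

    def test_missing_taxon_gap_filled(self):
        sm = concatenate({
            "atp6": {"a": "ATGATG", "b": "ATGATA"},
            "atp8": {"a": "ATGAAAGGG"},
        })
        assert sm.matrix["b"] == "ATGATA" + "-" * 9

    def test_duplicate_taxon_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            concatenate({"atp6": [("a", "AAA"), ("a", "AAA")]})

    def test_unequal_rows_error(self):
        with pytest.raises(ValueError, match="unequal"):
            concatenate({"atp6": {"a": "AAA", "b": "AAAA"}})

    def test_insertion_order_irrelevant(self, sim_set):
        """Shuffling gene-map insertion order leaves the matrix unchanged."""
        _, _, alignments, _ = sim_set
        genes = {g: alignments[g] for g in GENE_ORDER if g in alignments}
        shuffled = dict(reversed(list(genes.items())))
        a = concatenate(genes)
        b = concatenate(shuffled)
        assert a.matrix == b.matrix and a.partitions == b.partitions


@pytest.fixture(scope="module")
def gene_alns(sim_set):
    _, _, alignments, truth = sim_set
    pcgs = {g: alignments[g] for g in truth.omega}
    rrnas = {g: alignments[g] for g in ("rrnL", "rrnS")}
    return pcgs, rrnas


@pytest.fixture(scope="module")
def matrix(gene_alns):
    pcgs, rrnas = gene_alns
    return build_dataset(pcgs, rrnas, kind="P123R")


class TestBuildDataset:
    def test_length_identities(self, gene_alns):
        """len(P12R) = (2/3)*sum PCG + sum rrn; len(AA) = sum PCG / 3;
        len(P123R) = sum PCG + sum rrn — exact bookkeeping identities."""
        pcgs, rrnas = gene_alns
        pcg_len = sum(len(next(iter(a.values()))) for a in pcgs.values())
        rrn_len = sum(len(next(iter(a.values()))) for a in rrnas.values())
        p123r = build_dataset(pcgs, rrnas, kind="P123R")
        p12r = build_dataset(pcgs, rrnas, kind="P12R")
        aa = build_dataset(pcgs, kind="AA")
        assert p123r.length == pcg_len + rrn_len
        assert p12r.length == (2 * pcg_len) // 3 + rrn_len
        assert aa.length == pcg_len // 3

    def test_partitions_tile_exactly(self, gene_alns):
        pcgs, rrnas = gene_alns
        for kind in ("AA", "P12R", "P123R"):
            sm = build_dataset(pcgs, rrnas if kind != "AA" else None, kind=kind)
            pos = 1
            for name, start, end in sm.partitions:
                assert start == pos and end >= start
                pos = end + 1
            assert pos == sm.length + 1
            names = [p[0] for p in sm.partitions]
            assert names == [g for g in GENE_ORDER if g in names]

    def test_row_lengths_uniform(self, gene_alns):
        pcgs, rrnas = gene_alns
        sm = build_dataset(pcgs, rrnas, kind="P123R")
        assert len({len(r) for r in sm.matrix.values()}) == 1

    def test_pcg_length_matches_feature_sum(self, sim_set):
        """Concatenated-PCG length equals the sum of PCG feature lengths on
        the assembled genomes (cross-module consistency)."""
        _, genomes, alignments, truth = sim_set
        pcgs = {g: alignments[g] for g in truth.omega}
        sm = build_dataset(pcgs, kind="P123R")
        feat_sum = sum(f.length for f in genomes[0].features_of_kind("PCG"))
        assert sm.length == feat_sum

    def test_position_subpartitions(self, gene_alns):
        pcgs, rrnas = gene_alns
        p12r = build_dataset(pcgs, rrnas, kind="P12R")
        subs = p12r.position_subpartitions()
        assert len(subs) == 2 * len(pcgs)
        assert all(stride == 2 for *_, stride in subs)
        assert build_dataset(pcgs, kind="AA").position_subpartitions() == []


class TestWriters:
    def test_scheme_block_counts(self, matrix, tmp_path):
        paths_np = write_dataset(matrix, "NP", tmp_path, prefix="d")
        paths_fp = write_dataset(matrix, "FP", tmp_path, prefix="d")
        assert len(read_raxml_partitions(paths_np["raxml"])) == 1
        assert len(read_raxml_partitions(paths_fp["raxml"])) == 15

    def test_partition_round_trip_both_dialects(self, matrix, tmp_path):
        """Emitted RAxML and NEXUS partition files re-parse to exactly the
        Supermatrix partition ranges."""
        paths = write_dataset(matrix, "FP", tmp_path, prefix="rt")
        assert read_raxml_partitions(paths["raxml"]) == matrix.partitions
        assert read_nexus_sets(paths["nexus"]) == matrix.partitions

    def test_phylip_and_fasta_match_matrix(self, matrix, tmp_path):
        from mitocomp.io import read_fasta
        paths = write_dataset(matrix, "NP", tmp_path, prefix="m")
        assert read_fasta(str(paths["fasta"])) == matrix.matrix
        lines = paths["phylip"].read_text().splitlines()
        n, length = lines[0].split()
        assert (int(n), int(length)) == (len(matrix.taxa), matrix.length)


def test_supermatrix_invariant_enforced():
    with pytest.raises(ValueError):
        Supermatrix(["a"], {"a": "ACGT"}, [("g1", 1, 2), ("g2", 4, 4)], "P123R")
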