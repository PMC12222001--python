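"""COI-identity audit: alignment identity, verdict tiering and tree placement."""

import random

import pytest

from mitocomp.misid import (
    ThresholdConfig,
    audit_collection,
    extract_barcode,
    global_identity,
    parse_binomial,
    tier_verdict,
    tree_consistency,
)
from mitocomp.simulate import simulate_misid_audit_set

from oracles import brute_global_alignment_score


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("ACGT", "ACGT") == (100.0, 4)

    def test_one_mismatch(self):
        pid, cols = global_identity("ACGT", "ACGA")
        assert pid == 75.0 and cols == 4

    def test_symmetry_and_self_identity(self):
        rng = random.Random(9)
        for _ in range(10):
            a = "".join(rng.choice("ACGT") for _ in range(40))
            b = "".join(rng.choice("ACGT") for _ in range(35))
            assert global_identity(a, b) == global_identity(b, a)
            assert global_identity(a, a)[0] == 100.0

    def test_terminal_gaps_excluded(self):
        """A shorter fragment aligned inside a longer one is scored only over
        the overlapping columns (semi-global identity)."""
        pid, cols = global_identity("ACGTACGT", "GTAC")
        assert pid == 100.0 and cols == 4

    def test_score_matches_enumeration_oracle(self):
        """Aligner score equals the exhaustive dynamic-programming oracle on
        short random pairs."""
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1, -1
        aligner.open_gap_score = aligner.extend_gap_score = -2
        rng = random.Random(123)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            assert aligner.score(a, b) == brute_global_alignment_score(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


class TestBarcode:
    def test_barcode_equals_planted_cox1(self, sim_set):
        _, genomes, alignments, _ = sim_set
        g = genomes[0]
        expected = alignments["cox1"][g.taxon.split()[-1]]
        assert extract_barcode(g) == expected
        assert extract_barcode(g, barcode_window=True) == expected[:658]

    def test_missing_cox1_errors(self, sim_set):
        from mitocomp.io import MitoGenome
        _, genomes, _, _ = sim_set
        g = genomes[0]
        stripped = MitoGenome(g.identifier, g.sequence, g.circular,
                              [f for f in g.features if f.canonical_name != "cox1"],
                              g.taxon)
        with pytest.raises(ValueError, match="cox1"):
            extract_barcode(stripped)


class TestVerdicts:
    def test_threshold_config_validation(self):
        with pytest.raises(ValueError):
            ThresholdConfig(conspecific_min=90.0, congeneric_min=95.0)

    def test_conspecific_relabel_candidate(self):
        v = tier_verdict("Harpalus sp.1", "Harpalus tinctulus", 99.7)
        assert v == "suspected_conspecific"

    def test_congeneric_band(self):
        v = tier_verdict("Galerita orientalis", "Brachinus hirsutus", 92.0,
                         max_identity_in_genus=None)
        assert v == "suspected_congeneric"

    def test_same_genus_in_congeneric_band_is_consistent(self):
        v = tier_verdict("Harpalus griseus", "Harpalus anxius", 93.0,
                         max_identity_in_genus=93.0)
        assert v == "consistent"

    def test_misplaced_when_genus_maxes_below_band(self):
        v = tier_verdict("Selenophorus alternans", "Blethisa multipunctata",
                         85.0, max_identity_in_genus=80.0)
        assert v == "suspected_misplaced"

    def test_unparseable_name_inconclusive(self):
        assert tier_verdict("", "Harpalus anxius", 99.9) == "inconclusive"

    def test_tiers_exhaustive_and_exclusive(self):
        """Every (identity, name relation) combination yields exactly one
        verdict from the defined set."""
        from mitocomp.misid import VERDICTS
        for pid in (99.9, 98.0, 95.0, 91.0, 85.0, 50.0):
            for subject in ("Harpalus tinctulus", "Harpalus anxius",
                            "Carabus lafossei"):
                v = tier_verdict("Harpalus tinctulus", subject, pid,
                                 max_identity_in_genus=pid)
                assert v in VERDICTS


class TestAudit:
    def test_planted_swaps_recovered_perfectly(self):
        """Precision = recall = 1.0 for planted conspecific relabellings at
        the default audit-set conditions (within-species divergence 0.2%,
        between-species
        divergence ~20%)."""
        barcodes, names, truth = simulate_misid_audit_set(seed=21)
        report = audit_collection(barcodes, names)
        flagged = report[report.verdict == "suspected_conspecific"]
        flagged_pairs = {frozenset((r.accession, r.best_hit))
                         for r in flagged.itertuples()}
        planted_pairs = {frozenset((acc, acc[:-1] + "A"))
                         for acc, _, _ in truth.misid_swaps}
        assert flagged_pairs == planted_pairs      # precision = recall = 1
        # and the suggested name is the true species
        for acc, true_name, _ in truth.misid_swaps:
            row = report[report.accession == acc].iloc[0]
            assert row.suggested_name == true_name

    def test_consistent_collection_unflagged(self):
        barcodes, names, _ = simulate_misid_audit_set(n_swaps=0, seed=22)
        report = audit_collection(barcodes, names)
        assert (report.verdict == "consistent").all()


class TestTreeConsistency:
    TAXONOMY = {
        "Carabus_a": {"genus": "Carabus", "subfamily": "Carabinae"},
        "Carabus_b": {"genus": "Carabus", "subfamily": "Carabinae"},
        "Carabus_c": {"genus": "Carabus", "subfamily": "Carabinae"},
        "Harpalus_a": {"genus": "Harpalus", "subfamily": "Harpalinae"},
        "Harpalus_b": {"genus": "Harpalus", "subfamily": "Harpalinae"},
        "Pheropsophus_x": {"genus": "Pheropsophus", "subfamily": "Brachininae"},
    }

    def test_sorted_tree_has_no_flags(self):
        tree = "((Carabus_a,(Carabus_b,Carabus_c)),(Harpalus_a,Harpalus_b));"
        taxonomy = {k: v for k, v in self.TAXONOMY.items() if k in tree}
        df = tree_consistency(tree, taxonomy)
        assert (df.status == "consistent").all()

    def test_planted_misplacement_flagged_with_sister_genus(self):
        """A brachinine leaf nested among Carabus is the only flag, and the
        suggested group is Carabus."""
        tree = ("((Carabus_a,(Carabus_b,(Carabus_c,Pheropsophus_x))),"
                "(Harpalus_a,Harpalus_b));")
        df = tree_consistency(tree, self.TAXONOMY)
        flagged = df[df.status == "flagged"]
        assert list(flagged.leaf) == ["Pheropsophus_x"]
        assert flagged.iloc[0].sister_majority_genus == "Carabus"

    def test_unmapped_leaves_listed_not_fatal(self):
        tree = "((Carabus_a,Carabus_b),Mystery_sp);"
        df = tree_consistency(tree, self.TAXONOMY)
        assert (df[df.leaf == "Mystery_sp"].status == "unmapped").all()


def test_parse_binomial():
    assert parse_binomial("Harpalus tinctulus") == ("Harpalus", "tinctulus")
    assert parse_binomial("Harpalus_sp.") == ("Harpalus", "sp.")
    assert parse_binomial("") is None
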