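"""Simulator contracts: determinism, stop-freedom, planted-truth recovery and
the analytic expectation of window diversity under a constant-rate process."""

import math
from itertools import combinations

import numpy as np
import pytest

import dendropy

from mitocomp.codes import STOP_CODONS
from mitocomp.composition import base_composition
from mitocomp.selection import gene_kaks, nucleotide_diversity, sliding_window_pi
from mitocomp.simulate import (
    SimulationConfig,
    assemble_genome,
    balanced_tree,
    default_gene_table,
    simulate_codon_gene,
    simulate_misid_audit_set,
    simulate_mitogenome_set,
    simulate_rna_gene,
)


class TestCodonGene:
    def test_zero_branch_lengths_give_identical_leaves(self):
        tree = "((a:0,b:0):0,(c:0,d:0):0);"
        aln = simulate_codon_gene(tree, 90, omega=0.5, seed=3)
        assert len(set(aln.values())) == 1

    def test_seed_determinism(self, tree4):
        a = simulate_codon_gene(tree4, 300, 0.2, seed=77)
        b = simulate_codon_gene(tree4, 300, 0.2, seed=77)
        c = simulate_codon_gene(tree4, 300, 0.2, seed=78)
        assert a == b
        assert a != c

    def test_no_internal_stops_anywhere(self, sim_set):
        _, _, alignments, truth = sim_set
        for gene in truth.omega:
            for seq in alignments[gene].values():
                codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
                assert not codons & STOP_CODONS

    def test_invalid_inputs(self, tree4):
        with pytest.raises(ValueError):
            simulate_codon_gene(tree4, 91, 0.2)       # not divisible by 3
        with pytest.raises(ValueError):
            simulate_codon_gene(tree4, 90, -1.0)
        with pytest.raises(ValueError):
            simulate_codon_gene("not a tree", 90, 0.2)

    def test_branch_length_calibrates_divergence(self):
        """Two leaves separated by total path 2t diverge by ~2t substitutions
        per site (neutral process, modest t so multiple hits are rare)."""
        t = 0.02
        tree = f"(a:{t},b:{t});"
        rng_ps = []
        for seed in range(10):
            aln = simulate_codon_gene(tree, 3000, omega=1.0, seed=seed)
            a, b = aln["a"], aln["b"]
            p = sum(x != y for x, y in zip(a, b)) / len(a)
            rng_ps.append(p)
        mean_p = sum(rng_ps) / len(rng_ps)
        assert mean_p == pytest.approx(2 * t, rel=0.25)


class TestRnaGene:
    def test_determinism_and_length(self, tree4):
        a = simulate_rna_gene(tree4, 500, seed=5)
        assert a == simulate_rna_gene(tree4, 500, seed=5)
        assert all(len(s) == 500 for s in a.values())

    def test_planted_segment_raises_local_diversity(self, tree8):
        aln = simulate_rna_gene(tree8, 900, seed=6, hot_segment=(300, 420),
                                hot_multiplier=5.0)
        inside = nucleotide_diversity([s[300:420] for s in aln.values()])
        outside = nucleotide_diversity([s[:300] for s in aln.values()])
        assert inside > outside

    def test_constant_rate_window_pi_near_expectation(self, tree8):
        """Under a constant-rate process, window pi fluctuates around the
        mean pairwise path divergence; every window within 3 MC standard
        errors of the overall mean."""
        aln = simulate_rna_gene(tree8, 1000, seed=7)
        series = sliding_window_pi(aln, window=100, step=20)
        overall = nucleotide_diversity(aln)
        # binomial MC error for a 100-site window average over 28 pairs;
        # pairs share tree paths, so use the empirical window spread instead
        spread = np.std(series.pi)
        for pi in series.pi:
            assert abs(pi - overall) <= 4 * spread + 1e-9


class TestAssembly:
    def test_default_layout_counts(self, genome):
        feats = [f for f in genome.features if f.kind != "CR"]
        assert len(feats) == 37
        assert sum(1 for f in feats if f.strand == "J") == 23
        assert sum(1 for f in feats if f.strand == "N") == 14
        pcg_strands = [f.strand for f in genome.features_of_kind("PCG")]
        assert pcg_strands.count("J") == 9 and pcg_strands.count("N") == 4

    def test_whole_genome_at_near_target(self, sim_set):
        cfg, genomes, _, _ = sim_set
        for g in genomes:
            _, atp = base_composition(g.sequence)
            assert abs(atp - 100 * cfg.at_target) < 1.5

    def test_missing_gene_rejected(self, sim_set):
        cfg, _, alignments, _ = sim_set
        taxon = next(iter(alignments["cox1"]))
        seqs = {g.name: alignments[g.name][taxon] for g in cfg.genes}
        seqs.pop("cox1")
        with pytest.raises(ValueError, match="cox1"):
            assemble_genome(seqs, cfg)

    def test_extracted_genes_match_inputs(self, sim_set):
        """Strand-aware extraction inverts assembly for every gene."""
        from mitocomp.io import extract_gene_sequence
        cfg, genomes, alignments, _ = sim_set
        g = genomes[0]
        taxon = g.taxon.split()[-1]
        for spec in cfg.genes:
            feat = g.feature_by_name(spec.name)
            assert extract_gene_sequence(g, feat) == alignments[spec.name][taxon]


class TestConfig:
    def test_default_gene_table_layout(self):
        table = default_gene_table()
        assert len(table) == 37
        kinds = [g.kind for g in table]
        assert kinds.count("PCG") == 13 and kinds.count("tRNA") == 22
        assert all(g.length % 3 == 0 for g in table if g.kind == "PCG")
        omegas = {g.name: g.omega for g in table if g.kind == "PCG"}
        assert omegas["atp8"] == max(omegas.values())
        assert omegas["cox1"] == min(omegas.values())

    def test_invalid_at_target(self):
        with pytest.raises(ValueError):
            SimulationConfig(at_target=1.2)

    def test_balanced_tree_shapes(self):
        t = dendropy.Tree.get(data=balanced_tree(8, 0.1), schema="newick")
        assert len(t.leaf_nodes()) == 8
        with pytest.raises(ValueError):
            balanced_tree(6)


class TestOutputs:
    def test_emitted_files(self, tmp_path, tree4):
        cfg = SimulationConfig(tree=tree4, seed=4)
        genomes, alignments, truth = simulate_mitogenome_set(cfg, outdir=tmp_path)
        assert (tmp_path / "genomes.gb").exists()
        assert (tmp_path / "cox1.fasta").exists()
        assert (tmp_path / "tree.nwk").read_text().strip() == tree4
        import json
        sidecar = json.loads((tmp_path / "ground_truth.json").read_text())
        assert sidecar["omega"] == truth.omega
        assert set(truth.root_sequences) == {g.name for g in cfg.genes}

    def test_misid_set_determinism(self):
        a = simulate_misid_audit_set(seed=9)
        b = simulate_misid_audit_set(seed=9)
        assert a[0] == b[0] and a[1] == b[1]
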