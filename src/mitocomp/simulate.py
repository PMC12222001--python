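"""Synthetic mitogenome and alignment generator with known ground truth.

Every analysis stage in this package is testable without downloads because
this module simulates data with the statistical structure the analyses
assume:

* codon alignments evolved down a known tree under a Muse–Gaut-style codon
  process (AT-biased target composition, transition/transversion ratio kappa,
  synonymous rate 1 vs nonsynonymous rate omega, stop codons forbidden);
* RNA-gene alignments under the analogous nucleotide process, optionally with
  a planted high-diversity segment;
* whole annotated mitogenomes assembled in the ancestral insect 37-gene
  arrangement (23 major-strand / 14 minor-strand genes) with an AT-rich
  control region, emitted through the same GenBank I/O the real pipeline
  consumes;
* barcode audit sets with planted conspecific relabellings.

Substitutions are realized as exponential-waiting-time events per codon (or
site) along each branch; branch lengths are calibrated to expected
substitutions per nucleotide site under the root composition.  Every output
is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from .codes import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    reverse_complement,
)
from .io import GeneFeature, KIND_BY_NAME, MitoGenome, write_genbank

__all__ = [
    "GeneSpec", "SimulationConfig", "GroundTruth", "default_gene_table",
    "balanced_tree", "simulate_codon_gene", "simulate_rna_gene",
    "assemble_genome", "simulate_mitogenome_set", "simulate_misid_audit_set",
]

# realistic per-gene lengths (bp, divisible by 3 for PCGs) and an omega
# gradient emulating the canonical mitochondrial selection hierarchy:
# atp8 fastest; nad2/nad6/nad4l intermediate; cox1 slowest.
DEFAULT_PCG_PARAMS: dict[str, tuple[int, float]] = {
    "atp6": (678, 0.15), "atp8": (159, 0.60), "cob": (1140, 0.10),
    "cox1": (1536, 0.05), "cox2": (684, 0.08), "cox3": (786, 0.08),
    "nad1": (936, 0.15), "nad2": (1023, 0.35), "nad3": (351, 0.20),
    "nad4": (1338, 0.20), "nad4l": (288, 0.30), "nad5": (1716, 0.20),
    "nad6": (522, 0.35),
}
DEFAULT_RRNA_LENGTHS = {"rrnL": 1280, "rrnS": 780}
DEFAULT_TRNA_LENGTH = 66


@dataclass(frozen=True)
class GeneSpec:
    name: str
    kind: str            # PCG | tRNA | rRNA
    length: int
    strand: str          # J | N
    omega: float = 1.0   # dN/dS target; ignored for non-coding genes


@dataclass
class SimulationConfig:
    """Simulation conditions: tree, per-gene (length, omega), composition.

    Defaults emulate an insect mitogenome: canonical 37-gene arrangement with
    the 23 J / 14 N strand split, ~80% AT, kappa = 4, a 1.1 kb control region,
    and the conventional omega gradient across the 13 protein genes.
    """

    tree: str = ""                        # newick with branch lengths
    genes: list[GeneSpec] = field(default_factory=list)
    kappa: float = 4.0
    at_target: float = 0.80
    cr_length: int = 1100
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            self.genes = default_gene_table()
        if not self.tree:
            self.tree = balanced_tree(8, branch_length=0.05)
        if not (0.0 < self.at_target < 1.0):
            raise ValueError("at_target must be in (0,1)")
        for g in self.genes:
            if g.kind == "PCG" and g.length % 3:
                raise ValueError(f"{g.name}: PCG length must be divisible by 3")


@dataclass
class GroundTruth:
    """Planted truth addressable by tests: per-gene omega, high-diversity
    segments (gene, start, end; 0-based columns), misidentification swaps
    (record id, true name, planted wrong name) and the root sequences."""

    omega: dict[str, float] = field(default_factory=dict)
    diversity_segments: list[tuple[str, int, int]] = field(default_factory=list)
    misid_swaps: list[tuple[str, str, str]] = field(default_factory=list)
    root_sequences: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "omega": self.omega,
            "diversity_segments": self.diversity_segments,
            "misid_swaps": self.misid_swaps,
            "root_sequences": self.root_sequences,
        }, indent=1))


def default_gene_table() -> list[GeneSpec]:
    """The packaged ancestral insect gene arrangement with default lengths
    and the omega gradient (control region excluded — appended separately)."""
    out = []
    text = resources.files("mitocomp.data").joinpath("gene_order.tsv").read_text()
    for line in text.splitlines()[1:]:
        name, kind, strand = line.split("\t")
        if kind == "CR":
            continue
        if kind == "PCG":
            length, omega = DEFAULT_PCG_PARAMS[name]
        elif kind == "rRNA":
            length, omega = DEFAULT_RRNA_LENGTHS[name], 1.0
        else:
            length, omega = DEFAULT_TRNA_LENGTH, 1.0
        out.append(GeneSpec(name, kind, length, strand, omega))
    return out


def balanced_tree(n_taxa: int, branch_length: float = 0.05,
                  prefix: str = "t") -> str:
    """Newick for a fully balanced tree on ``n_taxa`` (a power of two) with a
    uniform branch length."""
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of two >= 2")
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]

    def build(block: list[str]) -> str:
        if len(block) == 1:
            return f"{block[0]}:{branch_length}"
        half = len(block) // 2
        return f"({build(block[:half])},{build(block[half:])}):{branch_length}"

    inner = build(labels)
    return inner.rsplit(":", 1)[0] + ";"


def _parse_tree(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:                      # dendropy raises various types
        raise ValueError(f"invalid newick tree: {exc}") from exc


# ---------------------------------------------------------------------------
# codon process
# ---------------------------------------------------------------------------

def _base_probs(at_target: float) -> np.ndarray:
    at = at_target / 2.0
    gc = (1.0 - at_target) / 2.0
    return np.array([at, gc, gc, at])    # A C G T


class _CodonProcess:
    """Precomputed event rates for one (omega, kappa, at_target) setting.

    For sense codon i, each of its 9 single-base neighbours j gets rate
    pi(target base) * kappa^[transition] * (1 if synonymous else omega), and 0
    if j is a stop.  ``scale`` converts branch lengths (expected substitutions
    per nucleotide site under the root codon distribution) into event time.
    """

    def __init__(self, omega: float, kappa: float, at_target: float):
        if omega <= 0:
            raise ValueError("omega must be positive")
        pi = _base_probs(at_target)
        base_index = {b: k for k, b in enumerate(NUCLEOTIDES)}
        self.codon_index = {c: i for i, c in enumerate(SENSE_CODONS)}
        n = len(SENSE_CODONS)
        self.targets = np.zeros((n, 9), dtype=np.int64)
        self.rates = np.zeros((n, 9))
        for i, codon in enumerate(SENSE_CODONS):
            slot = 0
            for pos in range(3):
                for b in NUCLEOTIDES:
                    if b == codon[pos]:
                        continue
                    mutant = codon[:pos] + b + codon[pos + 1:]
                    if mutant in STOP_CODONS:
                        rate = 0.0
                        tgt = i
                    else:
                        rate = pi[base_index[b]]
                        if is_transition(codon[pos], b):
                            rate *= kappa
                        if CODON_TO_AA[mutant] != CODON_TO_AA[codon]:
                            rate *= omega
                        tgt = self.codon_index[mutant]
                    self.targets[i, slot] = tgt
                    self.rates[i, slot] = rate
                    slot += 1
        self.total = self.rates.sum(axis=1)
        self.cum = np.cumsum(self.rates, axis=1)
        # root codon distribution: product of base probs, stops excluded
        root_p = np.array([
            pi[base_index[c[0]]] * pi[base_index[c[1]]] * pi[base_index[c[2]]]
            for c in SENSE_CODONS
        ])
        self.root_probs = root_p / root_p.sum()
        # expected events per codon at the root composition -> per-site scale
        self.scale = float(self.root_probs @ self.total) / 3.0

    def draw_root(self, n_codons: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(len(SENSE_CODONS), size=n_codons, p=self.root_probs)

    def evolve(self, codons: np.ndarray, t: float,
               rng: np.random.Generator) -> np.ndarray:
        """Evolve a codon-index vector for branch length t (subs/site)."""
        out = codons.copy()
        if t <= 0 or self.scale == 0:
            return out
        # per-codon Gillespie: waiting times Exp(total/scale); the scale makes
        # a branch of length t carry ~t expected substitutions per nt site
        for k in range(out.size):
            remaining = t
            state = out[k]
            while True:
                rate = self.total[state] / self.scale
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > remaining:
                    break
                remaining -= wait
                u = rng.random() * self.total[state]
                slot = int(np.searchsorted(self.cum[state], u, side="right"))
                state = int(self.targets[state, min(slot, 8)])
            out[k] = state
        return out


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def _simulate_down_tree(tree: dendropy.Tree, root, evolve) -> dict[str, object]:
    """Generic pre-order walk: ``evolve(state, branch_length)`` per edge."""
    states = {tree.seed_node: root}
    leaves = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = root
        else:
            t = node.edge.length or 0.0
            state = evolve(states[node.parent_node], t)
        states[node] = state
        if node.is_leaf():
            leaves[node.taxon.label] = state
    return leaves


def simulate_codon_gene(
    tree: str,
    length: int,
    omega: float,
    kappa: float = 4.0,
    at_target: float = 0.80,
    seed: int = 0,
    with_root: bool = False,
):
    """Simulate an in-frame codon alignment down ``tree`` (stop-free).

    ``length`` is in nucleotides and must be divisible by 3; branch lengths
    are expected substitutions per nucleotide site.  Deterministic in
    (arguments, seed).  With ``with_root=True`` returns (alignment, root
    sequence) so planted truth stays addressable.
    """
    if length % 3:
        raise ValueError("length must be divisible by 3")
    t = _parse_tree(tree)
    proc = _CodonProcess(omega, kappa, at_target)
    rng = np.random.default_rng(seed)
    root = proc.draw_root(length // 3, rng)
    leaves = _simulate_down_tree(
        t, root, lambda state, bl: proc.evolve(state, bl, rng)
    )
    out = {label: _indices_to_seq(idx) for label, idx in leaves.items()}
    if with_root:
        return out, _indices_to_seq(root)
    return out


# ---------------------------------------------------------------------------
# nucleotide (RNA gene / control region) process
# ---------------------------------------------------------------------------

class _NucProcess:
    """HKY-like per-site process with target composition pi and ratio kappa."""

    def __init__(self, kappa: float, at_target: float):
        pi = _base_probs(at_target)
        self.rates = np.zeros((4, 4))
        for i, a in enumerate(NUCLEOTIDES):
            for j, b in enumerate(NUCLEOTIDES):
                if i == j:
                    continue
                self.rates[i, j] = pi[j] * (kappa if is_transition(a, b) else 1.0)
        self.total = self.rates.sum(axis=1)
        self.cum = np.cumsum(self.rates, axis=1)
        self.pi = pi
        self.scale = float(pi @ self.total)

    def draw_root(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(4, size=n, p=self.pi)

    def evolve(self, sites: np.ndarray, t: float, rng: np.random.Generator,
               rate_multiplier: Optional[np.ndarray] = None) -> np.ndarray:
        out = sites.copy()
        if t <= 0:
            return out
        for k in range(out.size):
            mult = 1.0 if rate_multiplier is None else float(rate_multiplier[k])
            remaining = t
            state = out[k]
            while True:
                rate = mult * self.total[state] / self.scale
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > remaining:
                    break
                remaining -= wait
                u = rng.random() * self.total[state]
                slot = int(np.searchsorted(self.cum[state], u, side="right"))
                state = min(slot, 3)
            out[k] = state
        return out


def _nuc_indices_to_seq(idx: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[i] for i in idx)


def simulate_rna_gene(
    tree: str,
    length: int,
    at_target: float = 0.80,
    kappa: float = 4.0,
    seed: int = 0,
    hot_segment: Optional[tuple[int, int]] = None,
    hot_multiplier: float = 5.0,
    with_root: bool = False,
):
    """Simulate a non-coding nucleotide alignment; ``hot_segment=(start, end)``
    (0-based half-open columns) plants a segment evolving ``hot_multiplier``
    times faster, for sliding-window diversity recovery tests."""
    t = _parse_tree(tree)
    proc = _NucProcess(kappa, at_target)
    rng = np.random.default_rng(seed)
    root = proc.draw_root(length, rng)
    mult = None
    if hot_segment is not None:
        s, e = hot_segment
        if not (0 <= s < e <= length):
            raise ValueError("hot_segment outside [0, length)")
        mult = np.ones(length)
        mult[s:e] = hot_multiplier
    leaves = _simulate_down_tree(
        t, root, lambda state, bl: proc.evolve(state, bl, rng, mult)
    )
    out = {label: _nuc_indices_to_seq(idx) for label, idx in leaves.items()}
    if with_root:
        return out, _nuc_indices_to_seq(root)
    return out


def random_at_rich_sequence(length: int, at_target: float,
                            rng: np.random.Generator) -> str:
    """i.i.d. AT-biased sequence (the control-region model)."""
    return _nuc_indices_to_seq(rng.choice(4, size=length, p=_base_probs(at_target)))


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def assemble_genome(
    gene_sequences: dict[str, str],
    config: SimulationConfig,
    identifier: str = "synthetic",
    taxon: str = "Synthetica exempli",
    cr_sequence: Optional[str] = None,
) -> MitoGenome:
    """Lay per-gene coding-orientation sequences out on a circular genome.

    Genes follow the configured order; minor-strand genes are stored
    reverse-complemented on the forward strand; the AT-rich control region is
    appended after the last gene.  One sequence per configured gene is
    required.
    """
    missing = [g.name for g in config.genes if g.name not in gene_sequences]
    if missing:
        raise ValueError(f"missing gene sequences: {missing}")
    rng = np.random.default_rng(config.seed + 7919)
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for g in config.genes:
        seq = gene_sequences[g.name].upper()
        stored = reverse_complement(seq) if g.strand == "N" else seq
        features.append(GeneFeature(
            g.name, KIND_BY_NAME[g.name], pos, pos + len(stored), g.strand,
            raw_label=g.name,
        ))
        parts.append(stored)
        pos += len(stored)
    cr = cr_sequence if cr_sequence is not None else random_at_rich_sequence(
        config.cr_length, min(config.at_target + 0.05, 0.98), rng)
    features.append(GeneFeature("control_region", "CR", pos, pos + len(cr), "J",
                                raw_label="control region"))
    parts.append(cr)
    return MitoGenome(identifier, "".join(parts), True, features, taxon)


def simulate_mitogenome_set(
    config: Optional[SimulationConfig] = None,
    outdir: Optional[Union[str, Path]] = None,
) -> tuple[list[MitoGenome], dict[str, dict[str, str]], GroundTruth]:
    """Simulate a full mitogenome collection down the configured tree.

    Returns (genomes, per-gene leaf alignments, ground truth).  With
    ``outdir`` set, also writes a multi-record GenBank file, per-gene FASTA
    alignments, the tree and the ground-truth JSON sidecar.
    """
    config = config or SimulationConfig()
    truth = GroundTruth()
    alignments: dict[str, dict[str, str]] = {}
    for i, g in enumerate(config.genes):
        gene_seed = config.seed * 100003 + i
        if g.kind == "PCG":
            aln, root = simulate_codon_gene(
                config.tree, g.length, g.omega, config.kappa,
                config.at_target, gene_seed, with_root=True)
            truth.omega[g.name] = g.omega
        else:
            aln, root = simulate_rna_gene(
                config.tree, g.length, config.at_target, config.kappa,
                seed=gene_seed, with_root=True)
        alignments[g.name] = aln
        truth.root_sequences[g.name] = root
    taxa = list(next(iter(alignments.values())))
    genomes = []
    for j, taxon in enumerate(taxa):
        per_gene = {g.name: alignments[g.name][taxon] for g in config.genes}
        sub = SimulationConfig(tree=config.tree, genes=config.genes,
                               kappa=config.kappa, at_target=config.at_target,
                               cr_length=config.cr_length,
                               seed=config.seed * 1009 + j)
        genomes.append(assemble_genome(per_gene, sub, identifier=f"SYN{j + 1:04d}",
                                       taxon=f"Synthetica {taxon}"))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genbank(genomes, outdir / "genomes.gb")
        from .io import write_fasta
        for gene, aln in alignments.items():
            write_fasta(aln, outdir / f"{gene}.fasta")
        (outdir / "tree.nwk").write_text(config.tree + "\n")
        truth.to_json(outdir / "ground_truth.json")
    return genomes, alignments, truth


# ---------------------------------------------------------------------------
# misidentification audit set
# ---------------------------------------------------------------------------

def simulate_misid_audit_set(
    n_species: int = 6,
    barcode_length: int = 657,
    species_divergence: float = 0.10,
    conspecific_divergence: float = 0.002,
    n_swaps: int = 1,
    at_target: float = 0.70,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Barcode collection with planted conspecific relabellings.

    Each species contributes two individuals (tiny within-species divergence);
    species are mutually divergent.  For ``n_swaps`` species the second
    individual is deposited under the *next* species' name — the planted
    misidentifications an audit must recover.  Returns (barcodes, nominal
    names, ground truth).
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    proc = _CodonProcess(omega=0.1, kappa=4.0, at_target=at_target)
    root = proc.draw_root(barcode_length // 3, rng)
    species_roots = [proc.evolve(root, species_divergence, rng)
                     for _ in range(n_species)]
    names = {}
    barcodes = {}
    truth = GroundTruth()
    for i, sroot in enumerate(species_roots):
        species = f"Synthetica species{i + 1}"
        for k in range(2):
            acc = f"SYN{i + 1:03d}{'A' if k == 0 else 'B'}"
            ind = proc.evolve(sroot, conspecific_divergence / 2.0, rng)
            barcodes[acc] = _indices_to_seq(ind)
            names[acc] = species
    for i in range(n_swaps):
        acc = f"SYN{i + 1:03d}B"
        wrong = f"Synthetica species{(i + 1) % n_species + 1}"
        truth.misid_swaps.append((acc, names[acc], wrong))
        names[acc] = wrong
    return barcodes, names, truth
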