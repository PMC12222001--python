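"""Phylogenetic supermatrix construction from per-gene alignments.

Three dataset flavours are built from the 13 protein-coding genes and the two
rRNAs:

* ``AA``    — table-5 amino-acid translations of the 13 PCGs;
* ``P12R``  — codon positions 1+2 of the PCGs, plus rrnL and rrnS;
* ``P123R`` — all codon positions of the PCGs, plus rrnL and rrnS.

Genes are concatenated in a fixed canonical order with per-gene partition
bookkeeping; taxa missing from a gene are filled with gaps.  Partition
definitions are emitted both as RAxML-style plain text and as a NEXUS sets
block, for the no-partition (NP: one block) and full-partition (FP: one block
per gene) schemes.  Model selection and partition merging are downstream
tool concerns, not handled here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .codes import translate_codon
from .io import PCG_NAMES, write_fasta

logger = logging.getLogger(__name__)

#: fixed concatenation order: PCGs then rRNAs
GENE_ORDER = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "nad4l",
    "rrnL", "rrnS",
)
DATASET_KINDS = ("AA", "P12R", "P123R")
SCHEME_KINDS = ("NP", "FP")


@dataclass
class Supermatrix:
    """Concatenated character matrix with partition bookkeeping.

    ``partitions`` are (name, start, end), 1-based inclusive, disjoint and
    exactly tiling [1, length] in order.
    """

    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]
    dataset_kind: str

    def __post_init__(self):
        lengths = {len(s) for s in self.matrix.values()}
        if len(lengths) > 1:
            raise ValueError("matrix rows have unequal lengths")
        pos = 1
        for name, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError(f"partition {name} ({start}-{end}) breaks tiling at {pos}")
            pos = end + 1
        if self.matrix and pos != self.length + 1:
            raise ValueError("partitions do not tile the matrix")

    @property
    def length(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0

    @property
    def is_protein(self) -> bool:
        return self.dataset_kind == "AA"

    def position_subpartitions(self) -> list[tuple[str, int, int, int]]:
        """Codon-position subsets of each PCG partition as (name, start, end,
        stride) — RAxML ``start-end\\stride`` ranges — for optional export with
        position-aware partitioning tools.  Empty for amino-acid matrices."""
        if self.is_protein:
            return []
        stride = 2 if self.dataset_kind == "P12R" else 3
        out = []
        for name, start, end in self.partitions:
            if name not in PCG_NAMES:
                continue
            for p in range(stride):
                out.append((f"{name}_pos{p + 1}", start + p, end, stride))
        return out


def codon_positions(alignment: Mapping[str, str], keep: set[int]) -> dict[str, str]:
    """Keep only the given codon positions (subset of {1,2,3}) of an in-frame
    nucleotide alignment."""
    if not keep or not keep <= {1, 2, 3}:
        raise ValueError("keep must be a non-empty subset of {1,2,3}")
    out = {}
    for taxon, seq in alignment.items():
        if len(seq) % 3:
            raise ValueError(f"{taxon}: length {len(seq)} not divisible by 3")
        out[taxon] = "".join(
            seq[i + p - 1] for i in range(0, len(seq), 3) for p in sorted(keep)
        )
    return out


def translate_alignment(alignment: Mapping[str, str]) -> dict[str, str]:
    """Codon alignment -> amino-acid alignment under table 5.

    ``---`` -> ``-``; partially gapped or ambiguous codons -> ``X``; internal
    stops translate to ``*`` with a warning (annotations may be imperfect).
    """
    out = {}
    for taxon, seq in alignment.items():
        if len(seq) % 3:
            raise ValueError(f"{taxon}: length {len(seq)} not divisible by 3")
        aas = [translate_codon(seq[i:i + 3]) for i in range(0, len(seq), 3)]
        n_stops = sum(1 for i, aa in enumerate(aas[:-1]) if aa == "*")
        if n_stops:
            logger.warning("%s: %d internal stop codon(s) translated to '*'",
                           taxon, n_stops)
        out[taxon] = "".join(aas)
    return out


def _pairs_to_mapping(gene: str, pairs) -> dict[str, str]:
    out: dict[str, str] = {}
    for taxon, row in pairs:
        if taxon in out:
            raise ValueError(f"{gene}: duplicate taxon label {taxon!r}")
        out[taxon] = row
    return out


def concatenate(
    gene_alignments: Mapping[str, Mapping[str, str]],
    taxa: Optional[Sequence[str]] = None,
    dataset_kind: str = "P123R",
    fill_char: str = "-",
) -> Supermatrix:
    """Concatenate per-gene alignments (name -> {taxon: row}) in canonical
    gene order into a Supermatrix.

    The taxon universe defaults to the union over genes (first-seen order).
    Taxa missing from a gene get a gap-filled block; the fill count is logged.
    Per-gene alignments may also be given as (taxon, row) pair lists, in which
    case duplicate taxon labels raise.
    """
    gene_alignments = {
        gene: (aln if isinstance(aln, Mapping) else _pairs_to_mapping(gene, aln))
        for gene, aln in gene_alignments.items()
    }
    for gene, aln in gene_alignments.items():
        if len(set(map(len, aln.values()))) > 1:
            raise ValueError(f"{gene}: unequal row lengths")
    if taxa is None:
        taxa = []
        for gene in GENE_ORDER:
            for t in gene_alignments.get(gene, {}):
                if t not in taxa:
                    taxa.append(t)
    taxa = list(taxa)
    ordered = [g for g in GENE_ORDER if g in gene_alignments]
    extra = set(gene_alignments) - set(ordered)
    if extra:
        raise ValueError(f"unknown gene names: {sorted(extra)}")
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    n_filled = 0
    for gene in ordered:
        aln = gene_alignments[gene]
        glen = len(next(iter(aln.values())))
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t])
            else:
                rows[t].append(fill_char * glen)
                n_filled += 1
        partitions.append((gene, pos, pos + glen - 1))
        pos += glen
    if n_filled:
        logger.info("concatenate: gap-filled %d missing taxon-gene blocks", n_filled)
    return Supermatrix(taxa, {t: "".join(parts) for t, parts in rows.items()},
                       partitions, dataset_kind)


def build_dataset(
    pcg_alignments: Mapping[str, Mapping[str, str]],
    rrna_alignments: Optional[Mapping[str, Mapping[str, str]]] = None,
    kind: str = "P123R",
    taxa: Optional[Sequence[str]] = None,
    fill_char: str = "-",
) -> Supermatrix:
    """Build one of the three standard datasets from in-frame PCG alignments
    (and rRNA alignments for the nucleotide flavours)."""
    if kind not in DATASET_KINDS:
        raise ValueError(f"kind must be one of {DATASET_KINDS}")
    unknown = set(pcg_alignments) - set(PCG_NAMES)
    if unknown:
        raise ValueError(f"not protein-coding genes: {sorted(unknown)}")
    genes: dict[str, Mapping[str, str]] = {}
    if kind == "AA":
        for g, aln in pcg_alignments.items():
            genes[g] = translate_alignment(aln)
    else:
        keep = {1, 2} if kind == "P12R" else {1, 2, 3}
        for g, aln in pcg_alignments.items():
            genes[g] = codon_positions(aln, keep)
        for g, aln in (rrna_alignments or {}).items():
            if g not in ("rrnL", "rrnS"):
                raise ValueError(f"not an rRNA gene: {g}")
            genes[g] = aln
    return concatenate(genes, taxa=taxa, dataset_kind=kind, fill_char=fill_char)


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_phylip(sm: Supermatrix, path: Union[str, Path]) -> None:
    """Relaxed PHYLIP: labels of any length, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.matrix[t]}\n")


def _scheme_blocks(sm: Supermatrix, scheme: str) -> list[tuple[str, int, int]]:
    if scheme == "NP":
        return [("all", 1, sm.length)]
    if scheme == "FP":
        return list(sm.partitions)
    raise ValueError(f"scheme must be one of {SCHEME_KINDS}")


def write_raxml_partitions(sm: Supermatrix, scheme: str, path: Union[str, Path]) -> None:
    """RAxML-style partition lines, e.g. ``DNA, cox1 = 101-1636`` (``LG`` as a
    placeholder datatype for amino-acid matrices)."""
    datatype = "LG" if sm.is_protein else "DNA"
    with open(path, "w") as fh:
        for name, start, end in _scheme_blocks(sm, scheme):
            fh.write(f"{datatype}, {name} = {start}-{end}\n")


def write_nexus_sets(sm: Supermatrix, scheme: str, path: Union[str, Path]) -> None:
    """NEXUS sets block with one charset per scheme block."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin sets;\n")
        for name, start, end in _scheme_blocks(sm, scheme):
            fh.write(f"    charset {name} = {start}-{end};\n")
        fh.write("end;\n")


def read_raxml_partitions(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    blocks = []
    for line in Path(path).read_text().splitlines():
        m = re.match(r"\s*\S+,\s*(\S+)\s*=\s*(\d+)-(\d+)\s*$", line)
        if m:
            blocks.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return blocks


def read_nexus_sets(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    blocks = []
    for m in re.finditer(r"charset\s+(\S+)\s*=\s*(\d+)-(\d+)\s*;",
                         Path(path).read_text()):
        blocks.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return blocks


def write_dataset(
    sm: Supermatrix, scheme: str, outdir: Union[str, Path], prefix: str = "dataset"
) -> dict[str, Path]:
    """Emit matrix (FASTA + relaxed PHYLIP) and partition files (RAxML text +
    NEXUS sets) for one partition scheme; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}_{sm.dataset_kind}.fasta",
        "phylip": outdir / f"{prefix}_{sm.dataset_kind}.phy",
        "raxml": outdir / f"{prefix}_{sm.dataset_kind}_{scheme}.partitions.txt",
        "nexus": outdir / f"{prefix}_{sm.dataset_kind}_{scheme}.sets.nex",
    }
    write_fasta(sm.matrix, paths["fasta"])
    write_phylip(sm, paths["phylip"])
    write_raxml_partitions(sm, scheme, paths["raxml"])
    write_nexus_sets(sm, scheme, paths["nexus"])
    return paths
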