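"""Annotated-mitogenome I/O and gene-name normalization.

Reads and writes GenBank flatfiles through Biopython, converting between
GenBank's 1-based inclusive locations and the 0-based half-open forward-strand
coordinates used internally.  Gene labels are normalized to the canonical
37-gene insect mitochondrial vocabulary (13 PCGs, 22 tRNAs, 2 rRNAs) plus the
control region via a packaged synonym table; unknown labels map to an explicit
``None`` rather than a guess.

Features that span the circular origin (GenBank ``join(x..L,1..y)``) are kept
as an explicit pair of intervals with a wrap flag, never folded into modular
arithmetic.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codes import reverse_complement

logger = logging.getLogger(__name__)

PCG_NAMES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
TRNA_NAMES = tuple(
    f"trn{x}" for x in "ACDEFGHIKMNPQRTVWY"
) + ("trnL1", "trnL2", "trnS1", "trnS2")
RRNA_NAMES = ("rrnL", "rrnS")
CANONICAL_GENES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES
CONTROL_REGION = "control_region"

KIND_BY_NAME = {
    **{n: "PCG" for n in PCG_NAMES},
    **{n: "tRNA" for n in TRNA_NAMES},
    **{n: "rRNA" for n in RRNA_NAMES},
    CONTROL_REGION: "CR",
}

# anticodons of the two Leu/Ser isoacceptors (DNA alphabet)
_ANTICODON_TO_CANON = {
    "TAG": "trnL1", "TAA": "trnL2",   # CUN / UUR families
    "TCT": "trnS1", "GCT": "trnS1",   # AGN family
    "TGA": "trnS2",                   # UCN family
}


def _norm_key(label: str) -> str:
    return "".join(ch for ch in label.upper() if ch.isalnum())


def _load_name_table() -> dict[str, str]:
    table = {}
    text = resources.files("mitocomp.data").joinpath("gene_names.tsv").read_text()
    for line in text.splitlines()[1:]:
        raw, canon = line.rstrip("\n").split("\t")
        table[_norm_key(raw)] = canon
    for canon in CANONICAL_GENES:
        table.setdefault(_norm_key(canon), canon)
    return table


_NAME_TABLE = _load_name_table()


def load_gene_name_table(path: Optional[Union[str, Path]] = None) -> dict[str, str]:
    """The synonym->canonical mapping; a user TSV (raw_label, canonical_name)
    extends/overrides the packaged table."""
    table = dict(_NAME_TABLE)
    if path is not None:
        for line in Path(path).read_text().splitlines()[1:]:
            raw, canon = line.rstrip("\n").split("\t")[:2]
            table[_norm_key(raw)] = canon
    return table


def normalize_gene_name(
    raw_label: str,
    anticodon: Optional[str] = None,
    table: Optional[dict[str, str]] = None,
) -> Optional[str]:
    """Map a free-form gene label to its canonical name, or ``None`` if unmapped.

    Lookup is case-insensitive and punctuation-tolerant.  ``tRNA-Leu`` /
    ``tRNA-Ser`` are only resolved to trnL1/trnL2/trnS1/trnS2 when the
    anticodon (or a codon-family suffix in the label) disambiguates them;
    bare labels stay unmapped rather than being positionally guessed.
    """
    if not raw_label:
        return None
    table = table if table is not None else _NAME_TABLE
    key = _norm_key(raw_label)
    hit = table.get(key)
    if hit is not None:
        return hit
    # ambiguous Leu/Ser: try the anticodon qualifier
    if key in ("TRNALEU", "TRNL", "TRNASER", "TRNS") and anticodon:
        anti = _norm_key(anticodon).replace("U", "T")[-3:]
        canon = _ANTICODON_TO_CANON.get(anti)
        if canon is not None and canon[3] == ("L" if "L" in key else "S"):
            return canon
    return None


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the forward strand of a mitogenome.

    ``start``/``end`` are 0-based half-open.  A feature crossing the circular
    origin carries ``wrap=(0, tail_end)`` as its second interval; ``start``/
    ``end`` then describe the pre-origin part (ending at genome length).
    """

    canonical_name: str
    kind: str                       # PCG | tRNA | rRNA | CR
    start: int
    end: int
    strand: str                     # J (+) | N (-)
    codon_start_offset: int = 0
    raw_label: str = ""
    wrap: Optional[tuple[int, int]] = None

    def __post_init__(self):
        expected = KIND_BY_NAME.get(self.canonical_name)
        if expected is not None and expected != self.kind:
            raise ValueError(
                f"kind {self.kind!r} inconsistent with {self.canonical_name!r}"
            )
        if self.wrap is None and self.end <= self.start:
            raise ValueError("end must exceed start for non-wrapping features")
        if self.strand not in ("J", "N"):
            raise ValueError("strand must be 'J' or 'N'")

    @property
    def wraps_origin(self) -> bool:
        return self.wrap is not None

    @property
    def length(self) -> int:
        n = self.end - self.start
        if self.wrap is not None:
            n += self.wrap[1] - self.wrap[0]
        return n

    def intervals(self) -> tuple[tuple[int, int], ...]:
        if self.wrap is None:
            return ((self.start, self.end),)
        return ((self.start, self.end), self.wrap)


@dataclass
class MitoGenome:
    """An annotated (usually circular) mitochondrial genome."""

    identifier: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    taxon: str = ""
    taxonomy: Optional[dict[str, str]] = None   # genus/tribe/subfamily/family

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        n = len(self.sequence)
        seen = set()
        for f in self.features:
            for s, e in f.intervals():
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"feature {f.canonical_name} interval ({s},{e}) outside [0,{n})"
                    )
            key = (f.canonical_name, f.intervals())
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def feature_by_name(self, canonical_name: str) -> Optional[GeneFeature]:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        return None


def extract_gene_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Strand-aware gene sequence: forward slice for J, reverse complement for
    N; origin-wrapping features concatenated tail+head; ``codon_start_offset``
    applied to PCGs so the result starts in frame."""
    n = len(genome.sequence)
    parts = []
    for s, e in feature.intervals():
        if not (0 <= s < e <= n):
            raise ValueError(f"interval ({s},{e}) out of range for length {n}")
        parts.append(genome.sequence[s:e])
    seq = "".join(parts)
    if feature.strand == "N":
        seq = reverse_complement(seq)
    if feature.kind == "PCG" and feature.codon_start_offset:
        seq = seq[feature.codon_start_offset:]
    return seq


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "gene", "misc_feature", "D-loop")


def _feature_label(feat: SeqFeature) -> str:
    for q in ("gene", "product", "note", "standard_name"):
        if q in feat.qualifiers:
            return str(feat.qualifiers[q][0])
    return ""


def _feature_anticodon(feat: SeqFeature) -> Optional[str]:
    if "anticodon" in feat.qualifiers:
        text = str(feat.qualifiers["anticodon"][0])
        m = re.search(r"seq\s*:\s*([a-zA-Z]{3})", text)
        if m:
            return m.group(1)
        if len(text) <= 4:
            return text
    return None


def _record_to_genome(rec: SeqRecord) -> MitoGenome:
    seq = str(rec.seq).upper()
    n = len(seq)
    circular = rec.annotations.get("topology", "") == "circular"
    taxon = rec.annotations.get("organism", "") or ""
    feats: list[GeneFeature] = []
    seen: set[tuple] = set()
    for feat in rec.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        label = _feature_label(feat)
        canon = normalize_gene_name(label, anticodon=_feature_anticodon(feat))
        if canon is None:
            if feat.type in ("misc_feature", "D-loop"):
                if feat.type == "D-loop" or "control" in label.lower():
                    canon = CONTROL_REGION
            if canon is None:
                logger.debug("skipping unmapped feature %r (%s)", label, feat.type)
                continue
        kind = KIND_BY_NAME[canon]
        loc = feat.location
        strand = "N" if loc.strand == -1 else "J"
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 1:
            start, end, wrap = int(parts[0].start), int(parts[0].end), None
        elif len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
            # join across the circular origin
            start, end = int(parts[1].start), int(parts[1].end)
            wrap = (0, int(parts[0].end))
        else:
            raise ValueError(
                f"{rec.id}: unsupported compound location for {label!r}: {loc}"
            )
        offset = 0
        if "codon_start" in feat.qualifiers:
            offset = int(feat.qualifiers["codon_start"][0]) - 1
        key = (canon, start, end, wrap)
        if key in seen:
            # a typed feature refines an earlier bare 'gene' twin at the same span
            if feat.type != "gene":
                for i, prev in enumerate(feats):
                    if (prev.canonical_name, prev.start, prev.end, prev.wrap) == key:
                        feats[i] = replace(prev, codon_start_offset=offset,
                                           raw_label=label or prev.raw_label)
                        break
            continue
        seen.add(key)
        feats.append(GeneFeature(canon, kind, start, end, strand, offset, label, wrap))
    return MitoGenome(rec.id or rec.name, seq, circular, feats, taxon)


def parse_genbank(source: Union[str, Path, TextIO]) -> list[MitoGenome]:
    """Parse a (possibly multi-record) GenBank flatfile into MitoGenomes."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle: Union[TextIO, str] = str(source)
    elif isinstance(source, str):
        handle = _io.StringIO(source)
    else:
        handle = source
    genomes = []
    for rec in SeqIO.parse(handle, "genbank"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id}: empty sequence")
        genomes.append(_record_to_genome(rec))
    return genomes


def _genome_to_record(genome: MitoGenome) -> SeqRecord:
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier.split(".")[0][:16] or "mito",
        description=f"{genome.taxon} mitochondrion".strip(),
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    if genome.taxon:
        rec.annotations["organism"] = genome.taxon
        rec.annotations["source"] = genome.taxon
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.intervals()]
        if len(locs) == 2:
            # GenBank order for a wrap: tail (pre-origin) first
            location = CompoundLocation(locs)
        else:
            location = locs[0]
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}[f.kind]
        quals: dict[str, list[str]] = {"gene": [f.canonical_name]}
        if f.kind == "PCG":
            quals["codon_start"] = [str(f.codon_start_offset + 1)]
        if f.kind == "CR":
            quals = {"note": ["control region"]}
        if f.raw_label and f.raw_label != f.canonical_name:
            quals.setdefault("note", []).append(f.raw_label)
        rec.features.append(SeqFeature(location, type=ftype, qualifiers=quals))
    return rec


def write_genbank(genomes: Iterable[MitoGenome], target: Union[str, Path, TextIO]) -> None:
    """Write MitoGenomes as a GenBank flatfile (inverse of :func:`parse_genbank`)."""
    records = [_genome_to_record(g) for g in genomes]
    if isinstance(target, (str, Path)):
        with open(target, "w") as fh:
            SeqIO.write(records, fh, "genbank")
    else:
        SeqIO.write(records, target, "genbank")


def read_fasta(source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Multi-FASTA -> {label: sequence} (order preserved)."""
    if isinstance(source, str) and "\n" in source:
        source = _io.StringIO(source)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def write_fasta(seqs: dict[str, str], target: Union[str, Path, TextIO]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    if isinstance(target, (str, Path)):
        with open(target, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, target, "fasta")
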