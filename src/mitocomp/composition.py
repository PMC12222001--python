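"""Base composition, AT content and strand-skew statistics.

Mitogenomes replicate asymmetrically, which leaves a compositional fingerprint:
the two strands accumulate A vs T (and G vs C) at different rates.  The
standard summaries are

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on whole genomes and on pooled region classes (protein-coding genes,
tRNAs, rRNAs, control region).  Insect mitogenomes are strongly AT-biased
(~80% A+T), so the skews, not the raw content, carry the strand signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .io import MitoGenome, extract_gene_sequence

logger = logging.getLogger(__name__)

REGION_CLASSES = ("whole", "PCG", "tRNA", "rRNA", "CR")


@dataclass(frozen=True)
class SkewSummary:
    """Counts and skew statistics for one region class of one genome.

    ``at_percent`` and the skews are ``None`` when their denominator is zero
    (e.g. an all-ambiguous region); undefined is a value here, not an error.
    """

    region_class: str
    counts: tuple[int, int, int, int, int]   # nA, nC, nG, nT, nOther
    at_percent: Optional[float]
    at_skew: Optional[float]
    gc_skew: Optional[float]

    @property
    def length(self) -> int:
        return sum(self.counts)


def base_composition(sequence: str) -> tuple[tuple[int, int, int, int, int], Optional[float]]:
    """(nA,nC,nG,nT,nOther) and AT% of the unambiguous bases (None if none)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    nA, nC, nG, nT = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    other = len(s) - (nA + nC + nG + nT)
    acgt = nA + nC + nG + nT
    at_percent = 100.0 * (nA + nT) / acgt if acgt else None
    return (nA, nC, nG, nT, other), at_percent


def at_skew(sequence: str) -> Optional[float]:
    """(A - T)/(A + T); None when the sequence has no A or T."""
    s = sequence.upper()
    a, t = s.count("A"), s.count("T")
    return (a - t) / (a + t) if a + t else None


def gc_skew(sequence: str) -> Optional[float]:
    """(G - C)/(G + C); None when the sequence has no G or C."""
    s = sequence.upper()
    g, c = s.count("G"), s.count("C")
    return (g - c) / (g + c) if g + c else None


def _summary(region_class: str, sequence: str) -> SkewSummary:
    counts, atp = base_composition(sequence)
    return SkewSummary(region_class, counts, atp, at_skew(sequence), gc_skew(sequence))


def region_class_summary(
    genome: MitoGenome, pooling_strand: str = "coding"
) -> list[SkewSummary]:
    """Whole-genome plus pooled per-class composition summaries.

    Gene classes pool the concatenated gene sequences; with
    ``pooling_strand="coding"`` (default) each gene contributes its coding
    orientation, with ``"forward"`` the deposited forward strand.  Classes
    with no annotated member are omitted with a warning.
    """
    if pooling_strand not in ("coding", "forward"):
        raise ValueError("pooling_strand must be 'coding' or 'forward'")
    out = [_summary("whole", genome.sequence)]
    for cls in ("PCG", "tRNA", "rRNA", "CR"):
        feats = genome.features_of_kind(cls)
        if not feats:
            logger.warning("%s: no %s features annotated; class omitted",
                           genome.identifier, cls)
            continue
        parts = []
        for f in feats:
            if pooling_strand == "coding":
                parts.append(extract_gene_sequence(genome, f))
            else:
                parts.append("".join(genome.sequence[s:e] for s, e in f.intervals()))
        out.append(_summary(cls, "".join(parts)))
    return out


def composition_report(
    genomes: list[MitoGenome], pooling_strand: str = "coding"
) -> pd.DataFrame:
    """Long-format table: one row per (genome, region_class).

    Percentages/skews keep full precision; round at presentation time
    (the conventional report shows AT% to 1 d.p.).
    """
    rows = []
    for g in genomes:
        for s in region_class_summary(g, pooling_strand=pooling_strand):
            nA, nC, nG, nT, nO = s.counts
            rows.append({
                "genome": g.identifier, "taxon": g.taxon, "region_class": s.region_class,
                "length": s.length, "nA": nA, "nC": nC, "nG": nG, "nT": nT,
                "nOther": nO, "at_percent": s.at_percent,
                "at_skew": s.at_skew, "gc_skew": s.gc_skew,
            })
    return pd.DataFrame(rows)
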