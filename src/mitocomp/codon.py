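"""Codon extraction, start/stop classification, RSCU and amino-acid usage.

All translation is under the invertebrate mitochondrial code (table 5).
Relative synonymous codon usage for a sense codon c with synonymous family
size k is

    RSCU(c) = k * count(c) / sum over family of counts

so uniform usage within a family gives RSCU = 1 for every member and the
family values always sum to k.  Mitochondrial protein genes frequently end on
an incomplete stop (a bare T or TA completed to TAA by polyadenylation);
``split_codons`` records these as first-class stop classes rather than
discarding them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .codes import (
    AA_THREE_LETTER,
    CODON_TO_AA,
    FAMILY,
    SENSE_CODONS,
    STOP_CODONS,
    is_unambiguous,
    translate_codon,
)

logger = logging.getLogger(__name__)

START_ATN = ("ATA", "ATT", "ATG", "ATC")


@dataclass
class CodonProfile:
    """In-frame codon decomposition of one CDS."""

    gene: str
    codons: list[str]
    start_codon: str
    start_class: str                 # ATN | TTG | other
    stop_codon: str                  # full TAA/TAG, incomplete "T"/"TA", or last codon
    stop_class: str                  # TAA | TAG | incomplete_T | incomplete_TA | other
    internal_stops: list[int] = field(default_factory=list)  # codon indices

    def reconstruct(self) -> str:
        """Codons + stop remainder, i.e. the CDS after the codon_start offset."""
        return "".join(self.codons) + self.stop_codon


def split_codons(cds: str, codon_start_offset: int = 0, gene: str = "") -> CodonProfile:
    """Split a CDS into in-frame codons plus its (possibly incomplete) stop.

    The trailing element is always peeled off: a remainder of length 1/2 is an
    incomplete stop (T / TA), otherwise the final full codon is the stop
    (TAA/TAG, or class "other" if the annotation ends on a sense codon).
    Internal stop codons are reported with their position but tolerated —
    the module audits annotations, it does not fix them.
    """
    seq = cds.upper()[codon_start_offset:]
    if len(seq) < 6:
        raise ValueError(f"CDS too short after offset ({len(seq)} nt)")
    remainder = len(seq) % 3
    if remainder:
        stop = seq[-remainder:]
        body = seq[:-remainder]
        stop_class = {1: "incomplete_T", 2: "incomplete_TA"}[remainder]
        if (remainder == 1 and stop != "T") or (remainder == 2 and stop != "TA"):
            stop_class = "other"
    else:
        stop = seq[-3:]
        body = seq[:-3]
        stop_class = stop if stop in STOP_CODONS else "other"
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    start = codons[0]
    if start in START_ATN:
        start_class = "ATN"
    elif start == "TTG":
        start_class = "TTG"
    else:
        start_class = "other"
    internal = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    for i in internal:
        logger.warning("%s: internal stop codon %s at codon %d", gene or "CDS",
                       codons[i], i + 1)
    return CodonProfile(gene, codons, start, start_class, stop, stop_class, internal)


def count_codons(codons: Iterable[str]) -> Counter:
    """Sense-codon counts; stops never counted, ambiguous codons excluded
    with a logged tally."""
    counts: Counter = Counter()
    skipped = 0
    for c in codons:
        c = c.upper()
        if c in STOP_CODONS:
            continue
        if len(c) == 3 and is_unambiguous(c):
            counts[c] += 1
        else:
            skipped += 1
    if skipped:
        logger.info("count_codons: excluded %d ambiguous/partial codons", skipped)
    return counts


def rscu(counts: Mapping[str, int]) -> pd.DataFrame:
    """RSCU table over the 62 sense codons of table 5.

    Families with zero total usage get RSCU ``NaN`` for every member (the
    statistic is undefined, not zero).  Stop codons are excluded entirely.
    """
    rows = []
    for aa, fam in sorted(FAMILY.items()):
        total = sum(counts.get(c, 0) for c in fam)
        k = len(fam)
        for c in fam:
            n = counts.get(c, 0)
            value = k * n / total if total else float("nan")
            rows.append({"codon": c, "amino_acid": aa,
                         "amino_acid_3": AA_THREE_LETTER[aa],
                         "count": n, "rscu": value})
    return pd.DataFrame(rows)


def amino_acid_usage(counts: Mapping[str, int]) -> pd.DataFrame:
    """Amino-acid counts/frequencies through table 5, ranked descending.

    Table-5 reassignments apply: ATA counts toward Met, AGA/AGG toward Ser,
    TGA toward Trp."""
    aa_counts: Counter = Counter()
    for codon, n in counts.items():
        codon = codon.upper()
        if codon in CODON_TO_AA and n:
            aa_counts[CODON_TO_AA[codon]] += n
    total = sum(aa_counts.values())
    rows = [
        {"amino_acid": aa, "amino_acid_3": AA_THREE_LETTER[aa], "count": n,
         "percent": 100.0 * n / total}
        for aa, n in aa_counts.most_common()
    ]
    return pd.DataFrame(rows, columns=["amino_acid", "amino_acid_3", "count", "percent"])


def genome_codon_counts(
    profiles: Iterable[CodonProfile], genes: Optional[set[str]] = None
) -> Counter:
    """Pool codon counts over selected genes (default: all 13 PCGs pooled,
    as per-species RSCU is conventionally displayed)."""
    counts: Counter = Counter()
    for p in profiles:
        if genes is None or p.gene in genes:
            counts.update(count_codons(p.codons))
    return counts


def start_stop_table(profiles: Iterable[CodonProfile]) -> pd.DataFrame:
    """Per-gene start/stop codon classification table."""
    rows = [
        {"gene": p.gene, "start_codon": p.start_codon, "start_class": p.start_class,
         "stop_codon": p.stop_codon, "stop_class": p.stop_class,
         "n_codons": len(p.codons), "internal_stops": len(p.internal_stops)}
        for p in profiles
    ]
    return pd.DataFrame(rows)


def rscu_report(per_genome_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Long-format RSCU report over genomes; ``pooling`` column records that
    counts were pooled across the supplied genes."""
    frames = []
    for genome_id, counts in per_genome_counts.items():
        df = rscu(counts)
        df.insert(0, "genome", genome_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(out):
        out["pooling"] = "pooled_PCGs"
    return out
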