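"""Nei–Gojobori (1986) Ka/Ks estimation and sliding-window nucleotide diversity.

The NG86 method counts, for every codon, the fraction of possible single-base
changes that are synonymous (synonymous "sites"), and for every differing codon
pair the synonymous/nonsynonymous substitutions averaged over all mutational
pathways between the two codons.  Proportions pS = Sd/S and pN = Nd/N are then
corrected for multiple hits with the Jukes–Cantor formula

    d(p) = -(3/4) * ln(1 - (4/3) p),        undefined for p >= 3/4.

Conventions used here (and by the exhaustive enumeration oracle in the test
suite): translation table 5 throughout; single-base changes that create a stop
codon count as nonsynonymous in site counting; pathways passing through a stop
codon are excluded from difference counting, falling back to all pathways
(stop steps nonsynonymous) only if every ordering hits a stop.

Nucleotide diversity pi is the mean pairwise proportion of differing sites,
with pairwise deletion of columns where either sequence is gapped/ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Optional, Sequence

from .codes import CODON_TO_AA, STOP_CODONS, NUCLEOTIDES, is_unambiguous

__all__ = [
    "KaKsResult", "DiversitySeries", "jukes_cantor", "ng86_sites",
    "ng86_pairwise", "gene_kaks", "nucleotide_diversity", "sliding_window_pi",
]


@dataclass
class KaKsResult:
    """NG86 site/difference counts and JC-corrected rates.

    Pair-level results carry the raw counts; gene-level results carry the
    across-pair means (see :func:`gene_kaks`).  ``None`` marks an undefined
    quantity (saturated JC argument or Ks = 0) — never silently 0.
    """

    gene: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    Ks: Optional[float]
    Ka: Optional[float]
    ka_ks: Optional[float]
    n_codons: int = 0
    n_pairs: int = 1
    n_dropped_ks: int = 0
    n_dropped_ka: int = 0


@dataclass
class DiversitySeries:
    """Sliding-window nucleotide diversity along an alignment (1-based
    window coordinates; ``pi`` is NaN where a window has no comparable site)."""

    window_size: int
    step: int
    starts: list[int]
    midpoints: list[float]
    pi: list[float]


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance d = -(3/4) ln(1 - (4/3)p); None once p >= 3/4 (saturation)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon; s + n = 3.

    Each position contributes syn_changes/3 synonymous sites over its three
    possible substitutions; changes producing a stop are nonsynonymous.
    """
    codon = codon.upper()
    if codon in STOP_CODONS or not is_unambiguous(codon) or len(codon) != 3:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _usable(codon: str) -> bool:
    return (
        len(codon) == 3 and is_unambiguous(codon) and codon not in STOP_CODONS
    )


@lru_cache(maxsize=None)
def _pair_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []   # (syn, nonsyn) per stop-free pathway
    fallback: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = a
        syn = nonsyn = 0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                hits_stop = True
                nonsyn += 1          # step to a stop: nonsynonymous by policy
            elif cur in STOP_CODONS:
                hits_stop = True
                nonsyn += 1
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (fallback if hits_stop else valid).append((syn, nonsyn))
    paths = valid if valid else valid + fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_pairwise(seq_a: str, seq_b: str, gene: str = "") -> KaKsResult:
    """NG86 Ka/Ks between two equal-length in-frame coding sequences.

    Codon pairs containing a gap, ambiguity code or stop codon in either
    sequence are skipped whole (frame preservation).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (_usable(ca) and _usable(cb)):
            continue
        n_codons += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = jukes_cantor(pS) if pS is not None else None
    Ka = jukes_cantor(pN) if pN is not None else None
    ka_ks = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(gene, S, N, Sd, Nd, pS, pN, Ks, Ka, ka_ks, n_codons=n_codons)


def gene_kaks(
    alignment: dict[str, str] | Sequence[str], gene: str = "",
    ratio_mode: str = "mean_of_rates",
) -> KaKsResult:
    """Gene-level Ka/Ks over all unordered sequence pairs of a codon alignment.

    The per-gene ratio is (mean pairwise Ka)/(mean pairwise Ks) by default —
    robust to near-zero-Ks pairs; ``ratio_mode="mean_of_ratios"`` averages
    per-pair ratios instead.  Pairs whose Ka or Ks is undefined are dropped
    from the corresponding mean and counted.
    """
    seqs = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if ratio_mode not in ("mean_of_rates", "mean_of_ratios"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    kas, kss, ratios = [], [], []
    S = N = Sd = Nd = 0.0
    dropped_ka = dropped_ks = 0
    n_pairs = 0
    for a, b in combinations(seqs, 2):
        r = ng86_pairwise(a, b, gene=gene)
        n_pairs += 1
        S += r.S
        N += r.N
        Sd += r.Sd
        Nd += r.Nd
        if r.Ka is None:
            dropped_ka += 1
        else:
            kas.append(r.Ka)
        if r.Ks is None:
            dropped_ks += 1
        else:
            kss.append(r.Ks)
        if r.ka_ks is not None:
            ratios.append(r.ka_ks)
    mean_ka = sum(kas) / len(kas) if kas else None
    mean_ks = sum(kss) / len(kss) if kss else None
    if ratio_mode == "mean_of_rates":
        ka_ks = (
            mean_ka / mean_ks
            if (mean_ka is not None and mean_ks is not None and mean_ks > 0)
            else None
        )
    else:
        ka_ks = sum(ratios) / len(ratios) if ratios else None
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    return KaKsResult(
        gene, S / n_pairs, N / n_pairs, Sd / n_pairs, Nd / n_pairs, pS, pN,
        mean_ks, mean_ka, ka_ks,
        n_codons=int(round((S + N) / (3 * n_pairs))), n_pairs=n_pairs,
        n_dropped_ks=dropped_ks, n_dropped_ka=dropped_ka,
    )


_GOOD = frozenset(NUCLEOTIDES)


def _pair_pi(a: str, b: str) -> Optional[float]:
    sites = diffs = 0
    for x, y in zip(a, b):
        if x in _GOOD and y in _GOOD:
            sites += 1
            if x != y:
                diffs += 1
    return diffs / sites if sites else None


def nucleotide_diversity(alignment: dict[str, str] | Sequence[str]) -> Optional[float]:
    """pi: mean pairwise p-distance with pairwise deletion of gapped/ambiguous
    columns; None if no pair has a comparable site."""
    seqs = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    vals = [p for a, b in combinations([s.upper() for s in seqs], 2)
            if (p := _pair_pi(a, b)) is not None]
    return sum(vals) / len(vals) if vals else None


def sliding_window_pi(
    alignment: dict[str, str] | Sequence[str], window: int = 100, step: int = 20
) -> DiversitySeries:
    """Sliding-window pi (defaults 100 bp / 20 bp, the conventional scan).

    Windows start at 1-based columns 1, 1+step, ... while they fit entirely;
    a trailing partial window is dropped.  Window midpoint = start + w/2 - 1.
    """
    seqs = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    if window > length:
        raise ValueError(f"window {window} exceeds alignment length {length}")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    seqs = [s.upper() for s in seqs]
    starts, mids, pis = [], [], []
    start = 1
    while start + window - 1 <= length:
        sub = [s[start - 1:start - 1 + window] for s in seqs]
        vals = [p for a, b in combinations(sub, 2) if (p := _pair_pi(a, b)) is not None]
        pi = sum(vals) / len(vals) if vals else float("nan")
        starts.append(start)
        mids.append(start + window / 2 - 1)
        pis.append(pi)
        start += step
    return DiversitySeries(window, step, starts, mids, pis)


def diversity_table(series_by_gene: dict[str, DiversitySeries]):
    """Long-format per-gene sliding-window table (gene, window_start, midpoint, pi)."""
    import pandas as pd

    rows = []
    for gene, s in series_by_gene.items():
        for start, mid, pi in zip(s.starts, s.midpoints, s.pi):
            rows.append({"gene": gene, "window_start": start,
                         "midpoint": mid, "pi": pi})
    return pd.DataFrame(rows)


def kaks_table(results: Sequence[KaKsResult]):
    """Per-gene Ka/Ks report table."""
    import pandas as pd

    return pd.DataFrame([
        {"gene": r.gene, "n_pairs": r.n_pairs, "S": r.S, "N": r.N,
         "Sd": r.Sd, "Nd": r.Nd, "Ks": r.Ks, "Ka": r.Ka, "ka_ks": r.ka_ks,
         "dropped_ks": r.n_dropped_ks, "dropped_ka": r.n_dropped_ka}
        for r in results
    ])
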