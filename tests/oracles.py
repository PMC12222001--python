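"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own lookup tables and counting code:
translation goes through ``Bio.Seq.translate`` and every combinatorial
quantity is computed by exhaustive enumeration, so agreement with the
implementation is evidence, not tautology.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from Bio.Seq import Seq

BASES = "ACGT"


@lru_cache(maxsize=None)
def aa5(codon: str) -> str:
    """One-letter AA (or '*') under NCBI table 5 via Biopython translation."""
    return str(Seq(codon).translate(table=5))


def brute_sites(codon: str) -> tuple[float, float]:
    """NG86 (syn, nonsyn) sites by enumerating all nine single-base mutants;
    mutants that are stops count as nonsynonymous."""
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if aa5(mutant) != "*" and aa5(mutant) == aa5(codon):
                s += 1.0 / 3.0
    return s, 3.0 - s


def brute_pair_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons by exhaustive
    enumeration of all orderings of the differing positions; pathways through
    stop codons excluded, falling back to all pathways if none is stop-free."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        cur = a
        sd = nd = 0
        stop_hit = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if aa5(nxt) == "*" or aa5(cur) == "*":
                stop_hit = True
                nd += 1
            elif aa5(cur) == aa5(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if stop_hit else clean).append((sd, nd))
    paths = clean if clean else clean + dirty
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def brute_pairwise_counts(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for two in-frame sequences, skipping codon pairs with
    stops/non-ACGT characters — an independent re-statement of the NG86
    counting conventions."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in BASES for ch in ca + cb):
            continue
        if aa5(ca) == "*" or aa5(cb) == "*":
            continue
        sa = brute_sites(ca)
        sb = brute_sites(cb)
        S += (sa[0] + sb[0]) / 2
        N += (sa[1] + sb[1]) / 2
        d = brute_pair_differences(ca, cb)
        Sd += d[0]
        Nd += d[1]
    return S, N, Sd, Nd


def sense_codons() -> list[str]:
    return [c for c in ("".join(p) for p in product(BASES, repeat=3))
            if aa5(c) != "*"]


def brute_global_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimal global alignment score by exhaustive recursion over all
    alignments (feasible only for very short sequences)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(
                (match if a[i] == b[j] else mismatch) + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)
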