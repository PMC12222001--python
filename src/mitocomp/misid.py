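"""COI-identity misidentification screen.

Public mitogenome collections carry mislabelled records: a sequence deposited
under one species name that is molecularly (near-)identical to a different
species.  The screen audits a locally held collection in two complementary
ways:

* sequence identity — pairwise global (Needleman–Wunsch) alignment of cox1
  barcodes (or whole mitogenomes), with identity tiered into conspecific
  (default >= 98%), congeneric (default >= 91%) and below;
* tree placement — each leaf of a phylogeny is checked against a taxonomy
  table: a leaf whose smallest enclosing clade shares neither its genus nor
  its subfamily is flagged with the majority genus of its sister group.

Thresholds are configuration, not constants: they summarize how practitioners
read barcode similarity (same species typically >= 98%, same genus roughly
91-95%), and real decisions always combine both lines of evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import dendropy
import pandas as pd
from Bio import Align

from .io import MitoGenome, extract_gene_sequence

VERDICTS = (
    "suspected_conspecific", "suspected_congeneric", "suspected_misplaced",
    "consistent", "inconclusive",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Identity tiers (percent): >= conspecific_min -> same species;
    [congeneric_min, conspecific_min) -> same genus."""

    conspecific_min: float = 98.0
    congeneric_min: float = 91.0

    def __post_init__(self):
        if not (100.0 >= self.conspecific_min > self.congeneric_min > 0.0):
            raise ValueError("require 100 >= conspecific_min > congeneric_min > 0")


@dataclass
class IdentityReport:
    query: str
    subject: str
    region: str                     # COI_barcode | whole_mitogenome
    identity: float                 # percent of matching columns
    aligned_columns: int
    verdict: str


def extract_barcode(genome: MitoGenome, barcode_window: bool = False) -> str:
    """The cox1 sequence of a genome (full CDS, or its 5' 658-bp barcode
    window with ``barcode_window=True``)."""
    feat = genome.feature_by_name("cox1")
    if feat is None:
        raise ValueError(f"{genome.identifier}: no cox1 feature annotated")
    seq = extract_gene_sequence(genome, feat)
    return seq[:658] if barcode_window else seq


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> tuple[float, int]:
    """Percent identity and column count of an optimal global alignment.

    Needleman–Wunsch with linear gap penalties; terminal-gap columns are
    stripped before computing identity (semi-global behaviour), since barcode
    fragments differ in length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _make_aligner(match, mismatch, gap).align(a.upper(), b.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    lo, hi = 0, len(ra)
    while lo < hi and (ra[lo] == "-" or rb[lo] == "-"):
        lo += 1
    while hi > lo and (ra[hi - 1] == "-" or rb[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0, 0
    matches = sum(1 for x, y in zip(ra[lo:hi], rb[lo:hi]) if x == y and x != "-")
    return 100.0 * matches / cols, cols


def parse_binomial(name: str) -> Optional[tuple[str, str]]:
    """(genus, species) from a nominal name; 'Harpalus sp.'-style epithets are
    kept verbatim.  None when the name has no genus token."""
    tokens = name.replace("_", " ").split()
    if not tokens:
        return None
    genus = tokens[0]
    species = tokens[1] if len(tokens) > 1 else "sp."
    return genus, species


def tier_verdict(
    query_name: str,
    subject_name: str,
    identity: float,
    thresholds: ThresholdConfig = ThresholdConfig(),
    max_identity_in_genus: Optional[float] = None,
) -> str:
    """Tier one best-hit comparison into a verdict.

    ``max_identity_in_genus`` (the query's best identity against any member of
    its nominal genus, None when the genus has no other member in the
    collection) drives the 'misplaced' tier: a query below congeneric_min
    against its whole nominal genus does not belong there.
    """
    q = parse_binomial(query_name)
    s = parse_binomial(subject_name)
    if q is None or s is None:
        return "inconclusive"
    same_genus = q[0] == s[0]
    same_species = same_genus and q[1] == s[1]
    if identity >= thresholds.conspecific_min:
        return "consistent" if same_species else "suspected_conspecific"
    if (
        max_identity_in_genus is not None
        and max_identity_in_genus < thresholds.congeneric_min
        and identity < thresholds.congeneric_min
    ):
        return "suspected_misplaced"
    if identity >= thresholds.congeneric_min:
        return "consistent" if same_genus else "suspected_congeneric"
    return "inconclusive"


def audit_collection(
    barcodes: Mapping[str, str],
    names: Mapping[str, str],
    thresholds: ThresholdConfig = ThresholdConfig(),
    region: str = "COI_barcode",
) -> pd.DataFrame:
    """Best-hit identity audit of a barcode collection.

    ``barcodes`` maps record id -> sequence, ``names`` record id -> nominal
    binomial.  Each record is compared against every other; the best hit is
    tiered into a verdict, with the best within-nominal-genus identity used
    for the 'misplaced' tier.  Returns a Table-1-style report (one row per
    record: current name, best hit, identity, verdict, suggested name).
    """
    ids = list(barcodes)
    ident: dict[tuple[str, str], float] = {}
    cols: dict[tuple[str, str], int] = {}
    for i, qid in enumerate(ids):
        for sid in ids[i + 1:]:
            pid, c = global_identity(barcodes[qid], barcodes[sid])
            ident[qid, sid] = ident[sid, qid] = pid
            cols[qid, sid] = cols[sid, qid] = c
    rows = []
    for qid in ids:
        others = [s for s in ids if s != qid]
        if not others:
            continue
        best = max(others, key=lambda s: ident[qid, s])
        q_genus = (parse_binomial(names[qid]) or ("?",))[0]
        genus_ids = [
            s for s in others
            if (parse_binomial(names[s]) or ("?",))[0] == q_genus
        ]
        max_in_genus = max((ident[qid, s] for s in genus_ids), default=None)
        verdict = tier_verdict(names[qid], names[best], ident[qid, best],
                               thresholds, max_identity_in_genus=max_in_genus)
        if verdict == "suspected_conspecific":
            suggested = names[best]
        elif verdict == "suspected_congeneric":
            suggested = f"{(parse_binomial(names[best]) or ('?',))[0]} sp."
        elif verdict == "suspected_misplaced":
            suggested = f"cf. {names[best]}"
        else:
            suggested = names[qid]
        rows.append({
            "accession": qid, "current_name": names[qid], "region": region,
            "best_hit": best, "best_hit_name": names[best],
            "identity": ident[qid, best], "aligned_columns": cols[qid, best],
            "max_identity_in_genus": max_in_genus,
            "verdict": verdict, "suggested_name": suggested,
        })
    return pd.DataFrame(rows)


def tree_consistency(
    tree: Union[str, "dendropy.Tree"],
    taxonomy: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Flag leaves whose tree placement contradicts their nominal taxonomy.

    ``taxonomy`` maps leaf label -> {"genus": ..., "subfamily": ...}.  For
    each leaf the smallest enclosing clade with >= 2 leaves is inspected, and
    (to avoid punishing the innocent partner of a misplaced leaf nested next
    to it) the next enclosing clade as well; the leaf is flagged when neither
    neighbourhood contains another member of its genus nor (fallback) its
    subfamily.  The suggested group is the majority genus among the flagged
    leaf's nearest sisters.  Leaves absent from the taxonomy are listed as
    unmapped, not fatal.
    """
    if isinstance(tree, str):
        kwargs = {"schema": "newick", "preserve_underscores": True}
        tree = (dendropy.Tree.get(data=tree, **kwargs) if "(" in tree
                else dendropy.Tree.get(path=tree, **kwargs))
    rows = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else ""
        info = taxonomy.get(label) or taxonomy.get(label.replace(" ", "_"))
        if info is None:
            rows.append({"leaf": label, "status": "unmapped",
                         "sister_majority_genus": None})
            continue
        # sister-leaf sets of successively larger enclosing clades
        levels: list[list[str]] = []
        node = leaf.parent_node
        while node is not None and len(levels) < 2:
            sisters = [
                lf.taxon.label for lf in node.leaf_iter()
                if lf is not leaf and lf.taxon
            ]
            if sisters and (not levels or sisters != levels[-1]):
                levels.append(sisters)
            node = node.parent_node
        if not levels:
            rows.append({"leaf": label, "status": "consistent",
                         "sister_majority_genus": None})
            continue
        consistent = False
        for sisters in levels:
            sister_info = [taxonomy.get(s) or taxonomy.get(s.replace(" ", "_"))
                           for s in sisters]
            genera = [si["genus"] for si in sister_info if si]
            subfams = [si.get("subfamily") for si in sister_info if si]
            if info["genus"] in genera or (
                info.get("subfamily") is not None
                and info.get("subfamily") in subfams
            ):
                consistent = True
                break
        nearest = [taxonomy.get(s) or taxonomy.get(s.replace(" ", "_"))
                   for s in levels[-1]]
        genera = [si["genus"] for si in nearest if si]
        majority = Counter(genera).most_common(1)[0][0] if genera else None
        rows.append({
            "leaf": label,
            "status": "consistent" if consistent else "flagged",
            "sister_majority_genus": None if consistent else majority,
        })
    return pd.DataFrame(rows)
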