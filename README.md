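# mitocomp

Comparative mitogenomics for insect-type mitochondrial genomes: the analysis
battery conventionally run when new mitogenomes are described and compared —
base composition and strand skews, codon usage, selection-rate estimation,
phylogenetic dataset construction — plus a screen for the misidentified
records that plague public mitogenome collections, and a simulator that
makes every stage verifiable against planted ground truth.

**Who it is for.** Researchers working with annotated mitogenomes (GenBank
flatfiles) of insects and other invertebrates who want the standard
comparative analyses as reproducible, tested library calls instead of a
chain of GUI tools.

## What it computes

* **Composition & skews** — AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C)
  and AT% for whole genomes and pooled region classes (PCGs, tRNAs, rRNAs,
  control region).
* **Codon usage** — start/stop-codon classification (ATN/TTG starts,
  complete TAA/TAG and incomplete T/TA stops) and relative synonymous codon
  usage under the invertebrate mitochondrial code (table 5):
  RSCU(c) = k·n_c / Σ_family n, k the synonymous-family size.
* **Selection rates** — Nei–Gojobori (1986) counting of synonymous /
  nonsynonymous sites and pathway-averaged differences, Jukes–Cantor
  corrected: Ks = −¾·ln(1 − 4/3·pS) (same form for Ka), aggregated per gene
  over all sequence pairs; and sliding-window nucleotide diversity π
  (window 100 bp, step 20 bp).
* **Phylogenetic datasets** — concatenated supermatrices in three flavours
  (AA translations; codon positions 1+2 plus rRNAs, "P12R"; all positions
  plus rRNAs, "P123R") with exact partition bookkeeping and partition files
  (RAxML text + NEXUS sets) for no-partition and per-gene schemes.
* **Misidentification screen** — pairwise Needleman–Wunsch identity of cox1
  barcodes tiered into conspecific (≥98%), congeneric (91–98%) and
  misplaced verdicts, cross-checked by taxonomy-aware tree placement.
* **Simulation** — codon alignments under a tree-structured, AT-biased,
  stop-free ω-controlled substitution process; full annotated 37-gene
  mitogenomes; barcode audit sets with planted relabellings.

## Worked example

Estimate per-gene Ka/Ks on a simulated 8-genome collection with the default
selection gradient (`examples/kaks_and_diversity.py`):

```python
from mitocomp.selection import gene_kaks, kaks_table
from mitocomp.simulate import SimulationConfig, balanced_tree, simulate_mitogenome_set

cfg = SimulationConfig(tree=balanced_tree(8, 0.05), seed=42)
_, alignments, truth = simulate_mitogenome_set(cfg)
results = [gene_kaks(alignments[g], gene=g) for g in truth.omega]
print(kaks_table(results).sort_values("ka_ks")[["gene", "Ka", "Ks", "ka_ks"]])
```

prints (abridged):

```
 gene     Ka     Ks  ka_ks
 cox1 0.0369 1.0234 0.0360
 cox2 0.0606 1.2294 0.0493
  ...
 nad2 0.1391 0.5916 0.2352
 atp8 0.1938 0.5009 0.3869
```

Every Ka/Ks is far below 1 (purifying selection); the estimated ranking
recovers the planted gradient — cox1 (planted ω = 0.05) slowest, atp8
(planted ω = 0.6) fastest — the pattern expected of mitochondrial
protein-coding genes, and the reason cox1 serves as the species-barcoding
marker while atp8 is the least constrained gene.

The other example scripts each cover one capability: genome simulation and
GenBank round-trip, composition reports, RSCU tables, supermatrix
construction, and the misidentification audit (which, on a set with one
planted relabelling, flags exactly the planted pair at 100% identity and
suggests the true name).

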