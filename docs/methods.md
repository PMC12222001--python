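# Methods

This note documents the models, conventions and numerical choices behind
`mitocomp`, and what the synthetic-data generator does and does not emulate.

## Scope and data model

The package analyses annotated insect-type mitochondrial genomes: circular
molecules of ~14–20 kb carrying 37 genes (13 protein-coding genes, 22 tRNAs,
2 rRNAs) plus an AT-rich control region, with 23 genes on the major (J)
strand and 14 on the minor (N) strand in the ancestral insect arrangement.
Internally all coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive locations (and `complement()` / origin-spanning
`join()` constructs) are converted at the I/O boundary. A feature that
crosses the circular origin is stored explicitly as two intervals plus a
wrap flag — never via modular arithmetic — so GenBank round-trips are exact
and testable. Gene labels are normalized through a packaged synonym table;
the Leu/Ser tRNA isoacceptors (trnL1/trnL2, trnS1/trnS2) are resolved only
by anticodon or codon-family annotation, never by position: an unresolvable
label maps to an explicit "unmapped" value.

All translation uses the invertebrate mitochondrial code (NCBI table 5),
applied in a single module so its reassignments (ATA=Met, AGA/AGG=Ser,
TGA=Trp; stops TAA/TAG only, making Ser an 8-codon family) are consistent
across codon usage, site counting, dataset translation and simulation.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C). Ambiguity codes are preserved
in sequences, tallied separately, and excluded from AT% and skew
denominators; a zero denominator yields an explicit undefined value, not 0
and not an exception. Region-class summaries pool concatenated gene
sequences per class. Because conventional reports give gene-level
composition in coding orientation, pooling is strand-aware by default
(`pooling_strand="coding"`), with `"forward"` available since published
tables do not always state which convention was used; whole-genome values
always use the deposited forward strand.

## Codon usage

`split_codons` always peels a terminal element off the in-frame CDS: a
length-1/2 remainder is an incomplete stop (T / TA, completed to TAA by
polyadenylation in vivo), otherwise the final codon is the stop (TAA/TAG or
class "other"). This makes the decomposition a partition — codons + stop
remainder reconstruct the CDS — which is property-tested. Start classes are
restricted to ATN, TTG and "other": the module audits annotations rather
than re-annotating. RSCU(c) = k·count(c)/Σ_family counts with k the table-5
family size; zero-usage families are undefined (NaN) for all members. RSCU
is computed per-gene and pooled over the 13 PCGs per genome (the
conventional per-species display); reports state the pooling.

## NG86 Ka/Ks

Sites: each codon position contributes (synonymous changes)/3 over its three
possible substitutions; substitutions creating a stop codon count as
nonsynonymous. Differences: codon pairs differing at d positions are
averaged over all d! orderings of the changes; orderings that pass through a
stop codon are excluded, falling back to averaging all orderings (stop steps
counted nonsynonymous) only when every ordering hits a stop. Codon pairs
containing a gap, ambiguity code or stop in either sequence are excluded
whole, preserving frame. Proportions pS = Sd/S, pN = Nd/N are corrected with
Jukes–Cantor, d(p) = −(3/4)·ln(1−(4/3)p), undefined at p ≥ 3/4; undefined
values propagate as explicit `None`, never as 0. The identical conventions
are restated independently by the exhaustive-enumeration oracle in the test
suite, which checks every ordered sense-codon pair to 1e−9.

Gene-level Ka/Ks defaults to (mean pairwise Ka)/(mean pairwise Ks) rather
than the mean of per-pair ratios: near-zero-Ks pairs make per-pair ratios
explode, while the ratio of means stays stable and corresponds to how a
single per-gene value is sensibly produced. `ratio_mode="mean_of_ratios"` is
available; pairs with undefined rates are dropped from the respective mean
with counts reported.

## Nucleotide diversity

π is the mean pairwise proportion of differing sites with pairwise deletion
of columns where either sequence is gapped/ambiguous — a site-level
statistic, so no frame constraint applies. The sliding scan uses 100 bp
windows advanced by 20 bp (the conventional barcode-scale setting): windows
start at 1-based columns 1, 1+step, … while they fit entirely; the trailing
partial window is dropped; the midpoint is start + w/2 − 1.

## Supermatrix construction

Three dataset flavours: AA (table-5 translations of the 13 PCGs), P12R
(codon positions 1+2 of the PCGs plus both rRNAs) and P123R (all positions
plus rRNAs). Genes concatenate in a fixed canonical order (atp6, atp8, cob,
cox1–3, nad1–6, nad4l, rrnL, rrnS) regardless of input-map insertion order;
taxa absent from a gene are filled with `-` (configurable `?`), and
partitions are 1-based inclusive ranges that exactly tile the matrix — an
invariant enforced by the `Supermatrix` constructor. Two partition schemes
are emitted (RAxML-style text and NEXUS sets block): NP (one block) and FP
(one block per gene); the merged-partition scheme and substitution-model
selection belong to downstream tools (the FP files are their input).
Alignment and trimming are likewise upstream concerns: the module consumes
per-gene alignments, so matrices built from differently trimmed inputs will
differ column-wise while all bookkeeping contracts still hold.

## Misidentification screen

Identity is computed by Needleman–Wunsch global alignment (match +1,
mismatch −1, linear gap −2) over a locally held collection — deterministic
and self-contained, unlike BLAST-against-GenBank percentages, which use a
local aligner's identity definition and can differ by a few tenths of a
percent. Terminal-gap columns are excluded from the identity denominator
because barcode fragments vary in length. Default tiers: ≥ 98% identity to
a differently named record → suspected conspecific (relabel candidate);
91–98% with a different genus → suspected congeneric; below 91% against
every member of the nominal genus → suspected misplaced. The thresholds are
configuration (`ThresholdConfig`), summarizing how practitioners read
barcode similarity, not biological constants.

The tree check inspects, for each leaf, its smallest enclosing clade *and
one further ancestor level*: a leaf is flagged only when neither
neighbourhood contains another member of its genus nor, as a fallback, its
subfamily. The second level exists because a misplaced intruder's nearest
neighbour has the intruder as its only sister — inspecting just the cherry
would flag the innocent resident too. The flag suggests the majority genus
of the leaf's nearest sister group. Both lines of evidence (identity tier,
tree placement) are reported; neither alone renames anything.

## The simulator

Codon genes evolve down a user tree under a Muse–Gaut-style process: the
rate from codon i to a single-base neighbour j is π(target base) ×
κ^[transition] × (1 if synonymous else ω), and 0 if j is a stop. Root
codons are drawn i.i.d. from the product of the AT-biased base distribution
restricted to sense codons. Substitutions are realized as
exponential-waiting-time events per codon along each branch
(Gillespie-style) — exact for the defined process and easy to oracle-check —
with rates scaled so a branch length is the expected number of
substitutions per nucleotide site under the root composition (exact
stationary normalization is unnecessary for the ranking contracts the
simulator supports). RNA genes use the analogous HKY-like nucleotide
process, optionally with a planted segment evolving at a multiple of the
background rate; the control region is i.i.d. AT-biased sequence (only
composition statistics touch it). Defaults: κ = 4, AT target 0.80, 1.1 kb
control region, realistic per-gene lengths, and a per-gene ω gradient
(atp8 0.6 … cox1 0.05) mirroring the canonical mitochondrial selection
hierarchy. Every output is a pure function of (configuration, seed).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: indels and alignment/trimming error (simulated
alignments are gap-free and column-true); realistic start/stop codons
(simulated CDSs are stop-free sense-codon strings, so start/stop
classification is exercised on explicit cases, not on simulated genes);
tRNA secondary structure; tandem repeats in the control region; real codon
usage beyond what i.i.d. AT bias induces (notably, the empirical top-5
amino-acid ranking of real mitogenomes reflects genuine usage preferences
the i.i.d. model only partially reproduces — the tests assert the
model-implied ordering: Leu first, AT-rich residues above GC-rich ones);
among-site rate variation; and base-composition heterogeneity among
lineages. NG86 with JC correction also systematically compresses Ka/Ks
below the instantaneous ω under biased composition — the recovery contracts
are therefore about rank (Spearman ρ = 1 across planted ω ∈ {0.05, 0.2,
0.6}; correct ordering in ≥ 95% of replicates), not absolute values.

## Problem sizes

The test and reproduction runs use 4–8 taxon balanced trees with branch
length 0.05, 300-codon genes for the ω-recovery experiment (100
replicates), full default gene lengths for the 13-gene gradient check, and
a 12-record barcode audit set (6 species × 2 individuals, within-species
divergence 0.2%, between-species ~20%). These sizes give stable statistics
(the recovery experiments pass at every seed tried) while keeping the whole
suite under a minute.

## Known limitations

* GenBank parsing accepts the common single-interval and two-part
  origin-wrapping locations; exotic multi-part joins are rejected with a
  record-level error rather than guessed at.
* `global_identity` reports the first optimal alignment; co-optimal
  alignments with different column counts can shift identity by a fraction
  of a percent (the verdict tiers are far wider than this).
* Gene-level Ka/Ks treats pairs as independent; no phylogenetic correction
  is applied (matching the conventional per-gene bar-chart computation).
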