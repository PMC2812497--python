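# Methods

`archseek` re-implements, as a tested and reusable pipeline, the
comparative-genomics computations used to mine a methanogen genome for
methane-mitigation targets: functional genome distribution (FGD) with UPGMA
clustering, differential homology ("differential BLAST") classification,
a reverse-vaccinology surface-protein cascade, a chemogenomic three-set
intersection, and nucleotide-level screens (GC skew / oriC, codon adaptation
index, horizontal-gene-transfer flags).  Every stage is exercised end to end
on synthetic ORFeome clades with known ground truth, generated by the
package itself.

## Pairwise similarity and statistics

Homology scores come from Smith–Waterman local alignment with affine gaps
(BLOSUM62; a gap of length *k* costs `open + k·extend`, 11 + *k* at the
defaults), computed through Biopython's `PairwiseAligner`.  Raw scores are
converted to bit scores and e-values with the gapped Karlin–Altschul
parameters standard for BLOSUM62/11/1 (λ = 0.267, K = 0.041):
`bit = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bit)`.  Two deliberate divergences
from a production BLASTP search are documented rather than hidden: no
composition-based statistic adjustment and no low-complexity masking are
applied.  Ambiguous residues (B/Z/U) are mapped to X, and X scores 0 against
everything.

A shared 5-mer seed prefilter (`AlignParams.seed_prefilter`) can skip query–
target pairs with no exact 5-mer in common.  It is **off by default**, so
the aligner is exactly equivalent to a full dynamic-programming search; the
pipeline turns it on for all-vs-all panels, where it passes essentially all
genuine homologues at the panel's divergence scale (a 300-residue pair at
50 % identity shares ~9 conserved 5-mers in expectation) while skipping ~97 %
of unrelated pairs.  The prefilter is approximate for very short or very
diverged sequences; tests that probe search semantics therefore run with it
off.

## Functional genome distribution

The published description of FGD gives the idea (all-vs-all ORFeome
similarity summarised into a symmetric genome–genome distance) but not the
scoring function, so this package fixes one with the right formal
properties.  For each ORF of genome A against genome B the score is the
self-normalised bit-score ratio `s = min(1, best_bits/self_bits)` (0 with no
qualifying hit).  `S(A,B)` is the mean of `s` over A's ORFs (ORFs under 30
residues are excluded as noise), and

```
D(A,B) = 1 − (S(A,B) + S(B,A)) / 2
```

which is zero on the diagonal, symmetric, and bounded in [0,1] by
construction.  Because the original scoring is unpublished, no attempt is
made to reproduce published tree branch lengths; trees are compared at the
topology level only.

UPGMA is implemented directly (the closest pair is merged, inter-cluster
distances are size-weighted averages, node height is half the merge
distance).  Ties are broken deterministically: among equal minimal
distances, the pair whose sorted minimum-member labels compare smallest is
merged first.  Tests cross-check the merge sequence against a brute-force
oracle that rescans the full leaf-pair matrix at every step and against
SciPy's average-linkage on tie-free random matrices.

Gene-set mining follows the e-value semantics of the source analysis:
`conserved_core` = reference ORFs hit at e ≤ cutoff in every cluster
genome; `cluster_specific` additionally requires no hit at e ≤ e_floor
(default 1e-3) outside the cluster.  The literature cutoff for
core-function mining is 1e-100 for full nr-scale searches; on the synthetic
panels built here (300-codon genes, toy database sizes) the equivalent
operating point is around 1e-20, which is the pipeline default.  Note that
`cluster_specific ⊆ conserved_core` by construction.

## Differential homology classification

Best-hit e-values against an in-group panel ("db") and an out-group ("nr")
are discretized into integer trust levels `T = floor(−log10 e)`, floored at
e = 1e-3 (anything weaker counts 0) and capped at 200 (e = 0 maps to the
cap).  The differential is `Δ = T_nr − T_db`.  Classification uses two
thresholds, presence (`τ_present` = 10) and absence (`τ_absent` = 3):
specific to the in-group if `T_db ≥ 10` and `T_nr < 3`, the mirror class
for the out-group, `shared` when both are strong, `orphan` when both are
absent, and all remaining borderline profiles conservatively `shared`.
The published analysis states neither its binning nor its boundaries; the
values here are order-preserving, interpretable defaults surfaced in the
configuration.  Swapping the two databases negates Δ and mirrors the
classes exactly (tested as a property).

## Surface-target cascade

The cascade mirrors the published four-step funnel: (1) keep ORFs with ≥ 1
transmembrane helix or a signal peptide; (2) remove ORFs whose top hit is
outside the methanogen panel or absent, transposases, and adhesin-like ORFs
(each removal records exactly one reason); (3) keep ORFs conserved in at
least `min_conservation` panel genomes — a single configurable threshold
standing in for the original's manual curation by function, conservation
and membrane architecture; (4) split survivors at 4 TMH into Group A
(≤ 4, suited to heterologous expression) and Group B (> 4, suited to
synthetic-peptide work).  Counts are monotone non-increasing and
|A| + |B| equals the refined count, by construction and by test.

The built-in topology and signal-peptide predictors are intentionally
simple, transparent stand-ins for the heavyweight HMM/NN tools used in the
original study; imported prediction tables take precedence when available.

* **TMH**: mean Kyte–Doolittle hydropathy over a 19-residue window is
  assigned to the window's central residue; maximal runs of centres at or
  above 1.6 become helix candidates.  Runs are split to the 15–35-residue
  physical band; runs of 8–14 centres are padded symmetrically to 15 (a
  genuine short helix against strongly hydrophilic flanks produces exactly
  such runs), and runs under 8 are discarded as noise.  Orientation uses
  the positive-inside rule: K+R counted over the 15 loop residues flanking
  each helix, summed per side; the side with more wins, ties go to
  N-inside.  One known artefact: a single long hydrophobic stretch just
  over 35 residues is reported as two helices, which can inflate
  `tmh_count` for genes with closely spaced planted helices.
* **Signal peptide**: positive iff the first 45 residues show the n/h/c
  architecture — a K/R in residues 1–5, an 8-residue window in residues
  4–30 with mean hydropathy over the stringency threshold (strict 1.8,
  default 1.5, loose 1.2), and an A-x-A motif whose second A sits at
  position 16–40 (cleavage reported after the motif).  "Combined" means
  positive under any requested preset (OR), mirroring the practice of
  pooling several differently trained models.

Extracellular loop peptides — the antigen candidates for membrane-embedded
targets — are the outside-labelled loops (terminal tails included) of
length 8–40.

## Chemogenomic intersection

Pure set algebra over three ORF-id sets (FGD-conserved, differential-
homology-specific, curated metabolic list) into the 7 regions of a
three-set Venn diagram; the central region is the candidate list.  The
metabolic list is a plain-text curated input by design — the corresponding
analysis in the source study was literature/pathway curation, which this
package does not automate.  Unknown ids are kept with a warning, never
silently dropped.

## Genome statistics

Windowed G+C and GC skew `(G−C)/(G+C)` (window 5000, step 500 by default;
windows wrap on circular replicons; N bases are ignored in numerator and
denominator).  The cumulative skew's global minimum marks the replication
origin; the reported `oric_candidate` is the position at the **end** of the
extremal window — the polarity switch — which localises a constructed
switch to within about one step.  Both extrema (origin and terminus
candidates) are reported.

CAI uses relative adaptiveness `w = freq / max synonymous freq` fitted on a
reference gene set (codons unseen in the reference get a 0.01 pseudo-floor;
an amino acid wholly absent gets a flat family of 1.0), and the gene score
is the geometric mean of `w` excluding Met, Trp and stops.  The reference
set is user-supplied; the pipeline defaults to a sample of core
("housekeeping-like") genes, standing in for the conventional
ribosomal-protein reference.

The horizontal-transfer flag is a strict conjunction of three evidence
lines: |standardised GC deviation| ≥ 2, CAI in the lowest quartile, and a
non-methanogen top hit (the lineage-evidence column an external screen such
as a lineage-probability tool would provide; in simulation mode it comes
from the generator's truth table).  Requiring all three keeps the false
positive rate near zero at the cost of missing transfers that have
ameliorated toward host composition.

## The synthetic clade generator

The generator produces the statistical structure every upstream stage
assumes, with complete per-gene truth:

* A root proteome (default 200 core + 50 clade-specific families;
  length ~ Normal(300, 60) codons, floor 80) sampled from natural
  background residue frequencies.  Along each branch every site
  substitutes with probability `1 − exp(−b)` to a uniformly chosen
  different residue — uniform rather than matrix-biased so that expected
  pairwise identity stays in closed form (`≈ exp(−path length)`, within
  ±3 points at 200 genes × 300 residues, by test).  No indels, so planted
  feature coordinates survive evolution unchanged.
* The default tree is 6-leaf ultrametric with merge heights pairwise
  separated by ≥ 0.1, clade {A, B, C} against out-group {D, E, F}.
* Families are lost independently on each branch (p = 0.02);
  clade-specific families are emitted only inside the clade; gene gain is
  modelled only as clade-specific presence.  Because one loss event on the
  out-group stem can silently make a designated-core family genuinely
  clade-restricted, the truth table carries both the planted labels and a
  computed `is_clade_restricted` column (family present in ≥ 2 clade
  genomes and nowhere outside) — the correct presence/absence ground truth
  for the differential classifier.
* Membrane and signal-peptide features are planted at the root:
  1–7 helices of 19–25 residues drawn from {I,L,V,F,M,A} (resampled until
  mean hydropathy ≥ 2.0) separated by ≥ 18-residue native loops, and/or an
  N-terminal n/h/c template (M + 2×K/R + 12 hydrophobics + A-S-A) that
  satisfies even the strict signal-peptide preset by construction.
* Nucleotide genes are back-translations under a host codon model whose
  synonymous weights follow the host G+C (default 30 %) sharpened to the
  third power — emulating the peaked codon preferences translational
  selection produces, without which host genes would not have the high CAI
  the screens assume.  Transferred genes (default 20, placed in the first
  clade genome) are fresh random proteins back-translated under a donor
  model with G+C offset +12 points and Dirichlet-shuffled preferences (the
  "foreign codon usage"), and their truth rows carry `top_hit_group =
  "other"`.  Genomes are genes joined by AT-rich random spacers, all on
  the plus strand, with 1-based coordinates recorded for BED export.
* Everything is driven by one seeded generator: the same seed reproduces
  byte-identical output (tested).

What the generator does **not** emulate — and hence what green tests do not
demonstrate about real data: indel evolution and alignment-length
variation, matrix-structured substitution preferences, operon and strand
structure, rearrangement/synteny, compositional amelioration of old
transfers, paralogy (every family is single-copy), and database-scale
e-value calibration.  Recovery rates measured here characterise the
methods' internal consistency at the panel's divergence scale, not their
field performance against nr-scale databases.

## Problem sizes and numerical choices

The default verification panel (6 genomes × ~200–260 ORFs, 300-codon
genes) keeps the complete all-vs-all analysis around a minute on one CPU
with the seed prefilter on; property tests use smaller clades (25–30
families, 120–130-codon genes) chosen so each check runs in seconds while
leaving clear signal margins.  Distance-matrix validity is asserted on
every output (symmetry tolerance 1e-9).  Best-hit ties break by e-value,
then bit score, then lexicographic subject id; UPGMA ties as described
above; all member lists in reports are lexicographically sorted.  These
tie-break chains exist purely for determinism — the source analyses
specify none.

## Known limitations

* The FGD scoring function is this package's own (the original is
  unpublished); distances are comparable within a panel, not across tools.
* E-values are Karlin–Altschul approximations without edge-length or
  composition corrections; absolute values differ from BLASTP, monotone
  ordering is what the downstream trust levels rely on.
* The built-in TMH/SP predictors are hydropathy heuristics; on real
  proteomes, imported TMHMM/SignalP-style tables should be preferred (the
  cascade accepts them directly).
* The cascade's step 3 reduces the original study's manual curation to one
  conservation threshold; no attempt is made to reproduce published target
  counts, which depend on a specific nr snapshot and tool versions.
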