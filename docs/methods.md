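# Methods

This note documents the models, conventions and numerical choices behind
`songkit`, and what its synthetic-data validation does and does not show.

## Song representation and segmentation

Inputs are syllable annotation logs: one row per rendition with a label,
onset and offset in seconds, and optional pitch (Hz) and Wiener entropy.
Events must be sorted and non-overlapping; inter-syllable gaps under 5 ms
draw a warning but are never auto-merged, because annotations are treated
as upstream ground truth.

All silence rules act on the gap `next.onset − current.offset`:

| rule | threshold | comparison |
|---|---|---|
| song boundary ("/" state) | 100 ms | strictly greater |
| isolated-call removal | 100 ms on both sides | strictly greater |
| bout split | 500 ms | greater or equal |

The bout split uses ≥ because within-bout inter-motif intervals are
defined as *shorter than* 500 ms.  Recording edges count as infinite
silence for the call rule, so a lone annotated event is treated as a call.
Segmentation is a pure partition: concatenating bout sequences reproduces
the recording, and re-segmenting a bout is the identity.

## Repetition and d′

The per-bout repeat count of a vocal element is the sum over maximal runs
of (run length − 1); multi-syllable elements are tiled greedily left to
right without overlap, the unique tiling consistent with "consecutive
repetition".  Elements are *repeat-eligible* for screening when some bout
contains a run of length ≥ 3 (two or more repeats beyond the first
rendition).

d′ uses sample variances (n − 1): the per-day samples are bouts, not a
population.  When both variances vanish, d′ is 0 if the means agree and an
error otherwise — a silent infinity would be worse than a loud one.  d′ is
antisymmetric in its arguments and invariant under common shifts and
positive rescalings of both samples; the test suite checks this over 1,000
random series along with exact (1e-12) agreement with the defining
formula.  Coefficients of variation are 100·SD/|mean| (sample SD).

## Transition and difference matrices

Streams are built per recording: calls removed, "/" inserted at every
boundary gap and at both edges, adjacent pairs tallied, rows normalized.
"/" never self-transitions (double boundaries collapse).  Pruning rare
syllables (< 20% bout presence at *any* timepoint) re-tallies the stored
streams with pruned labels removed instead of renormalizing rows, so no
probability mass is silently reassigned.  Difference matrices default to
baseline − comparison with missing states as zero rows/columns; a `flip`
flag inverts the sign for the opposite display convention.

## Syntax classification

The classifier is an explicit operationalization of what an expert does by
eye.  Per bout:

1. maximal runs of repeated elements are collapsed to one rendition
   (repetition is quantified separately and must not read as insertion);
2. leading introductory labels are stripped;
3. the remaining sequence is globally aligned against m concatenated
   copies of the baseline motif template (match 0, mismatch 1, indel 1),
   with m chosen to minimize cost (ties → fewer copies) and co-optimal
   deletions resolved leftmost;
4. deletions of template syllables are omissions; insertions of labels
   outside the baseline repertoire are additions; substitutions count as
   both; adjacent pairs absent from the baseline pair set are new
   transitions.

A bout is *syntax-altered* only if some edit is interior to a motif copy
(template position strictly between first and last).  Edge edits are
reported in the omission/addition tallies but excluded from the alteration
percentage.  Percentages are over a seeded uniform 30-bout sample without
replacement (all bouts, with a warning, if fewer are available).  The cost
model and tie-break are this module's design choices; alignment costs are
verified against exhaustive edit-path enumeration on short strings.

## Synthetic song generator

The generator emits annotation logs, not audio, with the structure the
statistics assume: per bout, an introductory-note run, then 2–4 motif
renditions.  Defaults: four-syllable motif, within-bout gaps uniform on
10–60 ms (safely below the 100 ms boundary rule), inter-bout gaps 0.8–2 s,
syllable durations 60–120 ms, per-rendition pitch Normal with CV 1.5% and
entropy CV 10.7% — the magnitudes typical of adult zebra finch song.

Repeat counts per run are pluggable:

* **geometric(p)**: mean (1−p)/p, variance (1−p)/p² — the memoryless
  repeat/advance ("motor loop") choice.  Within this family the analytic
  repetition d′ between two conditions is bounded above by √2, because the
  mean and SD both scale as 1/p.
* **poisson(λ)**: mean = variance = λ, under-dispersed relative to a
  geometric of equal mean.  This is what allows injected effects in the
  d′ ≈ 2 regime observed for strong repetition phenotypes;
  `poisson_rate_for_dprime` solves the quadratic for the rate achieving an
  exact target d′ against any baseline.

Each element draws one repeat run per bout at its first occurrence, which
makes the analytic d′ exact (per-bout counts follow the repeat
distribution directly).  Multi-syllable elements repeat only when they end
a motif, so runs stay contiguous.  Effects are immutable step changes:
repeat-distribution replacement, per-syllable omission probability, novel
-syllable insertion probability (interior position, label outside the
repertoire so additions are detectable by identity), and pitch shifts in
units of the syllable's baseline SD.  All randomness flows from one seed;
each bout consumes an independent spawned substream, so output is
byte-identical for a fixed seed.

What the generator does *not* emulate: acoustic waveforms, social-context
modulation, gradual drift (effects are step changes), or annotation noise
(labels are exact).  Passing recovery tests therefore demonstrates
estimator correctness under the generative assumptions, not robustness to
labeling error.

## snRNA-seq chain

Containers are `AnnData` (cells × genes); raw UMIs live in
`layers["counts"]` after normalization.

* **QC**: remove cells with UMI total > 10,000 (doublet proxy) or
  mitochondrial share > 5% of UMIs (damage proxy); boundary cells stay
  (strict inequalities).  The filter is idempotent and equals brute-force
  predicate evaluation by construction; a report lists each removed
  barcode and reason.
* **Normalization**: ln(1 + c/total·10⁴), natural log.
* **Expression call**: a gene is "expressed" in a cell iff its normalized
  value is positive, i.e. ≥ 1 UMI — the only unambiguous threshold; a
  `min_value` parameter exposes stricter calls.
* **Clustering contract**: top variable genes (seurat flavor, default
  2,000) → covariate residualization on UMI total and mito% (one
  vectorized OLS across genes) → unit-variance scaling clipped at ±10 →
  PCA → kNN graph → Leiden community detection (igraph backend, fixed
  random state), clusters renumbered 1..K by decreasing size.  The PC
  count automates the scree elbow as the point of maximum distance to the
  chord joining the first and last explained-variance ratios, overridable
  by `n_pcs`.  Resolution defaults to 0.8.
* **Typing**: a marker is enriched in a cluster when ≥ 40% of its cells
  express it and its cluster mean reaches half the maximum cluster mean
  for that gene.  The relative-to-max criterion tolerates markers shared
  across sibling clusters (Gad2 across all MSN clusters) where a
  cluster-vs-rest fold change fails.  MSN requires Gad2 ∧ Ppp1r1b ∧ FoxP1;
  PN requires Penk or Tshz1; interneurons any of Pvalb/Sst/Npy/Nos1/Chat;
  then Slc17a6 (glutamatergic) and the glial/vascular singles; remaining
  Gad2-only clusters are "GABAergic", everything else "unassigned".
* **Receptor classes** partition MSNs exactly: D1/5-only, D2-only, both,
  none; FoxP2 co-expression is reported within each class.  Pathway
  groupings (direct-like vs indirect-like) can be supplied as cluster id
  sets or inferred from the per-cluster fraction of Drd2⁺ cells
  (> 0.25 → indirect-like).
* **Differential expression**: genes pre-filtered at expression fraction
  ≥ 0.1 in either group and |Δ mean ln-expression| ≥ 0.25, groups
  subsampled to 200 cells (seeded), Wilcoxon rank-sum per gene, Bonferroni
  over the genes tested after pre-filtering, direction labels at adjusted
  p < 0.001.  Condition contrasts of receptor expression use Welch's
  unequal-variance t within exact receptor-combination groups of FoxP2⁺
  cells.
* **Dendrograms**: cluster means over the union of each cluster's top-50
  fold-change genes, distance 1 − Pearson correlation, average linkage;
  node support is the fraction of 100 gene-bootstrap replicates whose tree
  contains the same leaf set; output includes Newick with supports.

## Synthetic expression generator

Counts are gamma-Poisson (negative binomial, dispersion 0.3 — a standard
UMI value) around per-program relative means scaled to a drawn library
size (Normal, clipped to 1.5–9.5k UMIs so singlets pass QC).  Marker genes
get low uniform background off-program; each program also carries a block
of dedicated signature genes so sibling programs remain separable.
Receptor/FoxP2 status is sampled per cell *first* from the program's class
probabilities; receptor-gene means are gated on status and status-positive
cells keep at least one UMI (negatives stay at zero), so the programmed
co-occurrence is recovered exactly under the ≥ 1 UMI expression rule
rather than only in expectation.  Mitochondrial fraction is drawn per cell
(≈ 2% typically; a 2% "damaged" subpopulation at 6–20% exercises the mito
filter) and realized by allocating that share of the library to a
dedicated mito gene set.  Doublets are sums of two independent cells;
since singlet libraries stay below 9.5k, doublet totals exceed the 10k QC
threshold by construction.

The packaged Area X preset programs the tissue's composition: five MSN
programs totalling 68% of cells (direct-like MSN-1/5 without D2-only
cells; indirect-like MSN-2/3/4 carrying them), pallidal-like cells at
2.4%, plus interneuron, glutamatergic, glial and vascular programs.  The
MSN-weighted receptor-class mix is 36/13/18/33 (D1/5-only / D2-only /
both / none) and FoxP2 co-expression is 61% in D1/5-only and 21% in
D2-only cells; the "both" (40%) and "none" (30%) rates are not pinned by
the tissue literature and were chosen once as plausible intermediates.
`scale_receptor_expression` binomially thins receptor counts (keeping ≥ 1
UMI in positive cells) to emulate a knockdown-like reduction in transcript
abundance without changing class structure.

Known gaps relative to real snRNA-seq: expression is denser (less dropout)
than typical tissue data, gene–gene correlation exists only through
program blocks, and there is no ambient RNA.  Recovery results therefore
validate the classification chain's logic, not its robustness to those
artifacts.

## Problem sizes and determinism

Validation runs at: 1,000 random series/sequences for the d′ and
repeat-count oracles; 2,000+ transitions for chain recovery (L∞ < 0.05);
30 bouts per day averaged over 50 seeds for effect recovery (±0.3 around
analytic d′ ∈ {0, 1, 2}); 30-bout samples for syntax metrics; and 10,000
cells × 1,000 genes for the end-to-end expression recovery (receptor split
within ±2 points, FoxP2 co-expression within ±3).  Smaller simulations
(300–1,500 cells) back the unit tests.  Every stochastic routine takes an
explicit seed; generators derive per-unit substreams from it, so all
reported numbers are exactly reproducible.
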