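# songkit

Quantitative tools for two linked questions in songbird neuroscience: **how
does adult zebra finch song change when basal-ganglia circuits are
perturbed**, and **which striatal cell types carry those perturbations**?

Zebra finch song is built from syllables arranged into a stereotyped motif,
sung in bouts of introductory notes followed by motif renditions.
Manipulations of the striatal song nucleus Area X — FoxP2 knockdown, phasic
dopamine stimulation — produce characteristic disruptions: dysfluent
repetition of syllables at motif edges, omission of motif syllables,
insertion of novel syllables, and altered syllable-to-syllable transitions.
`songkit` implements the statistics that quantify those disruptions from
syllable annotation logs, and the matching single-nucleus RNA-seq analysis
that classifies Area X cell types by dopamine-receptor and FoxP2
expression.  Both halves ship generative simulators with analytic ground
truth, so every estimator is validated by parameter recovery.

## The statistics

**Repetition d′.** For a vocal element (one syllable or a short syllable
group), the per-bout repeat count *n* is the number of consecutive
renditions beyond the first in each run.  Day-to-day change is the
standardized effect size

```
d′ = √2 (n̄_i − n̄_b) / √(σ_i² + σ_b²)
```

with day means and sample variances; when the variances agree, d′ is the
change in units of SD.  The same statistic applied to per-rendition pitch
gives |d′|, with |d′| > 0.75 as the criterion for a learned pitch change.

**Transition matrices.** After removing isolated calls (silence > 100 ms on
both sides), song boundaries ("/" states) are inserted at gaps > 100 ms, and
all adjacent syllable pairs are tallied into a row-stochastic first-order
transition matrix.  Difference matrices (baseline − comparison) expose
changed transitions; syllables present in under 20% of bouts at any
timepoint can be pruned by re-tallying.

**Syntax classification.** Post-manipulation bouts are aligned to the
baseline motif template (global alignment, unit costs, repeat runs collapsed
first).  Interior deletions are omissions, interior insertions of labels
outside the baseline repertoire are additions, and adjacent pairs absent at
baseline are new transitions.  Edits at the first or last motif position are
recorded but — by definition — do not count as syntax alterations.
Percentages are computed over a seeded 30-bout sample.

**snRNA-seq classification.** Cells with > 10,000 UMIs or > 5%
mitochondrial UMIs are removed; counts are log-normalized
(ln(1 + c/total·10⁴)); clustering runs variable genes → covariate
regression → PCA (elbow-selected) → graph community detection, with
clusters renumbered by size.  Clusters are typed from marker genes (MSNs by
joint Gad2/Ppp1r1b/FoxP1; pallidal-like by Penk; interneurons, glia, and
vascular types by their canonical markers).  MSNs are partitioned into
exclusive dopamine-receptor classes — D1/5-only, D2-only, both, none — with
FoxP2 co-expression per class, grouped into putative direct-like
(Drd1⁺/FoxP2⁺) and indirect-like (Drd2⁺) pathways for Wilcoxon rank-sum
differential expression (Bonferroni-corrected), Welch tests of receptor
expression between conditions, and bootstrap-supported dendrograms of
cluster profiles (1 − Pearson correlation, average linkage).

## Worked example

Inject a knockdown-like repetition effect into the song simulator and
recover it with the analysis chain:

```python
from songkit.annotations import segment_bouts
from songkit.sequence import repetition_series, dprime, transition_matrix
from songkit.simulate.song import (default_model, apply_effect, EffectSpec,
                                   geometric, poisson, poisson_rate_for_dprime,
                                   generate_recording, expected_repetition_dprime)

baseline = default_model(repeats={("i",): geometric(0.9)})
lam = poisson_rate_for_dprime(geometric(0.9), 2.0)
knockdown = apply_effect(baseline, EffectSpec(element="i", repeat=poisson(lam)))
print("analytic d':", round(expected_repetition_dprime(baseline, knockdown, "i"), 3))

rec_b = generate_recording(baseline, 30, seed=1, timepoint="baseline")
rec_k = generate_recording(knockdown, 30, seed=2, timepoint="post")
s_b = repetition_series(segment_bouts(rec_b), "i", "baseline")
s_k = repetition_series(segment_bouts(rec_k), "i", "post")
res = dprime(s_k, s_b)
print(f"estimated d' = {res.value:.2f} "
      f"(mean {res.mean_i:.2f} vs {res.mean_b:.2f} repeats/bout)")
print(transition_matrix(rec_b).probabilities.round(2))
```

prints

```
analytic d': 2.0
estimated d' = 2.36 (mean 2.27 vs 0.13 repeats/bout)
      a    b    c    d     i     /
a  0.00  1.0  0.0  0.0  0.00  0.00
b  0.00  0.0  1.0  0.0  0.00  0.00
c  0.00  0.0  0.0  1.0  0.00  0.00
d  0.65  0.0  0.0  0.0  0.00  0.35
i  0.88  0.0  0.0  0.0  0.12  0.00
/  0.00  0.0  0.0  0.0  1.00  0.00
```

The injected effect has an analytic d′ of exactly 2; a single 30-bout
sample estimates 2.36 (the 50-seed average lands within ±0.3 of the
target).  The baseline transition matrix shows the stereotyped a→b→c→d
motif, the intro note's rare self-transition (P(i|i) = 0.12 under
geometric p = 0.9 repeats), and the bout-internal d→a / bout-final d→"/"
branch.

A command-line layer wraps the same functions, e.g.

```sh
songkit simulate-song --bouts 100 --seed 7 --out song.tsv
songkit transitions --annotations song.tsv --out matrix.tsv
songkit snrna simulate --cells 2000 --genes 500 --seed 1 --out mtx/
songkit snrna run --mtx-dir mtx/ --outdir results/
```

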