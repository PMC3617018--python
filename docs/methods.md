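# Methods

## Data model

All analysis operates on fixed-width genomic bins (default 100 kb, 0-based
half-open coordinates).  A `GenomeLayout` holds one species' chromosome
names, lengths and optional centromere coordinates; terminal chromosome
remnants shorter than one bin are never binned, because a short window's
mean is not comparable with full-width windows.  The sign convention is
uniform: **larger value = more open chromatin**.  Replication-timing
(log2 early/late) and Hi-C first-eigenvector tracks already obey it;
lamina-association tracks (log2 Dam-fusion/Dam-only, where high = more
lamina-associated = more closed) are sign-flipped at load time via the
`sign_flip` flag in the dataset manifest.  Hi-C eigenvector orientation is
taken as published; if an input eigenvector is arbitrary-signed it should
be oriented by positive correlation with a replication-timing consensus
before loading.

## Binning, collation, orthology

Probe records are assigned to the bin containing their midpoint and
averaged; bins with fewer than `min_probes` (default 10) probes are
discarded as unreliable.  Within a species, datasets are collated on the
first track's grid, pairing each other dataset's best-overlapping bin when
the coordinate overlap is at least `min_collate_overlap` (default 0.5,
inclusive); with identical grids this reduces to exact coordinate match,
and the collated table is complete-case — a region missing from any
dataset is dropped.

Cross-species pairing consumes an orthology interval map (produced
upstream, e.g. by reciprocal liftOver; building it is out of scope) whose
pairs carry both overlap fractions, each denominated in the interval's own
length so that *both* fractions must clear the threshold (default 0.5,
inclusive).  Retained pairs must additionally be reciprocal best: each
side's largest-overlap partner is the other, with ties broken by larger
overlap, then lexicographic partner chromosome, then lower partner start —
deterministic.  Regions left unpaired on either side are reported as
putatively lineage specific; no input region is silently lost.

## Normalisation

Quantile normalisation is applied jointly across all datasets of both
species: every column is mapped onto the cross-column mean of order
statistics.  Tie dialects differ between implementations; here a group of
tied entries receives the mean of the reference values across the ranks
the group spans (the common microarray dialect; verified to agree with
limma's `normalizeQuantiles(ties=TRUE)` on hand-computed tables).  Rank
order within a column is preserved exactly, so rank correlations are
invariant under normalisation.  Per-species mean structure is the
arithmetic mean over that species' columns.

## Divergence calling

The per-region statistic is the moderated two-class unpaired form
`d = (mean_A − mean_B) / (s + s0)` with `s` the pooled standard error of
the mean difference.  The exchangeability constant `s0` defaults to the
median of the per-region `s`; a percentile-grid search minimising the
coefficient of variation of the d-scale across `s` bands is available.
With zero within-class variance the statistic is finite, regularised by
`s0` alone.

Permutations reassign species labels to dataset columns — one relabelling
per permutation, applied to all regions, which preserves the inter-region
correlation structure.  When the number of distinct label assignments
C(K, K_A) is at most 10,000 they are enumerated exhaustively (with six
datasets per species that is 924, so the default study is always
exhaustive); otherwise assignments are drawn uniformly with the given
seed.  Mixed-label permutations inflate the within-class variance of truly
divergent regions, which is what keeps their permuted scores small — the
moderation and the permutation scheme work together.

Cut-offs are selected by a delta search on the sorted observed scores
against the expected scores (the mean permuted order statistics): for each
candidate delta, the upper cut is the first observed order statistic above
the centre exceeding its expectation by delta, the lower cut the mirror
image.  The estimated FDR at a cut pair is the **median** over
permutations of the number of permuted scores beyond the cuts, divided by
the observed call count; the loosest cuts with estimated FDR at or below
the target are chosen, and polarity is the sign of d for called regions.
If no cut qualifies the result carries zero calls and a `no_calls` flag
rather than an error.  No pi0 (true-null fraction) factor is applied,
matching the median-false-positive FDR definition used.

**A property worth knowing.**  At very small targets the median-based FDR
is driven to exactly zero, which places the chosen cut near the median of
the permutation distribution of the genome-wide maximum null score.  By
exchangeability the observed null maximum exceeds such a cut about half
the time, so the *mean* realised false-discovery proportion of this rule
is roughly `ln 2 / n_calls` — with ~500 calls, about 1.4e-3 — however many
permutations are used.  The rule does deliver its stated guarantee (the
expected number of false positives stays around one), but the realised FDP
cannot be pushed arbitrarily far below that floor by tightening the
target.  The acceptance suite measures this honestly: on the reference
study the per-seed false-positive count is 0–2.

## Divergence clusters

Runs are maximal stretches of divergent bins that share polarity and are
exactly coordinate-adjacent; orthology coverage gaps break runs and no gap
tolerance is applied (a conservative choice — a single marginally
non-significant bin splits a cluster).  The null shuffles the
polarity-bearing call labels uniformly among each chromosome's orthologous
bins, keeping coordinates fixed, so each chromosome's label multiset and
gap structure are preserved.  The p-value of a run of length n is the
fraction of permuted genomes containing any run at least that long —
monotone non-increasing in n; lengths never seen in `n_perm` permutations
are reported as bounded above by `1/n_perm`, and significance compares the
raw exceedance fraction with alpha (default 1e-4 at 10,000 permutations;
the reference study uses 2,000 permutations, where only never-seen lengths
can be significant).  Clustering is run in each species' coordinate frame
and the reconciled intersection (clusters sharing member regions across
frames) is the headline output.

On the reference study (10% divergent bins, ~5/5 polarity split, 5,000
bins) runs of 4 bins still occur by chance in a few percent of permuted
genomes; the significance threshold settles at 6–7 bins.  Cluster-recovery
metrics are therefore evaluated over implanted tracts at or above the
null's own significance length.

## Positional enrichment

Circular permutation rotates all regions on each chromosome by one uniform
random offset per chromosome per permutation, wrapping past the end
(wrapped intervals are split for overlap computation).  Interval lengths,
pairwise spacings and hence the observed clustering are invariant — the
reason this null, and not independent replacement, is appropriate for
clustered region sets.  Two statistics are provided: the number of regions
intersecting any feature (≥ 1 bp by default; containment is an option) and
the median distance from region boundaries to the nearest feature
boundary.  Default p-values follow the raw `n/n_perm` convention with the
qualifying direction inclusive of the observed value; the
`(1+n)/(1+n_perm)` variant is available.  Subtelomeric windows cover both
chromosome ends except on acrocentric chromosomes (distal end only);
centromeric windows flank the centromere coordinate on both arms where a p
arm exists.  Note that on a single chromosome the two subtelomeric windows
abut through the wrap point, so single-chromosome rotations have little
power; power comes from combining chromosomes.

## Association statistics

Inter-dataset agreement is summarised by pairwise Spearman correlations
with an average-linkage ordering on (1 − rho) distances for heatmap
reproduction.  The chromosome distribution of calls is tested by
chi-squared against each chromosome's share of orthologous bins, flagging
|standardised residual| > 1.96.  GC content is contrasted between
divergence classes with two-sided rank-sum tests, per-class least-squares
regressions of GC on mean structure, and a per-category difference table
over equal-width structure bins.  Gene densities (emitted per 100 kb and
per Mb) use start-coordinate assignment of annotations to regions, which
is deterministic and strand-independent; strand is ignored throughout.
Expression divergence uses log2((RPKM_A + c)/(RPKM_B + c)) with pseudocount
c = 0.01 recorded in the output; the *absolute* mode restricts divergent
classes to regions whose normalised species means straddle zero (open side
positive, closed side negative).  A generic two-class Fisher exact test
relates any binary gene property to divergent residence, with a
Haldane-corrected odds ratio reported alongside when a margin is zero.
The alignment-overlap control compares the orthology overlap fractions of
divergent and non-divergent regions, the check that divergence calls do
not merely track poor cross-species alignment.  All tests are two-sided
unless a direction is inherent in the statistic.

## The synthetic study

The generator emulates the features the analysis relies on, no more:

* **Compartments** — a two-state renewal chain: each bin resamples
  i.i.d. Bernoulli(p_open) with probability `r = min(1, 2/m)` where m is
  the mean-domain parameter, else copies its neighbour.  Run lengths are
  geometric; at p_open = 0.5 the mean run length equals m (for m ≥ 2), and
  m = 1 degenerates to i.i.d. states.  For p_open ≠ 0.5 the chain keeps
  the stationary fraction exact and lets the tally mean deviate from m.
* **Divergent tracts** — species B starts as a copy of species A; tracts
  of 4–8 bins are flipped in B only, placed without overlap and (by
  default) only where A's state is constant so each tract has one
  polarity.  An end-bias parameter places a chosen fraction of tracts
  within a window of chromosome ends, giving the subtelomeric geometry.
  The B genome is then a block-reversal rearrangement of the aligned bins,
  and the emitted orthology map uses the same rearrangement, so pairing is
  consistent by construction.
* **Signal** — value = state mean (±1) + per-dataset offset
  (sd 0.2) + per-bin noise (sd 0.5), giving bimodal marginals, a 4-sigma
  implant effect and pairwise Spearman correlations in the 0.5–0.8 band.
  Probe-level sampling scatters Poisson(30) probes per bin (sd 0.3) whose
  mean recovers the bin value.
* **Annotations** — GC is state-shifted noise calibrated toward a target
  rank correlation with structure (default 0.6); gene counts are Poisson
  with state-dependent rates (open 3.0 / closed 1.5 per bin for the
  protein-coding class, a rarer lincRNA-like class with a 4x rate inside
  implanted tracts); expression log2 fold change is shifted by ±1 inside
  tracts (sd 1.5); a binary regulatory-divergence flag can be generated at
  a chosen odds ratio against tract residence.

What the generator does **not** emulate: platform-specific distribution
shapes, cell-type heterogeneity, segmental duplications and repeat-driven
lineage-specific sequence, GC isochore structure beyond a single
correlation, or Hi-C contact matrices (eigenvalues are consumed as a
track).  Passing tests therefore demonstrate that the machinery recovers
known truth under the stated statistical structure, not that any
particular biological dataset would yield particular calls.

## Problem sizes and seeds

The reference study is 5,000 bins over 8 equal 62.5 Mb chromosomes, six
datasets per species, 83 tracts of 4–8 bins (~10% of bins), half of the
tracts end-biased into 5 Mb windows.  Permutation counts are 10,000 for
divergence (resolved exhaustively as 924 label assignments), 2,000 for the
cluster null and 2,000 for enrichment — sizes chosen so a full run
completes in seconds while every permutation machine operates well away
from its small-sample edge cases; exhaustive enumeration backstops each
machine in the tests.  The reference orthology map keeps full bin coverage
so implanted tracts stay contiguous in the orthologous frame (boundary
recovery is then well defined); orthology dropout, sub-threshold decoys
and non-reciprocal candidates are exercised separately in the unit suite.
Every stage draws its RNG seed from the master seed plus a CRC of the
stage name, so adding draws to one stage never perturbs another.

## Known limitations

* Two species only; no multi-species contrasts.
* No gap-tolerant or HMM segmentation of divergent runs.
* The enrichment null is pure circular rotation; no GC- or
  density-matched resampling.
* The median-FDR floor on realised FDP discussed above.
* Functional (GO/annotation-database) enrichment is out of scope; the
  Fisher test on user-supplied gene flags is the provided generic
  replacement.
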