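# Methods

## Problem and model

The package compares a *query perturbation* — the change in one patient's
expression profile between a pre-treatment and a post-treatment sample —
against a *reference bank* of drug perturbation profiles, one total gene
ranking per instance (compound × dose × cell line). The comparison is made
per biological pathway rather than genome-wide: a treatment that acts
through a handful of pathways should be matched on those pathways, not
diluted across the whole array. The output for each reference instance is a
pair of counts — pathways where the instance significantly *mimics* the
query and pathways where it significantly *reverses* it — and instances are
ranked by the total.

The model behind the score is deliberately minimal. A reference instance is
reduced to an ordering of genes from most up- to most down-regulated; the
query is reduced to two tag lists (up- and down-regulated genes past a fold
change threshold). Whether the query's up-tags sit near the top or the
bottom of the instance's (pathway-restricted) ranking is measured with a
signed Kolmogorov–Smirnov statistic. No intensity scale information from
the bank is used beyond the ordering, which makes the method robust to
platform differences at the cost of ignoring effect magnitudes.

## The signed KS statistic

For t tag positions V(1) < … < V(t) in a ranked list of N genes:

    p = max_j [ j/t − V(j)/N ],   n = max_j [ V(j)/N − (j−1)/t ]
    KS = p if p ≥ n else −n

p measures the excess of the tag empirical CDF above uniform (top-loading),
n the excess below (bottom-loading). Values lie in [−1, 1]; tags occupying
the top t positions give 1 − t/N and the bottom t positions give
−(N − t + 1)/N.

Numerical choices:

* **Ties p = n.** The definition leaves p = n undecided; we return the
  positive branch. This is the only convention under which the top-extreme
  closed form 1 − t/N holds for *every* t < N (at t = N − 1 the top-extreme
  configuration itself is a tie with p = n = 1/N). The branch comparison
  uses a 1e−12 tolerance: true p/n gaps are integer multiples of 1/(tN), so
  the tolerance can only absorb float rounding of exact ties, which must
  take the positive branch.
* **Reversal symmetry.** Reversing a ranking maps (p, n) to
  (n − 1/N, p + 1/N) exactly. In the combined two-list score the ±1/N
  offsets cancel, so the score negates exactly under reversal *provided*
  neither list's branch margin |p − n| is within 2/N of the flip boundary;
  inside that margin the branch (or the same-sign rule) can flip and the
  symmetry is only approximate. Property tests assert exact negation under
  the margin condition.

## Combining up- and down-tag lists

Default (`combined` mode): score each list separately; if KS_up and KS_down
share a sign the instance treats both lists the same way — no coherent
mimicry or reversal — and the score is 0; otherwise the score is
(KS_up − KS_down)/2, halved to keep [−1, 1] (a config flag disables the
halving; `single_set` mode scores the union as one list). If one list is
empty in a pathway, the other list's statistic is used alone, the down list
with flipped sign (down-tags at the top of a reference ranking mean the
reference reverses the query).

N is always the *pathway-restricted* list length: the instance ranking is
filtered to the pathway's genes with order preserved and positions
renumbered. Using the global N instead would make scores incomparable
across pathways of different sizes. Tag genes absent from the instance
universe are dropped before scoring.

## Pathway gate

Connectivity is only computed in pathways the treatment plausibly affects.
With a single pre/post pair no sample-label permutation test is possible, so
two gene-level modes are provided:

* `ks_permutation` (default): the pathway's members are scored as one tag
  group against the full differential ranking; the null re-draws same-size
  random gene subsets (1,000 permutations by default), two-sided on |KS|.
  This uses the entire ranking and needs no threshold.
* `hypergeometric`: one-sided over-representation of the thresholded DE set
  in the pathway. Being a discrete test it is conservative for small
  pathways or DE sets: the attainable rejection rate at nominal 0.05 is
  ≈ 0.03 for 10–80-gene pathways and approaches 0.04–0.05 only when the
  expected overlap is large (hundreds of DE genes, 50–200-gene pathways) —
  the regime used for calibration checks.

Selection keeps pathways with raw p < 0.05 (strict), no multiple-testing
correction, matching common practice for a screening gate; a
Benjamini–Hochberg flag is available. Permutation p-values always carry the
+1 correction and are derived per (N, t) configuration from the run seed,
so they do not depend on evaluation order.

## Counting and ranking

A pathway counts as positive for an instance when score > 0 and the cell's
permutation p-value (tag positions shuffled within the pathway list,
preserving list sizes) is below `count_alpha` (default 0.05); negative
analogously. `count_alpha = 1` reduces to a pure sign count. Instances are
ordered by total count, then summed |score|, then instance id — fully
deterministic. Counts are rendered `"20+ 1−"` (U+2212 minus), the compact
signed style used in published connectivity tables.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fold_threshold` | 2.0 (linear) | tag gene gate, \|log2FC\| ≥ 1; inclusive |
| `enrichment_alpha` | 0.05 | pathway gate, strict `<` on raw p |
| `n_perm` | 1000 | permutations for both nulls; p resolution 1/1001 |
| `count_alpha` | 0.05 | per-cell significance for a pathway to count |
| `min_abs_score` | 0 | optional effect-size floor for counting |
| `k` | 10 | report length |
| `snr_threshold` | 2.0 | probe filter on max signal/noise across samples |

The SNR keep rule defaults to retaining probes with SNR ≥ 2 (the standard
reading of a robust-expression gate); `snr_keep_rule: below_threshold`
reproduces the inverted literal reading found in some descriptions. The
filter runs before normalization, on the scale of the noise estimates.
Quantile-normalization ties receive the mean of the reference values over
their tied positions; this makes tied entries equal in the output but means
exact idempotence holds only for tie-free columns (with ties a second pass
shifts values by at most the within-tie reference spread).

## Synthetic data

`pbsc.simulate` stands in for the two inputs that cannot be shipped:

* **Bank**: each instance receives disjoint up/down signature genes
  (default 50 per direction) sampled inside 5 randomly chosen "affected"
  pathways; its ranking is the descending order of a latent vector with
  ±2.0 (log2 units) on signature genes plus N(0, 0.5) noise. Concentrating
  signatures in pathways is what gives per-pathway scoring real structure —
  a genome-wide-uniform signature would be invisible to the pathway gate.
  Pathway sets whose union cannot host the signature are redrawn (bounded
  retries) before declaring the configuration infeasible.
* **Patient pair**: pre ~ N(8, 1) per gene (typical log2 microarray
  intensities; irrelevant to rank-based scoring), post = pre ± effect on
  one instance's signature genes plus N(0, 0.5) noise. With effect 2.0 and
  noise 0.5, a planted up-gene clears the 2-fold threshold with probability
  Φ(2) ≈ 0.977.

Defaults are 2,000 genes, 50 instances, 100 pathways of 10–80 genes. What
the generator does *not* model: probe-level effects, spatial artifacts,
correlated noise, batch structure, or partially overlapping gene universes
between patient and bank. Passing recovery tests therefore demonstrates the
statistical machinery — thresholding, gating, scoring, counting — under
idealized noise, not robustness to real microarray pathology.

## Problem sizes used in tests

Unit tests run on a scaled-down scenario (400 genes, 8 instances,
20 pathways). Recovery checks use the full default scenario across 20 seeds
(forward) and 5 seeds (reversed); enrichment calibration uses 2,000 null
pathway-draws at 1,000 permutations each. One full default pipeline run
(2,000 genes, 50 instances, 100 pathways, 1,000 permutations) takes about a
second thanks to null-distribution caching per (N, t) configuration.

## Known limitations

* One pre/post pair per patient: no variance estimate, so fold change is
  the only effect measure and the enrichment gate cannot use phenotype
  permutation.
* The cross-bank rescaling of raw scores into a normalized connectivity
  score is out of scope; scores are comparable across pathways but raw.
* The hypergeometric gate is conservative for small pathways (discreteness).
* Multi-patient aggregation is a post-hoc intersection of per-patient
  reports, not a joint model.
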