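# Methods

This note documents the models and procedures implemented in `scnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real data.

## Reference-guided network construction

### The contract

A cell-type-specific gene network (CGN) is always a subgraph of the
reference interactome: an edge appears in the CGN of population *c* if and
only if (i) it exists in the reference and (ii) both genes pass the activity
threshold for *c*. Edge weights are copied from the reference (its
log-likelihood scores, LLS) and never re-estimated from the expression
data — single-cell counts decide *which* part of the interactome is active,
not *how strongly* genes interact. This containment is asserted at build
time on every call.

### The activity transform

Archetype- or metacell-based transforms used by some pipelines introduce
stochastic, parameter-heavy preprocessing. `scnet` instead uses a
deterministic, parameter-free activity score:

1. per cell: counts are depth-normalized to 10,000 (CP10K) and
   log1p-transformed;
2. per cell: values are rank-transformed across genes (average ranks for
   ties) and mapped through the standard normal quantile function,
   z = Φ⁻¹((r − ½)/G) with G the number of genes — the (r − ½)/G offset
   keeps both extremes finite and symmetric;
3. per population: activity(g, c) is the mean of z over the cells of *c*.

The rank-based inverse-normal step makes the score invariant to monotone
distortions of the per-cell expression profile (depth, saturation), and the
per-population mean gives each gene a standardized activity whose scale is
comparable across populations. All-zero genes receive the transform of the
minimal (tied) rank rather than an error; all-zero cells contribute the
value shared by all-tied ranks.

The default threshold retains the top 50% of genes per population
(`threshold_mode="percentile"`, `threshold=0.5`); an absolute cutoff is
available. The retained fraction is monotone: stricter thresholds can only
remove edges. Populations with fewer than `min_cells = 50` cells are
skipped — below that, activity means are too noisy to threshold reliably.
When a condition column is supplied, strata are (cell type × condition)
pairs, each yielding its own network.

## Bayesian link scoring (LLS)

For a ranked link list *D* and a gold standard with positives *L* over a
gene universe *U*, each successive bin of `bin_size = 1000` evaluable links
is scored

    LLS = ln[ (n_pos / n_neg) / (P(L) / P(¬L)) ],

where P(L) = |L| / C(|U|, 2). We apply the natural log: "log likelihood
score" names a log-odds-ratio quantity, and the odds ratio alone would not
be a *log* score. Links with a gene outside *U* are skipped entirely rather
than counted as negatives — counting unknowns as negatives would bias the
posterior downward for any data source that ranks understudied genes
highly. Bins with zero positives or zero negatives get ∓∞ and a
`degenerate` flag instead of raising, so callers can trim or report them.
Score ties in the ranked list are broken by canonical gene-pair order so
binning is reproducible.

## Hub significance (rewiring null)

Centrality is weighted degree (strength): the sum of incident LLS. The
null model preserves each gene's *number* of interactions while
randomizing *which* interactions it has: degree-preserving double-edge
swaps, 10 × |E| attempts per replicate (enough to decorrelate networks of
the sizes CGNs reach), with each edge keeping its weight. Replicates are
generated until the pooled strengths of all genes reach `n_null = 10,000`
values; each gene's p is the pseudo-count upper-tail rank
(1 + #{null ≥ s}) / (1 + N) — never exactly zero — followed by
Benjamini–Hochberg across genes and an FDR < 0.05 hub call. Pooling across
genes (rather than stratifying the null by degree) follows from
accumulating "centrality scores of all genes" into one distribution; a
consequence worth knowing is that a gene's p-value reflects its strength
relative to the whole network's null strength distribution, so on small
networks the degree-peers of a strong gene populate the upper tail and
temper its significance. An optional `shuffle_weights` flag additionally
permutes weights across edges; it is off by default because moving weights
with their edges is the more conservative null (it preserves the weight—
topology coupling the data came with).

Graphs whose degree sequence admits no alternative wiring (stars, cliques)
reject every swap; such replicates equal the input and a warning is
emitted. Networks with fewer than 3 edges cannot be rewired at all and
raise.

Because interactomes are biased toward the ribosome complex, genes matching
the bundled RPL/RPS/MRPL/MRPS prefixes are excluded from hub *calls* (their
p-values are still computed); the list is user-overridable.

## Gene-set compactness (connectivity test)

The within-group connectivity of a gene set is the number of network edges
with both endpoints in the set (an LLS-weighted variant is available but
non-default — the contract is about wiring, not weight mass). Significance
is the rank of the observed connectivity among `n_null = 10,000` random
sets in which each real gene (those present in the network) is replaced by
a gene of matching unweighted degree, within ±20% (`tolerance = 0.2`),
interval bounds rounded outward to integers. Matching is positional — one
matched gene per real gene — and sampling is without replacement within a
set: a first vectorized draw is repaired per-row by per-gene rejection
sampling, filling the most constrained degree pools first. Null sets may
overlap the real set (each real gene is always its own candidate, so the
sampler cannot dead-end on a present gene). `normalized` reports
observed / n_present so sets of different sizes are comparable across
networks. Sets with fewer than two members in the network return an
explicit `evaluable=False` result rather than a silent NaN.

Two properties of the rank test matter for interpretation. First, because
connectivity counts are integers, the test is slightly conservative: the
attainable type-I error at α = 0.05 sits just below nominal (the synthetic
calibration measures ≈ 0.02–0.05). Second, for a very compact set the
p-value saturates at its floor 1/(n_null + 1); when several sets saturate,
ranking them by observed within-group connectivity (as the acceptance
checks do) is the meaningful tie-break.

## Differential centrality (diffPR)

Percentile rank uses the min-rank convention PR = (#{strictly smaller
strengths}) / (n − 1): the most central gene scores 1, the least 0, exact
ties share the lower value, and a single-gene network scores 1 by
convention. Genes absent from a network are assigned PR 0 there; a gene
*present* but isolated gets the PR of strength 0 under min-rank — the
absent-gene override applies only outside the node set. diffPR =
PR_disease − PR_control is antisymmetric and bounded in [−1, 1] by
construction.

`find_diff_hubs` builds its null by permuting the *control* network —
degree-preserving rewiring by default, consistent with the hub test (a
node-label-shuffle alternative is exposed) — recomputing every gene's
diffPR against the observed disease network, and pooling values until
`n_null = 1,000,000` accumulate (the tests scale this to 10,000). The p is
two-sided on |diffPR| with the pseudo-count form; BH runs over genes with
nonzero observed diffPR, since zero-diffPR genes are not candidates.
`top_diff_hubs` drops zero-diffPR genes and returns the top
⌈fraction × count⌉ by |diffPR| (fraction 0.05 by default), ties broken by
gene name. Lost/gained classification gates on centrality first
(PR > 0.7 in the relevant condition) and then on |diffPR| ≥ 0.7; both
cuts default to 0.7, and `diffpr_histogram` exports the nonzero-diffPR
distribution so users can check the bimodality that motivates a threshold
in that region before trusting it on their data.

## Synthetic benchmark

The generator produces the minimal structure the statistics are designed
to detect:

- **Reference**: a planted-partition graph — 300 genes, six 20-gene
  modules, within-module edge probability 0.3 over a 0.01 background,
  Uniform(1, 3) stand-in LLS weights. Module membership is returned as
  ground truth, and the gold standard's positives are all within-module
  pairs.
- **Counts**: negative binomial with gene-specific lognormal baseline means
  (log-mean ln 2, log-sd 1 — a right-skewed mean distribution typical of
  UMI data), dispersion 0.5 (variance μ + 0.5 μ²), and independent 50%
  dropout. Three cell types × 200 cells; cell type *i* over-expresses
  module *i* at 4-fold.
- **Disease fixtures**: `plant_disease_module` adds a new 20-gene module
  (wired at 0.3 internally, 0.01 to existing genes) to a control network —
  a condition-gained functional module, the canonical diffPR detection
  target; `knockdown_counts` binomially thins chosen genes' counts for
  counts-level perturbations.

Everything is deterministic per seed. Problem sizes were chosen so the full
benchmark (10 seeds of the end-to-end recovery, 500 calibration tests,
10-seed uniformity checks) runs in well under a minute each.

What passing these tests shows: the implementation's contracts hold
(containment, monotonicity, antisymmetry, exact null properties), its
empirical p-values are calibrated, and planted signal of realistic effect
size is recovered through the whole pipeline. What they do not show: the
activity transform was *not* tuned to reproduce any published network's
size or content — real scRNA-seq carries batch effects, cell-type
ambiguity, and expression structure the NB-plus-dropout model does not
emulate, so network sizes and hub lists on real data will differ from
pipelines using other activity transforms, even at identical thresholds.

## Degenerate inputs and numerical conventions

- Empirical p-values always use the (1 + k)/(1 + N) pseudo-count form.
- All stochastic operations accept either an integer seed or a
  `numpy.random.Generator`; outputs are bit-reproducible given either.
- Writers emit deterministic row order (canonical pair, then gene name) and
  a `#` header recording version, parameters, and seed.
- Self-loops in input edge lists are dropped with a warning; duplicate
  pairs are deduplicated; nonpositive weights and malformed rows are hard
  errors naming the line.
- Empty pass-sets yield empty networks with a warning, not an error; batch
  builds never abort on a skipped stratum.

## Known limitations

- The activity transform is intentionally simple; it does not model
  batch structure or ambient RNA, and treats cells within a population as
  exchangeable.
- The pooled (non-degree-stratified) hub null makes single-gene hub calls
  conservative on networks of a few hundred nodes; hub *ranking* is
  unaffected.
- Degree matching in the compactness test uses unweighted degree; on
  networks whose weights correlate strongly with degree this is the right
  control, but a weighted-degree matching variant is not provided.
- Gene identifiers are treated as opaque case-sensitive strings; no alias
  or ID-space mapping is attempted.
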