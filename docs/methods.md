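# Methods

## Problem setting and assumptions

A multilabel training set is *incompletely labeled* when documents may be
missing true labels while carrying no wrong ones: annotation errors are
one-sided.  The package's entire design rests on three assumptions:

1. many training objects have incomplete label sets;
2. assigned labels are correct (so positives are never removed — both
   modification modes only ever weaken or flip *negatives*);
3. the compactness hypothesis: objects near each other in feature space
   tend to share categories.

Assumption 3 is what makes neighborhood-based restoration identifiable at
all; the synthetic generator (below) is built to satisfy it by
construction, so tests certify the machinery *in the regime where the
method's premise holds*, not the premise itself.

## Restoration

Both restorers operate on the exact k-nearest-neighbor cosine graph over
the training documents (directed edges `j ∈ K(i)` with weights
`ω_ij = cos(x_i, x_j)`; ties in similarity break by ascending document
index for bit-reproducibility; self-edges are excluded so a document
never votes for its own labels).

**WkNN.**  `S(d, cl)` is the weight-normalized neighbor vote.  One
published form writes the vote weight as a *distance* ρ(d, d′) used
multiplicatively, which would up-weight far neighbors; this
implementation defaults to cosine *similarity* as the weight (consistent
with the graph weights and the weighted-kNN literature) and offers
`weight="inverse-distance"` (1/(1 − cos)) as the alternative reading.
Scores are convex combinations of neighbor memberships, hence in [0, 1],
and proposals are monotone decreasing in T.

**SoftSL.**  The misalignment functional uses the standard KL divergence
`Σ_t p_t log(p_t/q_t)` in all three terms.  References `r_i` are uniform
over document i's assigned labels.  Initialization is `p = r` (labeled
rows) / uniform (unlabeled rows), which is already optimal in the μ = 0
limit.  The minimizer takes exponentiated-gradient (mirror-descent)
steps — multiply each row elementwise by `exp(−η ∇)` and renormalize —
with backtracking halving of η until the objective does not increase and
a 1.5× step-growth on success.  This makes the objective trace monotone
non-increasing *by construction* and keeps every iterate row-stochastic;
those two properties, plus convergence of |ΔC₁| below a relative
tolerance, are the optimizer's contract (the published framework's exact
two-block update equations are not printed anywhere usable, and any
monotone scheme reaching a stationary point of the same convex-in-p
objective is equivalent for the downstream thresholding).  Probabilities
are floored at `eps = 1e-10` inside logs.  Defaults: T = 0.005, ν = 0
(every training document here carries at least one label, so the
uniformity term is unnecessary), tol = 1e-6 relative, max_iter = 200.

SoftSL proposes far more pairs than WkNN at its default threshold
(T = 0.005 accepts any label holding ≥ 0.5% of a document's probability
mass), which is why its arms trade precision for recall more
aggressively — visible in any side-by-side run of the two restorers.

## Modification

*add* flips proposed pairs to positive (elementwise OR — idempotent,
monotone).  *del* materializes nothing: it produces a per-label negative
mask consumed by the trainer, so label l's binary problem has exactly
`n − |mask[l]|` instances and every other label's problem is untouched.
Modification is single-round by default; iterating restore→modify is
possible by calling the functions again but is deliberately not part of
the pipeline, as the compounding behavior of self-training is untested
here.

## Corruption simulator

Given a completely labeled matrix, each class cl loses
`round(p · positives(cl))` labels (`round(x) = floor(x + 0.5)`;
`rounding="floor"` available), drawn uniformly without replacement,
skipping any deletion that would empty a document's label set.  Classes
are visited in seeded random order.  Blocked deletions are reported as
per-class shortfalls rather than redistributed, keeping the per-class
deletion fraction as close to p as the row constraint allows.  Exact
conservation holds: positives(Y_incomplete) + |deleted| = positives(Y).

## Synthetic generator

Each of m labels owns a center: a random nonnegative unit vector.  A
document draws a primary label uniformly, then adds each of the q = 5
clusters nearest its primary (by center cosine) with probability
`co_label_rate`; its feature vector is the normalized absolute value of
the mean of its labels' centers plus isotropic N(0, spread²) noise.
Blending the centers of co-occurring labels places multi-label documents
*between* their clusters, which is exactly the geometry that makes
missing labels recoverable from neighbors.  Defaults: n = 600, m = 8,
50 features, spread = 0.15, co_label_rate = 0.6 → mean
1 + 5·0.6 = 4 labels/document, the density of real gene-function
benchmarks (the 14-class yeast set averages ~4.2).

What the generator does **not** emulate: term sparsity and burstiness of
real text, label correlations beyond geometric adjacency, class
imbalance heavier than the multinomial primary draw, and annotator bias
in which labels go missing (deletion is uniform within class).  Passing
tests therefore demonstrate correct machinery and the direction of the
restoration effect under the compactness regime, not performance claims
on any real corpus.

## Classification and tuning

Binary Relevance with either a linear large-margin base (scikit-learn's
LinearSVC; the bespoke content here is the orchestration, masking and
tuning, not the solver) or a random forest (30 trees, √features split
candidates, vote-fraction scores).  Labels with no positives yield an
always-negative scorer.  Thresholds: label assigned iff
`score_l(x) > b_l`; defaults b_l = 0 (linear) / 0.5 (forest) — the
no-tuning protocol.  The tuner varies the shared cost parameter C over a
grid (default 10^{−2..2}); for each C every b_l is scanned over
cut-points of the sorted unique dev scores (midpoints plus assign-all /
assign-none sentinels) maximizing that label's F1, ties to the smaller
b_l; the aggregate dev F1 — micro by default, per-document averaging
optionally — then selects C, ties to the smaller C.  Per-label scanning
is used because jointly optimizing coupled thresholds against micro-F1
is combinatorial; the per-label optimum is the standard, auditable
choice.

## Evaluation

Micro metrics pool TP/FP/FN over all (document, label) cells.  CROC
rescales the ROC's false-positive axis by
`x_new(x) = (1 − e^{−αx})/(1 − e^{−α})` (α = 7 default).  The AUC is
`∫ tpr d(x_new)` along the ROC polyline: tied scores move together, each
segment is linear in the *original* fpr axis, and its rescaled integral
is evaluated in closed form (`∫(a + bx)·αe^{−αx}dx`), so the diagonal
ROC of an uninformative scorer integrates exactly and CROC AUC → ROC AUC
as α → 0⁺.  Plain trapezoids between rescaled points would instead
interpolate linearly in the rescaled axis and overstate the AUC of
coarse curves.

## Experimental protocol and problem sizes

`run_experiment` holds out a test set (1/3 by default, complete labels),
corrupts the training labels at each p, carves a 20% dev split from the
corrupted training set, and grid-searches (k, T) —
k ∈ {5, 10, 15, 20}, T ∈ {0.05, 0.1, 0.15, 0.25, 0.3, 0.5} by default —
by training on train∖dev with the candidate modification and scoring
micro-F1 on dev.  Dev labels are the corrupted ones (no oracle leakage);
`dev_labels="clean"` exists for diagnosis.  During grid search the
restorer's neighbor pool is restricted to train∖dev so dev documents
never vote; the winning (k*, T*) is re-run on the full training set
before the final fit and test evaluation.  Ties prefer smaller k, then
larger T (fewer speculative additions).  The shipped experiments use
n = 600 documents, 8 labels and 50 features — large enough for stable
micro metrics and dev-set grid search, small enough that the complete
two-arm protocol runs in seconds on one core.

The recovery-rate experiment (restoration precision/recall against the
known deleted pairs, p = 0.3) uses a *sparser* instance:
co_label_rate = 0.15, spread = 0.08.  At the 4-labels/document default,
deleted positives make up ~23% of all unlabeled cells, so a 5-fold
enrichment over the random-pair baseline would require precision above
1 — no restorer can be measured against that bar.  At ~1.75
labels/document the baseline is unsaturated and WkNN (k = 10, T = 0.5)
clears the 5× bar with better than 2× margin.

## Numerical choices and degenerate inputs

- Cosine of a zero vector with anything is 0; all-zero documents survive
  normalization (with a warning) and never win votes.
- k ≥ n is clamped to n − 1 with a warning.
- BM25 idf is floored at 0 (probabilistic idf goes negative for terms in
  more than half the corpus); a document whose every term is floored
  becomes a zero vector, warned about, not dropped.
- Deletion quotas, thresholds and tie rules are all deterministic given
  the seed; the only platform-dependent component would be the linear
  solver, pinned by a fixed `random_state` per label.

## Known limitations

Restoration is transductive over the training set only — it never labels
test documents.  The graph is exact brute-force cosine, adequate for
n up to a few tens of thousands but not for web-scale corpora.  The
evaluation of restoration quality against *deleted* pairs understates
true precision whenever the "complete" reference labeling is itself
incomplete — on real data the measured precision is a lower bound.
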