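# Methods

## Model

An siRNA guide is a word `x = x_1 … x_L` over {A, C, G, U}, `L = 19` by
default (the paired region of a canonical siRNA duplex; any `L ≥ 4` is
supported so the 5-mer simulations share the code path).  For each order
`h ∈ {1, 2, 3}` a Markov chain is estimated **from effective siRNAs only**:

```
Q_h(x) = Pr(x_1 … x_h) · ∏_{j = h+1}^{L} Pr(x_j | x_{j−h} … x_{j−1})
```

The initial term is the relative frequency of the leading h-mer among the
training sequences; every conditional is the relative frequency of the base
given its h-base context **at that position** (inhomogeneous chain).  The
three probabilities combine into the *relative mean probability*

```
Q_4(x) = (Q_1 + Q_2 + Q_3) / (1[Q_1>0] + 1[Q_2>0] + 1[Q_3>0]),   Q_4 = 0 if all are 0
```

— the arithmetic mean of the non-zero chain probabilities.  The indicator
denominator exists because higher-order chains run out of observed contexts
quickly on small training sets: a zero `Q_3` should not drag down a
sequence whose `Q_1` and `Q_2` are large.  `|ln Q_4|` is exposed as an
entropy-style rarity score (undefined at `Q_4 = 0`; callers may treat that
limit as +∞).

### Why position-specific conditionals

Potent siRNAs carry *positional* nucleotide preferences (5′ terminus, seed
region, 3′ terminus), so `Pr(x_j | context)` is estimated per position `j`
rather than pooled along the sequence.  A pooled (homogeneous) variant is
available (`position_specific=False` / `--homogeneous`) for comparison.
Nothing in the estimation forces one choice; position-specific is the
package default because the quantity being modelled — positional
preference — is the biological signal of interest.

### Smoothing

Default pseudocount is **0**: a zero probability is load-bearing
information (the sequence uses an h-mer or positional transition never seen
among effective siRNAs), and the `Q_4` indicator denominator is built
around it.  With a pseudocount `p > 0`, every (context, base) cell at every
position — including contexts never observed — receives `p` extra counts,
and the initial distribution is smoothed over the full 4^h h-mer space, so
every valid sequence scores positively.  Use it only for robustness
studies; it changes the semantics of `Q_4`.

## Mini-cluster agglomeration

Distance between two sequences is the squared difference of their feature
values, `d(i, j) = (Q(i) − Q(j))²`, with `Q = Q_4` by default (`Q_1…Q_3`
selectable).  The agglomeration:

1. sort all unordered pairs ascending by (distance, smaller index, larger
   index);
2. take the first pair whose members are both unassigned; if no cluster
   exists they found cluster 1; otherwise, if either member is at least as
   close (`≤`) to some already-assigned element as to its partner, each
   member joins the cluster of its own nearest assigned element, else the
   pair founds a new cluster;
3. repeat until no both-unassigned pair remains;
4. an at-most-one leftover element joins the cluster of its nearest
   assigned element (no distance threshold — every sequence must end in a
   cluster, and there is no singleton rule).

Numerical choices, made where the procedure is genuinely underdetermined:

- **Non-strict `≤` in step 2.**  With strict `<`, duplicated feature values
  split across clusters; with `≤`, ties always cohere.  The embedded
  17-sequence worked example (three value-groups plus seven zeros → exactly
  4 clusters) is the arbiter and is reproduced exactly.
- **Index tie-breaks** in the pair order and in nearest-element lookups
  make runs deterministic.  Consequence: the partition is invariant under
  input permutation for value sets in *generic position*; if two distinct
  pairs have exactly equal positive distances, the outcome can depend on
  input order.  Duplicate values are always safe (tie cohesion).
- Pairs with exactly one assigned member are skipped; their unassigned
  member is picked up by step 2's closer-to-cluster branch or the leftover
  rule.

**Labelling.**  A cluster is *effective* if any member carries a known
effective label, *ineffective* if its known members are all ineffective,
*uncertain* if it has no known member.  Each uncertain cluster is merged
into the nearest determined cluster under single linkage (minimum pairwise
squared difference over cross members) and adopts its label; determined
clusters are never relabelled; distances are measured against the
determined clusters' original members, so merges are decided independently
of each other.  An exact tie between an effective and an ineffective
cluster resolves toward the effective one — the method is deliberately
sensitivity-first (a candidate shortlist should not drop real hits).  If
uncertain clusters exist but no determined one, the error tells the caller
that no training label reached any cluster.

## Classification and evaluation

`MiniClusterClassifier` is transductive: `fit` stores the labelled training
sequences and estimates the three chains from the effective ones;
`predict` profiles training + query sequences together, clusters, labels,
merges, and reads each query's label off its cluster.  Predictions
therefore depend on the composition of the query batch — by design.

`evaluate` reports two "specificity" flavours: the conventional true-
negative rate TN/(TN+FP), and the precision-style TP/(TP+FP) — the fraction
of the predicted-effective shortlist that is truly effective, reported next
to the shortlist size ("Total").  The headline metric of this problem
domain is the precision flavour.  Reported percentages round half-up to 2
decimals.

**Resampling protocol.**  Repeated holdout: each repeat draws
`⌊0.8 · n_eff⌋` effective sequences without replacement to train the chains
and provide known effective labels; held-out effectives are classified and
miscalls averaged across repeats (default 1000).  Ineffective sequences
keep their known labels during these runs (switchable): without them no
cluster could ever be labelled ineffective and the false-positive rate
would be undefined.

**1-D k-means baseline.**  Optimal SSE clusters of scalar data are
contiguous in sorted order, so the baseline uses exact dynamic programming
over split points rather than a randomly initialised heuristic — it is
deterministic and globally optimal, and on the worked example it reproduces
the known failure mode: the quadratic objective splits off only the three
largest values, co-clustering 7 structured sequences with the unstructured
group.

## Synthetic data

The generators emulate the study's simulation conditions and are
first-class, tested code:

- **group X** (`generate_group_x`): 5-mers from the inhomogeneous order-1
  chain — position 1: U 0.75 / C 0.25; position 2: Pr(A|U)=0.75,
  Pr(U|U)=0.25, Pr(G|C)=1; positions 3–5 uniform.
- **group Y** (`generate_group_y`): 5-mers uniform over the 4⁵ space minus
  the two forbidden (position-1, position-5) combinations (U…A, C…G), by
  rejection sampling; the admissible space has 4⁵ − 2·4³ = 896 words
  (acceptance rate 7/8).
- **random siRNAs** (`generate_random_sirnas`): uniform i.i.d. 19-mers.
- **labelled pool** (`generate_labeled_pool`): benchmark harness for the
  resampling protocol.  Effectives come from an order-1 chain that puts
  probability `bias` (default 0.85 — strong but not degenerate) on one
  preferred base at each signal position (defaults 1, 2, 10 and the last,
  mimicking reported 5′/seed/3′ preferences); ineffectives are uniform.
  Efficiency percentages consistent with the 80% threshold are attached.

What the synthetic data does **not** emulate: real efficacy screens have
correlated measurement noise, near-threshold ambiguity (miscalled
sequences cluster just under the efficacy cutoff), batch effects across
source publications, and thermodynamic/structural covariates the sequence
alphabet alone does not encode.  Passing the simulation-based suites shows
the machinery is correct under the stated generative conditions, not that
the reported real-screen error rates transfer to new screens.

## Problem sizes used in the test suite

The suites run the worked example (17 sequences) exactly; property checks
use 500 random instances at n ≤ 16 against an independently coded naive
agglomerator (n ≤ 10); parameter recovery uses 10 000 simulated 5-mers
(±0.02 tolerance on the chain parameters); the resampling-beats-shuffled-
null check uses an 80 + 80 pool of 13-mers at 50 repeats.  These sizes are
the package's chosen validation scale; all scale linearly upward.

## Known limitations

- The agglomeration is O(n² log n) in memory and time (all pairs are
  sorted); fine for thousands of sequences, not for millions.
- Transductive predictions change with the query batch; for a fixed
  decision function use the fitted chains' `Q_4` directly.
- Order-h models with h > 3, and interpolated/backoff smoothing, are out of
  scope.
- With a 0 pseudocount, held-out sequences often score `Q_4 = 0` on small
  training sets; the zero-value cluster then inherits whatever label its
  known members give it, which is the dominant error mode of the
  resampling protocol at small n.
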