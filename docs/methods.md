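# Methods

This note documents the models and procedures `vireosyntax` implements, the
conventions chosen where the analysis design was genuinely open, what the
synthetic ground truth does and does not emulate, and the known limitations.

## Data model

A *recording* is an ordered list of timed phrases, each a label from the
individual's repertoire; a *corpus* is one individual's recordings in
chronological order (recording timestamps from the metadata table, falling
back to filename order). Transitions, N-grams and recurrence intervals are
always counted **within** recordings: the silence between files is
unobserved, so a context total `n_i·` can be slightly below the unigram
count `n_i` when type *i* ends a recording.

Filtering discards recordings with fewer than 50 phrases (too little
sequence context to constrain transition estimates).

The **train-test split** concatenates the recordings chronologically and
finds the phrase at position `ceil(total/2)` (1-based); the recording
containing it, and all earlier recordings, form the training set. Any fixed
midpoint convention works; this one is documented so results are exactly
reproducible. When the midpoint falls in the final recording the testing
set would be empty; the final recording is then moved to the testing side,
with a warning. LOOCV folds hold out one recording each.

## Models and likelihood

Count models of order k ∈ {0,1,2,3} are maximum-likelihood conditional
tables over sparse contexts (order 3 exists only to feed the dependency
screens). Held-out fit is the average per-phrase negative log-likelihood
(natural log), with the first two phrases of every recording excluded so
that all orders score identical positions.

**Smoothing.** Witten–Bell discounting with Katz-style backoff. For a
context with N observations and T distinct continuations, observed
probabilities become `count/(N+T)` and the reserved `T/(N+T)` is spread
over the unseen continuations proportionally to the next-shorter context's
smoothed distribution, normalized over the unseen set — this normalizer is
the standard construction that guarantees each context sums to one; the
chain terminates in a uniform distribution over the vocabulary. Two
conventions the discount rule does not fix:

- a context that has produced every vocabulary type keeps its MLE (no
  unseen set, so the redistribution factor is undefined);
- held-out data may contain types unseen in training; models are therefore
  built over the train∪test union vocabulary, and the uniform terminal
  keeps every in-union type strictly positive.

A context shorter than the model order enters the backoff chain at the
level matching its length.

**Forward selection.** Starting from the zero-order model, candidate states
(unincluded first-order states; unincluded second-order states whose
first-order parent is included) are added greedily by largest reduction in
*smoothed* training NLL; smoothed candidate scoring is used because
unsmoothed scoring would reward states that assign zero probability to
held-in events. Dispatch is deepest-match: a context ending in a selected
pair uses that second-order state, else the ultimate type's first-order
state if selected, else the zero-order fallback. Because a position's score
depends only on the deepest selected state for its own context, every
candidate's gain is a fixed sum over the positions it governs; selection
runs on a priority queue over these static gains (linear in corpus size).
Ties break lexicographically on the state's labels. The returned model is
the trace point with minimum testing NLL.

One consequence of smoothed candidate scoring: once all positive-gain
states are exhausted, the remaining forced additions (the procedure runs
until every observed second-order state is in) have slightly negative
training gains, so the training-NLL trace is non-increasing up to — and in
practice far beyond — the selected step, but can rise in the terminal tail.

Under LOOCV the interpolated model's **state set is fixed** from the
train-test selection and only its probabilities are re-estimated per fold;
re-selecting per fold would leak the held-out file into selection.

## Simulation and model assessment

Simulations are drawn from unsmoothed fits, matching the template corpus in
file structure, per-recording length, initial k phrases and timing. A
running context observed only at a recording end has no outgoing counts;
the simulator then backs off to the next-shorter context's MLE (down to
order 0), so simulations never halt. Replicates use independent child
streams spawned from one master seed.

Model adequacy compares simulations to the held-out testing set by L1
distance over N-gram (N = 1..7) and recurrence-interval distributions
(recurrence = intervening phrases between *consecutive* occurrences of a
type; adjacent repeat = 0). Two summaries are reported per model:

- `mean_L1`: the mean over replicates of L1(simulation, test). Each
  replicate carries its own sequence-sampling noise, which is a strictly
  positive offset over the train-vs-test baseline for **every** model,
  including the generating one — a paired t-test on this statistic rejects
  everything at every N.
- `pooled_L1`: L1 between the replicate-averaged simulated distribution
  and the testing set. Averaging the distributions first cancels the
  replicate noise and leaves the comparison between the model's N-gram law
  and the data, which is the comparison a model-adequacy figure needs.
  Significance tests (one-tailed paired t across individuals, alternative
  "simulation exceeds baseline") therefore default to `pooled_L1`.

Under `pooled_L1` the expected pattern emerges cleanly on synthetic truth:
all models adequate at N = 1; the zero-order model diverging from N = 2;
the first-order model from N = 3; the matched (second-order) model and
recurrence intervals clean throughout.

## Dependency screens

For each phrase type (order 2) or observed bigram (order 3), the two
best-sampled extended contexts (ties broken lexicographically) are compared
in a 2×C table over the union of their observed continuations. The exact
engine computes the Fisher–Freeman–Halton two-sided p-value by depth-first
enumeration of the multivariate hypergeometric law with feasibility
pruning; it defers to a chi-square test of independence when the table
exceeds the work bounds (total > 500, C > 12, or 2×10⁶ visited nodes —
the result records which engine ran). Bonferroni control is per individual
and order: threshold 0.05/n over the n comparisons performed. Null
calibration simulates the corpus once from a model one order below the
screen, fitted to the complete corpus.

## Predictability

Each model predicts its conditional mode (ties to the lexicographically
first label), scored over the same positions as the likelihood. The
disagreement analysis restricts scoring to positions where the models'
predictions are not unanimous. Rate stratification bins each scored
position by the *silent gap* (previous phrase end to current start;
onset-to-onset is available as an option) with default one-second bins up
to 10 s and an open final bin; non-positive gaps clamp into the first bin.

## Time homogeneity

An unsmoothed second-order model is fitted on the entire corpus, the corpus
is simulated whole `n_sims = 100` times, each simulate is split by the same
recording assignment as the real train-test split, and the observed
train/test L1 at each N is z-scored against the replicate distribution.
Across individuals a one-sample t-test per N (one-sided, alternative mean
z > 0, since inhomogeneity inflates the observed divergence) gives the
population-level verdict.

A caution discovered while validating the procedure: it is intrinsically
anti-conservative at large N whenever the truth has a thin tail of
low-probability transitions. The fitted model's N-gram law is then
under-dispersed relative to the truth (unseen transitions are zeroed and
estimated probabilities are jittered, both of which shrink the law's
support-richness functional), the simulated L1 distribution sits low, and
z-scores acquire a positive bias that does **not** vanish with corpus size
— the thin tail keeps supplying new under-represented N-grams at every
scale, and even a fitted model's own count-1 transitions reproduce the
effect one level down. The null-calibration checks therefore generate
their null corpora from a fitted second-order model pruned to transitions
observed at least 15 times — a generating process whose every transition
probability is well resolved at the corpus size, under which the z-scores
are well centred (the residual bias of an unpruned fitted null scales
roughly as the reciprocal of its typical transition count). Positive
results at N ≥ 4 on real-scale data should be interpreted with this bias
in mind.

## Synthetic ground truth

The generator emulates the study's statistical shape: ~14 individuals;
repertoires of 44–60 two-letter codes from a 126-type population inventory
(observed coverage, not nominal size, is what the range constrains);
4–34 recordings per individual with per-individual totals ~1.3k–10k
phrases (lognormal, mean ≈ 4k); phrase durations lognormal around 0.8 s
and silent gaps a short/long mixture giving a modal inter-onset interval
near 2 s with a long right tail.

Transition structure: the repertoire is partitioned into clusters of 4;
each conditional lives on a small within-cluster support with a single
dominant successor (top transition ≥ 0.7 before floors — matching the
strong determinism real phrase sequences show), a floored "ring" edge that
guarantees every cluster member inflow, and a small bridge linking clusters
into a ring; this yields the low recurrence intervals characteristic of the
species. 8% of types are zero-order (successor drawn from a shared
fallback, which carries a quarter of its mass on exactly these types so
they stay expressed), 40% are second-order: their two conditionals put
≥ 60% of their mass on disjoint halves of the cluster, switched by the
penultimate type's parity group, so the planted L1 separation (≥ the
`separation` parameter, 0.5 by default; ≈ 1.2 realized) is guaranteed by
construction and dependency screens and forward selection have a detectable
signal of known location. The truth record retains every type's order class
and separation.

Time inhomogeneity can be planted via `drift`: the chronologically later
half of each corpus is generated from a blend of the individual's model
with an independent same-repertoire alternative (`drift = 1` is a wholesale
switch). A `reset_gap` option makes long silent gaps restart the context
from the fallback — the mechanism behind rate-dependent predictability —
and is **off** by default so that the default truth is exactly the labelled
mixed-order Markov process, the property the recovery and null-calibration
checks rely on.

What the generator does not emulate: acoustic variation and annotation
error; bout structure and diurnal rhythm; social context (counter-singing,
song matching); gradual within-season drift (only blended/switched halves);
repeat-distribution idiosyncrasies beyond what a second-order process
captures. Passing tests therefore certify the statistical machinery against
a controlled truth, not the field realism of any particular biological
conclusion.

## Problem sizes in the test suite

The suite validates at desk scale, chosen so each check has the power it
needs: state recovery on ~5×10⁴ training phrases; dependency type-I/power
on 2×10⁴-phrase corpora (20 replicates); model assessment on 14-individual
studies with 100 simulation replicates; homogeneity null calibration on 20
replicate studies of 14 individuals (10 recordings × 1000 phrases, 100
simulations each — large enough corpora that the fitted second-order null
is estimated without support starvation). The exact Fisher engine is
checked to 10⁻¹² against rational-arithmetic enumeration, and the
smoothing chain to 10⁻¹² against an independently coded calculator over an
enumeration of small three-type corpora.

## Known limitations

- The exact 2×C engine enumerates; genuinely large sparse tables fall back
  to chi-square (recorded per result). No mid-p or network-algorithm
  optimizations.
- The homogeneity z-score inherits the anti-conservativeness described
  above; it is a diagnostic, not a calibrated hypothesis test, when the
  generating process has heavy-tailed transition structure.
- Forward selection is greedy; it returns a good mixed-order model, not a
  global optimum over state subsets.
- TextGrid support covers Praat's long and short text formats (UTF-8/16),
  interval tiers only; point tiers are skipped.
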