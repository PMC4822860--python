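# vireosyntax

Variable-order Markov analysis of birdsong phrase syntax.

Many songbirds deliver discrete, stereotyped phrases in long sequences whose
ordering follows probabilistic rules ("syntax"). `vireosyntax` is a toolkit
for asking how complex those rules are, built around the kind of data a field
study of Cassin's Vireo-like singers produces: per-recording sequences of
phrase-type labels (two-letter codes annotated in Praat TextGrids), tens of
recordings per individual, repertoires of roughly 44–60 types.

It fits and compares four candidate models of the next-phrase distribution:

- **zero-order** — `P(x) = n_x / N`: phrase frequency only;
- **first-order** — `P(j | i) = n_ij / n_i·`: conditioned on the last phrase;
- **second-order** — `P(k | ij) = n_ijk / n_ij·`: on the last two phrases;
- **interpolated** — a mixed-order model built by greedy forward selection:
  first- and second-order context states are added one at a time (each step
  taking the state with the greatest reduction in training negative
  log-likelihood, a second-order state `(i, j)` admissible only once its
  first-order parent `j` is in), and the model at the minimum held-out NLL
  along that path is kept.

Around the model comparison it implements the full supporting analysis:

- **Witten–Bell discounting with Katz-style backoff** — each context's
  probabilities are deflated by `N/(N+T)` and the reserved `T/(N+T)` is
  spread over unseen continuations in proportion to the next-shorter
  context's distribution, so held-out likelihoods are always finite;
- **sequence simulation** from unsmoothed fits (matching a template corpus's
  file structure, lengths and initial phrases), with model adequacy measured
  by the L1 distance `Σ|x_i − y_i|` between N-gram (N = 1..7) and
  recurrence-interval distributions of simulations and a held-out testing
  set;
- **Fisher's exact screens** (exact 2×C, chi-square fallback) for second- and
  third-order dependencies, with per-individual Bonferroni control and
  simulation-based null calibration;
- **next-phrase predictability**, overall, restricted to positions where the
  models disagree, and stratified by the silent interval before the phrase;
- a **time-homogeneity test**: z-scores of the observed train/test N-gram
  divergence against 100 corpora simulated from a second-order model fitted
  to the entire corpus;
- a **synthetic-data generator** that emulates the study's statistical shape
  with a known mixed-order ground truth (planted, L1-separated second-order
  contrasts; optional drifted or switched late halves), so every stage can
  be validated against a truth record.

## A worked example

Generate one synthetic individual, split it chronologically, and compare
models (statsmodels-style model/results objects):

```python
from vireosyntax import MarkovModel, InterpolatedMarkov, evaluate_all, train_test_split
from vireosyntax.synthetic import GroundTruthSpec, generate_study

corpora, truths = generate_study(GroundTruthSpec(seed=7), n_individuals=1)
corpus = corpora["SYN01"]
train, test = train_test_split(corpus).apply(corpus)

res1 = MarkovModel(train, 1, vocabulary=train.vocabulary | test.vocabulary).fit()
print(res1.summary())
print(f"held-out NLL/phrase: {res1.nll(test):.3f}   accuracy: {res1.accuracy(test):.1f}%")
```

```
Order-1 Markov model — individual 'SYN01'
  recordings:   17   phrases: 1366
  repertoire:   44   observed contexts: 44
  transitions counted: 1349
held-out NLL/phrase: 1.023   accuracy: 73.7%
```

An average held-out NLL of 1.02 nats/phrase means the model assigns the
observed next phrase a typical probability of `exp(−1.02) ≈ 0.36`, against
`1/44 ≈ 0.02` for a blind guess; 73.7% of phrases are exactly the model's
top prediction.

```python
interp = InterpolatedMarkov(train, test).fit()
print(interp.summary())
print(evaluate_all(corpus).round(2).to_string(index=False))
```

```
Interpolated (mixed-order) Markov model
  states: 112 (first-order 44, second-order 67, + zero-order fallback)
  repertoire shares — zero: 12%  first: 24%  second: 64%
  selection: step 111 of 168; test NLL/phrase 1.000 (zero-order start 3.390)

individual     method  sample_size   L0   L1   L2  LInt    P0    P1    P2  PInt
     SYN01 train-test         1366 3.39 1.02 1.02  1.00 11.86 73.65 75.73 76.04
     SYN01      LOOCV         2614 3.38 0.79 0.78  0.85  4.18 78.17 79.51 78.48
```

The L columns are per-phrase NLLs (lower = better fit) under the zero-,
first-, second-order and interpolated models; the P columns are percent
prediction accuracies. Here the interpolated model — 112 states, between the
45 of the first-order model and the several hundred of the second-order
model — fits the held-out data best under the train-test paradigm, the
signature of syntax intermediate between first- and second-order.

The whole pipeline (ingest → filter → split → assess → dependency screens →
model comparison → prediction → homogeneity) also runs from a single YAML
config:

```sh
vireosyntax run --config run.yaml
```

with a config like

```yaml
corpus: study/metadata.csv   # or `synthetic: {n_individuals: 14}`
out_dir: results/run1
assess_reps: 1000
homogeneity_reps: 100
seed: 7
```

producing Table-style CSVs (model comparison, dependency-screen summary,
assessment L1 table with significance, rate-stratified accuracy,
homogeneity z-scores) plus a manifest recording the seeds, so a rerun with
the same config is byte-identical.

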