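"""Simulation-based test of time homogeneity of the syntax.

A Markov model assumes transition probabilities constant over the recording
period.  The test asks whether the observed divergence between a bird's
(chronologically early) training set and (late) testing set exceeds what
finite sampling alone produces under a time-homogeneous process: an
unsmoothed second-order model is fitted on the ENTIRE corpus, the corpus is
simulated whole ``n_sims`` times (same file structure, lengths and initial
states), each simulate is split into simulated-train/test by the SAME
recording assignment as the real split, and the observed train-vs-test L1
distance for each N-gram size is z-scored against the replicate
distribution.  Across individuals, a one-sample t-test per N (alternative:
mean z > 0, since inhomogeneity inflates the observed divergence) gives the
population-level verdict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus, SplitSpec
from .markov import fit_counts
from .ngrams import N_RANGE, _CodedCorpus, _l1_tables, _shared_index
from .simulate import replicate_simulations


def homogeneity_test(
    corpus: Corpus,
    split: SplitSpec,
    n_sims: int = 100,
    seed: int = 0,
    n_values=N_RANGE,
) -> pd.DataFrame:
    """Per-N z-scores of observed train/test L1 against the homogeneous null.

    Columns: N, observed_l1, sim_mean, sim_sd, z.  Raises if the replicate
    L1 distances are degenerate (zero standard deviation), which signals the
    corpus is too small to calibrate the null.
    """
    n_values = list(n_values)
    model = fit_counts(corpus, 2)
    index = _shared_index(corpus)

    def split_l1(c: Corpus) -> dict[int, float]:
        train, test = split.apply(c)
        ctrain, ctest = _CodedCorpus(train, index), _CodedCorpus(test, index)
        return {
            n: _l1_tables(ctrain.ngram_table(n), ctest.ngram_table(n))
            for n in n_values
        }

    observed = split_l1(corpus)
    sim_l1 = {n: [] for n in n_values}
    for sim in replicate_simulations(model, corpus, n_sims, seed):
        for n, val in split_l1(sim).items():
            sim_l1[n].append(val)
    rows = []
    for n in n_values:
        arr = np.asarray(sim_l1[n])
        sd = arr.std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"replicate L1 distances at N={n} show no variability; "
                "corpus too small or degenerate for null calibration"
            )
        rows.append(
            {
                "N": n,
                "observed_l1": observed[n],
                "sim_mean": arr.mean(),
                "sim_sd": sd,
                "z": (observed[n] - arr.mean()) / sd,
            }
        )
    return pd.DataFrame(rows)


def homogeneity_summary(per_individual: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-individual one-sample t-test of the z-scores against 0, per N.

    Columns: N, mean_z, t, p, n_individuals; ``p`` is one-sided (greater).
    """
    big = pd.concat(per_individual, ignore_index=True)
    rows = []
    for n, grp in big.groupby("N", sort=True):
        t, p = stats.ttest_1samp(grp["z"], 0.0, alternative="greater")
        rows.append(
            {
                "N": n,
                "mean_z": grp["z"].mean(),
                "t": float(t),
                "p": float(p),
                "n_individuals": len(grp),
            }
        )
    return pd.DataFrame(rows)
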