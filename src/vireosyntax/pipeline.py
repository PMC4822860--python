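"""End-to-end analysis pipeline driven by a single configuration.

Stages: ingest (TextGrids + metadata, or a generated synthetic study) →
short-recording filter → chronological train/test split → simulation-based
model assessment (N-gram / recurrence L1) → dependency screens with null
calibration → likelihood model comparison incl. forward selection →
rate-stratified prediction → time-homogeneity test.  Every stochastic stage
draws a named child stream from one master seed, so a config reruns to
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import filter_short_recordings, load_corpora, train_test_split
from .dependencies import higher_order_tests, null_calibration, summarize_tests
from .homogeneity import homogeneity_summary, homogeneity_test
from .ngrams import assessment_significance, simulate_and_assess
from .prediction import rate_stratified_accuracy
from .selection import evaluate_all, forward_selection
from .synthetic import GroundTruthSpec, generate_study

log = logging.getLogger("vireosyntax")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "results"
    corpus: str | None = None  # metadata CSV of a TextGrid corpus
    synthetic: dict | None = None  # GroundTruthSpec overrides (+ n_individuals)
    tier: str = "phrases"
    min_phrases: int = 50
    n_max: int = 7
    assess_reps: int = 1000
    homogeneity_reps: int = 100
    paradigms: tuple[str, ...] = ("train-test", "loocv")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_max <= 7:
            raise ValueError("n_max must be in 1..7")
        if self.assess_reps < 1 or self.homogeneity_reps < 1:
            raise ValueError("simulation reps must be >= 1")
        if self.corpus is None and self.synthetic is None:
            raise ValueError("config needs either 'corpus' or 'synthetic'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "paradigms" in doc:
            doc["paradigms"] = tuple(doc["paradigms"])
        return cls(**doc)


def _child_seed(master: int, stage: str, index: int = 0) -> int:
    # zlib.crc32 is stable across processes (unlike hash()), keeping reruns
    # byte-identical
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    ss = np.random.SeedSequence([master, tag, index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            **dataclasses.asdict(config),
            "paradigms": list(config.paradigms),
        },
        "stages": {},
    }

    # -- ingest -------------------------------------------------------------
    if config.corpus is not None:
        corpora = load_corpora(config.corpus, config.tier)
        log.info("loaded %d individuals from %s", len(corpora), config.corpus)
    else:
        syn = dict(config.synthetic or {})
        n_individuals = syn.pop("n_individuals", 14)
        spec = GroundTruthSpec(**{**syn, "seed": syn.get("seed", config.seed)})
        corpora, _truths = generate_study(spec, n_individuals=n_individuals)
        log.info("generated synthetic study: %d individuals", len(corpora))
    manifest["stages"]["ingest"] = {
        ind: {"recordings": len(c), "phrases": c.n_phrases}
        for ind, c in corpora.items()
    }

    # -- filter -------------------------------------------------------------
    corpora = {
        ind: filter_short_recordings(c, config.min_phrases)
        for ind, c in corpora.items()
    }
    corpora = {ind: c for ind, c in corpora.items() if len(c) >= 2}
    manifest["stages"]["filter"] = {
        ind: {"recordings": len(c), "phrases": c.n_phrases}
        for ind, c in corpora.items()
    }
    log.info("after filtering: %d analysable individuals", len(corpora))

    n_values = range(1, config.n_max + 1)
    assess_tables = []
    dep_results: dict = {}
    eval_rows = []
    rate_tables = []
    homog_tables = []
    for i, (ind, corpus) in enumerate(sorted(corpora.items())):
        split = train_test_split(corpus)
        train, test = split.apply(corpus)
        log.info(
            "%s: %d train / %d test recordings", ind, len(split.train), len(split.test)
        )

        tab = simulate_and_assess(
            train,
            test,
            n_reps=config.assess_reps,
            seed=_child_seed(config.seed, "assess", i),
            n_values=n_values,
        )
        tab.insert(0, "individual", ind)
        assess_tables.append(tab)

        dep_results[ind] = {
            order: higher_order_tests(corpus, order) for order in (2, 3)
        }
        dep_results[f"{ind}:null"] = {
            order: null_calibration(
                corpus, order, seed=_child_seed(config.seed, "depnull", i)
            )
            for order in (2, 3)
        }

        table2 = evaluate_all(corpus, split, loocv="loocv" in config.paradigms)
        eval_rows.append(table2)

        interp, _ = forward_selection(train, test)
        rate = rate_stratified_accuracy(interp, test)
        rate.insert(0, "individual", ind)
        rate_tables.append(rate)

        hom = homogeneity_test(
            corpus,
            split,
            n_sims=config.homogeneity_reps,
            seed=_child_seed(config.seed, "homogeneity", i),
            n_values=n_values,
        )
        hom.insert(0, "individual", ind)
        homog_tables.append(hom)

    # -- report bundle ------------------------------------------------------
    pd.concat(assess_tables, ignore_index=True).to_csv(
        out / "assessment.csv", index=False
    )
    assessment_significance(assess_tables).to_csv(
        out / "assessment_significance.csv", index=False
    )
    summarize_tests(dep_results).to_csv(out / "dependency_tests.csv", index=False)
    pd.concat(eval_rows, ignore_index=True).to_csv(
        out / "model_comparison.csv", index=False
    )
    pd.concat(rate_tables, ignore_index=True).to_csv(
        out / "rate_accuracy.csv", index=False
    )
    homog = pd.concat(homog_tables, ignore_index=True)
    homog.to_csv(out / "homogeneity.csv", index=False)
    homogeneity_summary(homog_tables).to_csv(
        out / "homogeneity_summary.csv", index=False
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("report bundle written to %s", out)
    return manifest
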