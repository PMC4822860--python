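"""Ground-truth corpus generator with known mixed-order syntax.

Emulates the statistical shape of a wild-vireo song study — around 14
individuals, per-individual repertoires of ~44–60 two-letter phrase-type
codes drawn from a 126-type population inventory, a handful to a few dozen
recordings of 50–10000 phrases each, a modal inter-onset interval near 2 s
with a long right tail, sparse transition structure, and recurrence
intervals biased low — while retaining the generating model and the true
order class of every phrase type, so that estimation, selection, dependency
screens and homogeneity tests can be scored against a known truth.

Mechanics: the repertoire is partitioned into small "neighbourhood" clusters
and each conditional keeps most of its mass inside the current cluster (with
an occasional bridge to the next), which yields the low recurrence intervals
real birds show.  Phrase types are assigned an order class: *zero-order*
types hand the choice of successor to a shared fallback distribution;
*first-order* types carry their own sparse conditional; *second-order* types
carry two conditionals with guaranteed L1 separation, switched by the
penultimate phrase's group, planting a detectable non-adjacent dependency of
known effect size.  Optionally, sufficiently long silent gaps reset the
context (the next phrase is drawn from the fallback), which ties prediction
accuracy to song rate the way field data behave.
"""

from __future__ import annotations

import itertools
import json
import math
import string
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .corpus import Corpus, PhraseEvent, Recording, write_metadata, write_textgrid

#: the population-wide inventory of two-letter phrase-type codes
POPULATION_INVENTORY: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.islice(
        itertools.product(string.ascii_lowercase, repeat=2), 126
    )
)

ROLE_ZERO, ROLE_FIRST, ROLE_SECOND = "zero", "first", "second"


@dataclass
class GroundTruthSpec:
    """Parameters of the generative truth.

    The order-class fractions default to the structure a mixed-order fit
    typically recovers from this kind of corpus (roughly 8% zero-order,
    40% second-order, the remainder first-order); ``separation`` is the
    guaranteed minimum L1 distance between the conditionals planted for a
    second-order type, i.e. the effect size the dependency screens and
    forward selection are asked to detect.
    """

    repertoire_size: int = 50
    frac_second_order: float = 0.40
    frac_zero_order: float = 0.08
    sparsity: int = 2  # mean out-degree of a conditional
    concentration: float = 0.15  # Dirichlet alpha of conditionals; lower = peakier
    ring_mass: float = 0.05  # floor on each type's within-cluster ring edge
    cluster_size: int = 4
    bridge_mass: float = 0.04  # probability of stepping to the next cluster
    separation: float = 0.5  # min L1 between planted second-order variants
    mean_duration: float = 0.8  # s, lognormal phrase duration median
    short_gap: float = 1.2  # s, modal silent gap (inter-onset ~ 2 s)
    long_gap: float = 12.0  # s, long-tail gap component median
    long_gap_prob: float = 0.10
    # Optional realism knob: silent gaps longer than this restart the phrase
    # context from the fallback distribution, coupling predictability to song
    # rate.  Off by default so that the generated process is *exactly* the
    # labelled mixed-order Markov model — the property the recovery and
    # null-calibration checks rely on.
    reset_gap: float | None = None
    recording_lengths: tuple[int, ...] | None = None  # None: draw study-like
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repertoire_size < 2:
            raise ValueError("repertoire_size must be >= 2")
        fz, fs = self.frac_zero_order, self.frac_second_order
        if not (0 <= fz <= 1 and 0 <= fs <= 1 and fz + fs <= 1):
            raise ValueError("order-class fractions must be in [0,1] and sum <= 1")
        if self.sparsity < 1 or self.sparsity > self.repertoire_size:
            raise ValueError("sparsity must be in 1..repertoire_size")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")


def _dirichlet(rng: np.random.Generator, keys: list[str], alpha: float = 1.0):
    w = rng.dirichlet(np.full(len(keys), alpha))
    return dict(zip(keys, w.tolist()))


def _mix(base: dict, extra: dict, w: float) -> dict:
    out = {k: (1 - w) * v for k, v in base.items()}
    for k, v in extra.items():
        out[k] = out.get(k, 0.0) + w * v
    return out


def _combine(*parts: tuple[dict, float]) -> dict:
    """Weighted sum of distributions; the weights must sum to 1."""
    out: dict = {}
    for dist, w in parts:
        for k, v in dist.items():
            out[k] = out.get(k, 0.0) + w * v
    return out


def _l1(d1: dict, d2: dict) -> float:
    keys = set(d1) | set(d2)
    return sum(abs(d1.get(k, 0.0) - d2.get(k, 0.0)) for k in keys)


class GroundTruthModel:
    """A labelled second-order generator with known per-type order classes."""

    order = 2

    def __init__(self, spec: GroundTruthSpec, seed=None, labels: list[str] | None = None):
        self.spec = spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        c = spec.repertoire_size
        if labels is None:
            picks = sorted(
                rng.choice(len(POPULATION_INVENTORY), size=c, replace=False).tolist()
            )
            self.labels = [POPULATION_INVENTORY[i] for i in picks]
        else:
            if len(labels) != c:
                raise ValueError("labels must match repertoire_size")
            self.labels = list(labels)
        self.clusters: list[list[str]] = [
            self.labels[i : i + spec.cluster_size]
            for i in range(0, c, spec.cluster_size)
        ]
        self._cluster_of = {
            lab: ci for ci, cl in enumerate(self.clusters) for lab in cl
        }
        # order-class assignment
        n_second = round(spec.frac_second_order * c)
        n_zero = round(spec.frac_zero_order * c)
        perm = rng.permutation(c)
        self.role = {}
        for rank, idx in enumerate(perm):
            lab = self.labels[idx]
            self.role[lab] = (
                ROLE_SECOND
                if rank < n_second
                else ROLE_ZERO
                if rank < n_second + n_zero
                else ROLE_FIRST
            )
        # penultimate-group mapping: index parity, so both groups are common
        self.group = {lab: i % 2 for i, lab in enumerate(self.labels)}
        # shared fallback over the whole repertoire; a quarter of its mass is
        # spread over the zero-order types (their only structured inflow), so
        # every type is expressed in study-sized corpora
        base_fb = _dirichlet(rng, self.labels, alpha=0.8)
        zero_types = sorted(
            lab for lab, role in self.role.items() if role == ROLE_ZERO
        )
        boost_set = zero_types if zero_types else self.labels
        self.fallback = _mix(
            base_fb, {lab: 1.0 / len(boost_set) for lab in boost_set}, 0.25
        )
        # conditionals
        self.conditionals: dict[str, dict[str, float]] = {}
        self.variants: dict[str, tuple[dict, dict]] = {}
        self.planted_separation: dict[str, float] = {}
        self._cdf_cache: dict[int, tuple[list[str], np.ndarray]] = {}
        # Each conditional lives on a small within-cluster support with a
        # single dominant successor (top transition >= 0.7 before floors) —
        # the strong determinism real phrase sequences show — plus a floored
        # "ring" edge that guarantees every cluster member some inflow, and a
        # small bridge linking the clusters into a ring.  Second-order types
        # get two variants whose extra mass sits on disjoint halves of the
        # cluster, so their L1 separation is guaranteed by construction.
        w_sep = max(0.60, spec.separation / 2)  # disjoint-variant share
        if w_sep > 0.80:
            raise ValueError("separation too large to embed in the conditionals")
        for lab in self.labels:
            if self.role[lab] == ROLE_ZERO:
                continue
            ci = self._cluster_of[lab]
            cl = self.clusters[ci]
            nxt_cluster = self.clusters[(ci + 1) % len(self.clusters)]
            ring = cl[(cl.index(lab) + 1) % len(cl)]
            bridge = {nxt_cluster[0]: 1.0}
            k = min(spec.sparsity, len(cl))
            support = sorted(
                set(rng.choice(cl, size=k, replace=False).tolist()) | {ring}
            )
            while True:
                inside = _dirichlet(rng, support, alpha=spec.concentration)
                if len(support) == 1 or max(inside.values()) >= 0.7:
                    break
            if self.role[lab] == ROLE_FIRST:
                self.conditionals[lab] = _combine(
                    (inside, 0.96 - spec.ring_mass - spec.bridge_mass),
                    ({ring: 1.0}, spec.ring_mass + 0.04),
                    (bridge, spec.bridge_mass),
                )
            else:  # second-order: two variants with guaranteed L1 separation
                others = [x for x in cl if x != lab]
                if len(others) < 2:  # tail cluster: borrow from the next one
                    others += [x for x in nxt_cluster if x != lab][:2]
                half = max(1, len(others) // 2)
                perm2 = rng.permutation(len(others))
                sa = sorted(others[i] for i in perm2[:half])
                sb = sorted(others[i] for i in perm2[half:]) or sa
                da = _dirichlet(rng, sa, alpha=spec.concentration)
                db = _dirichlet(rng, sb, alpha=spec.concentration)
                r = 1.0 - w_sep - spec.ring_mass - spec.bridge_mass
                va = _combine(
                    (da, w_sep),
                    (inside, r),
                    ({ring: 1.0}, spec.ring_mass),
                    (bridge, spec.bridge_mass),
                )
                vb = _combine(
                    (db, w_sep),
                    (inside, r),
                    ({ring: 1.0}, spec.ring_mass),
                    (bridge, spec.bridge_mass),
                )
                self.variants[lab] = (va, vb)
                self.planted_separation[lab] = _l1(va, vb)
                if self.planted_separation[lab] < spec.separation:
                    raise ValueError(
                        "planted separation below the requested floor"
                    )  # pragma: no cover - construction guarantees this

    @property
    def second_order_types(self) -> set[str]:
        return {lab for lab, r in self.role.items() if r == ROLE_SECOND}

    def next_distribution(self, prev2: str | None, prev1: str) -> dict[str, float]:
        """P(next | penultimate, ultimate) of the generating process."""
        role = self.role[prev1]
        if role == ROLE_ZERO:
            return self.fallback
        if role == ROLE_FIRST:
            return self.conditionals[prev1]
        g = self.group[prev2] if prev2 is not None else 0
        return self.variants[prev1][g]

    # -- sequence generation ------------------------------------------------

    def _sample(self, dist: dict[str, float], rng: np.random.Generator) -> str:
        # distributions are fixed objects on the model: cache their CDFs
        cached = self._cdf_cache.get(id(dist))
        if cached is None:
            labs = list(dist)
            cached = labs, np.cumsum(np.asarray(list(dist.values())))
            self._cdf_cache[id(dist)] = cached
        labs, cum = cached
        return labs[int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))]

    def generate_corpus(
        self,
        lengths: list[int],
        seed,
        individual_id: str = "SYN",
        start_date: datetime = datetime(2013, 4, 25),
    ) -> Corpus:
        """One corpus: a recording per requested length, dated a day apart."""
        rng = np.random.default_rng(seed)
        recs = [
            self._timed_recording(n, rng, individual_id, i, start_date)
            for i, n in enumerate(lengths)
        ]
        return Corpus(individual_id, recs)

    def _timed_recording(self, n, rng, individual_id, i, start_date):
        return self._generate_timed(
            n,
            rng,
            individual_id,
            f"{individual_id}_{i:03d}.TextGrid",
            start_date + timedelta(days=i),
        )

    def _generate_timed(self, length, rng, individual_id, source, recorded_at):
        # like generate_recording, but the context reset (if enabled) is tied
        # to the actually-sampled gap so rate-stratified accuracy has a
        # planted mechanism
        spec = self.spec
        labels: list[str] = [self._sample(self.fallback, rng)]
        starts = [0.0]
        durs = [float(rng.lognormal(math.log(spec.mean_duration), 0.3))]
        reset = False
        t = durs[0]
        while len(labels) < length:
            if rng.random() < spec.long_gap_prob:
                gap = float(rng.lognormal(math.log(spec.long_gap), 0.4))
            else:
                gap = float(rng.lognormal(math.log(spec.short_gap), 0.4))
            reset = spec.reset_gap is not None and gap > spec.reset_gap
            prev1 = labels[-1]
            prev2 = labels[-2] if len(labels) >= 2 else None
            dist = self.fallback if reset else self.next_distribution(prev2, prev1)
            labels.append(self._sample(dist, rng))
            t += gap
            starts.append(t)
            durs.append(float(rng.lognormal(math.log(spec.mean_duration), 0.3)))
            t += durs[-1]
        events = [
            PhraseEvent(lab, s, s + d) for lab, s, d in zip(labels, starts, durs)
        ]
        return Recording(individual_id, events, source, recorded_at)


def make_ground_truth(spec: GroundTruthSpec, seed=None) -> GroundTruthModel:
    """Build the labelled generative model for one synthetic individual."""
    return GroundTruthModel(spec, seed=seed)


class BlendedGroundTruth(GroundTruthModel):
    """A convex mixture of two same-repertoire generators.

    Used to plant time inhomogeneity: the late half of a corpus is generated
    from ``(1 - w) * early + w * alternative``.  ``w`` near 0 gives the mild
    syntax change field corpora show; ``w = 1`` is a wholesale switch of the
    transition structure.
    """

    def __init__(self, a: GroundTruthModel, b: GroundTruthModel, w: float):
        if a.labels != b.labels:
            raise ValueError("blended models must share a repertoire")
        if not 0.0 <= w <= 1.0:
            raise ValueError("blend weight must be in [0, 1]")
        self.spec = a.spec
        self.labels = a.labels
        self.role = a.role
        self._a, self._b, self._w = a, b, w
        self.fallback = _mix(a.fallback, b.fallback, w)
        self._cdf_cache = {}
        self._mix_cache: dict[tuple[int, int], dict] = {}

    def next_distribution(self, prev2: str | None, prev1: str) -> dict[str, float]:
        da = self._a.next_distribution(prev2, prev1)
        db = self._b.next_distribution(prev2, prev1)
        key = (id(da), id(db))
        mixed = self._mix_cache.get(key)
        if mixed is None:
            mixed = self._mix_cache[key] = _mix(da, db, self._w)
        return mixed


def _draw_lengths(rng: np.random.Generator) -> list[int]:
    # study-like shape: per-individual totals ~1.3k-10k phrases (lognormal,
    # mean near 4k) split over 4-34 recordings of at least 50 phrases
    total = int(np.clip(rng.lognormal(math.log(3500.0), 0.5), 1335, 10336))
    n_rec = int(rng.integers(4, 35))
    parts = rng.dirichlet(np.full(n_rec, 5.0))
    lengths = np.maximum(50, np.round(parts * total).astype(int))
    return [int(x) for x in lengths]


def generate_study(
    spec: GroundTruthSpec,
    n_individuals: int = 14,
    out_dir: str | Path | None = None,
    tier_name: str = "phrases",
    drift: float = 0.0,
) -> tuple[dict[str, Corpus], dict[str, GroundTruthModel]]:
    """Generate a full multi-individual study with retained ground truth.

    Each individual gets an independent ground-truth model (child seed
    streams off ``spec.seed``) and a corpus of study-like recording lengths
    (or ``spec.recording_lengths`` if given).  ``drift`` plants time
    inhomogeneity: the chronologically later half of each corpus is
    generated from a blend of the individual's model with an independent
    same-repertoire alternative at that weight (0 = strictly homogeneous,
    1 = wholesale syntax switch).  If ``out_dir`` is given the corpora are
    written as TextGrids plus a metadata CSV and a truth-record JSON (role
    and planted separation per type, per individual).
    """
    master = np.random.SeedSequence(spec.seed)
    corpora: dict[str, Corpus] = {}
    truths: dict[str, GroundTruthModel] = {}
    children = master.spawn(n_individuals)
    for i, child in enumerate(children):
        ind = f"SYN{i + 1:02d}"
        model_seed, alt_seed, len_seed, gen_seed = child.spawn(4)
        model = GroundTruthModel(spec, seed=model_seed)
        lengths = (
            list(spec.recording_lengths)
            if spec.recording_lengths is not None
            else _draw_lengths(np.random.default_rng(len_seed))
        )
        corpus = model.generate_corpus(lengths, gen_seed, individual_id=ind)
        if drift > 0.0:
            alt = GroundTruthModel(spec, seed=alt_seed, labels=model.labels)
            late_model = BlendedGroundTruth(model, alt, drift)
            half = len(lengths) // 2
            late = late_model.generate_corpus(
                lengths[half:], alt_seed.spawn(1)[0], individual_id=ind
            )
            recs = corpus.recordings[:half]
            for j, rec in enumerate(late.recordings):
                rec.source = f"{ind}_{half + j:03d}.TextGrid"
                rec.recorded_at = datetime(2013, 4, 25) + timedelta(days=half + j)
                recs.append(rec)
            corpus = Corpus(ind, recs)
        corpora[ind] = corpus
        truths[ind] = model
    if out_dir is not None:
        _write_study(corpora, truths, Path(out_dir), tier_name)
    return corpora, truths


def _write_study(corpora, truths, out_dir: Path, tier_name: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ind, corpus in corpora.items():
        d = out_dir / ind
        d.mkdir(exist_ok=True)
        for rec in corpus.recordings:
            write_textgrid(rec, d / rec.source, tier_name)
            rows.append(
                {
                    "recording_id": rec.source,
                    "individual_id": ind,
                    "datetime": rec.recorded_at.isoformat() if rec.recorded_at else "",
                    "path": f"{ind}/{rec.source}",
                }
            )
    write_metadata(rows, out_dir / "metadata.csv")
    truth_doc = {
        ind: {
            "role": truths[ind].role,
            "planted_separation": truths[ind].planted_separation,
        }
        for ind in truths
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_doc, indent=1))


def second_order_recovery(truth: GroundTruthModel, interpolated) -> float:
    """Fraction of planted second-order phrase types that the interpolated
    model marks as second-order (some selected state (i, j) has them as
    ultimate type j)."""
    planted = truth.second_order_types
    if not planted:
        raise ValueError("no second-order types were planted")
    recovered = {j for _, j in interpolated.included_second}
    return len(planted & recovered) / len(planted)
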