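"""Synthetic multi-round SELEX pools with planted structure.

The generator emulates the study conditions: ten selection rounds, ~100
clones of 40-mer DNA per round.  "Binders" carry a designed hairpin — a
GC-rich stem enclosing a 5–7-nt unstructured loop — embedded in random
pads, so they fold to a strongly negative free energy E with a loop in the
descriptor-friendly size range.  "Non-binders" are uniform random 40-mers
with weak or absent structure.  The planted binder fraction follows the
saturating schedule f(r) = a·(1 − e^(−b·(r−1))): round 1 is the naive,
essentially binder-free pool, and the fraction saturates near the plateau
``a`` by the final round.

Ground-truth binder labels are returned (and written) separately from the
pools so no pipeline stage can consume them by accident.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classifier, descriptors, evolution, folding, pool_io
from .pool_io import Pool, SequenceRecord

_COMP = str.maketrans("ACGT", "TGCA")


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Study-condition parameters of the synthetic SELEX generator."""

    n_rounds: int = 10
    pool_size: int = 100
    plateau_a: float = 0.95
    rate_b: float = 0.6
    total_length: int = 40
    stem_length: int = 6
    loop_lengths: tuple[int, ...] = (5, 6, 7)
    #: loop alphabet weights; A/C-only loops cannot base-pair internally,
    #: keeping the designed hairpin loop intact in the MFE structure
    loop_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0}
    )
    #: per-base substitution rate applied to the pad regions of binders
    mutation_rate: float = 0.01
    seed: int = 7

    def planted_fraction(self, round_index: int) -> float:
        f = self.plateau_a * (1 - np.exp(-self.rate_b * (round_index - 1)))
        return float(np.clip(f, 0.0, 1.0))

    def validate(self) -> None:
        if self.n_rounds < 2 or self.pool_size < 1:
            raise GeneratorError("need at least 2 rounds and 1 clone per round")
        core = 2 * self.stem_length + min(self.loop_lengths)
        if core + 2 > self.total_length:
            raise GeneratorError(
                f"stem+loop ({core} nt) leaves no room for pads in {self.total_length} nt"
            )
        if abs(self.total_length - pool_io.NOMINAL_LENGTH) > pool_io.LENGTH_TOLERANCE:
            raise GeneratorError("total_length outside the 40±2 pool convention")


def _random_seq(rng: np.random.Generator, n: int, alphabet="ACGT", p=None) -> str:
    return "".join(rng.choice(list(alphabet), size=n, p=p))


def _binder_folds_as_designed(spec: GeneratorSpec, seq: str) -> bool:
    st = folding.fold_mfe(seq)
    if len(st.pairs) < spec.stem_length - 1:
        return False
    return any(
        lp.kind == "hairpin" and 5 <= lp.n_nucleotides <= 7
        for lp in folding.enumerate_loops(st)
    )


def _make_binder(spec: GeneratorSpec, rng: np.random.Generator, max_tries: int = 50) -> str:
    """5'pad — stem — loop — revcomp(stem) — 3'pad, padded to total length.

    Random pads occasionally set up a competing fold that displaces the
    designed hairpin; candidates are folded and resampled until the MFE
    structure carries the designed stem and a 5–7-nt hairpin loop, so the
    guarantee holds for every emitted binder.
    """
    for _ in range(max_tries):
        stem = _random_seq(rng, spec.stem_length, "GC")
        loop_len = int(rng.choice(spec.loop_lengths))
        bases = [b for b, w in spec.loop_weights.items() if w > 0]
        weights = np.array([spec.loop_weights[b] for b in bases], dtype=float)
        loop = _random_seq(rng, loop_len, bases, weights / weights.sum())
        pad_total = spec.total_length - 2 * spec.stem_length - loop_len
        pad5_len = int(rng.integers(0, pad_total + 1))
        pad5 = _random_seq(rng, pad5_len)
        pad3 = _random_seq(rng, pad_total - pad5_len)
        if spec.mutation_rate > 0:
            pad5 = _mutate(pad5, spec.mutation_rate, rng)
            pad3 = _mutate(pad3, spec.mutation_rate, rng)
        seq = pad5 + stem + loop + stem.translate(_COMP)[::-1] + pad3
        if _binder_folds_as_designed(spec, seq):
            return seq
    raise GeneratorError("could not realize a binder with the designed fold")  # pragma: no cover


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def generate_pools(spec: GeneratorSpec) -> tuple[Pool, dict[str, bool]]:
    """Generate all rounds; returns (pool, ground-truth binder flags by id).

    Per round, the binder count is a binomial draw at the planted fraction;
    binder/non-binder positions are shuffled within the round.  Fully
    deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth: dict[str, bool] = {}
    for rnd in range(1, spec.n_rounds + 1):
        f = spec.planted_fraction(rnd)
        n_binders = int(rng.binomial(spec.pool_size, f))
        flags = np.array([True] * n_binders + [False] * (spec.pool_size - n_binders))
        rng.shuffle(flags)
        for clone, is_binder in enumerate(flags, start=1):
            seq = _make_binder(spec, rng) if is_binder else _random_seq(rng, spec.total_length)
            rec = SequenceRecord(rnd, str(clone), seq)
            records.append(rec)
            truth[rec.key] = bool(is_binder)
    return Pool(records), truth


def write_ground_truth(truth: dict[str, bool], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "is_binder"])
        for key, flag in truth.items():
            w.writerow([key, int(flag)])


@dataclass
class RecoveryReport:
    """End-to-end pipeline run on one synthetic pool."""

    training_accuracy: float
    cv_accuracy: float
    C: float
    gamma: float
    summaries: list[evolution.RoundSummary]
    fit: evolution.EnrichmentFit
    energy_trend: evolution.EnergyTrend
    spearman_rho: float
    n_train: int
    n_total: int
    planted_a: float
    planted_b: float


def end_to_end_recovery(
    spec: GeneratorSpec | None = None,
    ga_generations: int = 200,
    ga_population: int = 20,
    use_ga: bool = True,
) -> RecoveryReport:
    """Run the full pipeline on a generated pool and measure recovery.

    fold → filter → loop selection → descriptors → train SVM on rounds 1
    and n (GA-tuned (C, γ) by default, at the study's GA scale of 20×200)
    → predict every round → round summaries → enrichment fit.
    """
    spec = spec or GeneratorSpec()
    pool, _truth = generate_pools(spec)
    structures = folding.fold_pool(pool)
    filtered = pool_io.filter_pool(pool, structures)
    loops = {
        rec.key: folding.select_loop(folding.enumerate_loops(structures[rec.key]))
        for rec in filtered
    }
    table = descriptors.descriptor_table(filtered.records, structures, loops)
    feats = ["PW4", "X3A", "JGI2", "E"]

    train, _test = pool_io.split_train_test(filtered)
    key_to_row = {k: i for i, k in enumerate(table["id"])}
    X_train = table.loc[[key_to_row[r.key] for r in train.records], feats].to_numpy()
    y_train = np.array(train.labels)

    if use_ga:
        config = classifier.GAConfig(
            population_size=ga_population, generations=ga_generations, seed=spec.seed
        )
        ga = classifier.ga_optimize(X_train, y_train, config)
        C, gamma, cv_acc = ga.C, ga.gamma, ga.cv_accuracy
    else:
        C, gamma = classifier.PRESET_C, classifier.PRESET_GAMMA
        cv_acc = classifier.cross_validate(X_train, y_train, C, gamma, seed=spec.seed)
    model = classifier.train_svm(X_train, y_train, C, gamma)

    X_all = table[feats].to_numpy()
    labels = classifier.predict(model, X_all)
    predictions = dict(zip(table["id"], labels))
    energies = dict(zip(table["id"], table["E"]))
    summaries = evolution.summarize_rounds(predictions, filtered, energies)
    fit = evolution.fit_enrichment(summaries)
    trend = evolution.mean_energy_trend(summaries)
    rho = evolution.fraction_monotonicity(summaries)
    return RecoveryReport(
        training_accuracy=model.training_accuracy,
        cv_accuracy=cv_acc,
        C=C,
        gamma=gamma,
        summaries=summaries,
        fit=fit,
        energy_trend=trend,
        spearman_rho=rho,
        n_train=len(train),
        n_total=len(filtered),
        planted_a=spec.plateau_a,
        planted_b=spec.rate_b,
    )
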