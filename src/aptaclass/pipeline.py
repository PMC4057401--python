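"""Run configuration and the end-to-end pipeline driver.

``run_pipeline`` chains pool_io → folding → descriptors → (optional)
feature selection → SVM training → round-wise evolution, writing each
stage's artifact plus a JSON manifest (seeds, parameters, versions, input
hash) into the output directory.  Re-running with the same manifest inputs
reproduces the outputs bit for bit: every stochastic stage is seeded and
the GA stage is optional (the fixed (C, γ) preset is the default fast
path).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, classifier, descriptors, evolution, feature_selection, folding, pool_io

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunables of a pipeline run; defaults follow the study settings."""

    params_path: str | None = None  # None = builtin DNA table
    wobble: bool = True
    include_closing_pair: bool = False
    strict_length: bool = True
    run_feature_selection: bool = False
    p_enter: float = 0.05
    p_remove: float = 0.10
    use_ga: bool = False
    C: float = classifier.PRESET_C
    gamma: float = classifier.PRESET_GAMMA
    ga_population: int = 20
    ga_generations: int = 200
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ConfigError("C and gamma must be positive")
        if not 0 < self.p_enter < self.p_remove:
            raise ConfigError("need 0 < p_enter < p_remove")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.ga_population < 2 or self.ga_generations < 1:
            raise ConfigError("GA population >= 2 and generations >= 1 required")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RunResult:
    out_dir: Path
    model: classifier.SVMModel
    summaries: list[evolution.RoundSummary]
    fit: evolution.EnrichmentFit
    selected: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, pools_path: str | Path, out_dir: str | Path,
                 format: str = "fasta") -> RunResult:
    """Execute every stage on a pool file and write artifacts to ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pools_path = Path(pools_path)

    params = (
        folding.EnergyParameters.from_file(config.params_path)
        if config.params_path
        else folding.default_parameters()
    )

    pool = pool_io.parse_pool(pools_path, format=format, strict_length=config.strict_length)
    logger.info("parsed %d records in rounds %s", len(pool), sorted(pool.rounds_present))

    structures = folding.fold_pool(pool, params, config.wobble)
    filtered = pool_io.filter_pool(pool, structures)
    pool_io.write_pool_csv(filtered, out / "filtered_pool.csv")

    loops = {
        rec.key: folding.select_loop(folding.enumerate_loops(structures[rec.key]))
        for rec in filtered
    }
    with open(out / "structures.csv", "w") as fh:
        fh.write("id,E,dot_bracket,loop_kind,loop_start,loop_size\n")
        for rec in filtered:
            st, lp = structures[rec.key], loops[rec.key]
            fh.write(
                f"{rec.key},{st.energy_E:.2f},{st.dot_bracket()},"
                f"{lp.kind},{lp.start},{lp.n_nucleotides}\n"
            )

    table = descriptors.descriptor_table(
        filtered.records, structures, loops, config.include_closing_pair
    )
    table.to_csv(out / "descriptors.csv", index=False)

    selected: list[str] = []
    if config.run_feature_selection:
        fam = descriptors.family_table(filtered.records, structures, loops)
        result = feature_selection.stepwise_mlr(
            fam.drop(columns=["id"]), "round", config.p_enter, config.p_remove
        )
        selected = result.selected
        (out / "selected.json").write_text(json.dumps({"selected": selected, "steps": result.steps}, indent=1))

    feats = ["PW4", "X3A", "JGI2", "E"]
    train, _test = pool_io.split_train_test(filtered)
    idx = {k: i for i, k in enumerate(table["id"])}
    X_train = table.loc[[idx[r.key] for r in train.records], feats].to_numpy()
    y_train = np.array(train.labels)

    if config.use_ga:
        ga = classifier.ga_optimize(
            X_train,
            y_train,
            classifier.GAConfig(
                population_size=config.ga_population,
                generations=config.ga_generations,
                cv_folds=config.cv_folds,
                seed=config.seed,
            ),
        )
        C, gamma = ga.C, ga.gamma
    else:
        C, gamma = config.C, config.gamma
    model = classifier.train_svm(X_train, y_train, C, gamma)
    model.save(out / "model.json")

    labels = classifier.predict(model, table[feats].to_numpy())
    predictions = dict(zip(table["id"], labels))
    energies = dict(zip(table["id"], table["E"]))
    summaries = evolution.summarize_rounds(predictions, filtered, energies)
    fit = evolution.fit_enrichment(summaries)
    with open(out / "round_summary.csv", "w") as fh:
        fh.write("round,n_sequences,winning_fraction,mean_E\n")
        for s in summaries:
            fh.write(f"{s.round_index},{s.n_sequences},{s.winning_fraction:.4f},{s.mean_E:.3f}\n")

    manifest = {
        "version": __version__,
        "input": str(pools_path),
        "input_sha256": hashlib.sha256(pools_path.read_bytes()).hexdigest(),
        "config": asdict(config),
        "energy_parameters": params.source,
        "model": {"C": model.C, "gamma": model.gamma, "training_accuracy": model.training_accuracy},
        "enrichment_fit": {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared},
        "selected_descriptors": selected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(out, model, summaries, fit, selected)
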