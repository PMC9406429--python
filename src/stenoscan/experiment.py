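"""End-to-end experiment orchestration.

Ties generation -> preprocessing -> extraction/training -> evaluation into
one reproducible run driven by a single YAML config and one base seed. All
randomness (corpus sampling, hold-out splits, weight initialization,
dropout) flows from that seed, and every output directory carries a
provenance log recording the config hash, seeds and library versions.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import EvalResult, run_experiment
from .lstm import LSTMClassifier, TrainingConfig
from .preprocessing import prepare_report
from .rules import CompiledMatcher, RuleSet, compile_rules
from .synthetic import (
    CorpusConfig,
    SyntheticReport,
    external_config,
    generate_corpus,
    internal_config,
    write_corpus_jsonl,
    write_labels_csv,
)

__all__ = ["RuleModel", "LSTMModel", "ExperimentConfig", "run_full_experiment"]


def target_texts(texts: list[str]) -> list[str]:
    """Front-end pass: cleaned findings+impression text per raw report."""
    return [prepare_report(t)[0].target_text for t in texts]


class RuleModel:
    """Prediction-contract adapter around the rule-based extractor.

    Built once (no training phase); emits hard 0/1 calls, so the evaluation
    harness scores it with the confusion-matrix AUROC.
    """

    requires_training = False
    is_probabilistic = False

    def __init__(self, matcher: CompiledMatcher | None = None):
        self.matcher = matcher or compile_rules()

    def predict(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), 11), dtype=np.int64)
        for i, raw in enumerate(texts):
            sectioned, sentences = prepare_report(raw, report_id=str(i))
            out[i] = self.matcher.extract_labels(sectioned, sentences).to_array()
        return out


class LSTMModel:
    """Prediction-contract adapter around the recurrent classifier.

    Re-initialized from a fresh seed on every ``fit`` call so that
    successive hold-out rounds train independent models; the per-round
    seeds derive deterministically from the configured base seed.
    """

    requires_training = True
    is_probabilistic = True

    def __init__(self, config: TrainingConfig | None = None):
        self.base_config = config or TrainingConfig()
        self.model: LSTMClassifier | None = None
        self._fit_count = 0

    def fit(self, texts: list[str], labels: np.ndarray) -> "LSTMModel":
        cfg_dict = asdict(self.base_config)
        cfg_dict["seed"] = (self.base_config.seed + 7919 * self._fit_count) % (2**31)
        self._fit_count += 1
        cfg = TrainingConfig(**cfg_dict)
        self.model = LSTMClassifier(cfg)
        self.model.fit(target_texts(texts), labels)
        return self

    def predict(self, texts: list[str]) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("LSTMModel.predict called before fit")
        return self.model.predict_proba(target_texts(texts))


@dataclass
class ExperimentConfig:
    """One full experiment: two corpora, two models, the hold-out protocol."""

    internal: CorpusConfig = field(default_factory=internal_config)
    external: CorpusConfig = field(default_factory=external_config)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    rules_path: str | None = None  # None -> packaged default lexicon
    rounds: int = 10
    lstm_rounds: int | None = None  # None -> same as rounds
    base_seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "internal" in data:
            kwargs["internal"] = CorpusConfig(**data["internal"])
        if "external" in data:
            kwargs["external"] = CorpusConfig(**data["external"])
        if "training" in data:
            t = dict(data["training"])
            if "lstm_units" in t:
                t["lstm_units"] = tuple(t["lstm_units"])
            kwargs["training"] = TrainingConfig(**t)
        for key in ("rules_path", "rounds", "lstm_rounds", "base_seed", "out_dir"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, CorpusConfig):
                d = asdict(o)
                d["prevalence"] = {k.value: v for k, v in o.prevalence.items()}
                return d
            return asdict(o)

        blob = json.dumps(
            {
                "internal": enc(self.internal),
                "external": enc(self.external),
                "training": asdict(self.training),
                "rules_path": self.rules_path,
                "rounds": self.rounds,
                "lstm_rounds": self.lstm_rounds,
                "base_seed": self.base_seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _reseed(config: CorpusConfig, seed: int) -> CorpusConfig:
    d = asdict(config)
    d["seed"] = seed
    return CorpusConfig(**d)


def run_full_experiment(config: ExperimentConfig) -> dict:
    """Generate corpora, run both models through the protocol, write outputs.

    Returns a bundle with the corpora, per-model :class:`EvalResult` objects
    and the provenance record. Deterministic given ``base_seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = config.base_seed

    stage = "generate"
    try:
        internal = generate_corpus(_reseed(config.internal, base + 1))
        external = generate_corpus(_reseed(config.external, base + 2))
        write_corpus_jsonl(internal, out / "internal.jsonl")
        write_corpus_jsonl(external, out / "external.jsonl")
        write_labels_csv(internal, out / "internal_labels.csv")
        write_labels_csv(external, out / "external_labels.csv")

        stage = "models"
        ruleset = (RuleSet.from_yaml(config.rules_path)
                   if config.rules_path else None)
        rule_model = RuleModel(compile_rules(ruleset))
        t = asdict(config.training)
        t["seed"] = base + 3
        t["lstm_units"] = tuple(t["lstm_units"])
        lstm_model = LSTMModel(TrainingConfig(**t))

        int_texts = [r.full_text for r in internal]
        int_gold = np.vstack([r.gold.to_array() for r in internal])
        ext_texts = [r.full_text for r in external]
        ext_gold = np.vstack([r.gold.to_array() for r in external])

        stage = "evaluate-rule"
        rule_result = run_experiment(
            int_texts, int_gold, ext_texts, ext_gold,
            {"rule_based": rule_model}, rounds=config.rounds, seed=base + 4)

        stage = "evaluate-lstm"
        lstm_rounds = config.lstm_rounds or config.rounds
        lstm_result = run_experiment(
            int_texts, int_gold, ext_texts, ext_gold,
            {"lstm": lstm_model}, rounds=lstm_rounds, seed=base + 4)

        stage = "report"
        merged = EvalResult(
            values={**rule_result.values, **lstm_result.values},
            excluded=rule_result.excluded + lstm_result.excluded,
        )
        df = merged.summary_frame()
        df.to_csv(out / "metrics.csv", index=False)
        (out / "metrics.txt").write_text(merged.format_table() + "\n")
        provenance = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "base_seed": base,
            "rounds": config.rounds,
            "lstm_rounds": lstm_rounds,
            "n_internal": len(internal),
            "n_external": len(external),
            "excluded_cells": len(merged.excluded),
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    return {
        "internal": internal,
        "external": external,
        "result": merged,
        "provenance": provenance,
    }
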