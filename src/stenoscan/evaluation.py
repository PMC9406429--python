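"""Assessment protocol: repeated hold-out splits and per-artery metrics.

The protocol is a 10-round hold-out cross-validation: each round draws an
independent random 80/20 train/test split (train size = ceil(0.8 n); this
is repeated sampling, not k-fold partitioning). Trainable models are refit
every round; the rule-based model is fixed and simply re-evaluated on each
round's test split. The external corpus is evaluated in full every round,
so only trainable models vary across its rounds.

Two AUROC definitions are used, matching how each model emits predictions:

* probabilistic outputs — the area under the ROC curve (trapezoidal, with
  midrank tie handling, i.e. the probability-of-correct-ranking estimator);
* hard binary outputs — the balanced-accuracy form computed from the
  confusion matrix, 1/2 (tp/(tp+fn) + tn/(tn+fp)).

On binary predictions the two definitions coincide. Sensitivity is
tp/(tp+fn), specificity tn/(tn+fp). The binarized task collapses the 11
labels to one with/without-stenosis indicator per report (gold: any artery
positive; probabilistic prediction: max over the 11 probabilities; hard
prediction: logical OR). Metrics are aggregated as mean +/- SD across
rounds; an artery whose test split contains a single class is excluded
from that round with a logged count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .arteries import ARTERY_ORDER

__all__ = [
    "ConfusionCounts",
    "SplitPlan",
    "EvalResult",
    "make_splits",
    "auroc_from_confusion",
    "auroc_from_probabilities",
    "sensitivity_specificity",
    "confusion_counts",
    "binarize_gold",
    "binarize_predictions",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-artery confusion-matrix counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SplitPlan:
    """One hold-out round: disjoint train/test report indices."""

    round_index: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int


def make_splits(
    n: int,
    rounds: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> list[SplitPlan]:
    """Independent random splits, train size = ceil(train_fraction * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = math.ceil(train_fraction * n)
    if n < 2 or n_train >= n:
        raise ValueError(f"corpus of size {n} cannot be split at {train_fraction}")
    plans = []
    for r in range(1, rounds + 1):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(n)
        plans.append(SplitPlan(r, np.sort(perm[:n_train]), np.sort(perm[n_train:]),
                               seed + r))
    return plans


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def auroc_from_confusion(c: ConfusionCounts) -> float:
    """Balanced-accuracy AUROC for hard predictions: (sens + spec) / 2."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        warnings.warn("AUROC undefined: one class is empty", stacklevel=2)
        return float("nan")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        warnings.warn("sensitivity/specificity undefined: empty class",
                      stacklevel=2)
        return (float("nan"), float("nan"))
    return (c.tp / (c.tp + c.fn), c.tn / (c.tn + c.fp))


def auroc_from_probabilities(y_true, scores) -> float:
    """ROC area for probabilistic scores (midrank handling of ties)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        warnings.warn("AUROC undefined: single-class gold labels", stacklevel=2)
        return float("nan")
    return float(roc_auc_score(y_true, scores))


def binarize_gold(labels: np.ndarray) -> np.ndarray:
    """(n, 11) gold matrix -> per-report with/without-stenosis indicator."""
    return (np.asarray(labels).sum(axis=1) > 0).astype(int)


def binarize_predictions(pred: np.ndarray, probabilistic: bool) -> np.ndarray:
    """Max probability (probabilistic) or logical OR (hard calls)."""
    pred = np.asarray(pred)
    if probabilistic:
        return pred.max(axis=1)
    return (pred.sum(axis=1) > 0).astype(int)


# ---------------------------------------------------------------------------
# experiment runner

_ROWS = [a.value for a in ARTERY_ORDER] + ["binarized"]
_METRICS = ("auroc", "sensitivity", "specificity")


@dataclass
class EvalResult:
    """Mean +/- SD of per-artery metrics across hold-out rounds."""

    # values[(model, dataset, row, metric)] -> list of per-round values
    values: dict[tuple[str, str, str, str], list[float]] = field(default_factory=dict)
    excluded: list[dict] = field(default_factory=list)

    def add(self, model, dataset, row, metric, value) -> None:
        self.values.setdefault((model, dataset, row, metric), []).append(value)

    def exclude(self, model, dataset, row, round_index, reason) -> None:
        self.excluded.append(dict(model=model, dataset=dataset, row=row,
                                  round=round_index, reason=reason))

    def mean_sd(self, model, dataset, row, metric) -> tuple[float, float]:
        vals = self.values.get((model, dataset, row, metric), [])
        if not vals:
            return (float("nan"), float("nan"))
        arr = np.array(vals, dtype=float)
        return (float(arr.mean()), float(arr.std(ddof=0)))

    def mean_artery_auroc(self, model, dataset) -> float:
        """Mean over arteries of the per-artery round-mean AUROC."""
        means = [self.mean_sd(model, dataset, a.value, "auroc")[0]
                 for a in ARTERY_ORDER]
        return float(np.nanmean(means))

    def summary_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (model, dataset, artery)."""
        records = []
        keys = sorted({(m, d) for m, d, _, _ in self.values})
        for model, dataset in keys:
            for row in _ROWS:
                rec = {"model": model, "dataset": dataset, "artery": row}
                for metric in _METRICS:
                    mean, sd = self.mean_sd(model, dataset, row, metric)
                    rec[f"{metric}_mean"] = mean
                    rec[f"{metric}_sd"] = sd
                rec["n_rounds"] = len(
                    self.values.get((model, dataset, row, "auroc"), []))
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def format_table(self) -> str:
        df = self.summary_frame()
        lines = []
        for (model, dataset), sub in df.groupby(["model", "dataset"]):
            lines.append(f"== {model} / {dataset} ==")
            for _, r in sub.iterrows():
                lines.append(
                    f"  {r['artery']:<10} AUROC {r['auroc_mean']:.3f} "
                    f"± {r['auroc_sd']:.3f}  sens {r['sensitivity_mean']:.3f}  "
                    f"spec {r['specificity_mean']:.3f}  (rounds={r['n_rounds']})"
                )
        return "\n".join(lines)


def _score_subset(result, model_name, dataset, round_index,
                  gold, pred, probabilistic, threshold=0.5):
    gold = np.asarray(gold)
    pred = np.asarray(pred)
    for j, artery in enumerate(ARTERY_ORDER):
        y = gold[:, j]
        if len(np.unique(y)) < 2:
            result.exclude(model_name, dataset, artery.value, round_index,
                           "single-class test labels")
            continue
        p = pred[:, j]
        hard = (p >= threshold).astype(int) if probabilistic else p.astype(int)
        c = confusion_counts(y, hard)
        if probabilistic:
            auroc = auroc_from_probabilities(y, p)
        else:
            auroc = auroc_from_confusion(c)
        sens, spec = sensitivity_specificity(c)
        result.add(model_name, dataset, artery.value, "auroc", auroc)
        result.add(model_name, dataset, artery.value, "sensitivity", sens)
        result.add(model_name, dataset, artery.value, "specificity", spec)
    yb = binarize_gold(gold)
    if len(np.unique(yb)) < 2:
        result.exclude(model_name, dataset, "binarized", round_index,
                       "single-class test labels")
        return
    pb = binarize_predictions(pred, probabilistic)
    hardb = (pb >= threshold).astype(int) if probabilistic else pb.astype(int)
    cb = confusion_counts(yb, hardb)
    aurocb = (auroc_from_probabilities(yb, pb) if probabilistic
              else auroc_from_confusion(cb))
    sensb, specb = sensitivity_specificity(cb)
    result.add(model_name, dataset, "binarized", "auroc", aurocb)
    result.add(model_name, dataset, "binarized", "sensitivity", sensb)
    result.add(model_name, dataset, "binarized", "specificity", specb)


def run_experiment(
    internal_texts: list[str],
    internal_gold: np.ndarray,
    external_texts: list[str],
    external_gold: np.ndarray,
    models: dict,
    rounds: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalResult:
    """Run the full hold-out protocol for a set of models.

    Each model must expose ``requires_training`` and ``is_probabilistic``
    flags, ``predict(texts) -> (n, 11)`` and, when trainable,
    ``fit(texts, labels)``. Static models are evaluated once per corpus and
    their predictions reused across rounds; trainable models are refit on
    each round's training split and re-applied to that round's internal
    test split and to the full external corpus.
    """
    internal_gold = np.asarray(internal_gold)
    external_gold = np.asarray(external_gold)
    result = EvalResult()
    plans = make_splits(len(internal_texts), rounds, train_fraction, seed)

    static_internal: dict[str, np.ndarray] = {}
    static_external: dict[str, np.ndarray] = {}
    for name, model in models.items():
        if not model.requires_training:
            static_internal[name] = np.asarray(model.predict(internal_texts))
            if len(external_texts):
                static_external[name] = np.asarray(model.predict(external_texts))

    for plan in plans:
        for name, model in models.items():
            if model.requires_training:
                model.fit([internal_texts[i] for i in plan.train_ids],
                          internal_gold[plan.train_ids])
                pred_int = np.asarray(
                    model.predict([internal_texts[i] for i in plan.test_ids]))
                pred_ext = (np.asarray(model.predict(external_texts))
                            if len(external_texts) else None)
            else:
                pred_int = static_internal[name][plan.test_ids]
                pred_ext = static_external.get(name)
            _score_subset(result, name, "internal", plan.round_index,
                          internal_gold[plan.test_ids], pred_int,
                          model.is_probabilistic, threshold)
            if pred_ext is not None:
                _score_subset(result, name, "external", plan.round_index,
                              external_gold, pred_ext,
                              model.is_probabilistic, threshold)
    return result
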