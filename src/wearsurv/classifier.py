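"""Noise-aware discriminative classifier over weakly labeled notes.

The label model only sees notes through the labeling functions; a
discriminative classifier trained on its probabilistic output generalizes
beyond the encoded rules. Training sets are stratified to a 1:2
positive:negative ratio (the corpus is heavily skewed negative), sampled
randomly from the hardened weak labels, and the gold test set is never
included. Each training example carries a weight equal to the label model's
confidence (``p`` for positives, ``1 - p`` for negatives), making the loss
noise-aware.

The default model is a weighted-loss logistic regression over word 1-3-gram
features with sublinear term frequency, exposed through an interface
(text -> probability of POSITIVE) that a transformer adapter could equally
satisfy. The fine-tuning settings such a transformer would use are retained
in :data:`TRANSFORMER_PROVENANCE` as configuration provenance only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve

from .corpus import ClinicalNote, LabeledNote
from .label_model import ProbabilisticLabel

__all__ = [
    "TrainingSet",
    "EvalReport",
    "FittedClassifier",
    "build_training_set",
    "train_noise_aware",
    "evaluate",
    "size_sweep",
    "TRANSFORMER_PROVENANCE",
]

#: fine-tuning settings for the transformer this classifier stands in for;
#: provenance only, never consumed by this implementation
TRANSFORMER_PROVENANCE: Mapping[str, object] = {
    "model": "Clinical-Longformer",
    "task": "sequence classification",
    "optimizer": "Adam",
    "peak_learning_rate": 1e-5,
    "schedule": "linear warmup then linear decay",
    "epochs": 3,
    "max_input_subword_tokens": 4096,
}

DEFAULT_HYPERPARAMS: Mapping[str, object] = {
    "ngram_range": (1, 3),
    "sublinear_tf": True,
    "min_df": 1,
    # strong regularization: n-gram features are high-dimensional and sparse,
    # and weak labels carry noise that weaker penalties memorize
    "C": 0.2,
    "max_iter": 2000,
    "threshold": 0.5,
}


@dataclass(frozen=True)
class TrainingSet:
    """Stratified weak-label training sample: (note_id, hard label, weight)."""

    entries: tuple[tuple[str, int, float], ...]
    requested_size: int
    ratio: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        n_pos = sum(1 for _, y, _ in self.entries if y == 1)
        n_neg = len(self.entries) - n_pos
        if abs(n_pos * self.ratio[1] - n_neg * self.ratio[0]) > 2:
            raise ValueError(
                f"entries violate the {self.ratio[0]}:{self.ratio[1]} ratio "
                f"({n_pos} positive vs {n_neg} negative)"
            )

    @property
    def note_ids(self) -> list[str]:
        return [nid for nid, _, _ in self.entries]


def build_training_set(
    labels: Sequence[ProbabilisticLabel],
    size: int,
    ratio: tuple[int, int] = (1, 2),
    exclusions: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    threshold: float = 0.5,
) -> TrainingSet:
    """Sample a stratified training set from hardened probabilistic labels.

    ``size * ratio[0]/(ratio[0]+ratio[1])`` positives and the complement of
    negatives are drawn uniformly without replacement (seeded) from labels
    hardened at ``threshold``, never touching ``exclusions`` (the gold
    development/test note ids).
    """
    denom = ratio[0] + ratio[1]
    n_pos = round(size * ratio[0] / denom)
    n_neg = size - n_pos
    pool_pos = [l for l in labels if l.note_id not in exclusions and l.p_positive >= threshold]
    pool_neg = [l for l in labels if l.note_id not in exclusions and l.p_positive < threshold]
    if len(pool_pos) < n_pos:
        raise ValueError(
            f"insufficient positives: need {n_pos}, have {len(pool_pos)} "
            f"(short by {n_pos - len(pool_pos)})"
        )
    if len(pool_neg) < n_neg:
        raise ValueError(
            f"insufficient negatives: need {n_neg}, have {len(pool_neg)} "
            f"(short by {n_neg - len(pool_neg)})"
        )
    rng = np.random.default_rng(seed)
    pos = [pool_pos[i] for i in rng.choice(len(pool_pos), n_pos, replace=False)]
    neg = [pool_neg[i] for i in rng.choice(len(pool_neg), n_neg, replace=False)]
    entries = tuple(
        [(l.note_id, 1, l.p_positive) for l in pos]
        + [(l.note_id, 0, 1.0 - l.p_positive) for l in neg]
    )
    return TrainingSet(entries, requested_size=size, ratio=ratio)


@dataclass
class FittedClassifier:
    """Text -> probability-of-POSITIVE model with a decision threshold."""

    vectorizer: TfidfVectorizer
    model: LogisticRegression
    threshold: float = 0.5
    seed: int = 0

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        X = self.vectorizer.transform(texts)
        return self.model.predict_proba(X)[:, 1]

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(texts) >= self.threshold).astype(int)


def _note_texts(notes) -> dict[str, str]:
    if isinstance(notes, Mapping):
        return dict(notes)
    return {n.note_id: n.text for n in notes}


def train_noise_aware(
    train: TrainingSet,
    notes,
    hyperparams: Mapping[str, object] | None = None,
    seed: int = 0,
) -> FittedClassifier:
    """Fit the weighted-loss n-gram classifier on a training set.

    ``notes`` is a mapping note_id -> text or a sequence of
    :class:`ClinicalNote`. Zero-weight examples are dropped before fitting
    (they contribute nothing to the loss and must not perturb document
    frequencies). Deterministic given the seed.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    texts_by_id = _note_texts(notes)
    rows = [(texts_by_id[nid], y, w) for nid, y, w in train.entries if w > 0]
    if not rows:
        raise ValueError("training set is empty after dropping zero-weight examples")
    texts, ys, ws = zip(*rows)
    if len(set(ys)) < 2:
        raise ValueError("training set contains a single class")
    vec = TfidfVectorizer(ngram_range=tuple(hp["ngram_range"]),
                          sublinear_tf=bool(hp["sublinear_tf"]),
                          min_df=hp["min_df"])
    X = vec.fit_transform(texts)
    clf = LogisticRegression(C=float(hp["C"]), max_iter=int(hp["max_iter"]),
                             random_state=seed)
    clf.fit(X, np.array(ys), sample_weight=np.array(ws))
    return FittedClassifier(vec, clf, threshold=float(hp["threshold"]), seed=seed)


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    roc_points: tuple[tuple[float, float], ...]  # (FPR, TPR) by threshold sweep
    pr_points: tuple[tuple[float, float], ...]   # (recall, precision)

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "f1", "accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def auroc(self) -> float:
        pts = sorted(self.roc_points)
        return float(np.trapezoid([p[1] for p in pts], [p[0] for p in pts]))


def evaluate(
    classifier: FittedClassifier,
    gold: Sequence[LabeledNote],
    notes,
) -> EvalReport:
    """Scalar metrics at the decision threshold plus ROC / PR curves.

    ROC and PR points come from sweeping every distinct predicted
    probability as a threshold.
    """
    if not gold:
        raise ValueError("empty gold set")
    y = np.array([g.gold_label for g in gold])
    if len(set(y.tolist())) < 2:
        raise ValueError("gold set contains a single class")
    texts_by_id = _note_texts(notes)
    p = classifier.predict_proba([texts_by_id[g.note_id] for g in gold])
    pred = (p >= classifier.threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    fpr, tpr, _ = roc_curve(y, p)
    prec_c, rec_c, _ = precision_recall_curve(y, p)
    return EvalReport(
        precision=precision, recall=recall, f1=f1,
        accuracy=(tp + tn) / len(y),
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        pr_points=tuple(zip(rec_c.tolist(), prec_c.tolist())),
    )


def size_sweep(
    labels: Sequence[ProbabilisticLabel],
    gold: Sequence[LabeledNote],
    notes,
    sizes: Sequence[int] = (600, 5000, 10000, 15000),
    replicates: int = 3,
    seed: int = 0,
    hyperparams: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Mean test metrics per training-set size, averaged over seeded replicates.

    Emits one row per size with mean precision / recall / F1 / accuracy —
    the grid showing how performance scales with the amount of weakly
    labeled training data.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    gold_ids = {g.note_id for g in gold}
    rows = []
    for size in sizes:
        reps = []
        for r in range(replicates):
            rep_seed = seed * 1000 + r
            ts = build_training_set(labels, size, exclusions=gold_ids, seed=rep_seed)
            clf = train_noise_aware(ts, notes, hyperparams=hyperparams, seed=rep_seed)
            reps.append(evaluate(clf, gold, notes))
        rows.append({
            "size": size,
            "precision": float(np.mean([e.precision for e in reps])),
            "recall": float(np.mean([e.recall for e in reps])),
            "f1": float(np.mean([e.f1 for e in reps])),
            "accuracy": float(np.mean([e.accuracy for e in reps])),
        })
    return pd.DataFrame(rows).set_index("size")
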