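"""Generative label model over labeling-function votes.

Labeling functions are one-sided: each either votes POSITIVE or abstains, and
no single function sees every positive note. The label model combines their
votes under a conditionally independent generative model:

* the true note label is ``y ~ Bernoulli(class_prior)``;
* LF *j* attempts a vote with probability ``propensity_j`` and, when voting,
  matches the true label with probability ``accuracy_j`` — but a one-sided
  LF can only *emit* POSITIVE, so a non-matching attempt on a negative note
  surfaces as POSITIVE while a would-be negative vote on a positive note is
  observed as an abstention.

Observationally each LF is therefore Bernoulli per class:
``P(POSITIVE | y=1) = propensity * accuracy`` and
``P(POSITIVE | y=0) = propensity * (1 - accuracy)``, with abstention the
complement. The E-step computes ``p(y=1 | votes)`` by Bayes' rule under
conditional independence; an abstention is weak negative evidence (the
positive class fires LFs more often), which is what lets the model score
all-abstain notes sensibly. The M-step re-estimates the prior and the two
per-LF vote rates from posterior-weighted counts and maps them back to
(accuracy, propensity). The log-likelihood is non-decreasing across
iterations, which the fitter asserts.

Model selection: candidate models from different random initializations are
scored by mean F1 over stratified k-fold splits of the gold-labeled set, and
the best one is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from .corpus import LabeledNote
from .weak_labeling import N_LFS, VoteMatrix

__all__ = [
    "LabelModelParams",
    "ProbabilisticLabel",
    "majority_vote",
    "fit_label_model",
    "predict_proba",
    "cv_select",
    "labels_to_frame",
]

EPS = 1e-3


@dataclass(frozen=True)
class LabelModelParams:
    """Class prior plus per-LF accuracy and propensity, all strictly in (0, 1)."""

    class_prior: float
    accuracies: np.ndarray   # shape (N_LFS,)
    propensities: np.ndarray  # shape (N_LFS,)
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, dtype=float)
        prop = np.asarray(self.propensities, dtype=float)
        object.__setattr__(self, "accuracies", acc)
        object.__setattr__(self, "propensities", prop)
        if acc.shape != (N_LFS,) or prop.shape != (N_LFS,):
            raise ValueError(f"need {N_LFS} accuracy and propensity entries")
        for name, v in (("class_prior", np.array([self.class_prior])),
                        ("accuracies", acc), ("propensities", prop)):
            if not ((v > 0) & (v < 1)).all():
                raise ValueError(f"{name} must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class ProbabilisticLabel:
    note_id: str
    p_positive: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must be in [0, 1]")


def labels_to_frame(labels: Sequence[ProbabilisticLabel]) -> pd.DataFrame:
    return pd.DataFrame({"note_id": [l.note_id for l in labels],
                         "p_positive": [l.p_positive for l in labels]})


def majority_vote(matrix: VoteMatrix, abstain_prior: float = 0.5) -> list[ProbabilisticLabel]:
    """Baseline: fraction of POSITIVE votes among non-abstains per note.

    With one-sided LFs every non-abstain vote is POSITIVE, so any firing LF
    yields 1.0; all-abstain rows fall back to ``abstain_prior``.
    """
    voted = (matrix.votes != 0).sum(axis=1)
    pos = (matrix.votes == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(voted > 0, pos / np.maximum(voted, 1), abstain_prior)
    return [ProbabilisticLabel(nid, float(pi)) for nid, pi in zip(matrix.note_ids, p)]


def _vote_rates(acc: np.ndarray, prop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class POSITIVE-vote probabilities (theta1, theta0)."""
    return _clamp(prop * acc), _clamp(prop * (1.0 - acc))


def _posteriors(votes: np.ndarray, prior: float, acc: np.ndarray,
                prop: np.ndarray) -> tuple[np.ndarray, float]:
    """E-step posteriors p(y=1 | votes) and the total log-likelihood."""
    v = votes.astype(float)
    theta1, theta0 = _vote_rates(acc, prop)
    log_p1 = v @ np.log(theta1) + (1.0 - v) @ np.log1p(-theta1)
    log_p0 = v @ np.log(theta0) + (1.0 - v) @ np.log1p(-theta0)
    joint = np.column_stack([log_p0 + np.log1p(-prior), log_p1 + np.log(prior)])
    ll = logsumexp(joint, axis=1)
    q = np.exp(joint[:, 1] - ll)
    return q, float(ll.sum())


def _clamp(x):
    return np.clip(x, EPS, 1 - EPS)


def fit_label_model(
    matrix: VoteMatrix,
    init: LabelModelParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> LabelModelParams:
    """Fit the generative model by expectation-maximization.

    ``init=None`` draws a random initialization (seeded): accuracies uniform
    in (0.6, 0.9) — above one half so EM settles into the basin where POSITIVE
    votes evidence the positive class — and prior uniform in (0.1, 0.4).
    Convergence: change in mean log-likelihood < ``tol``; parameters are
    clamped to [1e-3, 1 - 1e-3]. Non-convergence returns the last (best)
    iterate with ``converged=False``.
    """
    votes = matrix.votes
    n = len(matrix.note_ids)
    if n == 0 or not votes.any():
        raise ValueError("degenerate vote matrix: no non-abstain votes")
    rng = np.random.default_rng(seed)
    if init is None:
        init = LabelModelParams(
            class_prior=float(rng.uniform(0.1, 0.4)),
            accuracies=rng.uniform(0.6, 0.9, N_LFS),
            propensities=_clamp(np.maximum(votes.mean(axis=0), 2 * EPS)),
        )
    prior = float(_clamp(init.class_prior))
    acc = _clamp(np.asarray(init.accuracies, dtype=float))
    prop = _clamp(np.asarray(init.propensities, dtype=float))

    prev_ll = -np.inf
    converged = False
    it = 0
    v = votes.astype(float)
    for it in range(1, max_iter + 1):
        q, ll = _posteriors(votes, prior, acc, prop)
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        if it > 1 and abs(ll - prev_ll) / n < tol:
            converged = True
            break
        prev_ll = ll
        # M-step: prior from the mean posterior; per-class vote rates from
        # posterior-weighted counts, mapped back to (accuracy, propensity)
        prior = float(_clamp(q.mean()))
        theta1 = _clamp((v * q[:, None]).sum(axis=0) / max(q.sum(), EPS))
        theta0 = _clamp((v * (1 - q)[:, None]).sum(axis=0) / max((1 - q).sum(), EPS))
        prop = _clamp(theta1 + theta0)
        acc = _clamp(theta1 / (theta1 + theta0))
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations")
    _, final_ll = _posteriors(votes, prior, acc, prop)
    return LabelModelParams(prior, acc, prop, converged=converged,
                            n_iter=it, log_likelihood=final_ll)


def predict_proba(params: LabelModelParams, matrix: VoteMatrix) -> list[ProbabilisticLabel]:
    """Posterior probability of POSITIVE per note; deterministic given params."""
    q, _ = _posteriors(matrix.votes, params.class_prior,
                       _clamp(params.accuracies), _clamp(params.propensities))
    return [ProbabilisticLabel(nid, float(qi)) for nid, qi in zip(matrix.note_ids, q)]


def _f1(pred: np.ndarray, y: np.ndarray) -> float:
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    if tp == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 2 * p * r / (p + r)


def cv_select(
    candidates: Sequence[LabelModelParams],
    gold: Sequence[LabeledNote],
    matrix: VoteMatrix,
    k: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[LabelModelParams, pd.DataFrame]:
    """Choose the candidate with the best mean F1 over stratified k folds.

    Labels are hardened at ``threshold``. Folds with no positive gold notes
    are skipped with a warning. Ties break to the lowest candidate index.
    Returns (best candidate, per-candidate-per-fold F1 table).
    """
    if not candidates:
        raise ValueError("no candidate models")
    if len(gold) < k:
        raise ValueError(f"gold set of size {len(gold)} cannot form {k} folds")
    index = {nid: i for i, nid in enumerate(matrix.note_ids)}
    y = np.array([g.gold_label for g in gold])
    rows_idx = np.array([index[g.note_id] for g in gold])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = []
    means = []
    for ci, cand in enumerate(candidates):
        p = np.array([l.p_positive for l in predict_proba(cand, matrix)])
        pred = (p[rows_idx] >= threshold).astype(int)
        fold_f1s = []
        for fold, (_, test_idx) in enumerate(skf.split(rows_idx, y)):
            if y[test_idx].sum() == 0:
                warnings.warn(f"fold {fold} has no positive notes; skipped")
                continue
            f1 = _f1(pred[test_idx], y[test_idx])
            fold_f1s.append(f1)
            records.append({"candidate": ci, "fold": fold, "f1": f1})
        means.append(float(np.mean(fold_f1s)) if fold_f1s else 0.0)
    best = int(np.argmax(means))  # argmax takes the first (lowest index) on ties
    return candidates[best], pd.DataFrame(records)
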