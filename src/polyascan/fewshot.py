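"""Prototype-based few-shot classification over sequence embeddings.

A class prototype is the average of the mean-pooled embeddings of a handful
of labeled examples (two per class by default). A query is scored by its
cosine similarity to each prototype; a softmax over the two similarities
gives a pseudo-probability for the poly(A) class, and queries with
probability strictly above 0.5 are called positive.

The published similarity formula reads ``sim = 1 - cosine(q, p)``. Read with
``cosine`` as a *similarity* that inverts the decision rule, so the default
``convention="similarity"`` treats ``cosine`` as cosine distance (i.e. sim is
plain cosine similarity); ``convention="literal"`` applies the verbatim
formula for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import evaluation

CONVENTIONS = ("similarity", "literal")


@dataclass(frozen=True)
class PrototypePair:
    """Mean embeddings of the poly(A) and non-poly(A) support examples."""

    p_poly: np.ndarray
    p_non: np.ndarray

    def __post_init__(self) -> None:
        if self.p_poly.shape != self.p_non.shape or self.p_poly.ndim != 1:
            raise ValueError("prototypes must be 1-d vectors of equal dim")

    @property
    def dim(self) -> int:
        return self.p_poly.shape[0]


@dataclass(frozen=True)
class FewShotScore:
    sim_poly: float
    sim_non: float
    p: float
    label: int
    query: np.ndarray


def mean_pool(token_embeddings: np.ndarray) -> np.ndarray:
    """Average per-token embeddings (tokens x dim) into one vector."""
    m = np.asarray(token_embeddings, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("expected a non-empty tokens x dim matrix")
    return m.mean(axis=0)


def build_prototypes(
    pos_vecs: Sequence[np.ndarray], neg_vecs: Sequence[np.ndarray]
) -> PrototypePair:
    pos = np.asarray(pos_vecs, dtype=float)
    neg = np.asarray(neg_vecs, dtype=float)
    if pos.ndim != 2 or neg.ndim != 2 or pos.shape[1] != neg.shape[1]:
        raise ValueError("support vectors must share one embedding dim")
    return PrototypePair(pos.mean(axis=0), neg.mean(axis=0))


def _cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm vector has no cosine similarity")
    return float(np.dot(a, b) / (na * nb))


def prototype_score(
    q: np.ndarray,
    prototypes: PrototypePair,
    convention: str = "similarity",
) -> FewShotScore:
    """Softmax of the query's similarities to the two prototypes.

    ``p = exp(sim_poly) / (exp(sim_poly) + exp(sim_non))``; the predicted
    label is 1 iff ``p`` strictly exceeds 0.5.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    q = np.asarray(q, dtype=float)
    if q.shape != (prototypes.dim,):
        raise ValueError("query dim does not match prototypes")
    sim_poly = _cosine_similarity(q, prototypes.p_poly)
    sim_non = _cosine_similarity(q, prototypes.p_non)
    if convention == "literal":
        sim_poly, sim_non = 1.0 - sim_poly, 1.0 - sim_non
    # Numerically stable two-way softmax.
    p = float(1.0 / (1.0 + np.exp(sim_non - sim_poly)))
    return FewShotScore(sim_poly, sim_non, p, int(p > 0.5), q)


class PrototypeClassifier(ClassifierMixin, BaseEstimator):
    """Few-shot nearest-prototype classifier over fixed embeddings.

    ``fit`` draws ``n_shots`` support examples per class (without
    replacement, seeded) and averages their embeddings into one prototype
    per class; ``predict_proba`` is the softmax over cosine similarities to
    the two prototypes. The positive class is the larger label.

    Parameters
    ----------
    n_shots : int
        Support examples per class (default 2).
    convention : str
        ``"similarity"`` (default) or ``"literal"``; see module docstring.
    random_state : int, RandomState or None
        Controls which support examples are drawn.
    """

    def __init__(
        self,
        n_shots: int = 2,
        convention: str = "similarity",
        random_state: Optional[int] = None,
    ) -> None:
        self.n_shots = n_shots
        self.convention = convention
        self.random_state = random_state

    def fit(self, X, y) -> "PrototypeClassifier":
        X, y = check_X_y(X, y)
        if self.convention not in CONVENTIONS:
            raise ValueError(f"convention must be one of {CONVENTIONS}")
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError("exactly two classes required")
        rng = check_random_state(self.random_state)
        support: dict[int, np.ndarray] = {}
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if idx.shape[0] < self.n_shots:
                raise ValueError(
                    f"class {cls!r} has {idx.shape[0]} examples, "
                    f"need {self.n_shots}"
                )
            support[cls] = rng.choice(idx, size=self.n_shots, replace=False)
        self.classes_ = classes
        self.support_indices_ = support
        self.prototype_pair_ = build_prototypes(
            X[support[classes[1]]], X[support[classes[0]]]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "prototype_pair_")
        X = check_array(X)
        p_pos = np.array(
            [
                prototype_score(x, self.prototype_pair_, self.convention).p
                for x in X
            ]
        )
        return np.column_stack([1.0 - p_pos, p_pos])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p > 0.5, self.classes_[1], self.classes_[0])


@dataclass
class FewShotResult:
    """Per-repetition metrics and their means over the protocol."""

    per_rep: pd.DataFrame
    mean: dict[str, float]


def fewshot_evaluate(
    train_X,
    train_y,
    test_X,
    test_y,
    n_reps: int = 10,
    seed: int = 0,
    convention: str = "similarity",
) -> FewShotResult:
    """The repeated-prototype protocol: average metrics over ``n_reps`` draws.

    Each repetition fits a fresh :class:`PrototypeClassifier` on a new
    random 2+2 support draw from the training set and scores the full test
    set; accuracy, precision, recall, F1 and AUC are averaged over
    repetitions. Deterministic for a fixed seed.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    test_X = np.asarray(test_X, dtype=float)
    test_y = np.asarray(test_y)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        clf = PrototypeClassifier(
            convention=convention,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(train_X, train_y)
        p = clf.predict_proba(test_X)[:, 1]
        pred = (p > 0.5).astype(int)
        truth = (test_y == clf.classes_[1]).astype(int)
        counts = evaluation.ConfusionCounts(
            tp=int(np.sum((pred == 1) & (truth == 1))),
            fp=int(np.sum((pred == 1) & (truth == 0))),
            tn=int(np.sum((pred == 0) & (truth == 0))),
            fn=int(np.sum((pred == 0) & (truth == 1))),
        )
        report = evaluation.confusion_metrics(counts)
        rows.append(
            {
                "rep": rep,
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "auc": evaluation.auc(p, truth),
            }
        )
    per_rep = pd.DataFrame(rows).set_index("rep")
    mean = {k: float(v) for k, v in per_rep.mean().items()}
    return FewShotResult(per_rep=per_rep, mean=mean)
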