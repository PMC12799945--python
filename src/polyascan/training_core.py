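"""Training mathematics: warmup-cosine schedule, (weighted) cross-entropy,
token labeling, and a generic early-stopping harness.

These are pure functions; the actual model being optimized is pluggable
(the harness takes arbitrary train/eval callables), so the full fine-tuning
protocol — 3 epochs, batch 32, validation every 200 steps, patience 5 —
can be exercised with a scripted stand-in model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .genome_io import GenomicInterval

EPS = 1e-12
DEFAULT_WEIGHT_CAP = 1e4


def warmup_steps(
    n_epochs: int, n_train: int, batch: int, warmup_fraction: float = 0.1
) -> tuple[int, int]:
    """Return ``(t_warmup, t_total)``.

    ``t_total = n_epochs * ceil(n_train / batch)`` and the warmup is 10% of
    it, rounded to the nearest integer (round-half-even).
    """
    if n_epochs <= 0 or n_train <= 0 or batch <= 0:
        raise ValueError("n_epochs, n_train and batch must be positive")
    t_total = n_epochs * math.ceil(n_train / batch)
    return round(warmup_fraction * t_total), t_total


@dataclass(frozen=True)
class ScheduleParams:
    """Learning-rate schedule configuration.

    ``eta_base`` is the peak learning rate (default 1e-6); the rate ramps
    linearly from 0 over ``t_warmup`` steps and then cosine-anneals to 0 at
    ``t_total``.
    """

    eta_base: float = 1e-6
    t_warmup: int = 0
    t_total: int = 1
    n_epochs: int = 3
    batch: int = 32

    def __post_init__(self) -> None:
        if self.eta_base <= 0:
            raise ValueError("eta_base must be positive")
        if not 0 <= self.t_warmup <= self.t_total:
            raise ValueError("need 0 <= t_warmup <= t_total")

    @classmethod
    def from_dataset(
        cls,
        n_train: int,
        n_epochs: int = 3,
        batch: int = 32,
        eta_base: float = 1e-6,
    ) -> "ScheduleParams":
        tw, tt = warmup_steps(n_epochs, n_train, batch)
        return cls(
            eta_base=eta_base,
            t_warmup=tw,
            t_total=tt,
            n_epochs=n_epochs,
            batch=batch,
        )


def lr_at(t: int, params: ScheduleParams) -> float:
    """Learning rate at step ``t``: linear warmup, then cosine decay to 0.

    Both branches give ``eta_base`` at ``t = t_warmup`` (the decay branch is
    used there), so the schedule is continuous.
    """
    if not 0 <= t <= params.t_total:
        raise ValueError(f"step {t} outside [0, {params.t_total}]")
    if t < params.t_warmup:
        return params.eta_base * t / params.t_warmup
    if params.t_total == params.t_warmup:
        return params.eta_base
    frac = (t - params.t_warmup) / (params.t_total - params.t_warmup)
    return params.eta_base * 0.5 * (1.0 + math.cos(math.pi * frac))


def _as_prob_arrays(y, p) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if y.size == 0:
        raise ValueError("empty batch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return y, np.clip(p, EPS, 1.0 - EPS)


def bce_loss(y: Sequence[int], p: Sequence[float]) -> float:
    """Mean binary cross-entropy, with probabilities clipped to [eps, 1-eps]."""
    y, p = _as_prob_arrays(y, p)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class TokenLabeling:
    """Per-nucleotide binary labels plus (w_neg, w_pos) class weights."""

    labels: np.ndarray
    class_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.class_weights[0] <= 0 or self.class_weights[1] <= 0:
            raise ValueError("class weights must be positive")


def weighted_ce_loss(labeling: TokenLabeling, p: Sequence[float]) -> float:
    """Class-weighted cross-entropy over token positions.

    ``-(1/sum w) * sum w(y_i) * [y_i log p_i + (1-y_i) log(1-p_i)]`` with
    ``w(1) = w_pos`` up-weighting the rare cleavage positions. Reduces to
    :func:`bce_loss` at unit weights.
    """
    y, p = _as_prob_arrays(labeling.labels, p)
    w_neg, w_pos = labeling.class_weights
    w = np.where(y == 1, w_pos, w_neg)
    terms = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-np.sum(w * terms) / np.sum(w))


def build_token_labels(
    seq_interval: GenomicInterval,
    polya_sites: Sequence[GenomicInterval],
    weight_cap: float = DEFAULT_WEIGHT_CAP,
) -> TokenLabeling:
    """Binary label per base of an interval; 1 exactly at cleavage positions.

    ``w_pos`` defaults to the empirical negative/positive ratio of the
    interval, capped (and used as fallback when no positives exist).
    """
    labels = np.zeros(len(seq_interval), dtype=int)
    for site in polya_sites:
        if (
            site.chrom != seq_interval.chrom
            or site.start < seq_interval.start
            or site.end > seq_interval.end
        ):
            raise ValueError(f"site {site} outside interval {seq_interval}")
        labels[site.start - seq_interval.start : site.end - seq_interval.start] = 1
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    w_pos = min(n_neg / n_pos, weight_cap) if n_pos else weight_cap
    return TokenLabeling(labels, (1.0, max(w_pos, 1.0)))


@dataclass
class TrainingHistory:
    checks: list[dict] = field(default_factory=list)
    best_metric: Optional[float] = None
    best_step: Optional[int] = None
    stopped_early: bool = False
    steps_run: int = 0


def run_training(
    train_step: Callable[[int, float], None],
    eval_step: Callable[[int], float],
    params: ScheduleParams,
    patience: int = 5,
    check_interval: int = 200,
    minimize: bool = False,
) -> TrainingHistory:
    """Generic schedule-driven loop with periodic validation and early stop.

    ``train_step(t, lr)`` is called once per step; ``eval_step(t)`` every
    ``check_interval`` steps returns a validation metric (higher is better
    unless ``minimize``). Training stops once ``patience`` consecutive
    checks fail to improve on the best metric seen.
    """
    if patience <= 0 or check_interval <= 0:
        raise ValueError("patience and check_interval must be positive")
    history = TrainingHistory()
    bad_checks = 0
    for t in range(params.t_total):
        train_step(t, lr_at(t, params))
        history.steps_run = t + 1
        if (t + 1) % check_interval == 0:
            metric = float(eval_step(t))
            history.checks.append({"step": t + 1, "metric": metric})
            improved = history.best_metric is None or (
                metric < history.best_metric
                if minimize
                else metric > history.best_metric
            )
            if improved:
                history.best_metric = metric
                history.best_step = t + 1
                bad_checks = 0
            else:
                bad_checks += 1
                if bad_checks >= patience:
                    history.stopped_early = True
                    break
    return history
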