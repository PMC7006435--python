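"""Losses, Adagrad optimization, and the two-phase training schedule.

Training minimizes the length-normalized negative log-likelihood of the
reference assessment under teacher forcing.  The coverage phase adds
λ·Loss_cov, where Loss_cov sums min(β_ij, c_ij) over decoding steps and
source positions — a penalty that is only incurred when the decoder
re-attends to positions it has already covered.  Following the published
recipe, the model is first trained to convergence on the NLL alone, and
the coverage term (with its extra attention weight) is added in a second
fine-tuning phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .model import (
    AssessmentModel,
    Batch,
    ModelConfig,
    StepDistribution,
    add_coverage_parameters,
    make_batch,
)
from .notes_io import EncodedExample, Vocabulary

__all__ = [
    "TrainConfig",
    "TrainResult",
    "Adagrad",
    "nll_loss",
    "coverage_loss",
    "combined_loss",
    "sequence_losses",
    "enable_coverage",
    "train",
]

_PROB_FLOOR = 1e-12

PHASES = ("pretrain", "coverage_finetune")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The Adagrad learning rate 0.12 and initial accumulator 0.11 and the
    coverage weight λ=0.2 are the published values; batch size, gradient
    clipping and patience are desk-scale choices.
    """

    learning_rate: float = 0.12
    adagrad_init_accumulator: float = 0.11
    lambda_coverage: float = 0.2
    batch_size: int = 16
    grad_clip_norm: float = 2.0
    patience: int = 3
    max_epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lambda_coverage < 0:
            raise ValueError("lambda_coverage must be nonnegative")


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def nll_loss(steps: Sequence[StepDistribution], target_ids: np.ndarray, target_mask: np.ndarray) -> Tensor:
    """−Σ_i log p^i(y_i) / l per sequence, averaged over the batch.

    Probabilities are read off the final (extended-vocabulary)
    distribution at the gold extended id.  A zero probability is floored
    at a tiny epsilon with a warning rather than producing −inf.
    """
    B, L = target_ids.shape
    lengths = target_mask.sum(axis=1)
    if np.any(lengths == 0):
        raise ValueError("batch contains an empty target sequence")
    total = Tensor(np.zeros(B))
    floored = False
    width = steps[0].p_final.shape[1]
    # without the copy mechanism the output has no extended slots:
    # OOV targets fall back to UNK (reserved id 1)
    target_ids = np.where(target_ids >= width, 1, target_ids)
    for t in range(L):
        p_t = ad.take_per_row(steps[t].p_final, target_ids[:, t])
        if np.any((p_t.data <= _PROB_FLOOR) & (target_mask[:, t] > 0)):
            floored = True
        logp = ad.log(ad.clip_min(p_t, _PROB_FLOOR))
        total = total + logp * Tensor(target_mask[:, t])
    if floored:
        warnings.warn("target probability floored at epsilon (log(0) guard)", RuntimeWarning)
    per_seq = total * Tensor(-1.0 / lengths)
    return ad.sum_(per_seq) * Tensor(1.0 / B)


def coverage_loss(
    betas: Sequence[Tensor],
    coverages: Sequence[Tensor],
    step_mask: np.ndarray | None = None,
) -> Tensor:
    """Σ_k Σ_j min(β_kj, c_kj), summed per sequence, batch-averaged.

    Step 1 contributes nothing (its coverage is all zero), so the
    per-sequence value lies in [0, l−1], reaching l−1 only when the
    attention distribution is identical at every step.
    """
    if len(betas) != len(coverages):
        raise ValueError("betas and coverages must align per step")
    B = betas[0].shape[0]
    total = Tensor(np.zeros(B))
    for t, (beta, cov) in enumerate(zip(betas, coverages)):
        if np.any(beta.data < 0) or np.any(cov.data < 0):
            raise ValueError("attention and coverage must be nonnegative")
        step = ad.sum_(ad.minimum(beta, cov), axis=1)
        if step_mask is not None:
            step = step * Tensor(step_mask[:, t])
        total = total + step
    return ad.sum_(total) * Tensor(1.0 / B)


def combined_loss(nll: Tensor, cov: Tensor, lam: float) -> Tensor:
    """Loss = Loss_nll + λ·Loss_cov."""
    return nll + Tensor(lam) * cov


def sequence_losses(model: AssessmentModel, batch: Batch, lam: float, phase: str):
    """Forward pass plus the phase's loss terms.

    Returns (loss, nll, cov) tensors; ``cov`` is None outside the
    coverage phase.
    """
    steps = model.forward(batch)
    nll = nll_loss(steps, batch.target_ids, batch.target_mask)
    if phase == "coverage_finetune":
        covs = _coverage_sequence(steps, batch)
        cov = coverage_loss([s.source_attention for s in steps], covs, batch.target_mask)
        return combined_loss(nll, cov, lam), nll, cov
    return nll, nll, None


def _coverage_sequence(steps, batch: Batch):
    """Coverage vectors c_i = Σ_{k<i} β_k aligned with the steps."""
    if steps[0].coverage is not None:
        return [s.coverage for s in steps]
    B, n = batch.src_mask.shape
    covs = [Tensor(np.zeros((B, n)))]
    for s in steps[:-1]:
        covs.append(covs[-1] + s.source_attention)
    return covs


# ---------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------

class Adagrad:
    """Adagrad with a configurable initial accumulator value.

    One update moves a parameter by −lr·g/√(acc₀ + Σ g²) with the
    squared gradient added to the accumulator before the step.
    """

    def __init__(self, params: dict[str, Tensor], lr: float, initial_accumulator: float, clip_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.clip_norm = clip_norm
        self.acc = {k: np.full_like(v.data, initial_accumulator) for k, v in params.items()}

    def step(self) -> None:
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if self.clip_norm is not None and grads:
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                grads = {k: g * scale for k, g in grads.items()}
        for k, g in grads.items():
            self.acc[k] += g * g
            self.params[k].data -= self.lr * g / np.sqrt(self.acc[k])

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def register(self, name: str, param: Tensor, initial_accumulator: float) -> None:
        """Track a parameter added after construction (coverage weight)."""
        self.params[name] = param
        self.acc[name] = np.full_like(param.data, initial_accumulator)


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

@dataclass
class TrainResult:
    model: AssessmentModel
    history: list[dict] = field(default_factory=list)
    best_val_loss: float = float("inf")
    epochs_run: int = 0


def enable_coverage(model: AssessmentModel) -> AssessmentModel:
    """Convert a pretrained model into its coverage variant.

    The coverage attention weight is added at zero, so the converted
    model initially produces exactly the pretrained distributions.
    """
    if not model.config.use_copy:
        raise ValueError("coverage fine-tuning requires a copy model")
    cfg = replace(model.config, use_coverage=True)
    out = AssessmentModel(cfg, {k: Tensor(v.data.copy(), requires_grad=True) for k, v in model.params.items()})
    add_coverage_parameters(out.params, cfg)
    return out


def _batches(examples, vocab, batch_size, rng=None):
    idx = np.arange(len(examples))
    if rng is not None:
        rng.shuffle(idx)
    for start in range(0, len(idx), batch_size):
        chosen = [examples[i] for i in idx[start : start + batch_size]]
        yield make_batch(chosen, vocab)


def evaluate_loss(model: AssessmentModel, examples, vocab: Vocabulary, config: TrainConfig, phase: str) -> float:
    total, count = 0.0, 0
    for batch in _batches(examples, vocab, config.batch_size):
        loss, _, _ = sequence_losses(model, batch, config.lambda_coverage, phase)
        total += float(loss.data) * batch.size
        count += batch.size
    return total / count


def train(
    model: AssessmentModel,
    train_examples: Sequence[EncodedExample],
    dev_examples: Sequence[EncodedExample],
    vocab: Vocabulary,
    config: TrainConfig,
    phase: str = "pretrain",
) -> TrainResult:
    """Optimize with Adagrad and stop early on the validation loss.

    ``phase`` is ``pretrain`` (NLL only) or ``coverage_finetune`` (NLL +
    λ·coverage; requires a model with coverage enabled, normally built
    from a pretrained checkpoint via :func:`enable_coverage`).  The best-
    validation parameters are restored before returning.  Validation runs
    once per epoch; training stops when it has failed to improve
    ``patience`` + 1 times in a row or after ``max_epochs`` epochs.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if phase == "coverage_finetune" and not model.config.use_coverage:
        raise ValueError("coverage_finetune requires a model with use_coverage enabled")
    if not train_examples or not dev_examples:
        raise ValueError("train and dev sets must be non-empty")

    opt = Adagrad(
        model.params,
        lr=config.learning_rate,
        initial_accumulator=config.adagrad_init_accumulator,
        clip_norm=config.grad_clip_norm,
    )
    rng = np.random.default_rng(config.seed)
    best = {k: v.data.copy() for k, v in model.params.items()}
    best_val = float("inf")
    bad_evals = 0
    history: list[dict] = []
    epochs_run = 0

    for epoch in range(config.max_epochs):
        epochs_run = epoch + 1
        train_total, train_count = 0.0, 0
        for batch in _batches(train_examples, vocab, config.batch_size, rng):
            opt.zero_grad()
            loss, _, _ = sequence_losses(model, batch, config.lambda_coverage, phase)
            loss.backward()
            opt.step()
            train_total += float(loss.data) * batch.size
            train_count += batch.size
        val = evaluate_loss(model, dev_examples, vocab, config, phase)
        history.append(
            {"epoch": epoch, "train_loss": train_total / train_count, "val_loss": val, "phase": phase}
        )
        if val < best_val:
            best_val = val
            best = {k: v.data.copy() for k, v in model.params.items()}
            bad_evals = 0
        else:
            bad_evals += 1
            # patience=0 stops at the first non-improving check
            if bad_evals >= max(config.patience, 1):
                break

    for k, v in model.params.items():
        v.data = best[k]
    return TrainResult(model=model, history=history, best_val_loss=best_val, epochs_run=epochs_run)
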