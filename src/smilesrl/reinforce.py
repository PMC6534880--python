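"""Policy-gradient fine-tuning of the SMILES generator with an exploration
network.

Each epoch: sample a batch where, at every step, a uniform draw u < epsilon
delegates token choice to the frozen exploration network G_phi (both
networks consume the same realized token history); deduplicate the batch by
canonical SMILES; score every unique molecule with the QSAR predictor
(invalid molecules get reward 0); take one REINFORCE step ascending

    J(theta) = sum_t log G_theta(y_t | y_1:t-1) * (Q(y_1:T) - beta)

by minimizing the advantage-weighted negative log likelihood.  The gradient
flows through G_theta's log-probabilities of all realized tokens, including
exploration-chosen steps.  G_phi is never updated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from smilesrl.generator import GeneratorModel, SampleBatch, TrainingLog
from smilesrl.nn import Adam
from smilesrl.qsar import PredictorModel, compute_ecfp6
from smilesrl.vocab import canonical_smiles, decode


@dataclass
class RLConfig:
    """Hyperparameters of the RL loop.

    Training is documented unstable for epsilon > 0.25 or beta > 0.1; a
    warning is emitted but the values are not forbidden.
    """

    epsilon: float = 0.1
    beta: float = 0.0
    epochs: int = 200
    batch_size: int = 500
    seed: int = 0
    desired_threshold: float = 0.5
    lr: float = 1e-3
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.epsilon > 0.25 or self.beta > 0.1:
            warnings.warn(
                "training is documented unstable for epsilon > 0.25 or "
                "beta > 0.1", stacklevel=2)


@dataclass
class RewardBatch:
    """Per-sequence rewards R = Q(y_1:T) in [0,1] and advantages R - beta."""

    rewards: np.ndarray
    advantages: np.ndarray
    beta: float = 0.0


def sample_with_exploration(g_theta: GeneratorModel, g_phi: GeneratorModel,
                            epsilon: float, n: int,
                            max_steps: int | None = None,
                            seed: int = 0) -> SampleBatch:
    """Sample ``n`` sequences mixing the two policies at rate ``epsilon``.

    At each step, for each live sequence, u ~ Uniform[0,1] is drawn; if
    u < epsilon the token comes from G_phi's distribution, otherwise from
    G_theta's.  Both networks are advanced on the realized token.  The
    limits epsilon = 0 and epsilon = 1 reduce exactly (same random stream)
    to single-network sampling.
    """
    if g_theta.vocab.index != g_phi.vocab.index:
        raise ValueError("the two generators must share one vocabulary")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    vocab = g_theta.vocab
    if max_steps is None:
        max_steps = g_theta.max_steps
    pure = epsilon in (0.0, 1.0)
    rng = np.random.default_rng(seed)
    tokens = np.full(n, vocab.go, dtype=np.int64)
    h_theta = g_theta.net.init_hidden(n)
    h_phi = g_phi.net.init_hidden(n)
    alive = np.ones(n, dtype=bool)
    chosen_steps: list[np.ndarray] = []
    explore_steps: list[np.ndarray] = []
    for _ in range(max_steps):
        if pure:
            use_phi = np.full(n, epsilon == 1.0)
        else:
            use_phi = rng.random(n) < epsilon
        need_theta = not use_phi.all()
        need_phi = use_phi.any()
        if need_theta:
            probs_theta, h_theta = g_theta.net.step_probs(tokens, h_theta)
        else:
            _, h_theta = g_theta.net.step(tokens, h_theta)
            probs_theta = None
        if need_phi:
            probs_phi, h_phi = g_phi.net.step_probs(tokens, h_phi)
        else:
            _, h_phi = g_phi.net.step(tokens, h_phi)
            probs_phi = None
        if probs_theta is None:
            probs = probs_phi
        elif probs_phi is None:
            probs = probs_theta
        else:
            probs = np.where(use_phi[:, None], probs_phi, probs_theta)
        u = rng.random(n)
        chosen = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        chosen = np.minimum(chosen, vocab.size - 1)
        chosen = np.where(alive, chosen, vocab.eos)
        chosen_steps.append(chosen)
        explore_steps.append(use_phi & alive)
        alive = alive & (chosen != vocab.eos)
        if not alive.any():
            break
        tokens = chosen
    mat = np.stack(chosen_steps, axis=1)
    expl = np.stack(explore_steps, axis=1)
    sequences, smiles, provenance = [], [], []
    for i in range(n):
        row = mat[i]
        eos_pos = np.nonzero(row == vocab.eos)[0]
        end = int(eos_pos[0]) + 1 if eos_pos.size else len(row)
        sequences.append(tuple(int(v) for v in row[:end]))
        smiles.append(decode(row[:end], vocab))
        provenance.append(expl[i, :end].copy())
    return SampleBatch(sequences, smiles, provenance)


def _dedup_key(smiles: str) -> str:
    canon = canonical_smiles(smiles)
    return canon if canon is not None else f"\x00invalid:{smiles}"


def dedup_epoch(batch: SampleBatch) -> SampleBatch:
    """One representative per canonical SMILES (invalid entries keyed by
    their raw string); first-occurrence order preserved."""
    seen: set[str] = set()
    sequences, smiles, provenance = [], [], []
    for i, s in enumerate(batch.smiles):
        key = _dedup_key(s)
        if key in seen:
            continue
        seen.add(key)
        sequences.append(batch.sequences[i])
        smiles.append(s)
        if batch.provenance is not None:
            provenance.append(batch.provenance[i])
    return SampleBatch(sequences, smiles,
                       provenance if batch.provenance is not None else None)


def score_batch(batch: SampleBatch, predictor: PredictorModel,
                beta: float = 0.0) -> RewardBatch:
    """Reward R = Q(fingerprint) for valid molecules, 0 for invalid ones;
    advantage = R - beta."""
    rewards = np.zeros(len(batch))
    valid_idx = [i for i, ok in enumerate(batch.validity) if ok]
    if valid_idx:
        fps = [compute_ecfp6(batch.smiles[i]) for i in valid_idx]
        q = predictor.predict_q(fps)
        for j, i in enumerate(valid_idx):
            rewards[i] = q[j]
    return RewardBatch(rewards=rewards, advantages=rewards - beta, beta=beta)


def _batch_arrays(model: GeneratorModel, sequences: list[tuple[int, ...]]):
    """Teacher arrays for realized sequences: GO + y_1:T-1 -> y_1:T."""
    vocab = model.vocab
    B = len(sequences)
    T = max(len(s) for s in sequences)
    inputs = np.full((B, T), vocab.eos, dtype=np.int64)
    targets = np.full((B, T), vocab.eos, dtype=np.int64)
    mask = np.zeros((B, T), dtype=np.float64)
    for i, seq in enumerate(sequences):
        L = len(seq)
        inputs[i, 0] = vocab.go
        inputs[i, 1:L] = seq[:-1]
        targets[i, :L] = seq
        mask[i, :L] = 1.0
    return inputs, targets, mask


def policy_gradient_objective(model: GeneratorModel, batch: SampleBatch,
                              rewards: RewardBatch,
                              compute_grads: bool = True):
    """Objective (1/B) sum_b (beta - Q_b) * log G_theta(y_b) and gradients.

    Minimizing it ascends J(theta).  Returns ``(objective, grads)``.
    """
    if len(batch) != len(rewards.advantages):
        raise ValueError("rewards not aligned with batch")
    inputs, targets, mask = _batch_arrays(model, batch.sequences)
    weights = rewards.advantages / len(batch)
    obj, _, grads = model.net.loss_and_grads(inputs, targets, mask,
                                             seq_weights=weights,
                                             compute_grads=compute_grads)
    return obj, grads


def policy_gradient_step(model: GeneratorModel, batch: SampleBatch,
                         rewards: RewardBatch,
                         optimizer: Adam | None = None,
                         lr: float = 1e-3) -> GeneratorModel:
    """One REINFORCE update of G_theta in place; returns the model."""
    if model.frozen:
        raise ValueError("cannot update a frozen model")
    if optimizer is None:
        optimizer = Adam(model.net.params, lr=lr)
    _, grads = policy_gradient_objective(model, batch, rewards)
    optimizer.step(grads)
    return model


def train_rl(g_theta: GeneratorModel, g_phi: GeneratorModel,
             predictor: PredictorModel, config: RLConfig):
    """Run the RL loop; returns ``(trained G_theta copy, TrainingLog)``.

    G_phi is used only for sampling and is bit-identical before and after.
    The log records, per epoch, the mean reward of the deduplicated batch
    and the valid / desired / unique percentages of the raw batch.
    """
    if predictor is None:
        raise ValueError("a trained predictor is required")
    if not g_phi.frozen:
        g_phi = g_phi.copy(frozen=True)
    model = g_theta.copy(frozen=False)
    phi_before = g_phi.net.param_vector().copy()
    opt = Adam(model.net.params, lr=config.lr)
    log = TrainingLog()
    rng = np.random.default_rng(config.seed)
    for epoch in range(config.epochs):
        batch = sample_with_exploration(
            model, g_phi, config.epsilon, config.batch_size,
            max_steps=config.max_steps, seed=int(rng.integers(2 ** 31)))
        unique = dedup_epoch(batch)
        scored = score_batch(unique, predictor, beta=config.beta)
        policy_gradient_step(model, unique, scored, optimizer=opt)

        key_q = {_dedup_key(s): q for s, q in zip(unique.smiles, scored.rewards)}
        raw_q = np.array([key_q[_dedup_key(s)] for s in batch.smiles])
        valid = np.array(batch.validity)
        n = len(batch)
        log.append(
            epoch,
            loss=float("nan"),
            valid_pct=100.0 * valid.sum() / n,
            mean_reward=float(scored.rewards.mean()),
            desired_pct=100.0 * float(
                (valid & (raw_q > config.desired_threshold)).sum()) / n,
            unique_pct=100.0 * len(unique) / n,
        )
    assert np.array_equal(g_phi.net.param_vector(), phi_before), \
        "exploration network changed during training"
    return model, log
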