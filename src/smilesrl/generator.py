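"""Recurrent SMILES policy: embedding + stacked GRU + softmax over the
vocabulary, with maximum-likelihood pre-training / fine-tuning (teacher
forcing, GO prepended to inputs, EOS appended to targets) and autoregressive
multinomial sampling capped at ``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smilesrl.nn import Adam, GRUNetwork
from smilesrl.vocab import (
    DEFAULT_MAX_STEPS,
    Vocabulary,
    decode,
    is_valid_smiles,
    tokenize_symbols,
)


@dataclass
class TrainingLog:
    """Per-epoch training trace: NLL loss, valid-SMILES %, mean reward."""

    epochs: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    valid_pct: list[float] = field(default_factory=list)
    mean_reward: list[float] = field(default_factory=list)
    desired_pct: list[float] = field(default_factory=list)
    unique_pct: list[float] = field(default_factory=list)

    def append(self, epoch: int, loss: float = float("nan"),
               valid_pct: float = float("nan"),
               mean_reward: float = float("nan"),
               desired_pct: float = float("nan"),
               unique_pct: float = float("nan")) -> None:
        self.epochs.append(epoch)
        self.loss.append(loss)
        self.valid_pct.append(valid_pct)
        self.mean_reward.append(mean_reward)
        self.desired_pct.append(desired_pct)
        self.unique_pct.append(unique_pct)

    def to_tsv(self) -> str:
        lines = ["epoch\tloss\tvalid_pct\tmean_reward\tdesired_pct\tunique_pct"]
        for e, lo, v, r, d, u in zip(self.epochs, self.loss, self.valid_pct,
                                     self.mean_reward, self.desired_pct,
                                     self.unique_pct):
            lines.append(f"{e}\t{lo:.6f}\t{v:.2f}\t{r:.6f}\t{d:.2f}\t{u:.2f}")
        return "\n".join(lines) + "\n"


@dataclass
class SampleBatch:
    """Sampled sequences with decoded SMILES and optional step provenance.

    ``sequences`` hold realized token indices per step, ending with EOS when
    it was drawn (sequences hitting max_steps keep no EOS).  ``provenance``
    marks, per step, whether the exploration network chose the token.
    """

    sequences: list[tuple[int, ...]]
    smiles: list[str]
    provenance: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def validity(self) -> list[bool]:
        return [is_valid_smiles(s) for s in self.smiles]


class GeneratorModel:
    """A GRU policy over a SMILES vocabulary; trainable (G_theta) or frozen
    (exploration network G_phi)."""

    def __init__(self, vocab: Vocabulary, embed_dim: int = 128,
                 hidden_dim: int = 512, n_layers: int = 3,
                 max_steps: int = DEFAULT_MAX_STEPS, seed: int = 0,
                 frozen: bool = False, net: GRUNetwork | None = None):
        self.vocab = vocab
        self.max_steps = max_steps
        self.frozen = frozen
        if net is None:
            net = GRUNetwork(vocab.size, embed_dim, hidden_dim, n_layers,
                             rng=np.random.default_rng(seed))
        self.net = net

    # -- persistence ---------------------------------------------------

    def copy(self, frozen: bool | None = None) -> "GeneratorModel":
        return GeneratorModel(self.vocab, max_steps=self.max_steps,
                              frozen=self.frozen if frozen is None else frozen,
                              net=self.net.copy())

    def save(self, path: str) -> None:
        meta = dict(
            vocab="\n".join(t.symbol for t in self.vocab.tokens),
            max_steps=self.max_steps,
            embed_dim=self.net.embed_dim,
            hidden_dim=self.net.hidden_dim,
            n_layers=self.net.n_layers,
        )
        np.savez(path, __meta_vocab=np.array(meta["vocab"]),
                 __meta_dims=np.array([meta["max_steps"], meta["embed_dim"],
                                       meta["hidden_dim"], meta["n_layers"]]),
                 **self.net.params)

    @classmethod
    def load(cls, path: str) -> "GeneratorModel":
        data = np.load(path, allow_pickle=False)
        vocab = Vocabulary.from_lines(str(data["__meta_vocab"]))
        max_steps, embed_dim, hidden_dim, n_layers = (
            int(v) for v in data["__meta_dims"])
        net = GRUNetwork(vocab.size, embed_dim, hidden_dim, n_layers)
        for k in net.params:
            net.params[k] = np.array(data[k])
        return cls(vocab, max_steps=max_steps, net=net)

    def param_hash(self) -> int:
        return hash(self.net.param_vector().tobytes())

    # -- encoding helpers ----------------------------------------------

    def _encode_corpus(self, corpus: list[str]) -> list[np.ndarray]:
        """Token-index arrays (without GO/EOS); raises before training on
        any entry that fails to encode."""
        encoded = []
        for smiles in corpus:
            idx = []
            for sym in tokenize_symbols(smiles):
                if sym not in self.vocab:
                    raise KeyError(
                        f"token {sym!r} of corpus entry {smiles!r} not in vocabulary")
                idx.append(self.vocab.index[sym])
            encoded.append(np.array(idx, dtype=np.int64))
        return encoded

    def _teacher_arrays(self, encoded: list[np.ndarray]):
        """Right-padded (inputs, targets, mask): GO + tokens -> tokens + EOS."""
        B = len(encoded)
        T = max(len(e) for e in encoded) + 1  # +1 for the EOS target
        inputs = np.full((B, T), self.vocab.eos, dtype=np.int64)
        targets = np.full((B, T), self.vocab.eos, dtype=np.int64)
        mask = np.zeros((B, T), dtype=np.float64)
        for i, e in enumerate(encoded):
            L = len(e)
            inputs[i, 0] = self.vocab.go
            inputs[i, 1:L + 1] = e
            targets[i, :L] = e
            targets[i, L] = self.vocab.eos
            mask[i, :L + 1] = 1.0
        return inputs, targets, mask

    # -- sampling ------------------------------------------------------

    def sample(self, n: int, max_steps: int | None = None,
               seed: int = 0) -> SampleBatch:
        """Draw ``n`` sequences autoregressively from GO by multinomial
        sampling; stops at EOS or ``max_steps``."""
        if n < 1:
            raise ValueError("n must be >= 1")
        max_steps = self.max_steps if max_steps is None else max_steps
        rng = np.random.default_rng(seed)
        tokens = np.full(n, self.vocab.go, dtype=np.int64)
        hidden = self.net.init_hidden(n)
        alive = np.ones(n, dtype=bool)
        chosen_steps: list[np.ndarray] = []
        for _ in range(max_steps):
            probs, hidden = self.net.step_probs(tokens, hidden)
            u = rng.random(n)
            chosen = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            chosen = np.minimum(chosen, self.vocab.size - 1)
            chosen = np.where(alive, chosen, self.vocab.eos)
            chosen_steps.append(chosen)
            alive = alive & (chosen != self.vocab.eos)
            if not alive.any():
                break
            tokens = chosen
        mat = np.stack(chosen_steps, axis=1)
        sequences, smiles = [], []
        for i in range(n):
            row = mat[i]
            eos_pos = np.nonzero(row == self.vocab.eos)[0]
            end = int(eos_pos[0]) + 1 if eos_pos.size else len(row)
            seq = tuple(int(v) for v in row[:end])
            sequences.append(seq)
            smiles.append(decode(seq, self.vocab))
        return SampleBatch(sequences, smiles)

    def valid_rate(self, n: int = 1000, seed: int = 0) -> float:
        """% of ``n`` sampled sequences that parse as molecules."""
        batch = self.sample(n, seed=seed)
        return 100.0 * sum(batch.validity) / n

    # -- likelihoods ---------------------------------------------------

    def sequence_log_likelihood(self, smiles: str) -> float:
        """Sum over steps of log G(y_t | y_1:t-1), EOS step included."""
        encoded = self._encode_corpus([smiles])
        inputs, targets, mask = self._teacher_arrays(encoded)
        return float(self.net.sequence_log_probs(inputs, targets, mask)[0])

    def batch_nll(self, corpus: list[str]) -> float:
        """Mean per-sequence negative log likelihood of a corpus."""
        encoded = self._encode_corpus(corpus)
        inputs, targets, mask = self._teacher_arrays(encoded)
        obj, _, _ = self.net.loss_and_grads(inputs, targets, mask,
                                            compute_grads=False)
        return obj


def _assert_trainable(model: GeneratorModel) -> None:
    if model.frozen:
        raise ValueError("model is frozen; training operations are forbidden")


def _train_mle(model: GeneratorModel, corpus: list[str], epochs: int,
               lr: float, batch_size: int, seed: int,
               valid_sample_size: int) -> TrainingLog:
    _assert_trainable(model)
    if not corpus:
        raise ValueError("corpus is empty")
    encoded = model._encode_corpus(corpus)  # fails fast on OOV
    rng = np.random.default_rng(seed)
    opt = Adam(model.net.params, lr=lr)
    log = TrainingLog()
    order = np.arange(len(encoded))
    for epoch in range(epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), batch_size):
            batch = [encoded[i] for i in order[start:start + batch_size]]
            inputs, targets, mask = model._teacher_arrays(batch)
            obj, _, grads = model.net.loss_and_grads(inputs, targets, mask)
            opt.step(grads)
            losses.append(obj)
        valid = float("nan")
        if valid_sample_size > 0:
            valid = model.valid_rate(valid_sample_size,
                                     seed=int(rng.integers(2 ** 31)))
        log.append(epoch, loss=float(np.mean(losses)), valid_pct=valid)
    return log


def pretrain(corpus: list[str], vocab: Vocabulary, *, epochs: int,
             lr: float = 1e-3, batch_size: int = 500, embed_dim: int = 128,
             hidden_dim: int = 512, n_layers: int = 3,
             max_steps: int = DEFAULT_MAX_STEPS, seed: int = 0,
             valid_sample_size: int = 1000):
    """Maximum-likelihood pre-training from scratch on ``corpus``.

    Returns ``(model, log)``; the per-epoch log records the mean
    per-sequence NLL and the valid-SMILES percentage of a fresh sample.
    """
    model = GeneratorModel(vocab, embed_dim=embed_dim, hidden_dim=hidden_dim,
                           n_layers=n_layers, max_steps=max_steps, seed=seed)
    log = _train_mle(model, corpus, epochs, lr, batch_size, seed + 1,
                     valid_sample_size)
    return model, log


def finetune(model: GeneratorModel, target_corpus: list[str], *, epochs: int,
             lr: float = 1e-3, batch_size: int = 500, seed: int = 0,
             valid_sample_size: int = 1000):
    """Continue MLE training from ``model`` on a target corpus.

    The input model is left untouched; a new model is returned.  Raises if
    the target corpus contains tokens outside the model vocabulary.
    """
    _assert_trainable(model)
    tuned = model.copy(frozen=False)
    log = _train_mle(tuned, target_corpus, epochs, lr, batch_size, seed + 1,
                     valid_sample_size)
    return tuned, log
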