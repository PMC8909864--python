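"""Character-level SMILES generator: two LSTM layers, dropout, dense softmax.

The model is trained next-character style: for an encoded sequence
``G c1 c2 ... cn E`` the inputs are positions ``0..L-2`` and the targets
positions ``1..L-1``, so the network learns P(next char | prefix).  Loss is
categorical cross-entropy (nats) averaged over unmasked positions; padding
after ``E`` is masked out of both loss and accuracy.

Per-epoch diagnostics mirror common practice for SMILES language models:
validation log-loss, next-token top-1 accuracy, and a 1-D Wasserstein
distance between the token-frequency distribution of a small seeded sample
from the model and that of the validation corpus (tokens ordered by
vocabulary index).  The Wasserstein number is a convergence diagnostic, not
a calibrated quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .codec import Vocabulary, encode_indices, CodecError, SENTINELS
from .nn import LSTMLayer, DenseSoftmax, Adam, masked_ce_and_acc


class GeneratorError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the production settings (256-unit LSTMs, dropout 0.3,
    batch 512, 80/20 split); tests use smaller widths via the same fields.
    """

    lstm_units: int = 256
    n_lstm: int = 2
    dropout_rate: float = 0.3
    batch_size: int = 512
    epochs: int = 100
    val_fraction: float = 0.2
    seed: int = 0
    learning_rate: float = 1e-3
    diag_samples: int = 64  # 0 disables the Wasserstein diagnostic
    diag_max_len: int = 80

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise GeneratorError("val_fraction must be in (0, 1)")
        if self.lstm_units < 1:
            raise GeneratorError("lstm_units must be >= 1")
        if not (0.0 < self.dropout_rate < 1.0):
            raise GeneratorError("dropout_rate must be in (0, 1)")
        if self.n_lstm != 2:
            raise GeneratorError("architecture is fixed at two LSTM layers")


def count_trainable_params(config: ModelConfig, V: int) -> int:
    """Closed-form trainable-parameter count of the four-layer stack.

    Each LSTM with I inputs and U units holds 4*(U*(I+U)+U) parameters;
    dropout holds none; the dense softmax holds U*V+V.  At U=256, V=29 the
    total is 825,629.
    """
    if V < 1:
        raise GeneratorError("vocabulary size must be >= 1")
    U = config.lstm_units
    lstm1 = 4 * (U * (V + U) + U)
    lstm2 = 4 * (U * (U + U) + U)
    dense = U * V + V
    return lstm1 + lstm2 + dense


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    train_acc: float
    val_acc: float
    log_loss: float
    wasserstein: float
    checkpoint: str = ""


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    # corpus indices of the seeded 80/20 split, for eval-mode re-measurement
    train_indices: list[int] = field(default_factory=list)
    val_indices: list[int] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


class GeneratorModel:
    """The generator network plus its vocabulary and per-layer freeze flags."""

    def __init__(self, vocab: Vocabulary, config: ModelConfig):
        if len(vocab) < 3:
            raise GeneratorError("vocabulary must contain sentinels plus chemistry tokens")
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        U, V = config.lstm_units, len(vocab)
        self.lstm1 = LSTMLayer.init(rng, V, U)
        self.lstm2 = LSTMLayer.init(rng, U, U)
        self.dense = DenseSoftmax.init(rng, U, V)

    # -- parameter bookkeeping -------------------------------------------------

    @property
    def layers(self):
        return [self.lstm1, self.lstm2, self.dense]

    @property
    def layer_trainable(self) -> dict[str, bool]:
        return {
            "lstm_1": self.lstm1.trainable,
            "dropout": False,
            "lstm_2": self.lstm2.trainable,
            "dense": self.dense.trainable,
        }

    @property
    def trainable_param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers if layer.trainable)

    def trainable_params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            if layer.trainable:
                out.extend(layer.params())
        return out

    def copy(self) -> "GeneratorModel":
        from dataclasses import replace

        clone = GeneratorModel.__new__(GeneratorModel)
        clone.vocab = self.vocab
        clone.config = replace(self.config)
        clone.lstm1 = LSTMLayer(self.lstm1.W.copy(), self.lstm1.R.copy(),
                                self.lstm1.b.copy(), self.lstm1.trainable)
        clone.lstm2 = LSTMLayer(self.lstm2.W.copy(), self.lstm2.R.copy(),
                                self.lstm2.b.copy(), self.lstm2.trainable)
        clone.dense = DenseSoftmax(self.dense.W.copy(), self.dense.b.copy(),
                                   self.dense.trainable)
        return clone

    # -- forward / backward ----------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        H1 = self.lstm1.forward(X, train=train)
        if train:
            keep = 1.0 - self.config.dropout_rate
            mask = (rng.random(H1.shape) < keep) / keep
            self._dropout_mask = mask
            H1 = H1 * mask
        H2 = self.lstm2.forward(H1, train=train)
        return self.dense.forward(H2, train=train)

    def backward(self, targets: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
        """Gradients for the trainable parameter list (same order)."""
        dH2, dense_grads = self.dense.backward_from_ce(targets, mask)
        dH1, l2_grads = self.lstm2.backward(dH2)
        grads: list[np.ndarray] = []
        if self.lstm1.trainable:
            dH1 = dH1 * self._dropout_mask
            _, l1_grads = self.lstm1.backward(dH1)
            grads.extend(l1_grads)
        else:
            self.lstm1._cache = {}
        if self.lstm2.trainable:
            grads.extend(l2_grads)
        if self.dense.trainable:
            grads.extend(dense_grads)
        return grads

    # -- checkpoints -----------------------------------------------------------

    def save_weights(self, path: str | Path) -> None:
        np.savez(
            path,
            W1=self.lstm1.W, R1=self.lstm1.R, b1=self.lstm1.b,
            W2=self.lstm2.W, R2=self.lstm2.R, b2=self.lstm2.b,
            Wd=self.dense.W, bd=self.dense.b,
        )

    def load_weights(self, path: str | Path) -> None:
        z = np.load(path)
        self.lstm1.W, self.lstm1.R, self.lstm1.b = z["W1"], z["R1"], z["b1"]
        self.lstm2.W, self.lstm2.R, self.lstm2.b = z["W2"], z["R2"], z["b2"]
        self.dense.W, self.dense.b = z["Wd"], z["bd"]


def build_generator(config: ModelConfig, vocab: Vocabulary) -> GeneratorModel:
    """Build the LSTM -> dropout -> LSTM -> dense-softmax generator with
    seeded initial weights."""
    model = GeneratorModel(vocab, config)
    expected = count_trainable_params(config, len(vocab))
    assert model.trainable_param_count == expected
    return model


def make_next_token_tensors(
    corpus: list[str], vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift-by-one training tensors for a corpus.

    Returns ``(X, targets, mask)`` where X is (N, Lmax, V) one-hot inputs
    (positions 0..L-2 of each framed sequence), targets is (N, Lmax) integer
    classes (positions 1..L-1) and mask flags real positions; the number of
    unmasked targets is ``sum(len(s) + 1)``.
    """
    if not corpus:
        raise GeneratorError("empty corpus")
    seqs = []
    for lineno, s in enumerate(corpus):
        try:
            seqs.append(encode_indices(s, vocab))
        except CodecError as exc:
            raise GeneratorError(f"line {lineno}: {exc}") from exc
    V = len(vocab)
    Lmax = max(len(q) for q in seqs) - 1
    N = len(seqs)
    X = np.zeros((N, Lmax, V), dtype=np.float64)
    targets = np.zeros((N, Lmax), dtype=np.int64)
    mask = np.zeros((N, Lmax), dtype=np.float64)
    for i, q in enumerate(seqs):
        L = len(q) - 1
        X[i, np.arange(L), q[:-1]] = 1.0
        targets[i, :L] = q[1:]
        mask[i, :L] = 1.0
    return X, targets, mask


def _evaluate(model: GeneratorModel, X, targets, mask, batch_size: int = 512):
    losses, accs, weights = [], [], []
    for start in range(0, X.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        P = model.forward(X[sl], train=False)
        ce, acc = masked_ce_and_acc(P, targets[sl], mask[sl])
        w = mask[sl].sum()
        losses.append(ce * w)
        accs.append(acc * w)
        weights.append(w)
    total = max(sum(weights), 1.0)
    return sum(losses) / total, sum(accs) / total


def token_frequency_wasserstein(
    model: GeneratorModel, reference: list[str], n_samples: int, seed: int,
    max_len: int = 80,
) -> float:
    """1-D Wasserstein distance between token-frequency distributions of a
    seeded model sample and a reference corpus (token positions = vocabulary
    indices, sentinels excluded)."""
    from .sampler import SamplingConfig, sample_batch

    vocab = model.vocab
    strings = sample_batch(
        model, SamplingConfig(temperature=1.0, n_samples=n_samples,
                              max_len=max_len, seed=seed)
    )["smiles"]
    V = len(vocab)
    drop = {vocab.begin_index, vocab.end_index}

    def freqs(corpus) -> np.ndarray:
        counts = np.zeros(V)
        for s in corpus:
            for ch in s:
                j = vocab.index.get(ch)
                if j is not None and j not in drop:
                    counts[j] += 1
        return counts

    u, v = freqs(strings), freqs(reference)
    if u.sum() == 0:
        u[:] = 1.0  # degenerate model emitting only E; compare against uniform
    positions = np.arange(V)
    return float(wasserstein_distance(positions, positions, u, v))


def epoch_diagnostics(
    model: GeneratorModel, validation: list[str],
    n_samples: int = 64, seed: int = 0, max_len: int = 80,
) -> tuple[float, float]:
    """(log_loss, wasserstein) on a validation corpus."""
    if not validation:
        raise GeneratorError("empty validation set")
    X, t, m = make_next_token_tensors(validation, model.vocab)
    log_loss, _ = _evaluate(model, X, t, m)
    w = token_frequency_wasserstein(model, validation, n_samples, seed, max_len)
    return log_loss, w


def train_generator(
    model: GeneratorModel,
    corpus: list[str],
    config: ModelConfig | None = None,
    run_dir: str | Path | None = None,
    initial_epoch: int = 0,
) -> TrainingHistory:
    """Train with a seeded 80/20 split and per-epoch checkpoints.

    The corpus is split once (seeded permutation), then each epoch shuffles
    the training part into mini-batches.  If ``run_dir`` is given, a JSON
    manifest plus one weight file per epoch are written, so training can be
    resumed by loading a checkpoint and passing ``initial_epoch``.
    """
    config = config or model.config
    history = TrainingHistory()
    if config.epochs == 0:
        return history
    if len(corpus) < 10:
        raise GeneratorError("corpus too small to split (need >= 10 strings)")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(corpus))
    n_val = max(1, int(round(config.val_fraction * len(corpus))))
    val = [corpus[i] for i in perm[:n_val]]
    train = [corpus[i] for i in perm[n_val:]]
    history.val_indices = [int(i) for i in perm[:n_val]]
    history.train_indices = [int(i) for i in perm[n_val:]]

    Xt, tt, mt = make_next_token_tensors(train, model.vocab)
    Xv, tv, mv = make_next_token_tensors(val, model.vocab)

    opt = Adam(model.trainable_params(), lr=config.learning_rate)

    run_path = None
    if run_dir is not None:
        run_path = Path(run_dir)
        run_path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": asdict(config),
            "vocab": list(model.vocab.tokens),
            "epochs": [],
        }

    for epoch in range(initial_epoch, initial_epoch + config.epochs):
        order = rng.permutation(Xt.shape[0])
        batch_losses, batch_accs, batch_w = [], [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            P = model.forward(Xt[idx], train=True, rng=rng)
            ce, acc = masked_ce_and_acc(P, tt[idx], mt[idx])
            if not np.isfinite(ce):
                raise GeneratorError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            grads = model.backward(tt[idx], mt[idx])
            opt.step(grads)
            w = mt[idx].sum()
            batch_losses.append(ce * w)
            batch_accs.append(acc * w)
            batch_w.append(w)
        wsum = max(sum(batch_w), 1.0)
        train_loss = sum(batch_losses) / wsum
        train_acc = sum(batch_accs) / wsum
        val_loss, val_acc = _evaluate(model, Xv, tv, mv)

        if config.diag_samples > 0:
            wass = token_frequency_wasserstein(
                model, val, config.diag_samples,
                seed=config.seed + 100_003 * (epoch + 1),
                max_len=config.diag_max_len,
            )
        else:
            wass = float("nan")

        ckpt = ""
        if run_path is not None:
            ckpt = str(run_path / f"epoch_{epoch:04d}.npz")
            model.save_weights(ckpt)
            manifest["epochs"].append(epoch)
            (run_path / "manifest.json").write_text(json.dumps(manifest, indent=1))

        history.records.append(
            EpochRecord(epoch, train_loss, val_loss, train_acc, val_acc,
                        log_loss=val_loss, wasserstein=wass, checkpoint=ckpt)
        )
    return history


def load_checkpoint(run_dir: str | Path, epoch: int) -> GeneratorModel:
    """Rebuild a model from a run directory's manifest and epoch weights."""
    run_path = Path(run_dir)
    manifest = json.loads((run_path / "manifest.json").read_text())
    cfg = ModelConfig(**manifest["config"])
    vocab = Vocabulary(tokens=tuple(manifest["vocab"]))
    model = build_generator(cfg, vocab)
    weights = run_path / f"epoch_{epoch:04d}.npz"
    if not weights.exists():
        raise GeneratorError(f"missing checkpoint {weights}")
    model.load_weights(weights)
    return model
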