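"""Transfer learning: fine-tune a general generator into a target-specific one.

A generator pre-trained on a broad corpus is re-trained on a small
target-specific corpus (here, ligands of one receptor; in tests, a
motif-enriched synthetic corpus) with early layers optionally frozen.
Freezing the first LSTM keeps the low-level SMILES "grammar" features
fixed while the second LSTM and the output layer adapt to the target
chemistry; freezing both LSTMs leaves only the dense output trainable.

The target corpus must be encodable with the *existing* vocabulary —
characters the base model has never seen are a hard error, because a
one-hot model cannot grow its input dimension without invalidating every
pre-trained weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .generator import (
    GeneratorModel, GeneratorError, ModelConfig, TrainingHistory, train_generator,
)

FREEZE_STRATEGIES = ("none", "first_lstm", "both_lstm")


@dataclass(frozen=True)
class TransferConfig:
    freeze: str = "first_lstm"
    batch_size: int = 128
    epochs: int = 40
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.freeze not in FREEZE_STRATEGIES:
            raise GeneratorError(
                f"unknown freeze strategy {self.freeze!r}; choose from {FREEZE_STRATEGIES}"
            )
        if self.batch_size < 1 or self.epochs < 0:
            raise GeneratorError("batch_size must be >= 1 and epochs >= 0")


def freeze_layers(model: GeneratorModel, strategy: str) -> GeneratorModel:
    """Set per-layer trainable flags in place and return the model."""
    if strategy not in FREEZE_STRATEGIES:
        raise GeneratorError(f"unknown freeze strategy {strategy!r}")
    model.lstm1.trainable = strategy == "none"
    model.lstm2.trainable = strategy != "both_lstm"
    model.dense.trainable = True
    return model


def _check_vocabulary(model: GeneratorModel, corpus: list[str]) -> None:
    unknown = sorted({ch for s in corpus for ch in s} - set(model.vocab.tokens))
    if unknown:
        raise GeneratorError(
            "target corpus contains characters absent from the base vocabulary: "
            + ", ".join(repr(c) for c in unknown)
        )


def finetune(
    model: GeneratorModel,
    target_corpus: list[str],
    config: TransferConfig,
    run_dir=None,
) -> tuple[GeneratorModel, TrainingHistory]:
    """Fine-tune on a target corpus with the configured freeze strategy.

    The input model is left untouched; a fresh Adam optimizer drives the
    copy's trainable layers.  Frozen layers are bit-identical before and
    after.  Zero epochs returns an unchanged copy.
    """
    _check_vocabulary(model, target_corpus)
    tuned = freeze_layers(model.copy(), config.freeze)
    train_cfg = replace(
        tuned.config,
        batch_size=config.batch_size,
        epochs=config.epochs,
        seed=config.seed,
        learning_rate=config.learning_rate,
    )
    tuned.config = train_cfg
    history = train_generator(tuned, target_corpus, train_cfg, run_dir=run_dir)
    return tuned, history


def compare_strategies(
    model: GeneratorModel,
    target_corpus: list[str],
    grid: list[TransferConfig],
) -> pd.DataFrame:
    """Fine-tune once per config and stack the per-epoch curves.

    Output columns: freeze, batch_size, epoch, train/val loss and accuracy —
    one tidy frame, no ranking applied.
    """
    if not grid:
        raise GeneratorError("empty strategy grid")
    frames = []
    for cfg in grid:
        _, history = finetune(model, target_corpus, cfg)
        df = history.to_dataframe()
        df.insert(0, "freeze", cfg.freeze)
        df.insert(1, "batch_size", cfg.batch_size)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
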