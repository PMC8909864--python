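"""Shared fixtures: synthetic corpora and trained toy models.

The expensive fixtures (a generator trained on the toy corpus, its
fine-tuned counterpart, and a temperature sweep of sampled libraries) are
session-scoped so the whole suite trains each model exactly once.  Study
conditions for the toy model: 2,000-molecule corpus, 64 LSTM units,
30 epochs, batch 128; 500 samples per temperature cell.
"""

from __future__ import annotations

import pytest

from molgen import (
    ModelConfig, MotifSpec, SamplingConfig, ToyCorpusSpec, TransferConfig,
    build_generator, build_vocabulary, evaluate_library, finetune,
    motif_enriched_corpus, sample_batch, toy_smiles_corpus, train_generator,
)

MOTIF_SMILES = "C1=CC=CO1"  # furan, Kekulé spelling
TOY_MODEL_CONFIG = dict(
    lstm_units=64, batch_size=128, epochs=30, seed=7, diag_samples=0
)


@pytest.fixture(scope="session")
def motif_smiles() -> str:
    return MOTIF_SMILES


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return toy_smiles_corpus(ToyCorpusSpec(n=2000, seed=11))


@pytest.fixture(scope="session")
def motif_corpus() -> list[str]:
    # 949 molecules: the size of a typical target-ligand transfer set
    return motif_enriched_corpus(
        ToyCorpusSpec(n=949, seed=29), MotifSpec(motif_smiles=MOTIF_SMILES, enrichment=1.0)
    )


@pytest.fixture(scope="session")
def shared_vocab(toy_corpus, motif_corpus):
    """One vocabulary covering both corpora, as a production vocabulary
    built from a broad corpus would."""
    return build_vocabulary(toy_corpus + motif_corpus)


@pytest.fixture(scope="session")
def trained_model(toy_corpus, shared_vocab):
    config = ModelConfig(**TOY_MODEL_CONFIG)
    model = build_generator(config, shared_vocab)
    history = train_generator(model, toy_corpus, config)
    model.toy_history = history  # stashed for history-shape assertions
    return model


@pytest.fixture(scope="session")
def finetuned_model(trained_model, motif_corpus):
    tuned, history = finetune(
        trained_model, motif_corpus,
        TransferConfig(freeze="first_lstm", batch_size=128, epochs=20, seed=13),
    )
    tuned.transfer_history = history
    return tuned


@pytest.fixture(scope="session")
def temperature_sweep(trained_model):
    """{temperature: (sample table, LibraryMetrics)} at 500 samples per cell."""
    out = {}
    for T in (0.5, 1.0, 1.5):
        table = sample_batch(
            trained_model,
            SamplingConfig(temperature=T, n_samples=500, max_len=80, seed=123),
        )
        out[T] = (table, evaluate_library(list(table["smiles"])))
    return out
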