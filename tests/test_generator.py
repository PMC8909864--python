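"""Generator architecture, training loop, checkpoints and diagnostics."""

import numpy as np
import pytest

from molgen import (
    GeneratorError, ModelConfig, build_generator, build_vocabulary,
    toy_smiles_corpus, train_generator, ToyCorpusSpec,
)
from molgen.generator import (
    _evaluate, count_trainable_params, epoch_diagnostics, load_checkpoint,
    make_next_token_tensors,
)


class TestParameterCount:
    def test_production_architecture_parameter_total(self):
        # two 256-unit LSTMs + dropout + dense softmax over 29 tokens
        assert count_trainable_params(ModelConfig(lstm_units=256), 29) == 825_629

    def test_tiny_architecture_hand_sum(self):
        # 4*(2*(3+2)+2) + 4*(2*(2+2)+2) + (2*3+3) = 48 + 40 + 9
        assert count_trainable_params(ModelConfig(lstm_units=2), 3) == 97

    def test_dropout_rate_does_not_change_count(self):
        a = count_trainable_params(ModelConfig(lstm_units=32, dropout_rate=0.2), 10)
        b = count_trainable_params(ModelConfig(lstm_units=32, dropout_rate=0.5), 10)
        assert a == b

    def test_built_model_reports_closed_form(self):
        vocab = build_vocabulary(["CNO()=1cn23[]#+-SsFl4Br/\\@H"])  # 29 with sentinels
        assert len(vocab) == 29
        model = build_generator(ModelConfig(lstm_units=256), vocab)
        assert model.trainable_param_count == 825_629


class TestBuildGenerator:
    def test_same_seed_identical_initial_weights(self):
        vocab = build_vocabulary(["CCO"])
        a = build_generator(ModelConfig(lstm_units=8, seed=5), vocab)
        b = build_generator(ModelConfig(lstm_units=8, seed=5), vocab)
        for pa, pb in zip(a.trainable_params(), b.trainable_params()):
            assert np.array_equal(pa, pb)

    def test_different_seed_different_weights(self):
        vocab = build_vocabulary(["CCO"])
        a = build_generator(ModelConfig(lstm_units=8, seed=5), vocab)
        b = build_generator(ModelConfig(lstm_units=8, seed=6), vocab)
        assert not np.array_equal(a.lstm1.W, b.lstm1.W)

    def test_config_validation(self):
        with pytest.raises(GeneratorError):
            ModelConfig(val_fraction=0.0)
        with pytest.raises(GeneratorError):
            ModelConfig(lstm_units=0)


class TestNextTokenTensors:
    def test_shift_by_one_for_single_character(self):
        vocab = build_vocabulary(["C"])
        X, targets, mask = make_next_token_tensors(["C"], vocab)
        rows = X[0].argmax(axis=1)
        assert [vocab.tokens[i] for i in rows] == ["G", "C"]
        assert [vocab.tokens[i] for i in targets[0]] == ["C", "E"]
        assert mask[0].tolist() == [1.0, 1.0]

    def test_unmasked_count_is_sum_of_lengths_plus_one(self, toy_corpus, shared_vocab):
        sample = toy_corpus[:100]
        _, _, mask = make_next_token_tensors(sample, shared_vocab)
        assert mask.sum() == sum(len(s) + 1 for s in sample)

    def test_empty_corpus_rejected(self):
        vocab = build_vocabulary(["C"])
        with pytest.raises(GeneratorError):
            make_next_token_tensors([], vocab)

    def test_encoding_error_carries_line_number(self):
        vocab = build_vocabulary(["C"])
        with pytest.raises(GeneratorError, match="line 1"):
            make_next_token_tensors(["C", "O"], vocab)


class TestTraining:
    def test_zero_epochs_returns_empty_history_and_unchanged_model(self):
        vocab = build_vocabulary(["CCO", "CCN"])
        model = build_generator(ModelConfig(lstm_units=8, epochs=0, seed=2), vocab)
        before = [p.copy() for p in model.trainable_params()]
        history = train_generator(model, ["CCO", "CCN"] * 10, ModelConfig(lstm_units=8, epochs=0))
        assert len(history) == 0
        for p, q in zip(model.trainable_params(), before):
            assert np.array_equal(p, q)

    def test_tiny_corpus_rejected(self):
        vocab = build_vocabulary(["CCO"])
        model = build_generator(ModelConfig(lstm_units=8, epochs=1), vocab)
        with pytest.raises(GeneratorError, match="too small"):
            train_generator(model, ["CCO"] * 5)

    def test_same_seed_bit_identical_history(self):
        corpus = toy_smiles_corpus(ToyCorpusSpec(n=60, seed=4))
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(lstm_units=16, batch_size=16, epochs=3, seed=9, diag_samples=8)
        runs = []
        for _ in range(2):
            model = build_generator(cfg, vocab)
            runs.append(train_generator(model, corpus, cfg).to_dataframe())
        assert runs[0].equals(runs[1])

    def test_validation_loss_converged_over_last_five_epochs(self, trained_model):
        val_loss = [r.val_loss for r in trained_model.toy_history.records[-5:]]
        assert max(val_loss) - min(val_loss) < 0.05
        assert len(trained_model.toy_history) == 30

    def test_history_invariants(self, trained_model):
        df = trained_model.toy_history.to_dataframe()
        assert (df["train_loss"] >= 0).all() and (df["val_loss"] >= 0).all()
        assert df["train_acc"].between(0, 1).all() and df["val_acc"].between(0, 1).all()
        assert df["epoch"].tolist() == list(range(30))

    def test_one_string_memorization_drives_loss_near_zero(self):
        """Capacity sanity check: a 64-unit model memorizes a single
        repeated string to near-zero evaluation loss."""
        s = "CC(=O)NCCO"
        vocab = build_vocabulary([s])
        cfg = ModelConfig(lstm_units=64, batch_size=32, epochs=150, seed=3,
                          learning_rate=5e-3, diag_samples=0)
        model = build_generator(cfg, vocab)
        train_generator(model, [s] * 32, cfg)
        X, t, m = make_next_token_tensors([s], vocab)
        ce, acc = _evaluate(model, X, t, m)
        assert ce < 0.05
        assert acc == 1.0

    def test_larger_width_overfits_small_corpus_more(self, toy_corpus, shared_vocab):
        """On a 150-molecule corpus the 256-unit model shows a larger
        train/validation loss gap than the 64-unit model (evaluation mode,
        same seeded split)."""
        tiny = toy_corpus[:150]
        gaps = {}
        for units in (64, 256):
            cfg = ModelConfig(lstm_units=units, batch_size=32, epochs=60,
                              seed=5, diag_samples=0)
            model = build_generator(cfg, shared_vocab)
            history = train_generator(model, tiny, cfg)
            train_part = [tiny[i] for i in history.train_indices]
            val_part = [tiny[i] for i in history.val_indices]
            Xt, tt, mt = make_next_token_tensors(train_part, shared_vocab)
            Xv, tv, mv = make_next_token_tensors(val_part, shared_vocab)
            gaps[units] = _evaluate(model, Xv, tv, mv)[0] - _evaluate(model, Xt, tt, mt)[0]
        assert gaps[256] > gaps[64]


class TestCheckpoints:
    def test_checkpoint_round_trip_and_resume(self, tmp_path):
        corpus = toy_smiles_corpus(ToyCorpusSpec(n=60, seed=4))
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(lstm_units=16, batch_size=16, epochs=3, seed=9, diag_samples=0)
        model = build_generator(cfg, vocab)
        history = train_generator(model, corpus, cfg, run_dir=tmp_path)
        assert [r.epoch for r in history.records] == [0, 1, 2]
        reloaded = load_checkpoint(tmp_path, 2)
        assert np.array_equal(reloaded.lstm1.W, model.lstm1.W)
        assert np.array_equal(reloaded.dense.b, model.dense.b)
        # resume: two further epochs continue the numbering
        more = train_generator(
            reloaded, corpus,
            ModelConfig(lstm_units=16, batch_size=16, epochs=2, seed=10, diag_samples=0),
            run_dir=tmp_path, initial_epoch=3,
        )
        assert [r.epoch for r in more.records] == [3, 4]

    def test_missing_checkpoint_rejected(self, tmp_path):
        corpus = toy_smiles_corpus(ToyCorpusSpec(n=60, seed=4))
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(lstm_units=8, batch_size=16, epochs=1, seed=9, diag_samples=0)
        train_generator(build_generator(cfg, vocab), corpus, cfg, run_dir=tmp_path)
        with pytest.raises(GeneratorError, match="missing checkpoint"):
            load_checkpoint(tmp_path, 40)


class TestDiagnostics:
    def test_uniform_model_log_loss_is_log_vocab_size(self):
        vocab = build_vocabulary(["CCO", "CCN"])
        model = build_generator(ModelConfig(lstm_units=8, seed=2), vocab)
        model.dense.W[:] = 0.0  # uniform softmax regardless of context
        model.dense.b[:] = 0.0
        log_loss, _ = epoch_diagnostics(model, ["CCO", "CNC"], n_samples=4)
        assert log_loss == pytest.approx(np.log(len(vocab)), abs=1e-9)

    def test_empty_validation_rejected(self, trained_model):
        with pytest.raises(GeneratorError):
            epoch_diagnostics(trained_model, [])

    def test_both_diagnostics_improve_with_training(self, toy_corpus, shared_vocab,
                                                    trained_model):
        """Log-loss and the token-frequency Wasserstein distance are both
        strictly smaller after training than at initialization."""
        fresh = build_generator(trained_model.config, shared_vocab)
        val = toy_corpus[:200]
        ll0, w0 = epoch_diagnostics(fresh, val, n_samples=100, seed=42)
        ll1, w1 = epoch_diagnostics(trained_model, val, n_samples=100, seed=42)
        assert ll1 < ll0
        assert w1 < w0
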