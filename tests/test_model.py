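"""Architecture accounting, schedule, gradients, training and prediction."""

import math

import numpy as np
import pytest

import ms2mol as m
from ms2mol.model import _cross_entropy, _pad_batch


def _tiny_config(**overrides):
    base = dict(
        n_encoder_layers=1,
        n_decoder_layers=1,
        model_width=8,
        n_heads=2,
        ff_width=16,
        dropout=0.0,
        input_vocab=30,
        output_vocab=10,
        max_input_len=10,
        max_output_len=10,
    )
    base.update(overrides)
    return m.ModelConfig(**base)


class TestParameterAccounting:
    def test_default_config_is_about_400m(self):
        count = m.count_parameters_config(m.ModelConfig())
        assert 380e6 <= count <= 420e6

    @pytest.mark.parametrize("enc", [1, 2, 3])
    @pytest.mark.parametrize("width,heads,ff", [(8, 2, 16), (16, 4, 32)])
    @pytest.mark.parametrize("out_vocab", [10, 21])
    def test_closed_form_matches_instantiated_model(self, enc, width, heads, ff, out_vocab):
        config = _tiny_config(
            n_encoder_layers=enc,
            n_decoder_layers=enc + 1,
            model_width=width,
            n_heads=heads,
            ff_width=ff,
            output_vocab=out_vocab,
        )
        model = m.build_model(config, seed=0)
        assert m.count_parameters(model) == m.count_parameters_config(config)

    def test_spec_toy_example_config(self):
        config = m.ModelConfig(
            n_encoder_layers=2, n_decoder_layers=2, model_width=32, n_heads=4,
            ff_width=64, dropout=0.0, input_vocab=1001, output_vocab=20,
            max_input_len=20, max_output_len=20,
        )
        model = m.build_model(config, seed=0)
        assert m.count_parameters(model) == m.count_parameters_config(config)

    def test_extra_output_token_costs_2w_plus_1(self):
        base = _tiny_config()
        bigger = _tiny_config(output_vocab=11)
        delta = m.count_parameters_config(bigger) - m.count_parameters_config(base)
        assert delta == 2 * base.model_width + 1

    def test_width_heads_divisibility_enforced(self):
        with pytest.raises(ValueError):
            _tiny_config(model_width=10, n_heads=4)


class TestLrSchedule:
    def test_branches_meet_at_warmup(self):
        config = m.TrainConfig(warmup_steps=8000)
        w = config.warmup_steps
        assert w ** -0.5 == pytest.approx(w * w ** -1.5)
        left = m.lr_schedule(w - 1, config)
        peak = m.lr_schedule(w, config)
        right = m.lr_schedule(w + 1, config)
        assert left < peak and right < peak

    def test_monotone_rise_then_decay(self):
        config = m.TrainConfig(warmup_steps=100)
        rates = [m.lr_schedule(s, config) for s in range(1, 300)]
        peak = rates.index(max(rates)) + 1
        assert peak == 100
        assert all(a < b for a, b in zip(rates[:99], rates[1:100]))
        assert all(a > b for a, b in zip(rates[100:-1], rates[101:]))

    def test_closed_form_at_step_one(self):
        config = m.TrainConfig(warmup_steps=8000, model_width=1024,
                               batch_size=896, base_batch_size=896)
        assert m.lr_schedule(1, config) == pytest.approx(
            1024 ** -0.5 * 8000 ** -1.5
        )

    def test_step_zero_rejected(self):
        with pytest.raises(ValueError):
            m.lr_schedule(0, m.TrainConfig())

    def test_batch_scaling_is_linear(self):
        small = m.TrainConfig(batch_size=224, base_batch_size=896)
        assert m.lr_schedule(10, small) == pytest.approx(
            0.25 * m.lr_schedule(10, m.TrainConfig())
        )


class TestBackpropagation:
    def test_gradients_match_finite_differences(self):
        config = _tiny_config()
        model = m.build_model(config, seed=4)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        src = np.array([[1, 5, 7], [2, 3, config.src_pad_id]])
        tgt_in = np.array([[0, 4, 5], [0, 6, 3]])
        tgt_out = np.array([[4, 5, 1], [6, 1, 3]])

        logits, caches = model.forward(src, tgt_in)
        loss, dlogits = _cross_entropy(logits, tgt_out)
        grads = model.backward(dlogits.astype(np.float64), caches)

        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in ["emb_src", "emb_tgt", "proj_w", "enc0_attn_wq",
                     "dec0_cross_wk", "dec0_ff_w1", "enc0_ln1_g", "dec_lnf_b"]:
            flat = model.params[name].reshape(-1)
            for idx in rng.choice(flat.size, size=3, replace=False):
                original = flat[idx]
                flat[idx] = original + eps
                up, _ = _cross_entropy(model.forward(src, tgt_in)[0], tgt_out)
                flat[idx] = original - eps
                down, _ = _cross_entropy(model.forward(src, tgt_in)[0], tgt_out)
                flat[idx] = original
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=1e-6, rel=1e-4), (
                    name, idx
                )


def _micro_dataset(n=8, seed=0):
    molecules = m.generate_fixture_molecules(n, seed)
    return m.build_dataset(molecules, m.FragmentationConfig(min_fragment_mass=0))


def _micro_train(seed, epochs=6):
    samples = _micro_dataset()
    config = m.toy_model_config(model_width=32, n_heads=2, ff_width=64)
    model = m.build_model(config, seed=2)
    train_config = m.TrainConfig(
        batch_size=8, base_batch_size=8, model_width=32, warmup_steps=50,
        patience=epochs, max_epochs=epochs, seed=seed,
    )
    checkpoint = m.train(model, samples, samples[:6], train_config)
    return model, checkpoint


class TestTraining:
    def test_same_seed_identical_history(self):
        _, a = _micro_train(seed=9)
        _, b = _micro_train(seed=9)
        assert a.history == b.history

    def test_checkpoint_is_validation_argmin(self):
        _, checkpoint = _micro_train(seed=1)
        val_losses = [v for _, _, v in checkpoint.history]
        assert checkpoint.best_val_loss == min(val_losses)
        assert checkpoint.history[checkpoint.best_epoch][2] == checkpoint.best_val_loss

    def test_loss_decreases_over_training(self):
        _, checkpoint = _micro_train(seed=1, epochs=12)
        train_losses = [t for _, t, _ in checkpoint.history]
        assert train_losses[-1] < train_losses[0]

    def test_empty_dataset_rejected(self):
        config = m.toy_model_config(model_width=32, n_heads=2, ff_width=64)
        model = m.build_model(config, seed=0)
        with pytest.raises(ValueError):
            m.train(model, [], [], m.TrainConfig())

    def test_vocabulary_mismatch_rejected(self):
        samples = _micro_dataset()
        config = m.toy_model_config(model_width=32, n_heads=2, ff_width=64,
                                    output_vocab=5)
        model = m.build_model(config, seed=0)
        with pytest.raises(ValueError, match="vocabulary"):
            m.train(model, samples, samples[:2],
                    m.TrainConfig(batch_size=8, base_batch_size=8,
                                  model_width=32, warmup_steps=10))


class TestPadBatch:
    def test_shapes_and_padding(self):
        samples = _micro_dataset(4)
        config = m.toy_model_config()
        src, tgt_in, tgt_out = _pad_batch(samples, config)
        assert src.shape[0] == tgt_in.shape[0] == tgt_out.shape[0] == len(samples)
        assert tgt_in.shape == tgt_out.shape
        # teacher forcing: outputs are inputs shifted left by one
        for row, sample in enumerate(samples):
            n = len(sample.target) - 1
            assert list(tgt_in[row, :n]) == list(sample.target[:-1])
            assert list(tgt_out[row, :n]) == list(sample.target[1:])
            assert all(tgt_out[row, n:] == 3)


class TestSampling:
    def test_single_run_and_seed_determinism(self, trained_toy_model, fixture_dataset):
        model, _ = trained_toy_model
        spectrum = fixture_dataset[0].input
        one = m.sample_predictions(model, spectrum, n_runs=1, seed=5)
        assert len(one.raw_outputs) == 1
        again = m.sample_predictions(model, spectrum, n_runs=10, seed=5)
        third = m.sample_predictions(model, spectrum, n_runs=10, seed=5)
        assert again.raw_outputs == third.raw_outputs

    def test_frequencies_account_for_every_run(self, trained_toy_model, fixture_dataset):
        model, _ = trained_toy_model
        preds = m.sample_predictions(model, fixture_dataset[0].input, n_runs=30, seed=2)
        assert sum(preds.unique_canonical.values()) + preds.n_invalid == 30
        assert 0 < preds.uniqueness_ratio <= 1

    def test_bad_inputs_rejected(self, trained_toy_model):
        model, _ = trained_toy_model
        with pytest.raises(ValueError):
            m.sample_predictions(model, m.BinnedSpectrum(()), n_runs=5)
        with pytest.raises(ValueError):
            m.sample_predictions(model, m.BinnedSpectrum((1, 2)), n_runs=0)


class TestFormulaFilter:
    def _preds(self, smiles_list):
        tally = {s: 1 for s in smiles_list}
        return m.PredictionSet(
            raw_outputs=tuple(smiles_list), unique_canonical=tally, n_invalid=0
        )

    def test_cytosine_retained_at_its_protonated_mass(self):
        preds = self._preds([m.canonicalize("Nc1ccnc(=O)[nH]1"), "CCO"])
        kept = m.formula_filter(preds, precursor_mz=112.0505, tol=m.PpmTolerance(25))
        assert list(kept.formula_filtered) == [m.canonicalize("Nc1ccnc(=O)[nH]1")]

    def test_exact_formula_mode(self):
        preds = self._preds(["CCO", "CCN"])
        kept = m.formula_filter(
            preds, target_formula=m.MolecularFormula.from_string("C2H6O")
        )
        assert list(kept.formula_filtered) == ["CCO"]

    def test_empty_and_all_wrong_results(self):
        empty = self._preds([])
        assert m.formula_filter(empty, precursor_mz=100.0).formula_filtered == {}
        wrong = self._preds(["CCO"])
        kept = m.formula_filter(wrong, precursor_mz=400.0)
        assert kept.formula_filtered == {}
        assert kept.most_frequent() is None

    def test_requires_a_target(self):
        with pytest.raises(ValueError):
            m.formula_filter(self._preds(["CCO"]))
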