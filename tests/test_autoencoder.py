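"""Autoencoder losses, encode/decode services, training behaviour."""

import numpy as np
import pytest

from molmoo.autoencoder import (AutoencoderService, LossWeights, ModelConfig,
                                MolecularAutoencoder, TrainConfig,
                                _PropertyScaler, evaluate, joint_loss,
                                nt_xent_loss, reconstruction_accuracy, train,
                                visualize_latent)
from molmoo.autograd import Tensor
from molmoo.molecules import (DatasetSplit, MoleculeRecord, Vocabulary,
                              PROPERTY_NAMES)
from molmoo.presets import desk_dataset


def brute_force_nt_xent(z, tau):
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    S = zn @ zn.T / tau
    two_n = z.shape[0]

    def l(i, j):
        denom = sum(np.exp(S[i, k]) for k in range(two_n) if k != i)
        return -np.log(np.exp(S[i, j]) / denom)

    total = sum(l(2 * k, 2 * k + 1) + l(2 * k + 1, 2 * k)
                for k in range(two_n // 2))
    return total / two_n


class TestNTXent:
    def test_single_pair_is_zero(self, rng):
        z = rng.normal(size=(2, 5))
        assert abs(nt_xent_loss(z, 0.1).item()) < 1e-12

    def test_identical_quadruple_is_ln3(self):
        z = np.ones((4, 3))
        assert abs(nt_xent_loss(z, 0.1).item() - np.log(3)) < 1e-9

    @pytest.mark.parametrize("n_pairs", [2, 4, 8])
    def test_matches_double_sum_oracle(self, n_pairs, rng):
        z = rng.normal(size=(2 * n_pairs, 6))
        assert abs(nt_xent_loss(z, 0.1).item()
                   - brute_force_nt_xent(z, 0.1)) < 1e-6

    def test_zero_vector_raises(self):
        z = np.vstack([np.zeros(4), np.ones(4)])
        with pytest.raises(FloatingPointError):
            nt_xent_loss(z, 0.1)

    def test_odd_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            nt_xent_loss(rng.normal(size=(3, 4)), 0.1)


class TestJointLoss:
    def _perfect_logits(self, targets, vocab_size):
        logits = np.full((*targets.shape, vocab_size), -30.0)
        for idx in np.ndindex(targets.shape):
            logits[idx + (targets[idx],)] = 30.0
        return logits

    def test_perfect_everything_zero_total(self):
        targets = np.array([[3, 4, 2, 0]])
        logits = Tensor(self._perfect_logits(targets, 6))
        z = Tensor(np.zeros((1, 8)))
        pred = Tensor(np.zeros((1, 3)))
        total, breakdown = joint_loss(
            logits, targets, 0, z, pred, np.zeros((1, 3)), LossWeights(),
            contrastive_enabled=False)
        assert total.item() < 1e-9
        assert breakdown.recon_token_accuracy == 1.0

    def test_unit_norm_latents_contribute_l2_weight(self):
        targets = np.array([[3, 2, 0, 0]])
        logits = Tensor(self._perfect_logits(targets, 6))
        z = np.zeros((2, 4))
        z[:, 0] = 1.0                      # unit-norm latents
        total, breakdown = joint_loss(
            logits, targets.repeat(2, axis=0), 0, Tensor(z),
            Tensor(np.zeros((2, 3))), np.zeros((2, 3)), LossWeights(),
            contrastive_enabled=False)
        assert np.isclose(breakdown.latent_l2, 1.0)
        assert np.isclose(total.item(), 0.1, atol=1e-9)

    def test_total_is_weighted_sum_of_parts(self, rng):
        weights = LossWeights()
        targets = rng.integers(1, 5, size=(4, 6))
        logits = Tensor(rng.normal(size=(4, 6, 5)))
        z = Tensor(rng.normal(size=(4, 8)))
        pred = Tensor(rng.normal(size=(4, 3)))
        prop = rng.normal(size=(4, 3))
        total, b = joint_loss(logits, targets, 0, z, pred, prop, weights,
                              contrastive_enabled=True)
        manual = (weights.w_recon * b.recon_ce
                  + sum(w * b.aux_mse[k]
                        for w, k in zip(weights.w_aux, PROPERTY_NAMES))
                  + weights.w_contrast * b.contrastive
                  + weights.w_l2 * b.latent_l2)
        assert np.isclose(total.item(), manual, rtol=1e-12)
        assert np.isclose(b.total, manual, rtol=1e-12)


def _tiny_service(records, architecture="relso", seed=0):
    max_len = max(len(r.tokens) for r in records) + 2
    vocab = Vocabulary.from_records(records)
    config = ModelConfig.desk(architecture, contrastive_enabled=True,
                              max_len=max_len)
    model = MolecularAutoencoder(config, vocab, seed=seed)
    return AutoencoderService(model, _PropertyScaler.fit(records))


@pytest.fixture(scope="module")
def records():
    return desk_dataset(16, seed=3)


class TestEncodeDecode:
    def test_latent_dimension_from_config(self, records):
        service = _tiny_service(records)
        z = service.encode_smiles([records[0].smiles_canonical])
        assert z.shape == (1, service.model.config.latent_dim)

    def test_encode_deterministic_in_eval(self, records):
        service = _tiny_service(records)
        smi = [records[0].smiles_canonical]
        assert np.array_equal(service.encode_smiles(smi),
                              service.encode_smiles(smi))

    def test_two_molecules_encode_differently(self, records):
        service = _tiny_service(records)
        z = service.encode_smiles([records[0].smiles_canonical,
                                   records[1].smiles_canonical])
        assert np.any(np.abs(z[0] - z[1]) > 1e-9)

    @pytest.mark.parametrize("architecture", ["relso", "fragnet"])
    def test_any_latent_decodes_to_valid_molecule(self, records, architecture):
        from rdkit import Chem
        service = _tiny_service(records, architecture)
        z = np.vstack([np.zeros(service.latent_dim),
                       np.full(service.latent_dim, 3.0),
                       np.linspace(-2, 2, service.latent_dim)])
        for smiles in service.decode_latent(z):
            assert smiles == "" or Chem.MolFromSmiles(smiles) is not None

    def test_decode_deterministic(self, records):
        service = _tiny_service(records)
        z = np.random.default_rng(0).normal(size=(3, service.latent_dim))
        assert service.decode_latent(z) == service.decode_latent(z)

    def test_property_prediction_interface(self, records):
        service = _tiny_service(records)
        z = service.encode_smiles([records[0].smiles_canonical])
        pred = service.predict_properties(z)
        assert pred.shape == (1, 3)        # (logP, QED, SAS) order

    def test_checkpoint_round_trip(self, records, tmp_path):
        service = _tiny_service(records)
        path = str(tmp_path / "model.npz")
        service.save(path)
        loaded = AutoencoderService.load(path)
        smi = [records[0].smiles_canonical]
        assert np.allclose(service.encode_smiles(smi),
                           loaded.encode_smiles(smi))


class TestTraining:
    def _split(self, records):
        return DatasetSplit(train=records[:12], validation=records[12:16],
                            test=records[12:16])

    def test_history_reproducible_per_seed(self, records):
        losses = []
        for _ in range(2):
            service = _tiny_service(records, seed=5)
            history = train(service, self._split(records),
                            config=TrainConfig(learning_rate=1e-3,
                                               batch_size=8, max_epochs=3,
                                               seed=11))
            losses.append([h["train"].total for h in history])
        assert losses[0] == losses[1]

    def test_validation_checkpoints_every_fifth_of_epoch(self, records):
        service = _tiny_service(records)
        history = train(service, self._split(records),
                        config=TrainConfig(learning_rate=1e-3, batch_size=2,
                                           max_epochs=2, seed=0))
        # 6 steps/epoch at batch 2 -> validation every step//5=1 -> 12 checkpoints
        assert len(history) == 12

    def test_best_so_far_validation_nonincreasing(self, records):
        service = _tiny_service(records)
        history = train(service, self._split(records),
                        config=TrainConfig(learning_rate=1e-3, batch_size=8,
                                           max_epochs=4, seed=1))
        vals = [h["validation"].total for h in history]
        best = np.minimum.accumulate(vals)
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_early_stopping_on_consecutive_increases(self, records):
        # an absurdly large learning rate makes validation loss climb fast
        service = _tiny_service(records)
        config = TrainConfig(learning_rate=5.0, batch_size=8, max_epochs=200,
                             patience=4, seed=0)
        try:
            history = train(service, self._split(records), config=config)
        except Exception:
            pytest.skip("divergence raised before the stopping rule fired")
        increases = 0
        for prev, cur in zip(history, history[1:]):
            if cur["validation"].total > prev["validation"].total:
                increases += 1
                if increases >= 4:
                    break
            else:
                increases = 0
        assert len(history) < 200 * 2  # stopped well before max_epochs

    def test_evaluate_matches_manual_batch_average(self, records):
        from molmoo.autoencoder import _run_batch
        service = _tiny_service(records)
        subset = records[:8]
        result = evaluate(service, subset, batch_size=4, seed=0)
        service.model.eval()
        manual = []
        for start in (0, 4):
            _, b = _run_batch(service, subset[start:start + 4], LossWeights(),
                              n_views=2, attempts=10, seed=0)
            manual.append(b.total)
        assert np.isclose(result.total, np.mean(manual))

    def test_empty_split_rejected(self, records):
        with pytest.raises(ValueError):
            evaluate(_tiny_service(records), [])


class TestOverfitModel:
    """Checks on the session-scoped memorized model (shared with the
    end-to-end optimization tests)."""

    def test_high_reconstruction_accuracy(self, overfit_result):
        assert overfit_result.accuracy >= 0.99

    def test_property_heads_fit_training_set(self, overfit_result):
        service = overfit_result.service
        records = overfit_result.records
        z = service.encode_smiles([r.smiles_canonical for r in records])
        pred = service.predict_properties(z)
        target = np.stack([r.property_vector for r in records])
        scaled_err = ((pred - target) / service.scaler.std) ** 2
        assert np.all(scaled_err.mean(axis=0) < 0.1)

    def test_repair_is_idempotent_on_memorized_molecules(self, overfit_result):
        service = overfit_result.service
        smiles = [r.smiles_canonical for r in overfit_result.records[:10]]
        z = service.encode_smiles(smiles)
        decoded = service.decode_latent(z)
        z2 = service.encode_smiles(decoded)
        z3 = service.encode_smiles(service.decode_latent(z2))
        assert np.allclose(z2, z3, atol=1e-8)


def test_visualize_latent_outputs(tmp_path, overfit_result):
    service = overfit_result.service
    records = (overfit_result.records * 2)[:60]   # >= 51 samples
    frames = visualize_latent(service, records, str(tmp_path), seed=0)
    assert frames["pca"].shape == (60, 50)
    assert frames["embedding_2d"].shape == (60, 2)
    assert frames["embedding_3d"].shape == (60, 3)
    assert (tmp_path / "embedding_2d.csv").exists()
    assert (tmp_path / "latent_2d_logP.png").exists()
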