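"""Model contracts, masking, validation splitting and training behaviour."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from zfhelix.model import (
    MASK_TOKEN,
    ModelConfig,
    PairModel,
    SingleHelixModule,
    TrainedModel,
    encode_residues,
)
from zfhelix.training import (
    TrainConfig,
    accuracy_by_masked_count,
    build_validation_split,
    evaluate_masked,
    mask_residues,
    n_masked_positions,
    pretrain_single_module,
    pwm_mse,
    reconstruction_accuracy,
    train_full_model,
)
from zfhelix.types import InputError


def toy_model(kind="pair", seed=0) -> TrainedModel:
    config = ModelConfig.toy()
    rng = np.random.default_rng(seed)
    network = PairModel(config, rng) if kind == "pair" else SingleHelixModule(config, rng)
    return TrainedModel(network=network, config=config)


def state_hash(module) -> str:
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(p.data.tobytes())
    return h.hexdigest()


class TestMasking:
    def test_pair_half_masking_is_six(self):
        ex = mask_residues("RDHTNKQSGELV", 0.5, seed=1)
        assert len(ex.masked_positions) == 6
        assert all(ex.tokens[list(ex.masked_positions)] == MASK_TOKEN)

    def test_full_masking(self):
        ex = mask_residues("RDHTNKQSGELV", 1.0, seed=1)
        assert len(ex.masked_positions) == 12

    def test_small_fraction_floors_at_one(self):
        assert n_masked_positions(6, 0.01) == 1

    def test_seed_repeatable(self):
        a = mask_residues("RDHTNK", 0.5, seed=7)
        b = mask_residues("RDHTNK", 0.5, seed=7)
        assert a.masked_positions == b.masked_positions


class TestValidationSplit:
    def test_isolated_target_goes_to_validation(self):
        targets = ["AAAAAAA", "AAAAAAC", "AAAAACC", "GGGGTTT"]  # last is isolated
        spec = build_validation_split(targets)
        assert "GGGGTTT" in spec.validation

    def test_neighbours_never_straddle(self):
        spec = build_validation_split(["AAAAAAA", "AAAAAAC"])
        assert set(spec.validation) == {"AAAAAAA", "AAAAAAC"}
        assert spec.train == ()

    def test_bad_proportions_rejected(self):
        with pytest.raises(InputError):
            build_validation_split(["AAAAAAA", "TTTTTTT"], proportions=(0.8, 0.1))

    def test_partitions_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        targets = sorted(
            {"".join(rng.choice(list("ACGT"), 7)) for _ in range(120)}
        )
        spec = build_validation_split(targets)
        assert set(spec.train) | set(spec.validation) == set(targets)
        assert not set(spec.train) & set(spec.validation)
        assert len(spec.validation) >= max(1, round(0.1 * len(targets)))

    def test_validation_seeds_keep_their_neighbourhood(self):
        """Any train target within the radius of a validation target must be
        explained by the neighbour-inclusion rule, i.e. validation always
        contains whole seed units."""
        rng = np.random.default_rng(1)
        targets = sorted({"".join(rng.choice(list("ACGT"), 7)) for _ in range(60)})
        spec = build_validation_split(targets)
        # at least the first seed node has all its neighbours in validation
        val = set(spec.validation)
        ok = False
        for t in spec.validation:
            neighbours = {
                u for u in targets
                if u != t and sum(a != b for a, b in zip(t, u)) <= 2
            }
            if neighbours <= val:
                ok = True
                break
        assert ok


class TestForwardContracts:
    def test_rows_sum_to_one(self):
        model = toy_model("pair")
        probs = model.predict_probs("ACGTACG", encode_residues("______RDHTNK", "_"))
        assert probs.shape == (12, 20)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_single_module_rows_sum_to_one(self):
        model = toy_model("single")
        probs = model.predict_probs("ACGT", encode_residues("___TNK", "_"))
        assert probs.shape == (6, 20)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self):
        model = toy_model("pair")
        tokens = encode_residues("______RDHTNK", "_")
        a = model.predict_probs("ACGTACG", tokens)
        b = model.predict_probs("ACGTACG", tokens)
        np.testing.assert_array_equal(a, b)

    def test_length_mismatch_rejected(self):
        model = toy_model("pair")
        with pytest.raises(InputError):
            model.predict_probs("ACGT", encode_residues("_" * 12, "_"))

    def test_context_sensitivity(self, memo_pair_model):
        """Permuting two unmasked residue identities changes the output
        distribution at other positions on a trained model."""
        a = encode_residues("RD____" + "______", "_")
        b = a.copy()
        b[0], b[1] = b[1], b[0]
        pa = memo_pair_model.predict_probs("ACGTACG", a)
        pb = memo_pair_model.predict_probs("ACGTACG", b)
        assert np.abs(pa[2:] - pb[2:]).max() > 1e-4


class TestTraining:
    def test_initial_loss_near_log20(self):
        """Random small-weight initialisation predicts near-uniform
        distributions, so masked cross-entropy starts at about ln 20."""
        model = toy_model("pair", seed=3)
        rng = np.random.default_rng(0)
        examples = [
            (
                "".join(rng.choice(list("ACGT"), 7)),
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 12)),
            )
            for _ in range(200)
        ]
        loss, _ = evaluate_masked(model.network, examples, 0.5, seed=0)
        assert loss == pytest.approx(np.log(20), rel=0.1)

    def test_untrained_accuracy_near_chance(self):
        model = toy_model("single", seed=4)
        rng = np.random.default_rng(1)
        examples = [
            (
                "".join(rng.choice(list("ACGT"), 4)),
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 6)),
            )
            for _ in range(700)
        ]
        acc = reconstruction_accuracy(model, examples, seed=2)
        # ~2100 masked positions; 5 sigma of Binomial(2100, 0.05)
        assert abs(acc - 0.05) < 5 * np.sqrt(0.05 * 0.95 / 2100)

    def test_memorization_and_accuracy_curve(self, memo_pair_model):
        from tests.conftest import MEMO_ASSOCIATIONS

        acc = reconstruction_accuracy(memo_pair_model, MEMO_ASSOCIATIONS, seed=5)
        assert acc == 1.0
        curve = accuracy_by_masked_count(memo_pair_model, MEMO_ASSOCIATIONS, seed=5)
        assert len(curve) == 12
        assert curve[0] >= curve[-1] - 0.1  # nonincreasing within noise

    def test_per_sequence_averaging_option(self, memo_pair_model):
        from tests.conftest import MEMO_ASSOCIATIONS

        acc = reconstruction_accuracy(
            memo_pair_model, MEMO_ASSOCIATIONS, seed=5, per_sequence=True
        )
        assert acc == 1.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(InputError):
            pretrain_single_module([], ModelConfig.toy(), TrainConfig())

    def test_transfer_requires_pretrained(self):
        with pytest.raises(InputError):
            train_full_model(
                [("ACGTACG", "RDHTNKQSGELV")] * 4,
                ModelConfig.toy(),
                TrainConfig(init_mode="transfer"),
            )

    def test_config_mismatch_rejected(self):
        single_big = TrainedModel(
            network=SingleHelixModule(
                ModelConfig.toy(dropout=0.0).__class__(d_model=16, n_heads=2,
                                                       n_layer_repeats=1, d_k=8,
                                                       d_v=8, d_ff=16, dropout=0.0),
                np.random.default_rng(0),
            ),
            config=ModelConfig.toy(),
        )
        with pytest.raises(ValueError):
            train_full_model(
                [("ACGTACG", "RDHTNKQSGELV"), ("TTTTTTT", "WYYAMCFIPQRD")] * 4,
                ModelConfig.toy(),
                TrainConfig(init_mode="transfer", max_epochs=1),
                pretrained=(single_big, single_big),
            )


@pytest.fixture(scope="module")
def tiny_corpus():
    """A small synthetic pair corpus for convergence comparisons."""
    from zfhelix.b1h_io import basic_filter
    from zfhelix.synthetic import (
        SimulationParams,
        sample_code,
        sample_pair_targets,
        simulate_pair_campaign,
    )
    from zfhelix.types import SelectionDataset

    code = sample_code(2, 2.0)
    targets = sample_pair_targets(2, 60)
    datasets = simulate_pair_campaign(
        code, targets, SimulationParams(seed=2, n_candidates=1_000_000, max_survivors=40)
    )
    return [
        SelectionDataset(target=d.target, records=basic_filter(d.records))
        for d in datasets
    ]


@pytest.fixture(scope="module")
def tiny_single_module():
    from zfhelix.b1h_io import basic_filter
    from zfhelix.synthetic import (
        SimulationParams,
        make_library_contexts,
        sample_code,
        simulate_single_campaign,
    )
    from zfhelix.types import SelectionDataset

    code = sample_code(2, 2.0)
    contexts = make_library_contexts(code, 2)
    datasets = simulate_single_campaign(
        code, contexts, SimulationParams(seed=2, n_candidates=10_000_000, max_survivors=30)
    )
    data = [
        SelectionDataset(target=d.target, records=basic_filter(d.records), context=d.context)
        for d in datasets
    ]
    cfg = TrainConfig(learning_rate=3e-3, batch_size=256, max_epochs=10, patience=10, seed=2)
    return pretrain_single_module(data, ModelConfig.toy(), cfg)


class TestFullModelTraining:
    def test_frozen_modules_unchanged(self, tiny_corpus, tiny_single_module):
        cfg = TrainConfig(
            learning_rate=3e-3, batch_size=256, max_epochs=2, patience=2,
            seed=0, init_mode="transfer_frozen",
        )
        trained = train_full_model(
            tiny_corpus, ModelConfig.toy(), cfg,
            pretrained=(tiny_single_module, tiny_single_module),
        )
        before = state_hash(tiny_single_module.network)
        after1 = state_hash(trained.network.module1)
        after2 = state_hash(trained.network.module2)
        assert before == after1 == after2

    def test_transfer_init_converges_faster_than_random(
        self, tiny_corpus, tiny_single_module
    ):
        """Warm-starting the lower modules reaches a lower validation loss
        than random initialisation within the same small epoch budget
        (median over 3 seeds)."""
        diffs = []
        for seed in (0, 1, 2):
            losses = {}
            for mode in ("transfer", "random"):
                cfg = TrainConfig(
                    learning_rate=3e-3, batch_size=512, max_epochs=6,
                    patience=6, seed=seed, init_mode=mode,
                )
                trained = train_full_model(
                    tiny_corpus, ModelConfig.toy(), cfg,
                    pretrained=(tiny_single_module, tiny_single_module),
                )
                losses[mode] = trained.metadata["best_val_loss"]
            diffs.append(losses["transfer"] - losses["random"])
        assert np.median(diffs) < 0

    def test_trajectory_seed_determinism(self, tiny_corpus):
        cfg = TrainConfig(
            learning_rate=3e-3, batch_size=256, max_epochs=2, patience=2, seed=9
        )
        a = train_full_model(tiny_corpus, ModelConfig.toy(), cfg)
        b = train_full_model(tiny_corpus, ModelConfig.toy(), cfg)
        assert a.metadata["history"] == b.metadata["history"]
        assert state_hash(a.network) == state_hash(b.network)

    def test_early_stopping_restores_best(self, tiny_corpus):
        cfg = TrainConfig(
            learning_rate=3e-3, batch_size=256, max_epochs=8, patience=2, seed=0
        )
        trained = train_full_model(tiny_corpus, ModelConfig.toy(), cfg)
        history = trained.metadata["history"]
        best = min(h["val_loss"] for h in history)
        assert trained.metadata["best_val_loss"] == pytest.approx(best)


class TestPwmMse:
    def test_zero_on_identical(self):
        p = np.random.default_rng(0).dirichlet(np.ones(20), size=12)
        assert pwm_mse(p, p) == 0.0

    def test_uniform_vs_point_mass_closed_form(self):
        uniform = np.full((1, 20), 1 / 20)
        point = np.zeros((1, 20))
        point[0, 0] = 1.0
        expected = ((1 - 1 / 20) ** 2 + 19 * (1 / 20) ** 2) / 20
        assert pwm_mse(uniform, point) == pytest.approx(expected)
        assert expected == pytest.approx(0.0475)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            pwm_mse(np.ones((2, 20)), np.ones((3, 20)))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, memo_pair_model):
        path = tmp_path / "model.npz"
        memo_pair_model.save(path)
        back = TrainedModel.load(path)
        tokens = encode_residues("______RDHTNK", "_")
        np.testing.assert_allclose(
            back.predict_probs("ACGTACG", tokens),
            memo_pair_model.predict_probs("ACGTACG", tokens),
            atol=1e-12,
        )
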