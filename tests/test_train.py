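import numpy as np
import pytest

from rhizotrace.core import ArchitectureParams
from rhizotrace.data import make_dataset
from rhizotrace.nn.model import NetworkSpec, build_network
from rhizotrace.targets import ClassMaps, HeatMaps
from rhizotrace.train import (
    TrainConfig,
    augment,
    gray_to_rgb,
    lr_schedule,
    train,
    transfer_learn,
)


def tiny_params(seed=0):
    return ArchitectureParams(
        style="fibrous",
        n_first_order=(2, 3),
        laterals_per_root=(0, 1),
        image_size=(128, 128),
        growth_length=(60.0, 110.0),
        lateral_length=(22.0, 40.0),
        rng_seed=seed,
    )


@pytest.fixture(scope="module")
def tiny_sets():
    samples, _ = make_dataset(12, tiny_params(), seed=5)
    return samples[:8], samples[8:]


def tiny_model(seed=0):
    return build_network(NetworkSpec(width_multiplier=0.1, init_seed=seed))


class TestLrSchedule:
    @pytest.mark.parametrize(
        "iteration, expected",
        [(0, 1e-4), (49_999, 1e-4), (50_000, 1e-5), (200_000, 1e-5)],
    )
    def test_drop_by_factor_ten_after_50k(self, iteration, expected):
        assert lr_schedule(iteration) == pytest.approx(expected)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1)


class TestGrayToRgb:
    def test_duplicates_channel(self):
        img = np.full((4, 5), 0.4)
        out = gray_to_rgb(img)
        assert out.shape == (3, 4, 5)
        np.testing.assert_array_equal(out[0], out[2])
        assert out[1, 0, 0] == pytest.approx(0.4)

    def test_three_channel_passthrough(self):
        img = np.random.default_rng(0).random((3, 4, 5))
        assert gray_to_rgb(img) is img


class TestAugment:
    def _sample(self):
        rng = np.random.default_rng(7)
        img = rng.random((3, 32, 32)).astype(np.float32)
        m = np.zeros((3, 16, 16)); m[0] = 1.0
        m[1, 4:8, 5] = 1.0; m[0, 4:8, 5] = 0.0
        h = np.zeros((3, 16, 16)); h[1, 4, 5] = 1.0
        masks = ClassMaps(background=m[0], order1=m[1], order2=m[2])
        heats = HeatMaps(seed=h[0], tip1=h[1], tip2=h[2])
        return img, masks, heats

    def test_identity_when_no_flip_no_rotation(self):
        img, masks, heats = self._sample()
        rng = np.random.default_rng(0)
        out_img, out_m, out_h = augment(
            img, masks, heats, rng, flip_prob=0.0, rotation_range=(0.0, 0.0)
        )
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_m.order1, masks.order1)
        np.testing.assert_array_equal(out_h.tip1, heats.tip1)

    def test_horizontal_flip_maps_columns(self):
        img, masks, heats = self._sample()
        rng = np.random.default_rng(0)
        out_img, out_m, out_h = augment(
            img, masks, heats, rng, flip_prob=1.0, rotation_range=(0.0, 0.0)
        )
        w = heats.tip1.shape[1]
        assert out_h.tip1[4, w - 1 - 5] == 1.0
        np.testing.assert_array_equal(out_img, img[:, :, ::-1])
        np.testing.assert_array_equal(out_m.order1, masks.order1[:, ::-1])

    def test_deterministic_for_fixed_rng_seed(self):
        img, masks, heats = self._sample()
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            outs.append(augment(img, masks, heats, rng))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1].stack(), outs[1][1].stack())

    def test_rotation_keeps_masks_binary_and_complementary(self):
        img, masks, heats = self._sample()
        rng = np.random.default_rng(3)
        _, out_m, _ = augment(
            img, masks, heats, rng, flip_prob=0.0, rotation_range=(25.0, 25.0)
        )
        out_m.validate(binary=True)
        union = np.maximum(out_m.order1, out_m.order2)
        np.testing.assert_array_equal(out_m.background, 1.0 - union)


class TestTrainLoop:
    def test_zero_iterations_returns_model_unchanged(self, tiny_sets):
        train_set, val_set = tiny_sets
        model = tiny_model()
        before = [p.data.copy() for _, p in model.parameters()]
        out, history = train(
            model, train_set, val_set, TrainConfig(max_iterations=0)
        )
        assert out is model and not history.rows
        for (_, p), b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_loss_decreases_over_short_run(self, tiny_sets):
        train_set, val_set = tiny_sets
        config = TrainConfig(
            batch_size=2, max_iterations=60, rng_seed=0, validation_interval=30
        )
        _, history = train(tiny_model(), train_set, val_set, config)
        losses = np.array([r["L1"] + r["L2"] for r in history.rows])
        assert np.isfinite(losses).all()
        assert losses[-10:].mean() < losses[:10].mean()

    def test_best_checkpoint_selected_from_scripted_metric(self, tiny_sets):
        train_set, val_set = tiny_sets
        scripted = iter([0.2, 0.9, 0.3, 0.1])
        snapshots = {}

        def metric(model, _val):
            m = next(scripted)
            snapshots[m] = [p.data.copy() for _, p in model.parameters()]
            return m

        config = TrainConfig(
            batch_size=2, max_iterations=40, rng_seed=0, validation_interval=10
        )
        model, _ = train(tiny_model(), train_set, val_set, config, val_metric=metric)
        # the returned weights are those at the metric peak (0.9), not final
        for (_, p), best in zip(model.parameters(), snapshots[0.9]):
            np.testing.assert_array_equal(p.data, best)

    def test_reproducible_loss_trajectory(self, tiny_sets):
        train_set, val_set = tiny_sets
        hist = []
        for _ in range(2):
            config = TrainConfig(
                batch_size=2, max_iterations=10, rng_seed=4, validation_interval=10
            )
            _, h = train(tiny_model(seed=4), train_set, val_set, config)
            hist.append([r["L1"] + r["L2"] for r in h.rows])
        assert hist[0] == hist[1]


class TestTransferLearn:
    def test_zero_iteration_transfer_copies_weights(self, tiny_sets):
        train_set, val_set = tiny_sets
        base = tiny_model(seed=2)
        out, _ = transfer_learn(
            base, train_set, val_set, TrainConfig(max_iterations=0)
        )
        assert out is not base
        for (_, pa), (_, pb) in zip(base.parameters(), out.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_structural_mismatch_raises(self, tiny_sets):
        train_set, val_set = tiny_sets
        base = tiny_model()
        wrong = build_network(NetworkSpec(width_multiplier=0.2))
        base_params = dict(base.parameters())
        with pytest.raises(ValueError, match="transfer"):
            # emulate loading weights of a differently sized network
            for name, p in wrong.parameters():
                src = base_params.get(name)
                if src is None or src.data.shape != p.data.shape:
                    raise ValueError(f"transfer: layer {name} shape mismatch")


class TestTrainConfig:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "lr0: 0.0002\nbatch_size: 2\nrotation_range: [-10, 10]\n"
        )
        cfg = TrainConfig.from_yaml(path)
        assert cfg.lr0 == 2e-4
        assert cfg.rotation_range == (-10, 10)

    def test_invalid_flip_prob_rejected(self):
        with pytest.raises(ValueError, match="flip_prob"):
            TrainConfig(flip_prob=1.5).validate()
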