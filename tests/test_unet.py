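"""U-Net architecture, determinism, freezing, and training mechanics."""
import numpy as np
import pytest

from m3sl.errors import ArchitectureError, ShapeError
from m3sl.losses import combined_loss, combined_loss_grad
from m3sl.nn import (
    Adam,
    FreezePlan,
    ModelSpec,
    apply_freeze,
    build_unet,
    predict_slices,
)

DESK = dict(input_edge=16, width_multiplier=1.0 / 16.0)


def train_steps(model, x, y, n_steps, lr=1e-3):
    opt = Adam(model.parameters(), lr=lr)
    for _ in range(n_steps):
        p = model.forward(x)
        opt.zero_grad()
        model.backward(combined_loss_grad(p, y))
        opt.step()


@pytest.fixture
def tiny_batch(rng):
    x = rng.random((4, 16, 16))
    y = np.zeros((4, 16, 16))
    y[:, 5:9, 5:9] = 1.0
    return x, y


class TestArchitecture:
    def test_default_spec_has_thirteen_encoder_convs_in_five_blocks(self):
        model = build_unet(ModelSpec(seed=0, **DESK))
        assert len(model.enc_convs) == 5
        assert [len(b) for b in model.enc_convs] == [2, 2, 3, 3, 3]
        assert len(model.encoder_conv_layers()) == 13

    def test_forward_shape_and_open_unit_range(self, rng):
        model = build_unet(ModelSpec(seed=1, **DESK))
        out = model.forward(rng.random((3, 16, 16)))
        assert out.shape == (3, 16, 16)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_same_seed_builds_identical_parameters(self):
        a = build_unet(ModelSpec(seed=7, **DESK))
        b = build_unet(ModelSpec(seed=7, **DESK))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = build_unet(ModelSpec(seed=8, **DESK))
        assert any(
            not np.array_equal(pa.value, pc.value)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_parameter_count_is_function_of_spec(self):
        n16 = build_unet(ModelSpec(seed=0, **DESK)).n_parameters()
        assert n16 == build_unet(ModelSpec(seed=99, **DESK)).n_parameters()
        wider = build_unet(
            ModelSpec(seed=0, input_edge=16, width_multiplier=1.0 / 8.0)
        ).n_parameters()
        assert wider > n16

    def test_indivisible_input_edge_rejected(self):
        with pytest.raises(ArchitectureError, match="divisible"):
            build_unet(ModelSpec(input_edge=24, width_multiplier=1.0 / 16.0))

    def test_wrong_slice_size_rejected(self, rng):
        model = build_unet(ModelSpec(seed=0, **DESK))
        with pytest.raises(ShapeError):
            model.forward(rng.random((2, 32, 32)))


class TestInference:
    def test_repeated_inference_is_deterministic(self, rng):
        model = build_unet(ModelSpec(seed=3, **DESK))
        x = rng.random((5, 16, 16))
        np.testing.assert_array_equal(predict_slices(model, x), predict_slices(model, x))

    def test_constant_input_gives_constant_central_output(self):
        model = build_unet(ModelSpec(seed=2, **DESK))
        out = predict_slices(model, np.zeros((1, 16, 16)))[0]
        center = out[4:12, 4:12]
        assert center.std() < 1e-6

    def test_stack_maps_to_stack(self, rng):
        model = build_unet(ModelSpec(seed=0, **DESK))
        out = predict_slices(model, rng.random((9, 16, 16)))
        assert out.shape == (9, 16, 16)


class TestFreezing:
    def test_k_zero_everything_trainable(self):
        model = apply_freeze(build_unet(ModelSpec(seed=0, **DESK)), FreezePlan(k=0))
        assert all(p.trainable for p in model.parameters())

    @pytest.mark.parametrize("k", [5, 10, 13])
    def test_frozen_layers_bitwise_unchanged_by_training(self, k, tiny_batch):
        model = apply_freeze(build_unet(ModelSpec(seed=0, **DESK)), FreezePlan(k=k))
        frozen_before = [
            (p.name, p.value.copy())
            for conv in model.encoder_conv_layers()[:k]
            for p in conv.params()
        ]
        params_before = {p.name: p.value.copy() for p in model.parameters()}
        train_steps(model, *tiny_batch, n_steps=3)
        for name, before in frozen_before:
            after = next(p.value for p in model.parameters() if p.name == name)
            np.testing.assert_array_equal(before, after)
        changed = [
            name
            for name, before in params_before.items()
            if not np.array_equal(
                before, next(p.value for p in model.parameters() if p.name == name)
            )
        ]
        assert changed, "some unfrozen parameter must move"
        frozen_names = {name for name, _ in frozen_before}
        assert not (set(changed) & frozen_names)

    def test_full_freeze_only_decoder_moves(self, tiny_batch):
        model = apply_freeze(build_unet(ModelSpec(seed=0, **DESK)), FreezePlan(k=13))
        enc_names = {
            p.name for c in model.encoder_conv_layers() for p in c.params()
        }
        before = {p.name: p.value.copy() for p in model.parameters()}
        train_steps(model, *tiny_batch, n_steps=3)
        for p in model.parameters():
            if p.name in enc_names:
                np.testing.assert_array_equal(before[p.name], p.value)
        assert any(
            p.name not in enc_names and not np.array_equal(before[p.name], p.value)
            for p in model.parameters()
        )

    def test_out_of_range_k_rejected(self):
        model = build_unet(ModelSpec(seed=0, **DESK))
        with pytest.raises(ValueError):
            apply_freeze(model, FreezePlan(k=14))
        with pytest.raises(ValueError):
            apply_freeze(model, FreezePlan(k=-1))

    def test_refreezing_smaller_k_reenables_layers(self):
        model = build_unet(ModelSpec(seed=0, **DESK))
        apply_freeze(model, FreezePlan(k=10))
        apply_freeze(model, FreezePlan(k=5))
        layers = model.encoder_conv_layers()
        assert all(p.trainable for p in layers[5].params())
        assert not any(p.trainable for p in layers[4].params())


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model = build_unet(
            ModelSpec(seed=0, input_edge=16, width_multiplier=1 / 16, dtype="float64")
        )
        x = rng.random((2, 16, 16))
        y = (rng.random((2, 16, 16)) > 0.7).astype(float)
        p = model.forward(x)
        model.backward(combined_loss_grad(p, y))
        eps = 1e-6
        params = model.parameters()
        for pi in (0, 5, 21, 40, len(params) - 1):
            prm = params[pi]
            idx = (0,) * prm.value.ndim
            analytic = prm.grad[idx]
            prm.value[idx] += eps
            hi = combined_loss(model.forward(x), y)
            prm.value[idx] -= 2 * eps
            lo = combined_loss(model.forward(x), y)
            prm.value[idx] += eps
            fd = (hi - lo) / (2 * eps)
            assert analytic == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestCapacity:
    def test_can_overfit_one_slice(self, rng):
        """A width-shrunk net drives the loss near zero on a single slice
        within 200 steps — capacity sanity check."""
        model = build_unet(ModelSpec(seed=0, **DESK))
        x = 0.4 + 0.05 * rng.standard_normal((1, 16, 16))
        y = np.zeros((1, 16, 16))
        x[0, 5:9, 6:10] += 0.5
        y[0, 5:9, 6:10] = 1.0
        train_steps(model, x, y, n_steps=200, lr=5e-3)
        final = combined_loss(model.forward(x), y)
        assert final < 0.2


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = build_unet(ModelSpec(seed=4, **DESK))
        apply_freeze(model, FreezePlan(k=5))
        model.stage_history.append("silver")
        model.save(tmp_path / "ckpt.npz")
        from m3sl.nn import UNet2D

        loaded = UNet2D.load(tmp_path / "ckpt.npz")
        for pa, pb in zip(model.parameters(), loaded.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
            assert pa.trainable == pb.trainable
        assert loaded.freeze_history == [5]
        assert loaded.stage_history == ["silver"]
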