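"""Perturbation apply/align semantics and round-trip properties."""

import numpy as np
import pytest

from polypssl.losses import consistency_loss
from polypssl.nn.tensor import Tensor
from polypssl.perturb import (
    align_prediction,
    align_tensor,
    apply_batch,
    apply_perturbation,
    build_bundle,
    make_noise_spec,
    make_rotation_spec,
    make_scaling_spec,
    sample_specs,
)


def _smooth_image(rng, h=32, w=32, channels=3):
    """Band-limited test image (bilinear upsample of a coarse field)."""
    from polypssl.nn.functional import linear_resize_matrix

    coarse = rng.random((6, 6, channels) if channels else (6, 6))
    ah, aw = linear_resize_matrix(h, 6), linear_resize_matrix(w, 6)
    if channels:
        return np.einsum("oh,hwc,pw->opc", ah, coarse, aw)
    return ah @ coarse @ aw.T


class TestRotation:
    def test_four_quarter_turns_are_identity(self, rng):
        img = rng.random((16, 16, 3))
        spec = make_rotation_spec(90)
        out = img
        for _ in range(4):
            out = apply_perturbation(out, spec)
        np.testing.assert_array_equal(out, img)

    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_align_inverts_apply_bitwise(self, angle, rng):
        img = rng.random((16, 16))
        spec = make_rotation_spec(angle)
        np.testing.assert_array_equal(align_prediction(apply_perturbation(img, spec), spec), img)

    def test_bad_angle_rejected(self):
        with pytest.raises(ValueError):
            make_rotation_spec(45)


class TestNoise:
    def test_zero_sd_is_identity(self, rng):
        img = rng.random((8, 8, 3))
        np.testing.assert_array_equal(apply_perturbation(img, make_noise_spec(0.0)), img)

    def test_seeded_noise_replays_identically(self, rng):
        img = rng.random((8, 8, 3))
        spec = make_noise_spec(0.05, seed=99)
        np.testing.assert_array_equal(apply_perturbation(img, spec),
                                      apply_perturbation(img, spec))

    def test_output_stays_in_unit_interval(self, rng):
        img = rng.random((8, 8, 3))
        out = apply_perturbation(img, make_noise_spec(0.5, seed=1))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_alignment_is_identity(self, rng):
        pred = rng.random((8, 8))
        assert align_prediction(pred, make_noise_spec(0.1)) is not None
        np.testing.assert_array_equal(align_prediction(pred, make_noise_spec(0.1)), pred)


class TestScaling:
    def test_factor_one_is_near_identity(self, rng):
        img = rng.random((16, 16, 3))
        spec = make_scaling_spec(1.0, (16, 16), size_multiple=4)
        out = apply_perturbation(img, spec)
        assert out.shape == img.shape
        np.testing.assert_allclose(out, img, atol=1e-6)

    @pytest.mark.parametrize("factor", [0.8, 1.25])
    def test_round_trip_on_smooth_maps(self, factor):
        """Down/up resample pairs invert to interpolation accuracy on
        band-limited content (a one-period sinusoid)."""
        h = w = 32
        yy, xx = np.mgrid[0:h, 0:w]
        img = 0.5 + 0.4 * np.sin(2 * np.pi * xx / w) * np.cos(2 * np.pi * yy / h)
        spec = make_scaling_spec(factor, img.shape, size_multiple=4)
        back = align_prediction(apply_perturbation(img, spec), spec)
        assert np.abs(back - img).max() < 0.02

    def test_scaled_size_is_stride_compatible(self):
        spec = make_scaling_spec(1.17, (64, 64), size_multiple=8)
        sh, sw = spec.params["scaled_size"]
        assert sh % 8 == 0 and sw % 8 == 0

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            make_scaling_spec(2.0, (64, 64))


class TestBatchAndTensorPaths:
    """The (B,C,H,W) training path must agree with the public per-image path."""

    @pytest.mark.parametrize("spec_fn", [
        lambda: make_rotation_spec(270),
        lambda: make_scaling_spec(1.25, (16, 16), size_multiple=4),
    ])
    def test_apply_batch_matches_per_image_for_geometric_kinds(self, spec_fn, rng):
        spec = spec_fn()
        imgs = rng.random((2, 16, 16, 3))
        batch = imgs.transpose(0, 3, 1, 2)
        out_batch = apply_batch(batch, spec)
        for i in range(2):
            expect = apply_perturbation(imgs[i], spec)
            np.testing.assert_allclose(out_batch[i].transpose(1, 2, 0), expect, atol=2e-6)

    def test_apply_batch_noise_is_seed_reproducible(self, rng):
        spec = make_noise_spec(0.05, seed=3)
        batch = rng.random((2, 3, 16, 16))
        np.testing.assert_array_equal(apply_batch(batch, spec), apply_batch(batch, spec))

    @pytest.mark.parametrize("spec_fn", [
        lambda: make_rotation_spec(90),
        lambda: make_noise_spec(0.05, seed=3),
        lambda: make_scaling_spec(0.8, (16, 16), size_multiple=4),
    ])
    def test_align_tensor_matches_align_prediction(self, spec_fn, rng):
        spec = spec_fn()
        if spec.kind == "random_scaling":
            h = spec.params["scaled_size"][0]
        elif spec.kind == "rotation":
            h = 16
        else:
            h = 16
        pred = rng.random((2, h, h))
        out = align_tensor(Tensor(pred), spec).data
        for i in range(2):
            np.testing.assert_allclose(out[i], align_prediction(pred[i], spec), atol=1e-12)


class TestBundle:
    def test_three_kind_bundle(self, rng):
        img = _smooth_image(rng)
        specs = sample_specs(("random_scaling", "gaussian_noise", "rotation"),
                             img.shape[:2], np.random.default_rng(5), size_multiple=4)
        bundle = build_bundle(lambda x: x[..., 0], img, specs)
        assert len(bundle.aligned) == 3
        assert all(a.shape == bundle.reference.shape for a in bundle.aligned)

    def test_single_noise_bundle(self, rng):
        img = rng.random((16, 16, 3))
        bundle = build_bundle(lambda x: x[..., 0], img, [make_noise_spec(0.02, seed=1)])
        assert len(bundle.aligned) == 1

    def test_identity_network_rotation_equivariance(self, rng):
        """For an identity map, the aligned prediction equals the reference."""
        img = rng.random((16, 16, 3))
        bundle = build_bundle(lambda x: x, img, [make_rotation_spec(180)])
        np.testing.assert_array_equal(bundle.aligned[0], bundle.reference)
        assert consistency_loss(bundle) == 0.0

    def test_empty_or_duplicate_specs_rejected(self, rng):
        img = rng.random((8, 8, 3))
        with pytest.raises(ValueError):
            build_bundle(lambda x: x, img, [])
        with pytest.raises(ValueError):
            build_bundle(lambda x: x, img,
                         [make_rotation_spec(90), make_rotation_spec(180)])

    def test_reference_net_overrides_reference_branch(self, rng):
        img = rng.random((8, 8, 3))
        bundle = build_bundle(lambda x: x[..., 0], img, [make_noise_spec(0.0)],
                              reference_net=lambda x: np.zeros(x.shape[:2]))
        np.testing.assert_array_equal(bundle.reference, 0.0)
        np.testing.assert_allclose(bundle.aligned[0], img[..., 0])
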