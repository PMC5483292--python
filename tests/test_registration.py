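"""Binocular localization, fixed-image construction, GA affine registration."""

import numpy as np
import pytest

from thermoface.core import AffineParams, ThermalSequence, compose_displacement
from thermoface.phantom import face_template
from thermoface.registration import (
    GaConfig,
    RegistrationError,
    apply_affine,
    build_fixed_image,
    ga_affine_register,
    locate_binocular_centers,
    register_sequence,
)

FAST_GA = GaConfig(population=30, generations=30, seed=7)


class TestApplyAffine:
    def test_identity_is_bit_exact(self, small_template):
        out = apply_affine(small_template, AffineParams(), fill=0.0)
        assert np.array_equal(out, small_template)

    def test_translation_round_trip_on_interior(self, small_template):
        fwd = apply_affine(small_template, AffineParams(tx=10), fill=27.0)
        back = apply_affine(fwd, AffineParams(tx=-10), fill=27.0)
        interior = np.s_[20:-20, 20:-20]
        assert np.abs(back[interior] - small_template[interior]).max() < 1e-6

    def test_constant_frame_interior_and_fill(self):
        frame = np.full((40, 60), 30.0)
        out = apply_affine(frame, AffineParams(tx=8.0, theta=5.0), fill=27.0)
        assert out[20, 30] == pytest.approx(30.0)
        assert out[0, 0] == pytest.approx(27.0) or out[-1, -1] == pytest.approx(27.0)
        assert set(np.round(np.unique(out), 6)) <= {27.0, 30.0} | set(
            np.round(np.linspace(27, 30, 50), 6)
        )


class TestBinocularLocalization:
    def test_centroids_within_one_px_of_planted_eyes(self, small_template, small_config):
        left, right = locate_binocular_centers(small_template)
        assert np.hypot(*(np.subtract(left, small_config.eye_left))) < 1.0
        assert np.hypot(*(np.subtract(right, small_config.eye_right))) < 1.0

    def test_symmetric_eyes_give_midline_midpoint(self, small_template, small_config):
        left, right = locate_binocular_centers(small_template)
        mid_x = (left[0] + right[0]) / 2.0
        planted_mid = (small_config.eye_left[0] + small_config.eye_right[0]) / 2.0
        assert mid_x == pytest.approx(planted_mid, abs=0.5)

    def test_uniform_frame_fails(self):
        with pytest.raises(RegistrationError):
            locate_binocular_centers(np.full((60, 80), 30.0))

    def test_left_point_has_smaller_column(self, small_template):
        left, right = locate_binocular_centers(small_template)
        assert left[0] < right[0]


class TestFixedImage:
    def test_canonical_frame_unchanged(self, small_template):
        seq = ThermalSequence(frames=small_template[None])
        fixed = build_fixed_image(seq)
        assert np.array_equal(fixed, small_template)

    def test_shifted_frame_restored(self, small_template, small_config):
        shifted = apply_affine(small_template, AffineParams(tx=5), fill=small_config.ambient)
        fixed = build_fixed_image(ThermalSequence(frames=shifted[None]))
        left, right = locate_binocular_centers(fixed)
        mid_x = (left[0] + right[0]) / 2.0
        assert mid_x == pytest.approx(small_template.shape[1] / 2.0, abs=0.3)

    def test_mirrored_frame_flipped_back(self, small_template):
        mirrored = small_template[:, ::-1].copy()
        fixed = build_fixed_image(ThermalSequence(frames=mirrored[None]))
        assert np.abs(fixed - small_template).max() < 1e-9


class TestGaRegistration:
    def test_self_registration_recovers_identity(self, small_template):
        params, trace = ga_affine_register(small_template, small_template, FAST_GA)
        err_t, err_r = compose_displacement(params, AffineParams(), small_template.shape)
        assert err_t < 0.3 and err_r < 0.3
        assert trace[-1] == pytest.approx(0.0, abs=1e-3)

    def test_fitness_trace_non_decreasing(self, small_template):
        moving = apply_affine(small_template, AffineParams(tx=4, theta=1.5), fill=27.0)
        _, trace = ga_affine_register(moving, small_template, FAST_GA)
        assert np.all(np.diff(trace) >= -1e-12)

    def test_planted_transform_recovery(self, small_template, small_config):
        rng = np.random.default_rng(42)
        for i in range(3):
            planted = AffineParams(
                tx=rng.normal(0, 2), ty=rng.normal(0, 2), theta=rng.normal(0, 1)
            )
            moving = apply_affine(small_template, planted, fill=small_config.ambient)
            moving = moving + rng.normal(0, 0.05, moving.shape)
            rec, _ = ga_affine_register(moving, small_template, seed=100 + i)
            err_t, err_r = compose_displacement(rec, planted, small_template.shape)
            assert err_t <= 0.5 and err_r <= 0.5

    def test_unrelated_frames_terminate(self):
        rng = np.random.default_rng(0)
        a = rng.normal(31, 1, (60, 80))
        b = rng.normal(31, 1, (60, 80))
        params, trace = ga_affine_register(a, b, GaConfig(population=10, generations=5))
        assert len(trace) > 0 and np.isfinite(trace[-1])

    def test_degenerate_fixed_image_rejected(self, small_template):
        with pytest.raises(RegistrationError):
            ga_affine_register(small_template, np.full_like(small_template, 30.0), FAST_GA)

    def test_deterministic_given_seed(self, small_template):
        moving = apply_affine(small_template, AffineParams(tx=3), fill=27.0)
        p1, t1 = ga_affine_register(moving, small_template, FAST_GA, seed=5)
        p2, t2 = ga_affine_register(moving, small_template, FAST_GA, seed=5)
        assert p1 == p2 and t1 == t2

    def test_matches_grid_search_on_integer_translations(self):
        """On a tiny frame with integer-translation-only jitter, the GA finds
        the same optimum as exhaustive integer grid search."""
        rng = np.random.default_rng(3)
        fixed = np.full((16, 16), 27.0)
        fixed[5:11, 4:12] = 33.0 + rng.normal(0, 0.2, (6, 8))
        planted = AffineParams(tx=2.0, ty=-1.0)
        moving = apply_affine(fixed, planted, fill=27.0)
        mask = fixed > 28.5

        def mad(p):
            return -np.mean(np.abs(apply_affine(moving, p, fill=27.0)[mask] - fixed[mask]))

        best_grid = max(
            ((tx, ty) for tx in range(-4, 5) for ty in range(-4, 5)),
            key=lambda t: mad(AffineParams(tx=t[0], ty=t[1])),
        )
        cfg = GaConfig(
            population=40,
            generations=40,
            stage1_translation=4.0,
            stage1_rotation=0.0,
            stage2_translation=1.0,
            stage2_rotation=0.0,
            stage2_scale=0.0,
            stage2_shear=0.0,
            seed=1,
        )
        rec, _ = ga_affine_register(moving, fixed, cfg)
        assert (round(rec.tx), round(rec.ty)) == best_grid == (-2, 1)


class TestRegisterSequence:
    def _mini_sequence(self, config, n=4, jitter_sd=1.5, seed=0):
        rng = np.random.default_rng(seed)
        tpl = face_template(config)
        frames, planted = [tpl.copy()], [AffineParams()]
        for _ in range(n - 1):
            p = AffineParams(
                tx=rng.normal(0, jitter_sd),
                ty=rng.normal(0, jitter_sd),
                theta=rng.normal(0, 0.8),
            )
            frames.append(
                apply_affine(tpl, p, fill=config.ambient)
                + rng.normal(0, 0.05, tpl.shape)
            )
            planted.append(p)
        return ThermalSequence(frames=np.array(frames)), planted

    def test_planted_jitter_reduces_overlap_error(self, small_config):
        seq, _ = self._mini_sequence(small_config)
        _, result = register_sequence(seq, FAST_GA)
        assert len(result.params) == seq.n_frames
        assert result.err_after.mean() < result.err_before.mean()

    def test_jitter_free_sequence_stays_near_identity(self, small_config):
        tpl = face_template(small_config)
        seq = ThermalSequence(frames=np.repeat(tpl[None], 3, axis=0))
        _, result = register_sequence(seq, FAST_GA)
        for p in result.params:
            err_t, err_r = compose_displacement(p, AffineParams(), tpl.shape)
            assert err_t < 0.3 and err_r < 0.3

    def test_report_dataframe_schema(self, small_config):
        seq, _ = self._mini_sequence(small_config, n=2)
        _, result = register_sequence(seq, FAST_GA)
        df = result.to_dataframe()
        assert list(df.columns) == [
            "frame", "tx", "ty", "theta", "sx", "sy", "shear",
            "fitness", "err_before", "err_after",
        ]
        assert len(df) == 2
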