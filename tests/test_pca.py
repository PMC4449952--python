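"""PCA core: centering, Gram trick, lifting, projection, fit/predict."""

from __future__ import annotations

import numpy as np
import pytest

from xasurrogate import correlation
from xasurrogate.io import XASequence
from xasurrogate.pca import (
    PCAModel,
    center_columns,
    fit,
    fit_matrix,
    gram_eig,
    lift_first_component,
    predict,
    project,
)
from xasurrogate.preprocess import PreprocessConfig

SQ2 = np.sqrt(2.0)


def direct_first_component(Xc: np.ndarray) -> np.ndarray:
    """Oracle: leading eigenvector of the dense D x D covariance."""
    evals, evecs = np.linalg.eigh(Xc @ Xc.T)
    return evecs[:, np.argmax(evals)]


class TestCenter:
    def test_hand_example(self):
        Xc, mean = center_columns(np.array([[1.0, 3.0], [2.0, 2.0]]))
        np.testing.assert_allclose(mean, [2.0, 2.0])
        np.testing.assert_allclose(Xc, [[-1.0, 1.0], [0.0, 0.0]])

    def test_identical_columns_center_to_zero(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 4))
        Xc, _ = center_columns(X)
        np.testing.assert_allclose(Xc, 0.0)

    def test_row_sums_vanish(self, rng):
        Xc, _ = center_columns(rng.normal(size=(30, 7)))
        np.testing.assert_allclose(Xc.sum(axis=1), 0.0, atol=1e-12)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            center_columns(np.ones((4, 1)))


class TestGramEig:
    def test_hand_eigendecomposition(self):
        Xc = np.array([[1.0, -1.0], [1.0, -1.0]])
        evecs, evals = gram_eig(Xc)
        np.testing.assert_allclose(evals, [4.0, 0.0], atol=1e-12)
        v1 = evecs[:, 0]
        np.testing.assert_allclose(
            np.abs(v1), [1 / SQ2, 1 / SQ2], atol=1e-12
        )
        assert v1[0] * v1[1] < 0  # opposite signs

    def test_null_matrix(self):
        _, evals = gram_eig(np.zeros((4, 3)))
        np.testing.assert_allclose(evals, 0.0)

    def test_trace_identity(self, rng):
        Xc, _ = center_columns(rng.normal(size=(8, 5)))
        _, evals = gram_eig(Xc)
        assert evals.sum() == pytest.approx(
            np.trace(Xc.T @ Xc), abs=1e-9
        )

    def test_centering_forces_zero_eigenvalue(self, rng):
        Xc, _ = center_columns(rng.normal(size=(20, 6)))
        _, evals = gram_eig(Xc)
        assert evals[-1] == pytest.approx(0.0, abs=1e-8)


class TestLift:
    def test_hand_example(self):
        Xc = np.array([[1.0, -1.0], [1.0, -1.0]])
        evecs, evals = gram_eig(Xc)
        e1 = lift_first_component(Xc, evecs, evals)
        np.testing.assert_allclose(e1, [1 / SQ2, 1 / SQ2], atol=1e-12)

    def test_unit_norm(self, rng):
        Xc, _ = center_columns(rng.normal(size=(40, 9)))
        e1 = lift_first_component(Xc, *gram_eig(Xc))
        assert np.linalg.norm(e1) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_direct_covariance_eigendecomposition(self, rng):
        Xc, _ = center_columns(rng.normal(size=(30, 8)))
        e1 = lift_first_component(Xc, *gram_eig(Xc))
        ref = direct_first_component(Xc)
        if np.dot(ref, e1) < 0:
            ref = -ref
        np.testing.assert_allclose(e1, ref, atol=1e-8)

    def test_constant_sequence_raises_no_variance(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 4))
        Xc, _ = center_columns(X)
        with pytest.raises(ValueError, match="no variance"):
            lift_first_component(Xc, *gram_eig(Xc))

    def test_degenerate_spectrum_warns(self):
        u = np.array([1.0, 0.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0, 0.0])
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        Xc = np.outer(u, a) + np.outer(v, b)  # two equal eigenvalues
        with pytest.warns(RuntimeWarning, match="near-degenerate"):
            lift_first_component(Xc, *gram_eig(Xc))


class TestProject:
    def test_hand_example(self):
        Xc = np.array([[1.0, -1.0], [1.0, -1.0]])
        e1 = np.array([1 / SQ2, 1 / SQ2])
        np.testing.assert_allclose(project(Xc, e1), [SQ2, -SQ2])

    def test_null_matrix(self):
        np.testing.assert_allclose(
            project(np.zeros((3, 5)), np.array([1.0, 0, 0])), 0.0
        )

    def test_training_projection_energy_equals_lambda1(self, rng):
        Xc, _ = center_columns(rng.normal(size=(25, 7)))
        evecs, evals = gram_eig(Xc)
        e1 = lift_first_component(Xc, evecs, evals)
        p = project(Xc, e1)
        assert np.dot(p, p) == pytest.approx(evals[0], rel=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            project(np.zeros((3, 2)), np.zeros(4))


class TestGramTrickEquivalence:
    def test_surrogates_match_direct_eigendecomposition(self, rng):
        """Gram-trick surrogate equals the dense-covariance surrogate up
        to global sign on random D x N problems."""
        for _ in range(10):
            D = int(rng.integers(10, 100))
            N = int(rng.integers(4, 20))
            Xc, _ = center_columns(rng.normal(size=(D, N)))
            _, _, _, p = fit_matrix(Xc + 0.0)
            p_ref = Xc.T @ direct_first_component(Xc)
            if np.dot(p, p_ref) < 0:
                p_ref = -p_ref
            np.testing.assert_allclose(p, p_ref, atol=1e-8)


class TestFitPredict:
    def test_phantom_surrogate_tracks_breathing(self, small_phantom):
        model, signal = fit(small_phantom.sequence)
        assert correlation(signal, small_phantom.truth) >= 0.95
        assert model.plane_scope == "mono"
        assert model.n_train == small_phantom.sequence.n_frames

    def test_duplicated_biplane_pair_matches_monoplane(self, small_phantom):
        seq = small_phantom.sequence
        _, mono = fit(seq)
        _, bi = fit([seq, seq])
        assert bi.plane_scope == "biplane"
        r = abs(np.corrcoef(mono.values, bi.values)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_frame_range_restricts_training(self, small_phantom):
        model, signal = fit(small_phantom.sequence, frames=slice(0, 20))
        assert model.n_train == 20
        assert len(signal) == 20

    def test_predict_on_training_frames_reproduces_retrospective(
        self, small_phantom
    ):
        model, retro = fit(small_phantom.sequence)
        pro = predict(model, small_phantom.sequence)
        assert pro.mode == "prospective"
        np.testing.assert_allclose(pro.values, retro.values, atol=1e-9)

    def test_prospective_after_fade_tracks_breathing(self, small_phantom):
        n_train = small_phantom.config.fade_start_frame
        model, _ = fit(small_phantom.sequence, frames=slice(0, n_train))
        pro = predict(model, small_phantom.sequence.frames[n_train:])
        truth = small_phantom.truth.positions[n_train:]
        assert correlation(pro.values, truth) >= 0.90

    def test_single_frame_prediction(self, small_phantom):
        model, _ = fit(small_phantom.sequence)
        one = predict(model, small_phantom.sequence.frames[7])
        assert len(one) == 1

    def test_biplane_length_mismatch_rejected(self, small_phantom):
        seq = small_phantom.sequence
        short = XASequence(
            seq.frames[:10],
            pixel_spacing_mm=seq.pixel_spacing_mm,
            frame_rate_hz=seq.frame_rate_hz,
        )
        with pytest.raises(ValueError, match="time-synchronized"):
            fit([seq, short])

    def test_geometry_mismatch_rejected(self, small_phantom, rng):
        model, _ = fit(small_phantom.sequence)
        with pytest.raises(ValueError, match="training geometry"):
            predict(model, rng.normal(size=(2, 64, 64)))


class TestInvariances:
    def test_constant_offset_leaves_projection_unchanged(self, small_phantom):
        seq = small_phantom.sequence
        shifted = XASequence(
            seq.frames + 25.0,
            pixel_spacing_mm=seq.pixel_spacing_mm,
            frame_rate_hz=seq.frame_rate_hz,
        )
        _, p0 = fit(seq)
        _, p1 = fit(shifted)
        # float32 frame storage limits agreement to ~1e-8 relative
        scale = np.abs(p0.values).max()
        np.testing.assert_allclose(p1.values, p0.values, atol=1e-6 * scale)

    def test_intensity_scaling_scales_projection(self, small_phantom):
        seq = small_phantom.sequence
        scaled = XASequence(
            seq.frames * 3.0,
            pixel_spacing_mm=seq.pixel_spacing_mm,
            frame_rate_hz=seq.frame_rate_hz,
        )
        _, p0 = fit(seq)
        _, p1 = fit(scaled)
        np.testing.assert_allclose(p1.values, 3.0 * p0.values, rtol=1e-6)


class TestFrequencySpan:
    @pytest.mark.parametrize("f_breath,f_cardiac",
                             [(0.15, 1.0), (0.35, 1.5)])
    def test_recovery_across_physiological_frequencies(
        self, f_breath, f_cardiac
    ):
        """Breathing recovery holds at the edges of the physiological
        range: |r| >= 0.95 retrospective, >= 0.90 prospective (slow
        breathing leaves the training window short of a full cycle, so
        prospective accuracy drops but stays high)."""
        from conftest import small_config
        from xasurrogate.phantom import generate

        cfg = small_config(
            n_frames=120, fade_start_frame=60,
            breathing_freq_hz=f_breath, cardiac_freq_hz=f_cardiac,
            seed=31,
        )
        scene = generate(cfg)
        _, retro = fit(scene.sequence)
        assert correlation(retro, scene.truth) >= 0.95
        model, _ = fit(scene.sequence, frames=slice(0, 60))
        pro = predict(model, scene.sequence.frames[60:])
        assert correlation(pro.values, scene.truth.positions[60:]) >= 0.90


class TestEigenimage:
    def test_first_component_concentrates_on_diaphragm_band(
        self, small_phantom
    ):
        """Reshaped to the downsampled grid, the strongest |e1| weights
        lie in the band swept by the diaphragm border."""
        model, _ = fit(small_phantom.sequence)
        eigenimage = model.eigenimage(0)
        resolved = model.preprocess[0]
        band = small_phantom.swept_band_mask(
            factor=resolved.factor,
            margin_px=resolved.radius * resolved.factor,
        )
        mag = np.abs(eigenimage).ravel()
        top = mag >= np.quantile(mag, 0.9)
        frac = band.ravel()[top].mean()
        assert frac >= 0.5


class TestModelSerialization:
    def test_npz_round_trip(self, small_phantom, tmp_path):
        model, _ = fit(small_phantom.sequence)
        model.save(tmp_path / "model.npz")
        back = PCAModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.e1, model.e1)
        np.testing.assert_array_equal(back.mean_vector, model.mean_vector)
        assert back.plane_dims == model.plane_dims
        assert back.preprocess[0].to_dict() == model.preprocess[0].to_dict()
        pro = predict(back, small_phantom.sequence)
        _, retro = fit(small_phantom.sequence)
        np.testing.assert_allclose(pro.values, retro.values, atol=1e-9)
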