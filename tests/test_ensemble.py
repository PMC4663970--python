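import numpy as np
import pytest

from emdkit import (
    Image1D,
    PhotoreceptorConfig,
    SynthImageParams,
    build_ensemble,
    movie_response,
    photoreceptor_response,
    synth_image,
)
from emdkit.ensemble import _blur_panorama, load_ensemble, save_ensemble


@pytest.fixture(scope="module")
def image():
    return synth_image(SynthImageParams(target_kurtosis=5.0, asymmetry=0.2, seed=3))


def brute_force_response(image, velocity, offset, cfg, dx=0.1, dtf=0.0005):
    """Dense double-sum discretization of the response integral at ~10x finer
    dx and dt, treating the panorama as the periodic linear interpolant of
    its 1-degree samples."""
    c = image.contrast
    n = c.size

    def c_at(x):
        pos = np.mod(x, 360.0)
        i0 = np.floor(pos).astype(int)
        fr = pos - i0
        return c[i0 % n] * (1 - fr) + c[(i0 + 1) % n] * fr

    sig = cfg.spatial_fwhm / (2 * np.sqrt(2 * np.log(2)))
    xs = np.arange(-np.ceil(5 * sig / dx), np.ceil(5 * sig / dx) + 1) * dx
    M = np.exp(-0.5 * (xs / sig) ** 2)
    M /= M.sum()
    tf = np.arange(0, 25 * cfg.temporal_tau, dtf)
    T = np.exp(-tf / cfg.temporal_tau)
    T /= T.sum()
    tout = np.arange(cfg.n_steps) * cfg.dt
    V = np.zeros((cfg.n_receptors, cfg.n_steps))
    for i in range(cfg.n_receptors):
        xi = offset + i * cfg.spacing
        for k, t in enumerate(tout):
            sp = t - tf
            valid = sp >= 0
            u = np.array([np.sum(M * c_at(xi + xs - velocity * s)) for s in sp[valid]])
            V[i, k] = np.sum(T[valid] * u)
    return V


class TestPhotoreceptorResponse:
    def test_constant_image_tracks_kernel_mass(self):
        cfg = PhotoreceptorConfig(duration=0.1)
        img = Image1D(contrast=np.full(360, 0.4), source_tag="synthetic")
        for vel in (0.0, 120.0):
            clip = photoreceptor_response(img, vel, 15.0, cfg)
            expect = 0.4 * np.cumsum(cfg.temporal_kernel())[: cfg.n_steps]
            assert np.allclose(clip.V, expect[None, :])

    def test_static_scene_converges_to_blurred_contrast(self, image):
        cfg = PhotoreceptorConfig()
        clip = photoreceptor_response(image, 0.0, 77.0, cfg)
        blurred = _blur_panorama(image, cfg.spatial_fwhm)
        for i in range(3):
            x = 77.0 + i * cfg.spacing
            i0 = int(np.floor(x))
            fr = x - i0
            expect = blurred[i0 % 360] * (1 - fr) + blurred[(i0 + 1) % 360] * fr
            assert clip.V[i, -1] == pytest.approx(expect, rel=1e-6)

    def test_matches_brute_force_quadrature(self, image):
        """Post-transient response agrees with a 10x-finer dense discretization
        of the double integral to < 2% relative RMS.  The first 50 ms are the
        zero-state startup, where the two quadratures differ by construction
        and no model ever reads the signal."""
        cfg = PhotoreceptorConfig(duration=0.3)
        clip = photoreceptor_response(image, 90.0, 33.3, cfg)
        oracle = brute_force_response(image, 90.0, 33.3, cfg)
        cut = int(0.05 / cfg.dt)
        err = clip.V[:, cut:] - oracle[:, cut:]
        rel = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(oracle[:, cut:] ** 2))
        assert rel < 0.02

    def test_periodic_in_offset(self, image):
        a = photoreceptor_response(image, 50.0, 10.0)
        b = photoreceptor_response(image, 50.0, 370.0)
        assert np.allclose(a.V, b.V)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PhotoreceptorConfig(dt=-0.005)
        with pytest.raises(ValueError):
            PhotoreceptorConfig(duration=0.002, dt=0.005)
        with pytest.raises(ValueError):
            photoreceptor_response(
                Image1D(np.zeros(360), source_tag="synthetic"), np.inf, 0.0
            )


class TestMovieResponse:
    def test_consistent_with_rigid_translation(self, image):
        """A movie rendered by rigidly translating a panorama reproduces the
        rigid-translation code path."""
        cfg = PhotoreceptorConfig(duration=0.4)
        vel = 90.0
        t = cfg.times()
        # render at 1 deg pixels, one frame per dt, sub-pixel linear shift
        from emdkit.ensemble import _interp_periodic

        x = np.arange(360.0)
        frames = np.stack([_interp_periodic(image.contrast, 1.0, x - vel * tk) for tk in t])
        positions = np.array([20.0, 25.1, 30.2])
        resp = movie_response(frames, cfg, positions, pixel_pitch=1.0, frame_rate=1 / cfg.dt)
        clip = photoreceptor_response(image, vel, 20.0, cfg)
        cut = int(0.05 / cfg.dt)
        err = resp[:, cut:] - clip.V[:, cut:]
        rel = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(clip.V[:, cut:] ** 2))
        assert rel < 0.02

    def test_uniform_movie_gives_uniform_response(self, fast_cfg):
        movie = np.ones((20, 72))
        resp = movie_response(movie, fast_cfg, np.array([0.0, 90.0, 213.0]), 5.0, 40.0)
        assert np.allclose(resp[0], resp[1])
        assert np.allclose(resp[0], resp[2])

    def test_linearity_under_contrast_inversion(self, fast_cfg, rng):
        movie = rng.choice([-1.0, 1.0], size=(20, 72))
        pos = np.array([10.0, 15.1])
        a = movie_response(movie, fast_cfg, pos, 5.0, 40.0)
        b = movie_response(-movie, fast_cfg, pos, 5.0, 40.0)
        assert np.allclose(a, -b)

    def test_out_of_span_position_rejected(self, fast_cfg):
        movie = np.ones((8, 72))
        with pytest.raises(ValueError):
            movie_response(movie, fast_cfg, np.array([400.0]), 5.0, 40.0, boundary="clamp")
        with pytest.raises(ValueError):
            movie_response(movie * np.nan, fast_cfg, np.array([0.0]), 5.0, 40.0)


class TestBuildEnsemble:
    def test_mirror_pairs_are_exact(self, small_ensemble):
        V = small_ensemble.V
        assert np.array_equal(V[0::2], V[1::2, ::-1, :])
        v = small_ensemble.velocities
        assert np.array_equal(v[0::2], -v[1::2])

    def test_single_motion_yields_two_clips(self, asym_images):
        ens = build_ensemble(asym_images[:3], n_motions=1, seed=0)
        assert len(ens) == 2

    def test_velocity_distribution(self, asym_images):
        cfg = PhotoreceptorConfig(duration=0.01)  # stats only; clips can be tiny
        ens = build_ensemble(asym_images[:5], n_motions=10_000, seed=3, cfg=cfg)
        sd = ens.velocities[0::2].std()
        assert abs(ens.velocities.mean()) < 3.0
        assert 87.0 < sd < 93.0  # ~3 sigma band around 90 deg/s at n = 1e4

    def test_seed_reproducibility(self, asym_images, tmp_path):
        a = build_ensemble(asym_images[:10], n_motions=20, seed=5)
        b = build_ensemble(asym_images[:10], n_motions=20, seed=5)
        assert np.array_equal(a.V, b.V)
        save_ensemble(a, tmp_path / "e1.h5")
        save_ensemble(b, tmp_path / "e2.h5")
        assert (tmp_path / "e1.h5").read_bytes() == (tmp_path / "e2.h5").read_bytes()

    def test_hdf5_roundtrip(self, small_ensemble, tmp_path):
        save_ensemble(small_ensemble, tmp_path / "ens.h5")
        back = load_ensemble(tmp_path / "ens.h5")
        assert np.array_equal(back.V, small_ensemble.V)
        assert back.cfg == small_ensemble.cfg
        assert back.seed == small_ensemble.seed

    def test_rejects_empty_inputs(self, asym_images):
        with pytest.raises(ValueError):
            build_ensemble([], n_motions=5, seed=0)
        with pytest.raises(ValueError):
            build_ensemble(asym_images[:2], n_motions=0, seed=0)
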