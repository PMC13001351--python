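"""Pose sampling, projection, CTF, noise, and dataset generation."""

import numpy as np
import pytest
from scipy import stats

from actinpick import (
    CompositionParams,
    CTFParams,
    NoiseParams,
    ParameterError,
    Pose,
    PoseParams,
    add_pink_noise,
    apply_ctf,
    generate_dataset,
    project_volume,
    render_scene,
    sample_pose,
    sample_scene,
)
from actinpick.simulate import SceneSpec, ctf_1d, electron_wavelength_A
from actinpick.volumes import DensityVolume

VOX = 4.36


def test_degenerate_pose_distribution(rng):
    pose = sample_pose(rng, PoseParams(tilt_sd=0.0, t_max=0.0))
    assert pose.tilt == 90.0
    assert pose.shift_xy == (0.0, 0.0)


def test_psi_uniformity_ks(rng):
    psis = np.array([sample_pose(rng).psi for _ in range(100_000)])
    stat = stats.kstest(psis, stats.uniform(loc=0, scale=359).cdf)
    assert stat.pvalue > 0.01


def test_empty_composition(rng, small_library):
    comp = CompositionParams(p_count=(1.0, 0.0, 0.0, 0.0))
    for _ in range(20):
        assert sample_scene(rng, comp, small_library).n_filaments == 0


def test_composition_invariants_checked(small_library):
    with pytest.raises(ParameterError):
        CompositionParams(p_count=(0.5, 0.2, 0.2, 0.2)).validate(15)
    with pytest.raises(ParameterError):
        CompositionParams(p_bare=0.5, p_model=0.1).validate(15)


def test_projection_of_zero_volume(small_library):
    vol = DensityVolume(np.zeros((32, 32, 32), dtype=np.float32), VOX)
    img = project_volume(vol, Pose(10.0, 20.0, 95.0), 32)
    assert not img.any()


def test_projection_mass_conservation(small_library):
    """Identity-pose projection keeps total intensity to 1e-6 relative."""
    for vol in (small_library.bare, small_library.decorated[3]):
        img = project_volume(vol, Pose(0.0, 0.0, 0.0), vol.box_px)
        assert img.sum(dtype=np.float64) == pytest.approx(
            vol.total_density(), rel=1e-6
        )


def test_sphere_projection_matches_chord_length():
    """Radial profile of a projected ball follows 2*rho0*sqrt(R^2 - r^2)."""
    n, vox, radius, rho0 = 96, 2.0, 60.0, 1.0
    c = (n - 1) / 2.0
    idx = (np.arange(n) - c) * vox
    z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
    grid = (x * x + y * y + z * z <= radius * radius).astype(np.float32) * rho0
    vol = DensityVolume(grid, vox)
    img = project_volume(vol, Pose(0.0, 0.0, 0.0), n)

    yy, xx = np.meshgrid(idx, idx, indexing="ij")
    r = np.sqrt(xx * xx + yy * yy)
    interior = r < 0.8 * radius
    expected = 2.0 * rho0 * np.sqrt(radius**2 - r[interior] ** 2) / vox
    # a hard-edged ball quantizes each chord to whole voxels, so individual
    # pixels deviate by up to ~1 voxel of density and the mean sits near the
    # 0.5-voxel quantization floor
    np.testing.assert_allclose(img[interior], expected, atol=2.2 * rho0)
    assert np.abs(img[interior] - expected).mean() < 0.75 * rho0


def test_projection_rejects_oversized_output(small_library):
    with pytest.raises(ParameterError):
        project_volume(small_library.bare, Pose(0, 0, 0), 128)


def test_render_scene_linearity(small_library, rng):
    empty = SceneSpec([], box_px_out=64)
    img, per = render_scene(empty, small_library)
    assert not img.any() and per == []

    one = sample_scene(
        rng, CompositionParams(p_count=(0.0, 1.0, 0.0, 0.0)), small_library,
        PoseParams(t_max=60), box_px_out=64,
    )
    img1, per1 = render_scene(one, small_library)
    np.testing.assert_array_equal(img1, per1[0])

    two = SceneSpec(one.filaments * 2, box_px_out=64)
    img2, per2 = render_scene(two, small_library)
    np.testing.assert_allclose(img2, per2[0] + per2[1], atol=1e-4)


def test_ctf_identity_transfer(rng):
    img = rng.standard_normal((64, 64))
    out = apply_ctf(img, CTFParams(pixel_size_A=VOX), transfer=np.ones((64, 64)))
    np.testing.assert_allclose(out, img, atol=1e-10)


def test_ctf_first_zero_matches_bisection_oracle():
    """First CTF zero agrees with an independent bisection root-finder."""
    ctf = CTFParams(voltage_kv=300, cs_mm=2.7, amplitude_contrast=0.07,
                    defocus_um=1.5, pixel_size_A=1.09)
    # implementation path: locate the first sign change by fine scanning
    ks = np.linspace(1e-5, 0.1, 200_001)
    vals = ctf_1d(ks, ctf)
    i = np.argmax(np.sign(vals[1:]) != np.sign(vals[:-1]))
    k_impl = 0.5 * (ks[i] + ks[i + 1])

    # oracle: bisection on the phase condition gamma(k) = pi - atan2(A, s)
    lam = electron_wavelength_A(300.0)
    dz, cs, a = 1.5e4, 2.7e7, 0.07
    target = np.pi - np.arctan2(a, np.sqrt(1 - a * a))

    def phase(k):
        return np.pi * lam * dz * k**2 - 0.5 * np.pi * cs * lam**3 * k**4 - target

    lo, hi = 1e-6, 0.1
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if phase(lo) * phase(mid) <= 0:
            hi = mid
        else:
            lo = mid
    assert k_impl == pytest.approx(0.5 * (lo + hi), abs=1e-4)


def test_ctf_parseval(rng):
    """Output power equals the Fourier-space power of CTF * F(image)."""
    img = rng.standard_normal((64, 64))
    ctf = CTFParams(pixel_size_A=VOX)
    out = apply_ctf(img, ctf)
    f = np.fft.fftfreq(64, d=VOX)
    kx, ky = np.meshgrid(f, f)
    h = ctf_1d(np.sqrt(kx * kx + ky * ky), ctf)
    power_fourier = np.sum(np.abs(h * np.fft.fft2(img)) ** 2) / 64**2
    assert np.sum(out**2) == pytest.approx(power_fourier, rel=1e-9)


def test_noise_vanishes_at_huge_snr(rng):
    img = rng.standard_normal((64, 64))
    out = add_pink_noise(rng, img, NoiseParams(target_snr=1e30), VOX)
    np.testing.assert_allclose(out, img, atol=1e-10)


def test_zero_image_without_reference_stays_zero(rng):
    out = add_pink_noise(rng, np.zeros((32, 32)), NoiseParams(), VOX)
    assert not out.any()


def test_pink_noise_spectral_slope(rng):
    """Log-log regression of the radial amplitude spectrum gives -alpha."""
    noise_only = add_pink_noise(
        rng, np.zeros((512, 512)), NoiseParams(alpha=1.0, target_snr=1.0, reference_var=1.0), 1.0
    )
    assert np.all(np.isfinite(noise_only)) and noise_only.dtype.kind == "f"
    amp = np.abs(np.fft.fft2(noise_only))
    f = np.fft.fftfreq(512)
    kx, ky = np.meshgrid(f, f)
    k = np.sqrt(kx * kx + ky * ky).ravel()
    bins = np.linspace(0.01, 0.45, 40)
    which = np.digitize(k, bins)
    radial = np.array([amp.ravel()[which == b].mean() for b in range(1, len(bins))])
    centers = 0.5 * (bins[:-1] + bins[1:])
    slope = np.polyfit(np.log(centers), np.log(radial), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_dataset_determinism(small_library):
    kwargs = dict(
        n=6, seed=1, library=small_library, pose_params=PoseParams(t_max=60), box_px_out=64
    )
    a = generate_dataset(**kwargs)
    b = generate_dataset(**kwargs)
    np.testing.assert_array_equal(a.noisy, b.noisy)
    np.testing.assert_array_equal(a.noiseless, b.noiseless)
    np.testing.assert_array_equal(a.targets, b.targets)
    assert a.manifest == b.manifest


def test_dataset_shapes_default_box(library128):
    ds = generate_dataset(n=4, seed=2, library=library128)
    assert ds.noisy.shape == (4, 128, 128)
    assert ds.noiseless.shape == (4, 128, 128)
    assert ds.targets.shape == (4, 3, 128, 128)


def test_noiseless_intensity_tracks_scene_content(small_library):
    """Manifest cross-check: empty scenes render to exactly zero."""
    ds = generate_dataset(
        n=60, seed=5, library=small_library, pose_params=PoseParams(t_max=60), box_px_out=64
    )
    for i, scene in enumerate(ds.scenes):
        if scene.n_filaments == 0:
            assert not ds.noiseless[i].any()
        else:
            assert ds.noiseless[i].sum() > 0
        # noise is still present on empty scenes (reference-variance scaling)
        assert ds.noisy[i].var() > 0


def test_shift_bound_is_hard(rng):
    shifts = np.array(
        [sample_pose(rng, PoseParams()).shift_xy for _ in range(20_000)]
    )
    assert np.abs(shifts).max() <= 218.0
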