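"""Scene sampling, projection, and image corruption for training data.

This module turns the volume library into paired training images: it
samples scene compositions (0--3 filaments per image with probabilities
0.15/0.6/0.2/0.05; each filament bare with probability 0.5, otherwise
one of the decorated models at 1/30 each), samples random poses
(psi/rot uniform on [0, 359]°, tilt Gaussian 90° ± 10°, in-plane
translation uniform within ±218 Å), projects rotated volumes along *z*,
and corrupts projections with a contrast transfer function (CTF)
followed by pink noise synthesized in Fourier space.

Rotations use the ZYZ Euler convention common in cryo-EM:
``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` applied to the volume, followed by
projection along the image *z*-axis.  With the phantom filament axis
along volume *z*, tilt near 90° yields side views.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import DataError, ParameterError
from .volumes import DensityVolume, ModelLibrary

__all__ = [
    "Pose",
    "PoseParams",
    "CompositionParams",
    "FilamentInstance",
    "SceneSpec",
    "CTFParams",
    "NoiseParams",
    "TrainingSample",
    "Dataset",
    "sample_pose",
    "sample_scene",
    "rotation_matrix",
    "project_volume",
    "render_scene",
    "electron_wavelength_A",
    "ctf_1d",
    "apply_ctf",
    "add_pink_noise",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# pose and scene sampling

@dataclass(frozen=True)
class Pose:
    """One filament pose: ZYZ Euler angles (degrees) + in-plane shift (Å)."""

    psi: float
    rot: float
    tilt: float
    shift_xy: Tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class PoseParams:
    """Pose sampling distribution.

    tilt ~ Normal(tilt_mean, tilt_sd); psi, rot ~ Uniform(angle_range);
    each shift component ~ Uniform(-t_max, t_max) independently.
    """

    tilt_mean: float = 90.0
    tilt_sd: float = 10.0
    t_max: float = 218.0
    angle_range: Tuple[float, float] = (0.0, 359.0)

    def validate(self) -> None:
        if self.tilt_sd < 0:
            raise ParameterError("tilt_sd must be >= 0")
        if self.t_max < 0:
            raise ParameterError("t_max must be >= 0")
        if self.angle_range[1] < self.angle_range[0]:
            raise ParameterError("angle_range must be increasing")


@dataclass(frozen=True)
class CompositionParams:
    """Scene composition distribution.

    ``p_count[k]`` is the probability of an image containing ``k``
    filaments; each filament is bare with probability ``p_bare`` and
    each decorated model occurs with probability ``p_model``
    (``(1 - p_bare) / n_models`` when left unset).
    """

    p_count: Tuple[float, ...] = (0.15, 0.6, 0.2, 0.05)
    p_bare: float = 0.5
    p_model: Optional[float] = None

    def validate(self, n_models: int) -> None:
        p = np.asarray(self.p_count, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("p_count must be a probability vector summing to 1")
        p_model = self.model_probability(n_models)
        if abs(self.p_bare + n_models * p_model - 1.0) > 1e-9:
            raise ParameterError(
                "p_bare + n_models * p_model must equal 1 "
                f"(got {self.p_bare} + {n_models}*{p_model})"
            )

    def model_probability(self, n_models: int) -> float:
        if self.p_model is not None:
            return self.p_model
        return (1.0 - self.p_bare) / n_models


@dataclass(frozen=True)
class FilamentInstance:
    """One filament in a scene: ``model_index`` is None for bare F-actin."""

    model_index: Optional[int]
    pose: Pose

    @property
    def decorated(self) -> bool:
        return self.model_index is not None


@dataclass
class SceneSpec:
    filaments: List[FilamentInstance]
    box_px_out: int = 128

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)


def sample_pose(rng: np.random.Generator, params: PoseParams = PoseParams()) -> Pose:
    """Draw one random pose from the configured distributions."""
    params.validate()
    lo, hi = params.angle_range
    psi = float(rng.uniform(lo, hi))
    rot = float(rng.uniform(lo, hi))
    tilt = float(rng.normal(params.tilt_mean, params.tilt_sd))
    shift = rng.uniform(-params.t_max, params.t_max, size=2) if params.t_max > 0 else np.zeros(2)
    return Pose(psi=psi, rot=rot, tilt=tilt, shift_xy=(float(shift[0]), float(shift[1])))


def sample_scene(
    rng: np.random.Generator,
    comp: CompositionParams,
    library: ModelLibrary,
    pose_params: PoseParams = PoseParams(),
    box_px_out: int = 128,
) -> SceneSpec:
    """Draw a scene composition: filament count, identities, and poses."""
    comp.validate(library.n_models)
    count = int(rng.choice(len(comp.p_count), p=np.asarray(comp.p_count, dtype=float)))
    filaments = []
    for _ in range(count):
        if rng.random() < comp.p_bare:
            model_index: Optional[int] = None
        else:
            model_index = int(rng.integers(library.n_models))
        filaments.append(FilamentInstance(model_index, sample_pose(rng, pose_params)))
    return SceneSpec(filaments=filaments, box_px_out=box_px_out)


# ---------------------------------------------------------------------------
# projection

def rotation_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ rotation ``Rz(rot) @ Ry(tilt) @ Rz(psi)`` (degrees, xyz frame)."""
    a, b, c = np.deg2rad([rot, tilt, psi])

    def rz(t):
        return np.array([
            [np.cos(t), -np.sin(t), 0.0],
            [np.sin(t), np.cos(t), 0.0],
            [0.0, 0.0, 1.0],
        ])

    def ry(t):
        return np.array([
            [np.cos(t), 0.0, np.sin(t)],
            [0.0, 1.0, 0.0],
            [-np.sin(t), 0.0, np.cos(t)],
        ])

    return rz(a) @ ry(b) @ rz(c)


# permutation between array index order (z, y, x) and physical (x, y, z)
_AXIS_SWAP = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def _rotate_volume(grid: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a cubic grid about its centre: out(p) = in(R^-1 p).

    Trilinear interpolation with zero fill outside the box.
    """
    if np.allclose(R, np.eye(3), atol=1e-12):
        return grid
    n = grid.shape[0]
    c = (n - 1) / 2.0
    m = _AXIS_SWAP @ R.T @ _AXIS_SWAP  # R^-1 expressed in index space
    offset = c - m @ np.full(3, c)
    return ndimage.affine_transform(
        grid, m, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
    )


def _center_crop(image: np.ndarray, out_px: int) -> np.ndarray:
    n = image.shape[0]
    start = (n - out_px) // 2
    return image[start : start + out_px, start : start + out_px]


def project_volume(
    vol: DensityVolume, pose: Pose, box_px_out: Optional[int] = None
) -> np.ndarray:
    """Rotate, project along *z*, shift in-plane, and centre-crop.

    The in-plane translation is applied to the projection (a shift along
    the projection axis is invisible).  The uncropped, unshifted
    projection conserves the volume's total density.
    """
    if box_px_out is None:
        box_px_out = vol.box_px
    if box_px_out > vol.box_px:
        raise ParameterError(
            f"box_px_out {box_px_out} exceeds volume box {vol.box_px}"
        )
    R = rotation_matrix(pose.rot, pose.tilt, pose.psi)
    rotated = _rotate_volume(vol.grid, R)
    proj = rotated.sum(axis=0, dtype=np.float64)
    sx, sy = pose.shift_xy
    if sx != 0.0 or sy != 0.0:
        proj = ndimage.shift(
            proj,
            (sy / vol.voxel_size, sx / vol.voxel_size),
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
    return _center_crop(proj, box_px_out).astype(np.float32)


def render_scene(
    scene: SceneSpec, library: ModelLibrary
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Render a scene: returns (composite image, per-filament images).

    Per-filament projections are computed independently and retained for
    semantic labelling; the composite is their pixelwise sum.  Rendering
    is linear in the filament list.
    """
    out = scene.box_px_out
    per_filament = []
    for fil in scene.filaments:
        vol = library.bare if fil.model_index is None else library.decorated[fil.model_index]
        per_filament.append(project_volume(vol, fil.pose, out))
    if per_filament:
        composite = np.sum(per_filament, axis=0, dtype=np.float64).astype(np.float32)
    else:
        composite = np.zeros((out, out), dtype=np.float32)
    return composite, per_filament


# ---------------------------------------------------------------------------
# CTF

@dataclass(frozen=True)
class CTFParams:
    """Contrast transfer function parameters.

    Defocus is the underfocus magnitude in μm (the acquisition range
    0.8--2.2 μm is the default sampling interval in
    :func:`generate_dataset`).
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    defocus_um: float = 1.5
    pixel_size_A: Optional[float] = None

    def validate(self) -> None:
        if self.defocus_um <= 0:
            raise ParameterError("defocus_um must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ParameterError("amplitude_contrast must lie in [0, 1]")


def electron_wavelength_A(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_1d(k: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """Radial CTF value at spatial frequency ``k`` (Å^-1).

    ``CTF(k) = -[sqrt(1 - A^2) sin(gamma) + A cos(gamma)]`` with phase
    ``gamma(k) = pi * lambda * dz * k^2 - (pi/2) * Cs * lambda^3 * k^4``.
    """
    lam = electron_wavelength_A(ctf.voltage_kv)
    dz = ctf.defocus_um * 1e4  # μm -> Å
    cs = ctf.cs_mm * 1e7  # mm -> Å
    k = np.asarray(k, dtype=float)
    gamma = np.pi * lam * dz * k**2 - 0.5 * np.pi * cs * lam**3 * k**4
    a = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(gamma) + a * np.cos(gamma))


def apply_ctf(
    image: np.ndarray, ctf: CTFParams, transfer: Optional[np.ndarray] = None
) -> np.ndarray:
    """Multiply the image spectrum by the CTF and return the real part.

    ``transfer`` overrides the computed 2-D transfer function (testing
    hook; pass ``np.ones_like`` output for an identity filter).
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ParameterError("apply_ctf expects a square 2-D image")
    if transfer is None:
        ctf.validate()
        if ctf.pixel_size_A is None or ctf.pixel_size_A <= 0:
            raise ParameterError("CTFParams.pixel_size_A must be set to apply a CTF")
        f = np.fft.fftfreq(image.shape[0], d=ctf.pixel_size_A)
        kx, ky = np.meshgrid(f, f)
        transfer = ctf_1d(np.sqrt(kx * kx + ky * ky), ctf)
    spec = np.fft.fft2(image) * transfer
    out = np.fft.ifft2(spec).real
    return out.astype(image.dtype) if image.dtype == np.float32 else out


# ---------------------------------------------------------------------------
# pink noise

@dataclass(frozen=True)
class NoiseParams:
    """Pink-noise model: Fourier amplitude ``1/f^alpha``, random phases.

    ``target_snr`` sets var(signal)/var(noise).  The reference signal
    variance defaults to the image's own variance; ``reference_var``
    overrides it (used by the dataset generator so noise power does not
    depend on how many filaments a scene contains, and so empty scenes
    still receive noise).  ``empirical_profile`` optionally replaces the
    parametric amplitude with a measured radial table
    ``(freqs_A_inv, amplitudes)``.
    """

    alpha: float = 1.0
    target_snr: float = 0.1
    reference_var: Optional[float] = None
    empirical_profile: Optional[Tuple[Sequence[float], Sequence[float]]] = None

    def validate(self) -> None:
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if self.target_snr <= 0:
            raise ParameterError("target_snr must be positive")


def add_pink_noise(
    rng: np.random.Generator,
    image: np.ndarray,
    noise: NoiseParams = NoiseParams(),
    pixel_size_A: float = 1.0,
) -> np.ndarray:
    """Add Fourier-synthesized pink noise scaled to the target SNR.

    Noise is generated by filtering white Gaussian noise with a radial
    ``1/f^alpha`` amplitude (Hermitian symmetry holds by construction,
    so the synthesized noise is real).  If the reference signal variance
    is zero the image is returned unchanged.
    """
    noise.validate()
    in_dtype = np.asarray(image).dtype
    out_dtype = np.float32 if in_dtype == np.float32 else np.float64
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ParameterError("add_pink_noise expects a square 2-D image")
    n = image.shape[0]

    ref_var = noise.reference_var if noise.reference_var is not None else float(image.var())
    if ref_var == 0.0:
        return image.astype(out_dtype)

    f = np.fft.fftfreq(n, d=pixel_size_A)
    kx, ky = np.meshgrid(f, f)
    k = np.sqrt(kx * kx + ky * ky)
    if noise.empirical_profile is not None:
        freqs, amps = noise.empirical_profile
        amp = np.interp(k, np.asarray(freqs, dtype=float), np.asarray(amps, dtype=float))
    else:
        with np.errstate(divide="ignore"):
            amp = np.where(k > 0, k ** (-noise.alpha), 0.0)
    amp[0, 0] = 0.0  # no DC offset

    white = rng.standard_normal((n, n))
    coloured = np.fft.ifft2(np.fft.fft2(white) * amp).real
    std = coloured.std()
    if std == 0.0:
        return image.astype(out_dtype)
    coloured *= np.sqrt(ref_var / noise.target_snr) / std
    return (image + coloured).astype(out_dtype)


# ---------------------------------------------------------------------------
# dataset generation

@dataclass
class TrainingSample:
    """One paired simulator output."""

    noisy: np.ndarray
    noiseless: np.ndarray
    target: "np.ndarray"  # (3, H, W) one-hot uint8
    scene: SceneSpec
    ctf: CTFParams
    seed_record: List[int]


@dataclass
class Dataset:
    """In-memory paired dataset with a regeneration manifest."""

    noisy: np.ndarray  # (n, H, W) float32
    noiseless: np.ndarray  # (n, H, W) float32
    targets: np.ndarray  # (n, 3, H, W) uint8
    scenes: List[SceneSpec]
    manifest: dict

    def __len__(self) -> int:
        return self.noisy.shape[0]


def _scene_record(scene: SceneSpec) -> dict:
    return {
        "box_px_out": scene.box_px_out,
        "filaments": [
            {
                "model_index": f.model_index,
                "psi": f.pose.psi,
                "rot": f.pose.rot,
                "tilt": f.pose.tilt,
                "shift_xy": list(f.pose.shift_xy),
            }
            for f in scene.filaments
        ],
    }


def _reference_signal_variance(
    library: ModelLibrary,
    pose_params: PoseParams,
    ctf: CTFParams,
    box_px_out: int,
    rng: np.random.Generator,
    n_probe: int = 8,
) -> float:
    """Typical one-filament projection variance after CTF corruption.

    Used as the noise-scaling reference so that noise power is a
    property of the imaging model, not of the sampled scene content.
    """
    variances = []
    for i in range(n_probe):
        vol = library.decorated[i % library.n_models] if i % 2 else library.bare
        img = project_volume(vol, sample_pose(rng, pose_params), box_px_out)
        img = apply_ctf(img, ctf)
        variances.append(float(img.var()))
    return float(np.mean(variances))


def generate_dataset(
    n: int,
    seed: int,
    library: ModelLibrary,
    pose_params: PoseParams = PoseParams(),
    comp: CompositionParams = CompositionParams(),
    ctf: CTFParams = CTFParams(),
    noise: NoiseParams = NoiseParams(),
    defocus_range_um: Tuple[float, float] = (0.8, 2.2),
    box_px_out: int = 128,
    target_params=None,
    out_dir=None,
) -> Dataset:
    """Generate ``n`` paired training samples, deterministically.

    All randomness flows from ``seed`` through one spawned child stream
    per sample (recorded in the manifest), so identical arguments
    reproduce the dataset bitwise.  Per-sample defocus is drawn
    uniformly from ``defocus_range_um``.  When ``out_dir`` is given the
    dataset is also written to disk (MRC stacks for images, a TIFF stack
    for targets, JSON manifest).
    """
    from .targets import TargetParams, make_semantic_target

    if n < 1:
        raise DataError("dataset size must be >= 1")
    if target_params is None:
        target_params = TargetParams(pixel_size_A=library.voxel_size)

    pixel_size = library.voxel_size
    base_ctf = CTFParams(
        voltage_kv=ctf.voltage_kv,
        cs_mm=ctf.cs_mm,
        amplitude_contrast=ctf.amplitude_contrast,
        defocus_um=ctf.defocus_um,
        pixel_size_A=pixel_size,
    )

    root = np.random.SeedSequence(seed)
    ref_seq, sample_root = root.spawn(2)
    if noise.reference_var is None:
        ref_var = _reference_signal_variance(
            library, pose_params, base_ctf, box_px_out, np.random.default_rng(ref_seq)
        )
        noise = NoiseParams(
            alpha=noise.alpha,
            target_snr=noise.target_snr,
            reference_var=ref_var,
            empirical_profile=noise.empirical_profile,
        )

    children = sample_root.spawn(n)
    noisy = np.empty((n, box_px_out, box_px_out), dtype=np.float32)
    noiseless = np.empty_like(noisy)
    targets = np.empty((n, 3, box_px_out, box_px_out), dtype=np.uint8)
    scenes: List[SceneSpec] = []
    records = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        defocus = float(rng.uniform(*defocus_range_um))
        sample_ctf = CTFParams(
            voltage_kv=base_ctf.voltage_kv,
            cs_mm=base_ctf.cs_mm,
            amplitude_contrast=base_ctf.amplitude_contrast,
            defocus_um=defocus,
            pixel_size_A=pixel_size,
        )
        scene = sample_scene(rng, comp, library, pose_params, box_px_out)
        composite, per_filament = render_scene(scene, library)
        kinds = [f.decorated for f in scene.filaments]
        target = make_semantic_target(
            per_filament, kinds, target_params, shape=(box_px_out, box_px_out)
        )
        corrupted = apply_ctf(composite, sample_ctf) if per_filament else composite
        noisy[i] = add_pink_noise(rng, corrupted, noise, pixel_size)
        noiseless[i] = composite
        targets[i] = target.channels
        scenes.append(scene)
        records.append(
            {
                "index": i,
                "seed_state": list(map(int, child.generate_state(4))),
                "defocus_um": defocus,
                "scene": _scene_record(scene),
            }
        )

    manifest = {
        "n": n,
        "seed": int(seed),
        "box_px_out": box_px_out,
        "pixel_size_A": pixel_size,
        "library": {
            "n_models": library.n_models,
            "box_px": library.box_px,
            "voxel_size": library.voxel_size,
        },
        "noise": {
            "alpha": noise.alpha,
            "target_snr": noise.target_snr,
            "reference_var": noise.reference_var,
        },
        "defocus_range_um": list(defocus_range_um),
        "samples": records,
    }
    ds = Dataset(noisy=noisy, noiseless=noiseless, targets=targets, scenes=scenes, manifest=manifest)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: Dataset, out_dir) -> None:
    """Write a dataset to disk: MRC image stacks + TIFF targets + manifest."""
    import pathlib

    import tifffile

    from .io import write_mrc

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    px = ds.manifest["pixel_size_A"]
    try:
        write_mrc(out / "noisy.mrc", ds.noisy, px)
        write_mrc(out / "noiseless.mrc", ds.noiseless, px)
        tifffile.imwrite(
            out / "targets.tif", ds.targets, photometric="minisblack"
        )
    except OSError as exc:
        raise DataError(f"failed writing dataset to {out}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(ds.manifest, indent=1))


def load_dataset(in_dir) -> Dataset:
    """Load a dataset written by :func:`write_dataset` (scenes from manifest)."""
    import pathlib

    import tifffile

    from .io import read_mrc

    src = pathlib.Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    noisy, _ = read_mrc(src / "noisy.mrc")
    noiseless, _ = read_mrc(src / "noiseless.mrc")
    targets = tifffile.imread(src / "targets.tif")
    scenes = []
    for rec in manifest["samples"]:
        filaments = [
            FilamentInstance(
                f["model_index"],
                Pose(psi=f["psi"], rot=f["rot"], tilt=f["tilt"], shift_xy=tuple(f["shift_xy"])),
            )
            for f in rec["scene"]["filaments"]
        ]
        scenes.append(SceneSpec(filaments, rec["scene"]["box_px_out"]))
    return Dataset(
        noisy=noisy.astype(np.float32),
        noiseless=noiseless.astype(np.float32),
        targets=targets.astype(np.uint8),
        scenes=scenes,
        manifest=manifest,
    )
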