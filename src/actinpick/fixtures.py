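"""Seeded miniature datasets for tests and demos.

:func:`make_fixture` builds a small deterministic dataset (default 20
samples on 64-px volumes) whose scene list is *stratified* rather than
sampled: it always contains zero-filament images, bare and decorated
single-filament images covering every rod pose modulo the model count,
and overlapping bare+decorated pairs.  The same seed always produces a
byte-identical directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .simulate import (
    CompositionParams,
    CTFParams,
    Dataset,
    FilamentInstance,
    NoiseParams,
    PoseParams,
    SceneSpec,
    add_pink_noise,
    apply_ctf,
    render_scene,
    sample_pose,
    write_dataset,
    _reference_signal_variance,
    _scene_record,
)
from .targets import TargetParams, make_semantic_target
from .volumes import ModelLibrary, PhantomParams, build_model_library

__all__ = ["FixtureSpec", "make_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """What the fixture contains."""

    n_samples: int = 20
    box_px: int = 64
    voxel_size: float = 4.36
    n_models: int = 15
    box_px_out: Optional[int] = None  # default: full box (no crop)
    t_max_A: float = 60.0  # keep filaments near the small box centre
    target_snr: float = 0.1
    with_noise: bool = True


def _stratified_scenes(
    spec: FixtureSpec, library: ModelLibrary, rng: np.random.Generator
) -> List[SceneSpec]:
    """Deterministic scene roster: empty / bare / every rod pose / overlaps."""
    pose_params = PoseParams(t_max=spec.t_max_A)
    out = spec.box_px_out or spec.box_px
    kinds: List[List[Optional[int]]] = [[]]  # one guaranteed empty scene
    pose_cycle = 0
    while len(kinds) < spec.n_samples:
        k = len(kinds) % 4
        if k == 1:
            kinds.append([None])  # bare
        elif k == 2:
            kinds.append([pose_cycle % library.n_models])  # decorated
            pose_cycle += 1
        elif k == 3:
            kinds.append([None, pose_cycle % library.n_models])  # overlap
            pose_cycle += 1
        else:
            kinds.append([])
    scenes = []
    for members in kinds[: spec.n_samples]:
        filaments = [
            FilamentInstance(mi, sample_pose(rng, pose_params)) for mi in members
        ]
        scenes.append(SceneSpec(filaments, out))
    return scenes


def make_fixture(seed: int, spec: FixtureSpec = FixtureSpec(), out_dir=None) -> Dataset:
    """Render the stratified fixture dataset; optionally write it to disk."""
    library = build_model_library(
        PhantomParams(), spec.n_models, spec.box_px, spec.voxel_size
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scenes = _stratified_scenes(spec, library, rng)
    out = spec.box_px_out or spec.box_px
    target_params = TargetParams(pixel_size_A=spec.voxel_size)
    ctf = CTFParams(pixel_size_A=spec.voxel_size)
    noise = NoiseParams(target_snr=spec.target_snr)
    pose_params = PoseParams(t_max=spec.t_max_A)
    ref_var = _reference_signal_variance(
        library, pose_params, ctf, out, np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    )
    noise = NoiseParams(target_snr=spec.target_snr, reference_var=ref_var)

    n = spec.n_samples
    noisy = np.empty((n, out, out), dtype=np.float32)
    noiseless = np.empty_like(noisy)
    targets = np.empty((n, 3, out, out), dtype=np.uint8)
    records = []
    for i, scene in enumerate(scenes):
        composite, per_fil = render_scene(scene, library)
        flags = [f.decorated for f in scene.filaments]
        targets[i] = make_semantic_target(
            per_fil, flags, target_params, shape=(out, out)
        ).channels
        noiseless[i] = composite
        corrupted = apply_ctf(composite, ctf) if per_fil else composite
        noisy[i] = (
            add_pink_noise(rng, corrupted, noise, spec.voxel_size)
            if spec.with_noise
            else corrupted
        )
        records.append({"index": i, "scene": _scene_record(scene)})

    manifest = {
        "n": n,
        "seed": int(seed),
        "box_px_out": out,
        "pixel_size_A": spec.voxel_size,
        "stratified": True,
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
        "samples": records,
    }
    ds = Dataset(noisy=noisy, noiseless=noiseless, targets=targets, scenes=scenes, manifest=manifest)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds
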