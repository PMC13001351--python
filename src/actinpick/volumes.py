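"""Parametric density-volume library for filament picking simulations.

The simulator needs a small library of 3-D density volumes: one bare
F-actin filament and ``n_models`` "decorated" variants carrying a bound
crosslinker actin-binding domain (ABD) plus a rod-domain arm in a range
of poses, emulating crosslinker flexibility.  Volumes are generated as
smooth parametric phantoms on a cubic grid (default 256 px at
4.36 Å/voxel); experimentally determined maps in MRC format can be
loaded in their place via :func:`load_volume`.

Geometry conventions
--------------------
Arrays are indexed ``[iz, iy, ix]``; the physical frame is ``(x, y, z)``
in Å relative to the box centre.  The canonical filament axis is the
volume *z*-axis (the projection axis at identity pose), so that a tilt
angle near 90° produces side views under the ZYZ rotation convention
used by :mod:`actinpick.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "PhantomParams",
    "DensityVolume",
    "ModelLibrary",
    "make_bare_phantom",
    "make_decorated_phantom",
    "build_model_library",
    "load_volume",
    "save_volume",
]

#: Default box side in pixels for library volumes.
DEFAULT_BOX_PX = 256
#: Default voxel size in Å (micrograph pixel size after 4x downsampling).
DEFAULT_VOXEL_SIZE = 4.36
#: Default number of decorated models in the library.
DEFAULT_N_MODELS = 15


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the parametric filament phantom (all lengths in Å).

    The bare filament is a soft-edged cylinder of radius
    ``filament_radius`` with a helical surface modulation of period
    ``helical_bump_period`` along the axis.  Decoration adds a compact
    spherical ABD blob of radius ``abd_radius`` centred ``abd_offset``
    from the axis at the box mid-plane, plus a capsule-shaped rod arm of
    length ``rod_length`` and radius ``rod_radius`` whose in-plane
    orientation is swept over a fan of ``rod_fan_deg`` degrees across
    the model library.
    """

    filament_radius: float = 40.0
    filament_length: float = 1200.0
    helical_bump_period: float = 55.0
    abd_radius: float = 22.0
    abd_offset: float = 55.0
    rod_length: float = 120.0
    rod_radius: float = 12.0
    density_scale: float = 1.0
    rod_fan_deg: float = 120.0

    def validate(self) -> None:
        for name in (
            "filament_radius",
            "filament_length",
            "helical_bump_period",
            "abd_radius",
            "abd_offset",
            "rod_radius",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"PhantomParams.{name} must be positive")
        if self.rod_length < 0:
            raise ParameterError("PhantomParams.rod_length must be >= 0")
        if self.density_scale < 0:
            raise ParameterError("PhantomParams.density_scale must be >= 0")


@dataclass
class DensityVolume:
    """A cubic 3-D density grid with physical metadata.

    Attributes
    ----------
    grid:
        ``(n, n, n)`` float32 array indexed ``[iz, iy, ix]``.
    voxel_size:
        Å per voxel.
    interface_xyz:
        Optional ``(x, y, z)`` coordinate (Å, relative to the box
        centre) of the crosslinker--filament interface; set for
        decorated volumes only.
    filament_axis:
        Unit vector of the filament axis in the ``(x, y, z)`` frame.
    """

    grid: np.ndarray
    voxel_size: float
    interface_xyz: Optional[np.ndarray] = None
    filament_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ParameterError(
                f"DensityVolume grid must be cubic, got shape {self.grid.shape}"
            )
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ParameterError("density grid contains non-finite values")
        if self.interface_xyz is not None:
            self.interface_xyz = np.asarray(self.interface_xyz, dtype=float)
            half = self.box_px * self.voxel_size / 2.0
            if np.any(np.abs(self.interface_xyz) > half):
                raise ParameterError("interface_xyz lies outside the box")

    @property
    def box_px(self) -> int:
        return self.grid.shape[0]

    @property
    def box_A(self) -> float:
        """Physical box side in Å."""
        return self.box_px * self.voxel_size

    def total_density(self) -> float:
        return float(self.grid.sum(dtype=np.float64))


@dataclass
class ModelLibrary:
    """One bare volume plus an ordered set of decorated variants."""

    bare: DensityVolume
    decorated: Sequence[DensityVolume]
    metadata: Sequence[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.decorated) < 1:
            raise ParameterError("library needs at least one decorated model")
        box, vox = self.bare.box_px, self.bare.voxel_size
        for i, vol in enumerate(self.decorated):
            if vol.box_px != box or vol.voxel_size != vox:
                raise ParameterError(
                    f"decorated model {i} geometry differs from bare volume"
                )
            if vol.interface_xyz is None:
                raise ParameterError(f"decorated model {i} lacks interface_xyz")

    @property
    def n_models(self) -> int:
        return len(self.decorated)

    @property
    def box_px(self) -> int:
        return self.bare.box_px

    @property
    def voxel_size(self) -> float:
        return self.bare.voxel_size


def _phys_coords(box_px: int, voxel_size: float):
    """1-D physical coordinate (Å, centred) along one axis."""
    c = (box_px - 1) / 2.0
    return (np.arange(box_px) - c) * voxel_size


def make_bare_phantom(
    params: PhantomParams = PhantomParams(),
    box_px: int = DEFAULT_BOX_PX,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> DensityVolume:
    """Generate the bare-filament phantom.

    The density is a parabolic-profile cylinder along *z* with a
    30 %-amplitude helical surface modulation; support is exactly
    ``r <= filament_radius`` and ``|z| <= filament_length / 2``.
    """
    params.validate()
    if box_px < 32:
        raise ParameterError("box_px must be >= 32")
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be positive")

    ax = _phys_coords(box_px, voxel_size)
    z = ax[:, None, None]
    y = ax[None, :, None]
    x = ax[None, None, :]
    r2 = x * x + y * y
    radial = np.clip(1.0 - r2 / params.filament_radius**2, 0.0, None)
    theta = np.arctan2(y, x)
    helical = 1.0 + 0.3 * np.cos(
        2.0 * np.pi * z / params.helical_bump_period - theta
    )
    grid = params.density_scale * radial * helical
    grid *= np.abs(z) <= params.filament_length / 2.0
    return DensityVolume(grid.astype(np.float32), voxel_size)


def _rod_direction(rod_pose_index: int, n_models: int, fan_deg: float) -> np.ndarray:
    """In-plane unit direction of the rod arm for one library member.

    Orientations are evenly spaced over a fan of ``fan_deg`` degrees
    centred on the outward (+x) radial direction, in the plane
    perpendicular to the filament axis.
    """
    if n_models == 1:
        phi = 0.0
    else:
        phi = np.deg2rad(-fan_deg / 2.0 + fan_deg * rod_pose_index / (n_models - 1))
    return np.array([np.cos(phi), np.sin(phi), 0.0])


def make_decorated_phantom(
    params: PhantomParams = PhantomParams(),
    rod_pose_index: int = 0,
    n_models: int = DEFAULT_N_MODELS,
    box_px: int = DEFAULT_BOX_PX,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> DensityVolume:
    """Bare phantom plus an ABD blob and a rod arm at one library pose.

    Composition is purely additive, so the decorated density dominates
    the bare density voxelwise.  ``interface_xyz`` is set to the ABD
    attachment point ``(abd_offset, 0, 0)``.
    """
    if not 0 <= rod_pose_index < n_models:
        raise ParameterError(
            f"rod_pose_index {rod_pose_index} out of range [0, {n_models})"
        )
    bare = make_bare_phantom(params, box_px, voxel_size)
    grid = bare.grid.astype(np.float64)

    ax = _phys_coords(box_px, voxel_size)
    z = ax[:, None, None]
    y = ax[None, :, None]
    x = ax[None, None, :]
    centre = np.array([params.abd_offset, 0.0, 0.0])

    d2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
    grid += params.density_scale * np.clip(1.0 - d2 / params.abd_radius**2, 0.0, None)

    if params.rod_length > 0:
        direction = _rod_direction(rod_pose_index, n_models, params.rod_fan_deg)
        # distance from each voxel to the rod segment [centre, centre + L*d]
        px = x - centre[0]
        py = y - centre[1]
        pz = z - centre[2]
        t = np.clip(px * direction[0] + py * direction[1] + pz * direction[2],
                    0.0, params.rod_length)
        d2 = (px - t * direction[0]) ** 2 + (py - t * direction[1]) ** 2 + (
            pz - t * direction[2]
        ) ** 2
        grid += 0.8 * params.density_scale * np.clip(
            1.0 - d2 / params.rod_radius**2, 0.0, None
        )

    return DensityVolume(
        grid.astype(np.float32), voxel_size, interface_xyz=centre.copy()
    )


def build_model_library(
    params: PhantomParams = PhantomParams(),
    n_models: int = DEFAULT_N_MODELS,
    box_px: int = DEFAULT_BOX_PX,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> ModelLibrary:
    """Build the full library: one bare volume + ``n_models`` decorated.

    Construction is deterministic: identical parameters give bitwise
    identical volumes.
    """
    if n_models < 1:
        raise ParameterError("n_models must be >= 1")
    bare = make_bare_phantom(params, box_px, voxel_size)
    decorated = [
        make_decorated_phantom(params, i, n_models, box_px, voxel_size)
        for i in range(n_models)
    ]
    metadata = [
        {
            "rod_pose_index": i,
            "rod_direction_xyz": _rod_direction(i, n_models, params.rod_fan_deg).tolist(),
        }
        for i in range(n_models)
    ]
    return ModelLibrary(bare=bare, decorated=decorated, metadata=metadata)


def load_volume(path, interface_xyz=None) -> DensityVolume:
    """Load a cubic density volume from an MRC file.

    ``interface_xyz`` (Å, box-centred frame) must be supplied separately
    for decorated volumes, e.g. from the run configuration.
    """
    from .io import read_mrc

    grid, voxel_size = read_mrc(path)
    from .exceptions import FormatError

    if grid.ndim != 3 or len(set(grid.shape)) != 1:
        raise FormatError(
            f"{path}: expected a cubic volume, got shape {grid.shape}"
        )
    return DensityVolume(grid, voxel_size, interface_xyz=interface_xyz)


def save_volume(vol: DensityVolume, path) -> None:
    """Write a volume to an MRC file (float32, voxel size in header)."""
    from .io import write_mrc

    write_mrc(path, vol.grid, vol.voxel_size)
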