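"""MRC and STAR file I/O, built on gemmi.

MRC2014 maps carry the voxel size in the header cell parameters; data
are written in float32 mode 2 so that grids round-trip bitwise.  Pick
coordinates are exported as STAR files with RELION-style column names
(``rlnCoordinateX``, ``rlnCoordinateY``, ``rlnAutopickFigureOfMerit``),
formatted with shortest round-trip representations so coordinates
re-read exactly.
"""

from __future__ import annotations

import numpy as np

from .exceptions import FormatError

__all__ = [
    "read_mrc",
    "write_mrc",
    "write_star_picks",
    "read_star_picks",
]

_STAR_COLUMNS = ("CoordinateX", "CoordinateY", "AutopickFigureOfMerit")


def write_mrc(path, grid: np.ndarray, voxel_size: float) -> None:
    """Write a 2-D image or 3-D volume as an MRC2014 map.

    2-D images are stored as single-section volumes (``nz = 1``).
    """
    import gemmi

    grid = np.asarray(grid, dtype=np.float32)
    if grid.ndim == 2:
        grid = grid[None]
    if grid.ndim != 3:
        raise FormatError(f"can only write 2-D or 3-D arrays, got ndim={grid.ndim}")
    if voxel_size <= 0:
        raise FormatError("voxel_size must be positive")

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid))
    nu, nv, nw = m.grid.nu, m.grid.nv, m.grid.nw
    m.grid.unit_cell = gemmi.UnitCell(
        nu * voxel_size, nv * voxel_size, nw * voxel_size, 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path):
    """Read an MRC map; returns ``(grid, voxel_size)``.

    The voxel size must be isotropic across the sampled axes; an
    anisotropic cell raises :class:`FormatError` naming the axes.
    """
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable MRC map ({exc})") from exc

    grid = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    sizes = {
        "x": cell.a / m.grid.nu,
        "y": cell.b / m.grid.nv,
        "z": cell.c / m.grid.nw,
    }
    vals = np.array(list(sizes.values()))
    if not np.allclose(vals, vals[0], rtol=1e-6):
        axes = ", ".join(f"{k}={v:.6g}" for k, v in sizes.items())
        raise FormatError(f"{path}: anisotropic voxel size ({axes} Å)")
    return grid.astype(np.float32), float(vals[0])


def read_micrograph_mrc(path):
    """Read a 2-D micrograph (or single-section volume) from MRC."""
    grid, voxel_size = read_mrc(path)
    if grid.ndim == 3:
        if grid.shape[0] != 1:
            raise FormatError(
                f"{path}: expected a 2-D micrograph, got shape {grid.shape}"
            )
        grid = grid[0]
    return grid, voxel_size


def write_star_picks(picks, path, block_name: str = "picks") -> None:
    """Write a pick list as a STAR file, one loop row per pick.

    Zero picks produce a valid STAR file with an empty loop.  Numbers
    are written with shortest round-trip formatting, so a
    write-read cycle reproduces the coordinates exactly.
    """
    import gemmi

    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    loop = block.init_loop("_rln", list(_STAR_COLUMNS))
    for (x, y), score in zip(picks.coords, picks.scores):
        loop.add_row([repr(float(x)), repr(float(y)), repr(float(score))])
    doc.write_file(str(path))


def read_star_picks(path):
    """Read pick coordinates and scores back from a STAR file.

    Returns ``(coords, scores)`` with ``coords`` of shape ``(n, 2)``
    holding ``(x, y)`` pairs.
    """
    import gemmi

    try:
        doc = gemmi.cif.read_file(str(path))
        block = doc.sole_block()
        cols = [list(block.find_loop("_rln" + c)) for c in _STAR_COLUMNS]
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable STAR file ({exc})") from exc
    if any(len(c) != len(cols[0]) for c in cols):
        raise FormatError(f"{path}: ragged coordinate loop")
    xs, ys, scores = (np.array([float(v) for v in c]) for c in cols)
    coords = np.stack([xs, ys], axis=1) if len(xs) else np.empty((0, 2))
    return coords, scores
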