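"""Density maps on regular grids.

Two map classes cover the two experimental worlds:

* :class:`Xmap` — a crystallographic map.  One unit cell of values is
  stored on a regular grid; lattice periodicity plus the space-group
  symmetry make the map *appear infinite*: a value lookup at any
  integer grid coordinate succeeds, and symmetry-equivalent grid
  points always hold equal values (storage is symmetrised on write).
* :class:`NXmap` — a non-crystallographic map (typical of cryo-EM):
  finite in extent, no symmetry, placed in orthogonal space by an
  affine transform (origin plus axis step vectors).  Lookup outside
  the stored extent is an index-category error.

Both export rectangular sections to numpy arrays on the map's native
axes and spacing (:func:`export_section`), and the Xmap additionally
exports boxes resampled onto strictly Cartesian axes by trilinear
interpolation (:func:`export_interpolated_box`).  Maps are read and
written in the CCP4/MRC 2014 format, mode 2 (float32).
"""

from __future__ import annotations

import numpy as np

from .cell_symmetry import Cell, Coord_frac, Coord_grid, Grid_sampling, Spacegroup
from .errors import InvalidArgument, LengthError, MessageFatal, OutOfRange

__all__ = [
    "Xmap",
    "NXmap",
    "MapBox",
    "grid_symop",
    "export_section",
    "export_interpolated_box",
    "read_map_file",
    "write_map_file",
]

#: built-in space-group short symbol <-> International Tables number
SPACEGROUP_NUMBERS = {
    "P1": 1, "P-1": 2, "P21": 4, "C2": 5,
    "P212121": 19, "P43212": 96, "P6322": 182,
}
_NUMBER_TO_NAME = {v: k for k, v in SPACEGROUP_NUMBERS.items()}


def grid_symop(symop, grid: Grid_sampling) -> tuple[np.ndarray, np.ndarray]:
    """Express a fractional-space symop in integer grid units.

    Returns (M, t) with ``g' = M @ g + t`` acting on grid coordinates.
    The grid must be compatible with the operator (every entry of
    ``R_ij * N_i / N_j`` and ``trn_i * N_i`` integral), otherwise a
    value-category error is raised.
    """
    n = grid.nuvw.astype(float)
    m = symop.rot * n[:, None] / n[None, :]
    t = symop.trn * n
    if not (np.allclose(m, np.round(m), atol=1e-6) and np.allclose(t, np.round(t), atol=1e-6)):
        raise InvalidArgument(
            f"grid {tuple(grid)} is incompatible with symmetry operator {symop.triplet()!r}")
    return np.round(m).astype(int), np.round(t).astype(int)


class Xmap:
    """Crystallographic map: one unit cell of values + symmetry.

    ``values`` is indexed ``[u, v, w]`` with shape ``(nu, nv, nw)``.
    """

    def __init__(self, cell: Cell, spacegroup: Spacegroup, grid: Grid_sampling,
                 values=None):
        self.cell = cell
        self.spacegroup = spacegroup
        self.grid = grid
        shape = tuple(grid.nuvw)
        if values is None:
            self.values = np.zeros(shape)
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != shape:
                raise LengthError(f"values must have shape {shape}, got {values.shape}")
            self.values = values.copy()
        # precompute grid-unit symops; validates grid/spacegroup compatibility
        self._grid_ops = [grid_symop(s, grid) for s in spacegroup]

    # -- infinite indexing -------------------------------------------------

    def _wrap(self, g) -> tuple:
        return tuple(np.mod(np.asarray(g, dtype=int).reshape(3), self.grid.nuvw))

    def get(self, coord_grid) -> float:
        """Value at ANY integer grid coordinate (lattice wrap + symmetry)."""
        g = coord_grid.uvw if isinstance(coord_grid, Coord_grid) else coord_grid
        return float(self.values[self._wrap(g)])

    def set(self, coord_grid, value: float) -> None:
        """Set a value, writing through to all symmetry images."""
        g = coord_grid.uvw if isinstance(coord_grid, Coord_grid) else np.asarray(coord_grid)
        g = np.asarray(g, dtype=int).reshape(3)
        for m, t in self._grid_ops:
            self.values[self._wrap(m @ g + t)] = value

    def __getitem__(self, coord_grid):
        return self.get(coord_grid)

    def __setitem__(self, coord_grid, value):
        self.set(coord_grid, value)

    # -- symmetrisation ----------------------------------------------------

    def symmetrize(self, how: str = "mean") -> None:
        """Make symmetry-equivalent grid points equal.

        ``how='mean'`` replaces each point by the mean over its orbit;
        ``how='first'`` propagates the value at the canonical (lowest
        flat-index) orbit representative.
        """
        if how not in ("mean", "first"):
            raise InvalidArgument(f"unknown symmetrization mode {how!r}")
        if len(self._grid_ops) == 1:
            return
        shape = self.values.shape
        idx = np.indices(shape).reshape(3, -1)  # (3, N)
        flat = self.values.ravel()
        perms = []
        for m, t in self._grid_ops:
            img = np.mod(m @ idx + t[:, None], self.grid.nuvw[:, None])
            perms.append(np.ravel_multi_index(img, shape))
        perms = np.array(perms)  # (n_ops, N)
        if how == "mean":
            new = flat[perms].mean(axis=0)
        else:
            rep = perms.min(axis=0)
            new = flat[rep]
        self.values = np.asarray(new).reshape(shape)

    # -- interpolation -----------------------------------------------------

    def interp_frac(self, frac_points) -> np.ndarray:
        """Trilinear interpolation at fractional positions (n,3) or (3,)."""
        pts = np.atleast_2d(np.asarray(frac_points, dtype=float))
        x = pts * self.grid.nuvw  # real grid units
        i0 = np.floor(x).astype(int)
        f = x - i0
        n = self.grid.nuvw
        out = np.zeros(len(pts))
        for du in (0, 1):
            for dv in (0, 1):
                for dw in (0, 1):
                    w = (np.where(du, f[:, 0], 1 - f[:, 0])
                         * np.where(dv, f[:, 1], 1 - f[:, 1])
                         * np.where(dw, f[:, 2], 1 - f[:, 2]))
                    iu = np.mod(i0[:, 0] + du, n[0])
                    iv = np.mod(i0[:, 1] + dv, n[1])
                    iw = np.mod(i0[:, 2] + dw, n[2])
                    out += w * self.values[iu, iv, iw]
        return out if np.asarray(frac_points).ndim > 1 else out[0]

    def interp_orth(self, orth_points) -> np.ndarray:
        """Trilinear interpolation at orthogonal positions in angstroms."""
        return self.interp_frac(self.cell.fractionalize(orth_points))

    def stats(self) -> tuple[float, float, float, float]:
        v = self.values
        return float(v.min()), float(v.max()), float(v.mean()), float(v.std())


class NXmap:
    """Finite, symmetry-free map placed in space by an affine transform.

    ``origin`` is the orthogonal position (A) of grid point (0,0,0) and
    the columns of ``axes`` are the orthogonal step vectors per grid
    unit, so point (i,j,k) sits at ``origin + axes @ (i,j,k)``.
    """

    def __init__(self, values, origin, axes, cell: Cell | None = None,
                 grid_full: Grid_sampling | None = None, start_grid=None):
        self.values = np.asarray(values, dtype=float).copy()
        if self.values.ndim != 3:
            raise LengthError(f"values must be a 3-D array, got ndim {self.values.ndim}")
        self.origin = np.asarray(origin, dtype=float).reshape(3)
        self.axes = np.asarray(axes, dtype=float).reshape(3, 3)
        # crystal-frame placement, kept when the map derives from a cell grid
        self.cell = cell
        self.grid_full = grid_full
        self.start_grid = (np.asarray(start_grid, dtype=int).reshape(3)
                           if start_grid is not None else None)

    @classmethod
    def from_cell_grid(cls, values, cell: Cell, grid_full: Grid_sampling,
                       start_grid=(0, 0, 0)) -> "NXmap":
        """Place a finite block of a cell-axis-aligned grid in space."""
        start = np.asarray(start_grid, dtype=int).reshape(3)
        axes = cell.orth_matrix / grid_full.nuvw[None, :]
        origin = axes @ start
        return cls(values, origin, axes, cell=cell, grid_full=grid_full, start_grid=start)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def get(self, coord_grid) -> float:
        """Value at a grid coordinate inside the stored extent."""
        g = coord_grid.uvw if isinstance(coord_grid, Coord_grid) else coord_grid
        g = np.asarray(g, dtype=int).reshape(3)
        if np.any(g < 0) or np.any(g >= self.shape):
            raise OutOfRange(f"grid coordinate {tuple(g)} outside map extent {self.shape}")
        return float(self.values[tuple(g)])

    def __getitem__(self, coord_grid):
        return self.get(coord_grid)

    def stats(self) -> tuple[float, float, float, float]:
        v = self.values
        return float(v.min()), float(v.max()), float(v.mean()), float(v.std())


class MapBox:
    """A rectangular block of map values exported to a numpy array.

    ``start`` is the grid coordinate of the first element (None for
    Cartesian interpolated boxes, which carry ``origin``/``spacing``
    instead); ``order`` is the memory layout ('C' or 'F') and ``rot``
    the axis order of the array ('xyz' -> [u,v,w], 'zyx' -> [w,v,u]).
    """

    def __init__(self, data: np.ndarray, start: Coord_grid | None,
                 order: str = "C", rot: str = "xyz",
                 origin=None, spacing: float | None = None):
        self.data = data
        self.start = start
        self.order = order
        self.rot = rot
        self.origin = None if origin is None else np.asarray(origin, dtype=float)
        self.spacing = spacing

    @property
    def shape(self):
        return self.data.shape


def export_section(xmap, start, end, order: str = "C", rot: str = "xyz",
                   target: np.ndarray | None = None) -> MapBox:
    """Export the inclusive grid box [start, end] to a numpy array.

    Values come out on the map's native axes and spacing — no
    resampling.  For an :class:`Xmap` the box may straddle the unit
    cell (wrap semantics); for an :class:`NXmap` it must lie inside
    the stored extent.  With ``target`` supplied the existing array is
    re-filled in place (no reallocation) and must match the expected
    shape.
    """
    if order not in ("C", "F"):
        raise InvalidArgument(f"order must be 'C' or 'F', got {order!r}")
    if rot not in ("xyz", "zyx"):
        raise InvalidArgument(f"rot must be 'xyz' or 'zyx', got {rot!r}")
    s = np.asarray(start.uvw if isinstance(start, Coord_grid) else start, dtype=int)
    e = np.asarray(end.uvw if isinstance(end, Coord_grid) else end, dtype=int)
    if np.any(e < s):
        raise InvalidArgument(f"box end {tuple(e)} must be >= start {tuple(s)} componentwise")
    counts = e - s + 1
    ranges = [np.arange(s[i], e[i] + 1) for i in range(3)]
    if isinstance(xmap, Xmap):
        n = xmap.grid.nuvw
        idx = [np.mod(r, n[i]) for i, r in enumerate(ranges)]
        block = xmap.values[np.ix_(*idx)]
    elif isinstance(xmap, NXmap):
        if np.any(s < 0) or np.any(e >= xmap.shape):
            raise OutOfRange(
                f"section [{tuple(s)}, {tuple(e)}] outside NXmap extent {xmap.shape}")
        block = xmap.values[s[0]:e[0] + 1, s[1]:e[1] + 1, s[2]:e[2] + 1]
    else:
        raise InvalidArgument(f"cannot export a section of {type(xmap).__name__}")
    if rot == "zyx":
        block = block.transpose(2, 1, 0)
        counts = counts[::-1]
    if target is not None:
        if target.shape != tuple(counts):
            raise LengthError(
                f"target array shape {target.shape} does not match section shape {tuple(counts)}")
        target[...] = block
        data = target
    else:
        data = (np.ascontiguousarray(block) if order == "C"
                else np.asfortranarray(block)).astype(float)
    return MapBox(data, Coord_grid(s), order=order, rot=rot)


def export_interpolated_box(xmap: Xmap, origin_orth, spacing: float,
                            shape: tuple[int, int, int]) -> MapBox:
    """Export a box on strictly Cartesian axes by trilinear interpolation.

    Output point (i,j,k) is the map value interpolated at orthogonal
    position ``origin + spacing * (i,j,k)`` angstroms.
    """
    if spacing <= 0:
        raise InvalidArgument(f"spacing must be positive, got {spacing}")
    shape = tuple(int(x) for x in shape)
    origin = np.asarray(origin_orth, dtype=float).reshape(3)
    ijk = np.indices(shape).reshape(3, -1).T
    pts = origin[None, :] + spacing * ijk
    vals = xmap.interp_orth(pts).reshape(shape)
    return MapBox(vals, None, origin=origin, spacing=spacing)


# ---------------------------------------------------------------------------
# CCP4/MRC 2014 I/O (mode 2, float32)

_MRC_HEADER_SIZE = 1024


def write_map_file(xmap, path) -> None:
    """Write a map as CCP4/MRC 2014, mode 2, axis order x,y,z.

    An :class:`Xmap` is written as one full unit cell (start 0, ISPG
    from the built-in table); an :class:`NXmap` must carry a
    crystal-frame placement (``from_cell_grid``) and is written with
    its start offsets and ISPG 0.
    """
    if isinstance(xmap, Xmap):
        values = xmap.values
        cell = xmap.cell
        mxyz = xmap.grid.nuvw
        start = np.zeros(3, dtype=int)
        ispg = SPACEGROUP_NUMBERS.get(xmap.spacegroup.name, 1)
    elif isinstance(xmap, NXmap):
        if xmap.cell is None or xmap.grid_full is None or xmap.start_grid is None:
            raise InvalidArgument(
                "NXmap must carry a cell-grid placement (from_cell_grid) to be written as MRC")
        values = xmap.values
        cell = xmap.cell
        mxyz = xmap.grid_full.nuvw
        start = xmap.start_grid
        ispg = 0
    else:
        raise InvalidArgument(f"cannot write {type(xmap).__name__} as a map file")
    if values.size == 0:
        raise InvalidArgument("refusing to write an empty map")

    header_i = np.zeros(256, dtype="<i4")
    header_f = header_i.view("<f4")
    nxyz = values.shape
    header_i[0:3] = nxyz  # NX, NY, NZ (x fastest in file order)
    header_i[3] = 2  # MODE 2: float32
    header_i[4:7] = start
    header_i[7:10] = mxyz
    header_f[10:13] = (cell.a, cell.b, cell.c)
    header_f[13:16] = (cell.alpha, cell.beta, cell.gamma)
    header_i[16:19] = (1, 2, 3)  # MAPC, MAPR, MAPS
    header_f[19] = values.min()
    header_f[20] = values.max()
    header_f[21] = values.mean()
    header_i[22] = ispg
    header_i[23] = 0  # NSYMBT
    # ORIGIN (words 50-52): mirror of the start offset, for cryo-EM tools
    axes = cell.orth_matrix / np.asarray(mxyz, dtype=float)[None, :]
    header_f[49:52] = axes @ start
    header_i[52] = int.from_bytes(b"MAP ", "little")
    header_i[53] = int.from_bytes(bytes([0x44, 0x44, 0, 0]), "little")
    header_f[54] = values.std()
    header_i[55] = 1
    label = b"Created by xtalkit" + b" " * 62
    try:
        with open(path, "wb") as fh:
            fh.write(header_i[:56].tobytes())
            fh.write(label)
            fh.write(b"\x00" * (80 * 9))
            fh.write(np.ascontiguousarray(values.transpose(2, 1, 0), dtype="<f4").tobytes())
    except OSError as exc:
        raise MessageFatal(f"cannot write map file {path}: {exc}") from exc


def read_map_file(path, spacegroup: Spacegroup | None = None):
    """Read a CCP4/MRC 2014 file into an :class:`Xmap` or :class:`NXmap`.

    Honours the MAPC/MAPR/MAPS axis permutation, the start offsets,
    the cell and mode 2 floats.  A map covering exactly one full unit
    cell with zero start offsets and a crystallographic ISPG comes
    back as an :class:`Xmap` (the space group resolved from the
    built-in table, or passed explicitly); everything else is an
    :class:`NXmap`.
    """
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise MessageFatal(f"cannot read map file {path}: {exc}") from exc
    if len(raw) < _MRC_HEADER_SIZE:
        raise InvalidArgument(f"{path}: file too short to be an MRC map")
    if raw[208:212] != b"MAP ":
        raise InvalidArgument(f"{path}: bad MRC magic {raw[208:212]!r} (expected b'MAP ')")
    machst = raw[212:216]
    byteorder = ">" if machst[0] == 0x11 else "<"
    header_i = np.frombuffer(raw[:_MRC_HEADER_SIZE], dtype=f"{byteorder}i4")
    header_f = header_i.view(f"{byteorder}f4")
    mode = int(header_i[3])
    if mode != 2:
        raise InvalidArgument(f"{path}: unsupported MRC mode {mode} (only mode 2)")
    ncrs = header_i[0:3].astype(int)
    start_crs = header_i[4:7].astype(int)
    mxyz = header_i[7:10].astype(int)
    cell = Cell(*header_f[10:13], *header_f[13:16])
    mapc, mapr, maps = (int(x) for x in header_i[16:19])
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise InvalidArgument(f"{path}: bad axis codes {(mapc, mapr, maps)}")
    ispg = int(header_i[22])
    nsymbt = int(header_i[23])
    data_start = _MRC_HEADER_SIZE + nsymbt
    count = int(np.prod(ncrs))
    data = np.frombuffer(raw[data_start:data_start + 4 * count],
                         dtype=f"{byteorder}f4")
    if data.size != count:
        raise InvalidArgument(f"{path}: truncated data section")
    # file order is [sections, rows, columns]; permute to [x, y, z]
    arr = data.reshape(ncrs[::-1]).transpose(2, 1, 0)  # now [c, r, s]
    ax_of_dim = (mapc, mapr, maps)
    perm = [ax_of_dim.index(axis + 1) for axis in range(3)]
    values = np.ascontiguousarray(arr.transpose(perm)).astype(float)
    start_xyz = np.array([start_crs[perm[axis]] for axis in range(3)])

    grid_full = Grid_sampling(*mxyz)
    full_cell = (np.array_equal(values.shape, mxyz) and np.all(start_xyz == 0))
    if full_cell and (ispg >= 1 or spacegroup is not None):
        if spacegroup is None:
            name = _NUMBER_TO_NAME.get(ispg)
            spacegroup = (Spacegroup.from_name(name) if name
                          else Spacegroup.from_name("P1"))
        return Xmap(cell, spacegroup, grid_full, values)
    return NXmap.from_cell_grid(values, cell, grid_full, start_xyz)
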