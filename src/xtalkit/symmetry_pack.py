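"""Symmetry packing search: which operators fill a volume with copies
of the model.

Molecular viewers need, for a model sitting somewhere in the crystal,
the full set of symmetry operators — space-group elements *combined
with whole-cell lattice translations* — whose action brings a copy of
the model into a target volume (one unit cell, or an arbitrary box the
user is looking at).  :class:`Unit_Cell` precomputes the model's
grid-aligned bounding box and the operators packing one unit cell;
:meth:`Unit_Cell.all_symops_in_box` runs the stepped search over an
arbitrary box, trading accuracy for speed but erring on the side of
inclusiveness; :func:`brute_force_symops_in_box` is the exact
per-grid-point reference.  Found operators export as stacked affine
matrices (3x4 or 4x4) in the fractional or orthogonal frame for direct
consumption by graphics code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .cell_symmetry import Cell, Coord_grid, Grid_sampling, Spacegroup, Symop
from .errors import InvalidArgument
from .model_hierarchy import Atom_list

__all__ = [
    "PackSymop",
    "Symops",
    "Unit_Cell",
    "make_unit_cell",
    "all_symops_in_box",
    "brute_force_symops_in_box",
    "symops_matrices",
]

_BRUTE_FORCE_LIMIT = 10**6


class PackSymop:
    """A space-group operator plus an integer whole-cell lattice shift.

    Acts on fractional coordinates as ``x' = rot @ x + trn + shift``.
    Two instances are duplicates iff rotation, translation and shift
    all match exactly.
    """

    __slots__ = ("isym", "symop", "shift")

    def __init__(self, isym: int, symop: Symop, shift=(0, 0, 0)):
        self.isym = int(isym)
        self.symop = symop
        self.shift = np.asarray(shift, dtype=int).reshape(3)

    def apply(self, frac) -> np.ndarray:
        return self.symop.apply(frac) + self.shift

    @property
    def is_identity(self) -> bool:
        return self.symop.is_identity and not self.shift.any()

    def key(self) -> tuple:
        return (self.isym,) + tuple(self.shift)

    def __eq__(self, other):
        if not isinstance(other, PackSymop):
            return NotImplemented
        return (self.symop == other.symop
                and np.array_equal(self.shift, other.shift))

    def __hash__(self):
        return hash((self.symop.key(), tuple(self.shift)))

    def matrix_frac(self, format: str = "3x4") -> np.ndarray:
        """Affine matrix in the fractional frame (acts on column vectors)."""
        m = np.zeros((3, 4))
        m[:, :3] = self.symop.rot
        m[:, 3] = self.symop.trn + self.shift
        return _with_format(m, format)

    def matrix_orth(self, cell: Cell, format: str = "3x4") -> np.ndarray:
        """Affine matrix in orthogonal angstroms: the fractional operator
        conjugated by the cell orthogonalisation, lattice shift folded
        into the translation column."""
        rot = cell.orth_matrix @ self.symop.rot @ cell.frac_matrix
        trn = cell.orth_matrix @ (self.symop.trn + self.shift)
        m = np.zeros((3, 4))
        m[:, :3] = rot
        m[:, 3] = trn
        return _with_format(m, format)

    def __repr__(self):
        return f"PackSymop({self.symop.triplet()!r}, shift={tuple(self.shift)})"


def _with_format(m: np.ndarray, format: str) -> np.ndarray:
    if format == "3x4":
        return m
    if format == "4x4":
        out = np.zeros((4, 4))
        out[:3, :] = m
        out[3, 3] = 1.0
        return out
    raise InvalidArgument(f"matrix format must be '3x4' or '4x4', got {format!r}")


class Symops:
    """A duplicate-free, canonically ordered list of :class:`PackSymop`.

    Canonical order: by space-group operator index, then by lattice
    shift.
    """

    def __init__(self, ops=()):
        seen = set()
        self._ops: list[PackSymop] = []
        for op in sorted(ops, key=lambda o: o.key()):
            if op.key() not in seen:
                seen.add(op.key())
                self._ops.append(op)

    def __len__(self):
        return len(self._ops)

    def __iter__(self):
        return iter(self._ops)

    def __getitem__(self, i) -> PackSymop:
        return self._ops[i]

    def __contains__(self, op):
        return any(op == o for o in self._ops)

    def keys(self) -> set:
        return {op.key() for op in self._ops}

    def all_matrices_frac(self, format: str = "3x4") -> np.ndarray:
        """Stacked fractional affine matrices, shape (n, 3, 4) or (n, 4, 4)."""
        if not self._ops:
            return np.zeros((0, *(_with_format(np.zeros((3, 4)), format).shape)))
        return np.stack([op.matrix_frac(format) for op in self._ops])

    def all_matrices_orth(self, cell: Cell, format: str = "3x4") -> np.ndarray:
        """Stacked orthogonal-frame affine matrices; ``format='4x4'``
        appends the row (0, 0, 0, 1) to each matrix."""
        if not self._ops:
            return np.zeros((0, *(_with_format(np.zeros((3, 4)), format).shape)))
        return np.stack([op.matrix_orth(cell, format) for op in self._ops])

    def __repr__(self):
        return f"Symops({len(self)} operators)"


def symops_matrices(symops: Symops, cell: Cell, frame: str = "orth",
                    format: str = "3x4") -> np.ndarray:
    """Stacked affine matrices of a :class:`Symops` set.

    ``frame`` selects the fractional or orthogonal representation;
    matrices act on column vectors.
    """
    if frame == "orth":
        return symops.all_matrices_orth(cell, format)
    if frame == "frac":
        return symops.all_matrices_frac(format)
    raise InvalidArgument(f"frame must be 'orth' or 'frac', got {frame!r}")


class Unit_Cell:
    """Packing context for one atomic model in its crystal.

    ``reference_box`` is the smallest grid-aligned parallelepiped
    encompassing the model; ``symops_cell`` holds every (operator,
    lattice shift) whose image of the reference box intersects the
    unit cell.
    """

    def __init__(self, reference_coord, atom_list: Atom_list, cell: Cell,
                 spacegroup: Spacegroup, grid_sampling: Grid_sampling):
        if len(atom_list) == 0:
            raise InvalidArgument("atom list must not be empty")
        self.reference_coord = np.asarray(
            reference_coord.xyz if hasattr(reference_coord, "xyz") else reference_coord,
            dtype=float).reshape(3)
        self.atom_list = atom_list
        self.cell = cell
        self.spacegroup = spacegroup
        self.grid = grid_sampling

        gm = cell.fractionalize(atom_list.coords) * grid_sampling.nuvw  # real grid units
        self.box_min = Coord_grid(np.floor(gm.min(axis=0)).astype(int))
        self.box_max = Coord_grid(np.ceil(gm.max(axis=0)).astype(int))
        self.symops_cell = self._pack_unit_cell()

    @property
    def reference_box(self) -> tuple[Coord_grid, Coord_grid]:
        return self.box_min, self.box_max

    def identity_shift(self) -> np.ndarray:
        """Lattice shift placing the reference coordinate inside the cell."""
        frac = self.cell.fractionalize(self.reference_coord)
        return -np.floor(frac).astype(int)

    def _box_corners_frac(self) -> np.ndarray:
        """The 8 reference-box corners, fractional coordinates (8, 3)."""
        lo = self.box_min.uvw / self.grid.nuvw
        hi = self.box_max.uvw / self.grid.nuvw
        return np.array([[(hi if b else lo)[i] for i, b in enumerate(bits)]
                         for bits in itertools.product((0, 1), repeat=3)])

    def _pack_unit_cell(self) -> Symops:
        """Operators whose reference-box image intersects the cell [0,1)^3."""
        corners = self._box_corners_frac()
        ops = []
        for isym, symop in enumerate(self.spacegroup):
            img = symop.apply(corners)
            lo, hi = img.min(axis=0), img.max(axis=0)
            shift_ranges = []
            for ax in range(3):
                # n with [lo+n, hi+n] intersecting [0, 1)
                n_lo = int(math.ceil(-hi[ax] - 1e-9))
                n_hi = int(math.floor(1.0 - lo[ax] - 1e-9))
                shift_ranges.append(range(n_lo, n_hi + 1))
            for shift in itertools.product(*shift_ranges):
                ops.append(PackSymop(isym, symop, shift))
        return Symops(ops)

    # -- box search --------------------------------------------------------

    def _memberships(self, points_frac: np.ndarray) -> list[PackSymop]:
        """All (operator, shift) mapping any of ``points`` (n, 3) into the
        reference box; vectorised over the points."""
        pts = np.atleast_2d(points_frac)
        lo = self.box_min.uvw / self.grid.nuvw
        hi = self.box_max.uvw / self.grid.nuvw
        found: list[PackSymop] = []
        for isym, symop in enumerate(self.spacegroup):
            inv = symop.inverse()
            q0 = inv.apply(pts)  # (n, 3)
            # (S, n)^-1 p = q0 - R^-1 n; enumerate m = R^-1 n per axis
            m_lo = np.ceil(q0 - hi - 1e-9).astype(int)
            m_hi = np.floor(q0 - lo + 1e-9).astype(int)
            width = (m_hi - m_lo).max(axis=0, initial=0)
            shifts: set[tuple] = set()
            for offs in itertools.product(*(range(w + 1) for w in width)):
                m = m_lo + np.asarray(offs, dtype=int)
                valid = np.all(m <= m_hi, axis=1)
                if not valid.any():
                    continue
                n_vec = m[valid] @ symop.rot.T
                shifts.update(map(tuple, np.unique(n_vec, axis=0)))
            found.extend(PackSymop(isym, symop, s) for s in shifts)
        return found

    def all_symops_in_box(self, origin_xyz, box_size_uvw,
                          always_include_identity: bool = False,
                          sample_frequency: float = 2.0) -> Symops:
        """Operators needed to pack an arbitrary box, by stepped search.

        The box starts at orthogonal position ``origin_xyz`` (A) and
        extends ``box_size_uvw`` grid units along the cell axes.  The
        volume is searched in steps of (shortest reference-box side) /
        ``sample_frequency``, clamped so that all 8 box corners, the
        box faces and any unit-cell boundary crossings are sampled; for
        each search point the inverse operators mapping it into the
        reference box are collected, then sorted and culled of
        duplicates.  Low sample frequencies trade accuracy for speed
        but err on the side of inclusiveness.
        """
        size = np.asarray(box_size_uvw, dtype=float).reshape(3)
        if np.any(size <= 0):
            raise InvalidArgument(f"box size must be positive, got {tuple(size)}")
        if sample_frequency < 1:
            raise InvalidArgument(f"sample_frequency must be >= 1, got {sample_frequency}")
        origin = np.asarray(
            origin_xyz.xyz if hasattr(origin_xyz, "xyz") else origin_xyz,
            dtype=float).reshape(3)
        g0 = self.cell.fractionalize(origin) * self.grid.nuvw  # grid units
        sides = self.box_max.uvw - self.box_min.uvw
        step = max(sides.min(), 1) / float(sample_frequency)
        axes_points = []
        for ax in range(3):
            lo, hi = g0[ax], g0[ax] + size[ax]
            pts = list(np.arange(lo, hi, step)) + [hi]
            # unit-cell face crossings along this axis (multiples of N)
            n_ax = self.grid.nuvw[ax]
            k0 = int(math.ceil(lo / n_ax))
            pts.extend(float(k * n_ax) for k in range(k0, int(math.floor(hi / n_ax)) + 1))
            axes_points.append(np.unique(np.asarray(pts)))
        gu, gv, gw = np.meshgrid(*axes_points, indexing="ij")
        pts = np.stack([gu, gv, gw], axis=-1).reshape(-1, 3) / self.grid.nuvw
        result = Symops(self._memberships(pts))
        if always_include_identity:
            ident = PackSymop(0, self.spacegroup[0], self.identity_shift())
            if ident not in result:
                result = Symops(list(result) + [ident])
        return result

    def brute_force_symops_in_box(self, origin_xyz, box_size_uvw) -> Symops:
        """Exact reference: visit every integer grid point of the box.

        Collects every (operator, shift) mapping a grid point into the
        reference box; same duplicate culling and canonical order as
        the stepped search.  Limited to 10^6 grid points.
        """
        size = np.asarray(box_size_uvw, dtype=float).reshape(3)
        if np.any(size <= 0):
            raise InvalidArgument(f"box size must be positive, got {tuple(size)}")
        origin = np.asarray(
            origin_xyz.xyz if hasattr(origin_xyz, "xyz") else origin_xyz,
            dtype=float).reshape(3)
        g0 = self.cell.fractionalize(origin) * self.grid.nuvw
        axes_points = []
        count = 1
        for ax in range(3):
            lo = int(math.ceil(g0[ax] - 1e-9))
            hi = int(math.floor(g0[ax] + size[ax] + 1e-9))
            axes_points.append(range(lo, hi + 1))
            count *= max(hi - lo + 1, 0)
        if count > _BRUTE_FORCE_LIMIT:
            raise InvalidArgument(
                f"box has {count} grid points, above the brute-force limit {_BRUTE_FORCE_LIMIT}")
        gu, gv, gw = np.meshgrid(*[np.asarray(list(r)) for r in axes_points],
                                 indexing="ij")
        pts = np.stack([gu, gv, gw], axis=-1).reshape(-1, 3) / self.grid.nuvw
        return Symops(self._memberships(pts))


def make_unit_cell(reference_coord, atom_list: Atom_list, cell: Cell,
                   spacegroup: Spacegroup, grid_sampling: Grid_sampling) -> Unit_Cell:
    """Build a :class:`Unit_Cell` packing context."""
    return Unit_Cell(reference_coord, atom_list, cell, spacegroup, grid_sampling)


def all_symops_in_box(uc: Unit_Cell, origin_xyz, box_size_uvw,
                      always_include_identity: bool = False,
                      sample_frequency: float = 2.0) -> Symops:
    """Functional form of :meth:`Unit_Cell.all_symops_in_box`."""
    return uc.all_symops_in_box(origin_xyz, box_size_uvw,
                                always_include_identity, sample_frequency)


def brute_force_symops_in_box(uc: Unit_Cell, origin_xyz, box_size_uvw) -> Symops:
    """Functional form of :meth:`Unit_Cell.brute_force_symops_in_box`."""
    return uc.brute_force_symops_in_box(origin_xyz, box_size_uvw)
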