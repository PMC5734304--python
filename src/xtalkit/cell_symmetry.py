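"""Unit cells, coordinate frames and space-group symmetry.

The module provides the metric side of crystallography: the unit cell
with its fractional/orthogonal transformation matrices, the three
coordinate types (integer grid, fractional, orthogonal angstroms) with
their conversion algebra, symmetry operators parsed from International
Tables triplet strings (``"-x,y+1/2,-z"``), finite space groups
generated to closure from a small built-in generator table, and map
grid sampling chosen from a resolution limit.

Conventions fixed here and relied on throughout the package:

* Orthogonalisation follows the PDB standard: **a** along x, **b** in
  the x-y plane.  Angles are degrees everywhere in the public API.
* Grid coordinates are 0-based; fractional -> grid conversion rounds
  half away from zero.
* Symmetry operators store an integer rotation acting on fractional
  coordinates and a translation reduced mod 1 to ``[0, 1)``.
* The canonical operator order of a space group is: identity first,
  then lexicographic on (flattened rotation, translation).
"""

from __future__ import annotations

import math
import re
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidArgument, LengthError

__all__ = [
    "Cell",
    "Grid_sampling",
    "Coord_grid",
    "Coord_frac",
    "Coord_orth",
    "Symop",
    "Spacegroup",
    "make_cell",
    "convert_coord",
    "parse_symop",
    "format_symop",
    "spacegroup_from_generators",
    "grid_from_resolution",
]

# Translations in conventional settings are multiples of 1/12; this
# denominator keys exact comparisons of mod-1 translations.
_TRN_DENOM = 24


def _as_vec3(values, dtype=float, what="coordinate"):
    arr = np.asarray(values, dtype=dtype)
    if arr.shape != (3,):
        raise LengthError(f"{what} must have exactly 3 components, got shape {arr.shape}")
    return arr


def round_half_away(x):
    """Round to nearest integer, halves away from zero (elementwise)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x)).astype(int)


# ---------------------------------------------------------------------------
# Cell and grid sampling

class Cell:
    """Unit-cell metric: lengths in angstroms, angles in degrees.

    ``orth_matrix`` maps fractional coordinates to orthogonal angstroms
    (a along x, b in the x-y plane); ``frac_matrix`` is its inverse.
    """

    def __init__(self, a: float, b: float, c: float,
                 alpha: float = 90.0, beta: float = 90.0, gamma: float = 90.0):
        if min(a, b, c) <= 0:
            raise InvalidArgument(f"cell lengths must be positive, got {(a, b, c)}")
        for name, ang in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not 0.0 < ang < 180.0:
                raise InvalidArgument(f"cell angle {name}={ang} outside (0, 180)")
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.alpha, self.beta, self.gamma = float(alpha), float(beta), float(gamma)

        ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
        sg = math.sin(math.radians(gamma))
        vsq = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if vsq <= 0.0:
            raise InvalidArgument(
                f"degenerate cell metric: angles {(alpha, beta, gamma)} give volume^2 <= 0")
        v = math.sqrt(vsq)
        self.orth_matrix = np.array([
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ])
        self.frac_matrix = np.linalg.inv(self.orth_matrix)
        self.volume = a * b * c * v

    def orthogonalize(self, frac) -> np.ndarray:
        """Fractional -> orthogonal angstroms (vector or (n,3) array)."""
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, orth) -> np.ndarray:
        """Orthogonal angstroms -> fractional (vector or (n,3) array)."""
        return np.asarray(orth, dtype=float) @ self.frac_matrix.T

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """G* with ``|s|^2 = h . G* . h`` for Miller indices h."""
        return self.frac_matrix @ self.frac_matrix.T

    def invresolsq(self, hkl) -> np.ndarray:
        """``1/d^2`` for one (h,k,l) or an (n,3) array of them."""
        h = np.asarray(hkl, dtype=float)
        s = h @ self.frac_matrix
        return np.sum(s * s, axis=-1)

    def __repr__(self):
        return (f"Cell({self.a:g}, {self.b:g}, {self.c:g}, "
                f"{self.alpha:g}, {self.beta:g}, {self.gamma:g})")

    def __eq__(self, other):
        if not isinstance(other, Cell):
            return NotImplemented
        return np.allclose(
            [self.a, self.b, self.c, self.alpha, self.beta, self.gamma],
            [other.a, other.b, other.c, other.alpha, other.beta, other.gamma],
        )


def make_cell(a, b, c, alpha=90.0, beta=90.0, gamma=90.0) -> Cell:
    """Construct a :class:`Cell`; lengths in angstroms, angles in degrees."""
    return Cell(a, b, c, alpha, beta, gamma)


class Grid_sampling:
    """Number of grid divisions (nu, nv, nw) along the three cell axes."""

    def __init__(self, nu: int, nv: int, nw: int):
        for n in (nu, nv, nw):
            if int(n) != n or n < 2:
                raise InvalidArgument(f"grid divisions must be integers >= 2, got {(nu, nv, nw)}")
        self.nu, self.nv, self.nw = int(nu), int(nv), int(nw)

    @property
    def nuvw(self) -> np.ndarray:
        return np.array([self.nu, self.nv, self.nw])

    @property
    def size(self) -> int:
        return self.nu * self.nv * self.nw

    def __iter__(self):
        return iter((self.nu, self.nv, self.nw))

    def __eq__(self, other):
        if not isinstance(other, Grid_sampling):
            return NotImplemented
        return (self.nu, self.nv, self.nw) == (other.nu, other.nv, other.nw)

    def __repr__(self):
        return f"Grid_sampling({self.nu}, {self.nv}, {self.nw})"


def _next_smooth(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}."""
    n = max(2, int(n))
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


def grid_from_resolution(cell: Cell, d_min: float, rate: float = 1.5,
                         spacegroup: "Spacegroup | None" = None) -> Grid_sampling:
    """Grid sampling fine enough for a resolution limit.

    Each axis gets at least ``ceil(2 * rate * length / d_min)`` divisions
    (``rate`` is the Shannon oversampling factor), rounded up to an
    FFT-friendly size with prime factors 2, 3 and 5 only.  With a
    ``spacegroup`` given, the divisions additionally respect its
    symmetry: each axis count is divisible by the denominators of the
    group's translations along that axis, and axes mixed by a rotation
    (e.g. hexagonal a/b) share one count.
    """
    if d_min <= 0:
        raise InvalidArgument(f"d_min must be positive, got {d_min}")
    if rate < 1.0:
        raise InvalidArgument(f"Shannon rate must be >= 1, got {rate}")
    lower = [math.ceil(2.0 * rate * length / d_min)
             for length in (cell.a, cell.b, cell.c)]
    if spacegroup is None:
        return Grid_sampling(*(_next_smooth(lb) for lb in lower))

    # per-axis divisibility from translation denominators
    factors = [1, 1, 1]
    for op in spacegroup:
        for ax, t24 in enumerate(op._trn_key()):
            den = Fraction(int(t24), _TRN_DENOM).denominator
            factors[ax] = math.lcm(factors[ax], den)
    # axes mixed by any rotation must share a grid count
    group_of = list(range(3))
    for op in spacegroup:
        for i in range(3):
            for j in range(3):
                if i != j and op.rot[i, j] != 0:
                    lo, hi = sorted((group_of[i], group_of[j]))
                    group_of = [lo if g == hi else g for g in group_of]
    dims = [0, 0, 0]
    for g in set(group_of):
        axes = [ax for ax in range(3) if group_of[ax] == g]
        lb = max(lower[ax] for ax in axes)
        fac = math.lcm(*(factors[ax] for ax in axes))
        n = _next_smooth(lb)
        while n % fac:
            n = _next_smooth(n + 1)
        for ax in axes:
            dims[ax] = n
    return Grid_sampling(*dims)


# ---------------------------------------------------------------------------
# Coordinate types

class Coord_grid:
    """Integer 0-based grid coordinate (u, v, w).

    Constructible from any 3-element integer iterable; ``+`` and ``-``
    are componentwise and accept a :class:`Coord_grid` or a plain
    iterable on the right-hand side, returning a new object.
    """

    __slots__ = ("_uvw",)

    def __init__(self, uvw=(0, 0, 0)):
        self._uvw = _as_vec3(uvw, dtype=int, what="grid coordinate")

    @property
    def uvw(self) -> np.ndarray:
        """The (u, v, w) triple as a fresh integer array."""
        return self._uvw.copy()

    @uvw.setter
    def uvw(self, values):
        self._uvw = _as_vec3(values, dtype=int, what="grid coordinate")

    @property
    def u(self) -> int:
        return int(self._uvw[0])

    @property
    def v(self) -> int:
        return int(self._uvw[1])

    @property
    def w(self) -> int:
        return int(self._uvw[2])

    def __add__(self, other):
        other = other._uvw if isinstance(other, Coord_grid) else _as_vec3(other, int)
        return Coord_grid(self._uvw + other)

    def __sub__(self, other):
        other = other._uvw if isinstance(other, Coord_grid) else _as_vec3(other, int)
        return Coord_grid(self._uvw - other)

    def __neg__(self):
        return Coord_grid(-self._uvw)

    def __eq__(self, other):
        if isinstance(other, Coord_grid):
            return bool(np.array_equal(self._uvw, other._uvw))
        return NotImplemented

    def __hash__(self):
        return hash(tuple(self._uvw))

    def __iter__(self):
        return iter(int(x) for x in self._uvw)

    def __getitem__(self, i):
        return int(self._uvw[i])

    def coord_frac(self, grid: Grid_sampling) -> "Coord_frac":
        return Coord_frac(self._uvw / grid.nuvw)

    def unit(self, grid: Grid_sampling) -> "Coord_grid":
        """Equivalent coordinate wrapped into one unit cell's grid."""
        return Coord_grid(np.mod(self._uvw, grid.nuvw))

    def __repr__(self):
        return f"Coord_grid({self.u}, {self.v}, {self.w})"


class Coord_frac:
    """Real-valued fractional coordinate (cell fractions)."""

    __slots__ = ("_uvw",)

    def __init__(self, uvw=(0.0, 0.0, 0.0)):
        self._uvw = _as_vec3(uvw, what="fractional coordinate")

    @property
    def uvw(self) -> np.ndarray:
        return self._uvw.copy()

    @property
    def u(self) -> float:
        return float(self._uvw[0])

    @property
    def v(self) -> float:
        return float(self._uvw[1])

    @property
    def w(self) -> float:
        return float(self._uvw[2])

    def coord_orth(self, cell: Cell) -> "Coord_orth":
        return Coord_orth(cell.orthogonalize(self._uvw))

    def coord_grid(self, grid: Grid_sampling) -> Coord_grid:
        """Nearest grid point (half rounds away from zero)."""
        return Coord_grid(round_half_away(self._uvw * grid.nuvw))

    def coord_map(self, grid: Grid_sampling) -> np.ndarray:
        """Real-valued (non-integer) grid units, for interpolation."""
        return self._uvw * grid.nuvw

    def lattice_copy_unit(self) -> "Coord_frac":
        return Coord_frac(np.mod(self._uvw, 1.0))

    def __add__(self, other):
        other = other._uvw if isinstance(other, Coord_frac) else _as_vec3(other)
        return Coord_frac(self._uvw + other)

    def __sub__(self, other):
        other = other._uvw if isinstance(other, Coord_frac) else _as_vec3(other)
        return Coord_frac(self._uvw - other)

    def __iter__(self):
        return iter(float(x) for x in self._uvw)

    def __repr__(self):
        return "Coord_frac({:.6g}, {:.6g}, {:.6g})".format(*self._uvw)


class Coord_orth:
    """Orthogonal coordinate in angstroms."""

    __slots__ = ("_xyz",)

    def __init__(self, xyz=(0.0, 0.0, 0.0)):
        self._xyz = _as_vec3(xyz, what="orthogonal coordinate")

    @property
    def xyz(self) -> np.ndarray:
        return self._xyz.copy()

    @property
    def x(self) -> float:
        return float(self._xyz[0])

    @property
    def y(self) -> float:
        return float(self._xyz[1])

    @property
    def z(self) -> float:
        return float(self._xyz[2])

    def coord_frac(self, cell: Cell) -> Coord_frac:
        return Coord_frac(cell.fractionalize(self._xyz))

    def __add__(self, other):
        other = other._xyz if isinstance(other, Coord_orth) else _as_vec3(other)
        return Coord_orth(self._xyz + other)

    def __sub__(self, other):
        other = other._xyz if isinstance(other, Coord_orth) else _as_vec3(other)
        return Coord_orth(self._xyz - other)

    def __iter__(self):
        return iter(float(x) for x in self._xyz)

    def __repr__(self):
        return "Coord_orth({:.6g}, {:.6g}, {:.6g})".format(*self._xyz)


def convert_coord(cell: Cell, grid: Grid_sampling | None, coord, target_frame: str):
    """Convert a coordinate between the grid, fractional and orthogonal frames.

    ``grid`` is required only when the source or target frame is ``grid``.
    Grid -> frac divides componentwise by the grid divisions; frac -> grid
    rounds to the nearest point, halves away from zero.
    """
    if target_frame not in ("grid", "frac", "orth"):
        raise InvalidArgument(f"unknown target frame {target_frame!r}")
    if isinstance(coord, Coord_grid):
        frac = coord.coord_frac(_require_grid(grid))
    elif isinstance(coord, Coord_frac):
        frac = coord
    elif isinstance(coord, Coord_orth):
        frac = coord.coord_frac(cell)
    else:
        raise InvalidArgument(f"cannot convert object of type {type(coord).__name__}")
    if target_frame == "frac":
        return frac
    if target_frame == "orth":
        return frac.coord_orth(cell)
    return frac.coord_grid(_require_grid(grid))


def _require_grid(grid):
    if grid is None:
        raise InvalidArgument("grid_sampling is required for grid-frame conversions")
    return grid


# ---------------------------------------------------------------------------
# Symmetry operators

_TERM_RE = re.compile(r"([+-]?)(\d+(?:\.\d+)?(?:/\d+)?|\d*[xyzXYZ])")


def _parse_triplet_term(term: str, triplet: str) -> tuple[np.ndarray, float]:
    """One comma-separated term like ``-x+1/2`` -> (row of rot, translation)."""
    row = np.zeros(3, dtype=int)
    trn = Fraction(0)
    pos = 0
    compact = term.replace(" ", "")
    if not compact:
        raise InvalidArgument(f"empty term in symmetry triplet {triplet!r}")
    while pos < len(compact):
        m = _TERM_RE.match(compact, pos)
        if not m:
            raise InvalidArgument(
                f"malformed token {compact[pos:]!r} in symmetry triplet {triplet!r}")
        sign = -1 if m.group(1) == "-" else 1
        body = m.group(2)
        axis = body[-1].lower()
        if axis in "xyz":
            coef = int(body[:-1]) if len(body) > 1 else 1
            row["xyz".index(axis)] += sign * coef
        elif "/" in body:
            num, den = body.split("/")
            trn += sign * Fraction(int(num), int(den))
        else:
            trn += sign * Fraction(body).limit_denominator(_TRN_DENOM)
        pos = m.end()
    return row, float(trn)


class Symop:
    """A symmetry operator: integer rotation + fractional translation.

    Acts on fractional coordinates as ``x' = rot @ x + trn``; the
    translation is stored reduced mod 1 to ``[0, 1)``.
    """

    __slots__ = ("rot", "trn")

    def __init__(self, rot, trn=(0.0, 0.0, 0.0)):
        rot = np.asarray(rot)
        if rot.shape != (3, 3):
            raise LengthError(f"rotation must be 3x3, got shape {rot.shape}")
        if not np.allclose(rot, np.round(rot), atol=1e-9):
            raise InvalidArgument("rotation part must be integer-valued on fractional axes")
        self.rot = np.round(rot).astype(int)
        if round(abs(np.linalg.det(self.rot))) != 1:
            raise InvalidArgument(f"rotation must be unimodular, |det| = "
                                  f"{abs(np.linalg.det(self.rot)):g}")
        self.trn = np.mod(_as_vec3(trn, what="translation"), 1.0)
        # guard against -1e-16 style residues pushing components to 1.0
        self.trn[np.isclose(self.trn, 1.0)] = 0.0

    @classmethod
    def identity(cls) -> "Symop":
        return cls(np.eye(3, dtype=int))

    @classmethod
    def from_triplet(cls, triplet: str) -> "Symop":
        parts = triplet.split(",")
        if len(parts) != 3:
            raise InvalidArgument(
                f"symmetry triplet must have 3 comma-separated terms: {triplet!r}")
        rows, trns = zip(*(_parse_triplet_term(p, triplet) for p in parts))
        return cls(np.vstack(rows), np.array(trns))

    def apply(self, frac) -> np.ndarray:
        """Apply to a fractional vector or (n,3) array (no mod-1 reduction)."""
        return np.asarray(frac, dtype=float) @ self.rot.T + self.trn

    def compose(self, other: "Symop") -> "Symop":
        """``self . other``, translation reduced mod 1."""
        return Symop(self.rot @ other.rot, self.rot @ other.trn + self.trn)

    def __mul__(self, other):
        return self.compose(other)

    def inverse(self) -> "Symop":
        inv_rot = np.round(np.linalg.inv(self.rot)).astype(int)
        return Symop(inv_rot, -inv_rot @ self.trn)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.rot, np.eye(3, dtype=int))
                    and np.all(self._trn_key() == 0))

    def _trn_key(self) -> np.ndarray:
        return np.mod(np.round(self.trn * _TRN_DENOM).astype(int), _TRN_DENOM)

    def key(self) -> tuple:
        """Exact comparison key (rotation entries, translation in 1/24ths)."""
        return tuple(self.rot.ravel()) + tuple(self._trn_key())

    def __eq__(self, other):
        if not isinstance(other, Symop):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self):
        return hash(self.key())

    def triplet(self) -> str:
        """Canonical triplet string, e.g. ``-x,y+1/2,-z``."""
        parts = []
        for i in range(3):
            term = ""
            for j, axis in enumerate("xyz"):
                c = self.rot[i, j]
                if c == 0:
                    continue
                sign = "-" if c < 0 else ("+" if term else "")
                mag = abs(c)
                term += sign + (f"{mag}" if mag != 1 else "") + axis
            t = Fraction(int(self._trn_key()[i]), _TRN_DENOM)
            if t:
                term += ("+" if term else "") + f"{t.numerator}/{t.denominator}"
            parts.append(term or "0")
        return ",".join(parts)

    def __repr__(self):
        return f"Symop({self.triplet()!r})"


def parse_symop(triplet: str) -> Symop:
    """Parse an International Tables triplet string into a :class:`Symop`."""
    return Symop.from_triplet(triplet)


def format_symop(symop: Symop) -> str:
    """Canonical triplet string of a :class:`Symop`."""
    return symop.triplet()


# ---------------------------------------------------------------------------
# Space groups

# Generators (beyond the identity) for the built-in table, conventional
# settings; the full group is produced by closure under composition.
_BUILTIN_GENERATORS: dict[str, list[str]] = {
    "P1": [],
    "P-1": ["-x,-y,-z"],
    "P21": ["-x,y+1/2,-z"],
    "C2": ["-x,y,-z", "x+1/2,y+1/2,z"],
    "P212121": ["-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z"],
    "P43212": ["-y+1/2,x+1/2,z+3/4", "y,x,-z"],
    "P6322": ["-y,x-y,z", "-x,-y,z+1/2", "y,x,-z"],
}

_MAX_GROUP_ORDER = 1000


class Spacegroup:
    """A finite space group: ordered symmetry operators, identity first."""

    def __init__(self, name: str, symops: Sequence[Symop]):
        self.name = name
        ops = list(symops)
        if not ops or not ops[0].is_identity:
            raise InvalidArgument("space group must contain the identity first")
        self.symops = ops

    @property
    def num_symops(self) -> int:
        return len(self.symops)

    def __len__(self):
        return len(self.symops)

    def __iter__(self):
        return iter(self.symops)

    def __getitem__(self, i) -> Symop:
        return self.symops[i]

    @classmethod
    def from_generators(cls, name: str, generator_triplets: Iterable[str]) -> "Spacegroup":
        """Generate the group to closure under composition mod lattice
        translations; canonical order (identity, then lexicographic)."""
        ops = {Symop.identity().key(): Symop.identity()}
        gens = [parse_symop(t) for t in generator_triplets]
        for g in gens:
            ops[g.key()] = g
        changed = True
        while changed:
            changed = False
            current = list(ops.values())
            for a in current:
                for b in current:
                    c = a.compose(b)
                    if c.key() not in ops:
                        ops[c.key()] = c
                        changed = True
                        if len(ops) > _MAX_GROUP_ORDER:
                            raise InvalidArgument(
                                f"generators do not close within {_MAX_GROUP_ORDER} "
                                f"elements: {list(generator_triplets)}")
        # identity first, remainder in lexicographic key order
        ident = [s for s in ops.values() if s.is_identity]
        rest = sorted((s for s in ops.values() if not s.is_identity), key=lambda s: s.key())
        return cls(name, ident + rest)

    @classmethod
    def from_name(cls, name: str) -> "Spacegroup":
        """Look up one of the built-in groups by short symbol (e.g. ``P21``)."""
        key = name.replace(" ", "")
        if key not in _BUILTIN_GENERATORS:
            raise InvalidArgument(
                f"unknown space group {name!r}; built-ins: {sorted(_BUILTIN_GENERATORS)}")
        return cls.from_generators(key, _BUILTIN_GENERATORS[key])

    @classmethod
    def builtin_names(cls) -> list[str]:
        return sorted(_BUILTIN_GENERATORS)

    def __repr__(self):
        return f"Spacegroup({self.name!r}, {self.num_symops} symops)"


def spacegroup_from_generators(name: str, generator_triplets: Iterable[str]) -> Spacegroup:
    """Build a :class:`Spacegroup` from generator triplet strings."""
    return Spacegroup.from_generators(name, list(generator_triplets))
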