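"""Reflection data: HKL lists, (F, phi) containers, structure factors,
FFT map synthesis/analysis, Patterson coefficients and B-factor scaling.

The central container, :class:`HKL_data_F_Phi`, holds the symmetry- and
Friedel-unique reflections of a crystal to a resolution limit, each with
an amplitude F (arbitrary scattering units) and a phase phi (degrees at
the public surface; radians internally).  Missing observations are
encoded as NaN amplitudes and skipped by every transform.

Fourier conventions (crystallographic standard):

.. math::

    F(h) = \\sum_j f_j\\, occ_j\\, e^{-B_j |s|^2/4}\\, e^{2\\pi i\\, h\\cdot x_j},
    \\qquad
    \\rho(x) = \\frac{1}{V} \\sum_h F(h)\\, e^{-2\\pi i\\, h\\cdot x}

with ``|s| = 1/d`` and B the isotropic displacement ``8 pi^2 u_iso``.
Scattering factors are constant per element (the electron count); see
the package docs for the rationale and the form-factor extension point.
"""

from __future__ import annotations

import math

import numpy as np

from .cell_symmetry import Cell, Grid_sampling, Spacegroup
from .crystal_maps import Xmap
from .errors import InvalidArgument, LengthError, MessageFatal
from .model_hierarchy import Atom_list, u_to_b

__all__ = [
    "HKL",
    "HKL_data_F_Phi",
    "generate_hkl_list",
    "export_array",
    "import_array",
    "patterson_coeffs",
    "calc_sf_direct",
    "fft_synthesis",
    "fft_analysis",
    "scale_coeffs",
    "write_text",
    "read_text",
    "write_mmcif_sf",
    "write_mtz",
    "read_mtz",
]


class HKL:
    """A Miller index (h, k, l)."""

    __slots__ = ("h", "k", "l")

    def __init__(self, h: int, k: int, l: int):
        self.h, self.k, self.l = int(h), int(k), int(l)

    @property
    def hkl(self) -> np.ndarray:
        return np.array([self.h, self.k, self.l])

    def invresolsq(self, cell: Cell) -> float:
        """``1/d^2`` in inverse square angstroms."""
        return float(cell.invresolsq(self.hkl))

    def d_spacing(self, cell: Cell) -> float:
        s2 = self.invresolsq(cell)
        if s2 <= 0:
            raise InvalidArgument("d-spacing undefined for (0,0,0)")
        return 1.0 / math.sqrt(s2)

    def __iter__(self):
        return iter((self.h, self.k, self.l))

    def __eq__(self, other):
        return tuple(self) == tuple(other)

    def __hash__(self):
        return hash((self.h, self.k, self.l))

    def __repr__(self):
        return f"HKL({self.h}, {self.k}, {self.l})"


def _hkl_array(hkls) -> np.ndarray:
    arr = np.array([tuple(h) for h in hkls], dtype=int).reshape(-1, 3)
    return arr


def _in_hemisphere(hkl: np.ndarray) -> np.ndarray:
    """Friedel-unique hemisphere: h>0, or h=0 & k>0, or h=k=0 & l>0."""
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    return (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))


def generate_hkl_list(cell: Cell, spacegroup: Spacegroup, d_min: float) -> list[HKL]:
    """All symmetry- and Friedel-unique reflections with ``d >= d_min``.

    Excludes (0,0,0) and the systematic absences of the group; the
    result is deterministic, sorted by (h, k, l).  The canonical orbit
    representative is the lexicographically greatest index among all
    point-group images and their Friedel mates.
    """
    if d_min <= 0:
        raise InvalidArgument(f"d_min must be positive, got {d_min}")
    hmax = [int(math.ceil(length / d_min)) + 1 for length in (cell.a, cell.b, cell.c)]
    rng = [np.arange(-m, m + 1) for m in hmax]
    hh, kk, ll = np.meshgrid(*rng, indexing="ij")
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    s2 = cell.invresolsq(hkl)
    keep = (s2 > 0) & (s2 <= 1.0 / d_min**2 + 1e-12)
    hkl = hkl[keep]

    rots = [s.rot for s in spacegroup]
    trns = [s.trn for s in spacegroup]
    # orbit images under the point group (reciprocal action h' = h R) + Friedel
    images = np.stack([hkl @ r for r in rots] + [-(hkl @ r) for r in rots])
    canonical = images[
        np.lexsort([images[:, :, 2], images[:, :, 1], images[:, :, 0]], axis=0)[-1],
        np.arange(len(hkl))]
    is_canonical = np.all(hkl == canonical, axis=1)
    hkl = hkl[is_canonical]

    # systematic absences: h R = h with non-integral h.t for some operator
    absent = np.zeros(len(hkl), dtype=bool)
    for r, t in zip(rots, trns):
        fixed = np.all(hkl @ r == hkl, axis=1)
        phase = hkl @ t
        absent |= fixed & (np.abs(phase - np.round(phase)) > 1e-9)
    hkl = hkl[~absent]

    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return [HKL(*row) for row in hkl[order]]


class HKL_data_F_Phi:
    """Symmetry-unique reflections with amplitude/phase payload.

    ``f`` is in arbitrary scattering units, ``phi`` in degrees.  A NaN
    amplitude marks a missing observation; transforms skip such
    records.
    """

    def __init__(self, cell: Cell, spacegroup: Spacegroup, d_min: float,
                 hkls=None, f=None, phi=None):
        self.cell = cell
        self.spacegroup = spacegroup
        self.d_min = float(d_min)
        if hkls is None:
            hkls = generate_hkl_list(cell, spacegroup, d_min)
        self._hkl = _hkl_array(hkls)
        n = len(self._hkl)
        self._f = np.full(n, np.nan) if f is None else self._col(f, n, "f")
        self._phi = np.zeros(n) if phi is None else self._col(phi, n, "phi")

    @staticmethod
    def _col(values, n, name):
        arr = np.array(values, dtype=float).reshape(-1)
        if arr.shape != (n,):
            raise LengthError(f"{name} must have length {n}, got {arr.shape}")
        return arr

    def __len__(self):
        return len(self._hkl)

    @property
    def hkl(self) -> np.ndarray:
        """(n, 3) integer Miller indices (a copy)."""
        return self._hkl.copy()

    @property
    def f(self) -> np.ndarray:
        return self._f.copy()

    @f.setter
    def f(self, values):
        self._f = self._col(values, len(self), "f")

    @property
    def phi(self) -> np.ndarray:
        """Phases in degrees."""
        return self._phi.copy()

    @phi.setter
    def phi(self, values):
        self._phi = self._col(values, len(self), "phi")

    def invresolsq(self) -> np.ndarray:
        return self.cell.invresolsq(self._hkl)

    def export_numpy(self) -> np.ndarray:
        """Detached (n, 2) array: column 0 = F, column 1 = phi (degrees)."""
        return np.column_stack([self._f, self._phi])

    def import_numpy(self, array) -> None:
        """Replace (F, phi) from an (n, 2) array."""
        arr = np.asarray(array, dtype=float)
        if arr.shape != (len(self), 2):
            raise LengthError(
                f"array must have shape ({len(self)}, 2), got {arr.shape}")
        self._f = arr[:, 0].copy()
        self._phi = arr[:, 1].copy()

    def copy(self) -> "HKL_data_F_Phi":
        return HKL_data_F_Phi(self.cell, self.spacegroup, self.d_min,
                              self._hkl, self._f, self._phi)

    def __repr__(self):
        return (f"HKL_data_F_Phi({len(self)} reflections, "
                f"d_min={self.d_min:g} A, {self.spacegroup.name})")


def export_array(hkl_data: HKL_data_F_Phi) -> np.ndarray:
    """Detached (n, 2) array of (F, phi degrees)."""
    return hkl_data.export_numpy()


def import_array(hkl_data: HKL_data_F_Phi, array) -> None:
    """Load (F, phi degrees) back from an (n, 2) array."""
    hkl_data.import_numpy(array)


def patterson_coeffs(hkl_data: HKL_data_F_Phi) -> HKL_data_F_Phi:
    """Coefficients of the Patterson function: |F|^2 amplitudes, zero phases.

    The synthesized map is the autocorrelation of the density and is
    centrosymmetric by construction.
    """
    data = hkl_data.export_numpy()
    data[:, 0] = data[:, 0] ** 2
    data[:, 1] = 0.0
    out = hkl_data.copy()
    out.import_numpy(data)
    return out


def calc_sf_direct(atom_list: Atom_list, hkls, cell: Cell,
                   spacegroup: Spacegroup | None = None,
                   d_min: float | None = None) -> HKL_data_F_Phi:
    """Structure factors by direct summation over atoms and symmetry images.

    ``F(h) = sum_S sum_j f_j occ_j exp(-B_j |s|^2 / 4)
    exp(2 pi i h . (R_S x_j + t_S))`` with constant per-element
    scattering weights f_j (electron counts) and ``B = 8 pi^2 u_iso``.
    """
    if spacegroup is None:
        spacegroup = Spacegroup.from_name("P1")
    hkl = _hkl_array(hkls)
    frac = cell.fractionalize(atom_list.coords)  # (n_atoms, 3)
    weights = atom_list.electrons() * atom_list.occupancies
    b = u_to_b(atom_list.u_isos)
    s2 = cell.invresolsq(hkl)  # (n_refl,)
    damp = np.exp(-np.outer(s2, b) / 4.0)  # (n_refl, n_atoms)
    fcal = np.zeros(len(hkl), dtype=complex)
    for symop in spacegroup:
        x = symop.apply(frac)  # (n_atoms, 3)
        phase = 2.0 * np.pi * (hkl @ x.T)  # (n_refl, n_atoms)
        fcal += (weights[None, :] * damp * np.exp(1j * phase)).sum(axis=1)
    if d_min is None:
        s2pos = s2[s2 > 0]
        d_min = 1.0 / math.sqrt(s2pos.max()) if s2pos.size else 1.0
    return HKL_data_F_Phi(cell, spacegroup, d_min, hkl,
                          np.abs(fcal), np.degrees(np.angle(fcal)))


def _expand_to_sphere(hkl_data: HKL_data_F_Phi) -> dict[tuple, complex]:
    """Expand unique reflections to the full sphere by symmetry + Friedel.

    Returns {(h,k,l): complex F}; NaN amplitudes are skipped.  Under
    the convention above, ``F(h R) = F(h) exp(-2 pi i h . t)``.
    """
    coeffs: dict[tuple, complex] = {}
    hkl = hkl_data.hkl
    f = hkl_data.f
    phi = np.radians(hkl_data.phi)
    good = ~np.isnan(f)
    for h, amp, ph in zip(hkl[good], f[good], phi[good]):
        fc = amp * np.exp(1j * ph)
        for symop in hkl_data.spacegroup:
            h_img = h @ symop.rot
            fc_img = fc * np.exp(-2j * np.pi * (h @ symop.trn))
            coeffs.setdefault(tuple(h_img), fc_img)
            coeffs.setdefault(tuple(-h_img), np.conj(fc_img))
    return coeffs


def fft_synthesis(hkl_data: HKL_data_F_Phi, grid: Grid_sampling) -> Xmap:
    """Synthesize a density map from (F, phi) coefficients by inverse FFT.

    Unique reflections are expanded to the full sphere by symmetry and
    Friedel pairing, placed on the reciprocal grid and transformed with
    ``rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)``.
    """
    coeffs = _expand_to_sphere(hkl_data)
    n = grid.nuvw
    half = (n - 1) // 2
    for h in coeffs:
        if np.any(np.abs(h) > half):
            raise InvalidArgument(
                f"grid {tuple(grid)} too coarse for reflection {h} (needs > 2|h| points)")
    recip = np.zeros(tuple(n), dtype=complex)
    for h, fc in coeffs.items():
        recip[tuple(np.mod(h, n))] = fc
    rho = np.fft.fftn(recip).real / hkl_data.cell.volume
    return Xmap(hkl_data.cell, hkl_data.spacegroup, grid, rho)


def fft_analysis(xmap: Xmap, d_min: float) -> HKL_data_F_Phi:
    """Structure factors of a map by forward FFT (adjoint of synthesis).

    Returns the symmetry-unique (F, phi) set to ``d_min``; with an
    adequately fine grid, ``fft_analysis(fft_synthesis(x)) == x`` to
    FFT precision.
    """
    hkls = generate_hkl_list(xmap.cell, xmap.spacegroup, d_min)
    hkl = _hkl_array(hkls)
    n = xmap.grid.nuvw
    half = (n - 1) // 2
    if len(hkl) and np.any(np.abs(hkl) > half[None, :]):
        raise InvalidArgument(
            f"grid {tuple(xmap.grid)} too coarse for d_min={d_min} A")
    recip = np.fft.ifftn(xmap.values) * xmap.cell.volume
    fc = recip[tuple(np.mod(hkl, n).T)]
    return HKL_data_F_Phi(xmap.cell, xmap.spacegroup, d_min, hkl,
                          np.abs(fc), np.degrees(np.angle(fc)))


def scale_coeffs(hkl_data: HKL_data_F_Phi, b_factor: float,
                 d_min: float | None = None) -> HKL_data_F_Phi:
    """Apply a reciprocal-space B-factor: ``F <- F exp(-B |s|^2 / 4)``.

    A negative ``b_factor`` sharpens, positive blurs.  With ``d_min``
    given, reflections beyond the limit (d < d_min) are removed.
    """
    hkl = hkl_data.hkl
    f = hkl_data.f * np.exp(-b_factor * hkl_data.invresolsq() / 4.0)
    phi = hkl_data.phi
    new_d_min = hkl_data.d_min
    if d_min is not None:
        keep = hkl_data.invresolsq() <= 1.0 / d_min**2 + 1e-12
        hkl, f, phi = hkl[keep], f[keep], phi[keep]
        new_d_min = max(d_min, hkl_data.d_min)
    return HKL_data_F_Phi(hkl_data.cell, hkl_data.spacegroup, new_d_min, hkl, f, phi)


# ---------------------------------------------------------------------------
# Text / mmCIF / MTZ export

def write_text(hkl_data: HKL_data_F_Phi, path) -> None:
    """Tab-separated reflection list: columns h, k, l, F, phi (degrees)."""
    try:
        with open(path, "w") as fh:
            fh.write("h\tk\tl\tF\tphi\n")
            for (h, k, l), f, phi in zip(hkl_data.hkl, hkl_data.f, hkl_data.phi):
                fh.write(f"{h}\t{k}\t{l}\t{f:.6g}\t{phi:.6g}\n")
    except OSError as exc:
        raise MessageFatal(f"cannot write reflection file {path}: {exc}") from exc


def read_text(path, cell: Cell, spacegroup: Spacegroup, d_min: float) -> HKL_data_F_Phi:
    """Read a tab-separated reflection list written by :func:`write_text`."""
    hkls, fs, phis = [], [], []
    try:
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("h"):
                raise InvalidArgument(f"{path}: missing 'h k l F phi' header line")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise InvalidArgument(f"{path} line {lineno}: expected 5 columns")
                hkls.append((int(parts[0]), int(parts[1]), int(parts[2])))
                fs.append(float(parts[3]))
                phis.append(float(parts[4]))
    except OSError as exc:
        raise MessageFatal(f"cannot read reflection file {path}: {exc}") from exc
    return HKL_data_F_Phi(cell, spacegroup, d_min, hkls, fs, phis)


def write_mmcif_sf(hkl_data: HKL_data_F_Phi, path, block_name: str = "xtalkit") -> None:
    """Write mmCIF structure-factor categories (_cell, _symmetry, _refln)."""
    c = hkl_data.cell
    lines = [
        f"data_{block_name}",
        "#",
        f"_cell.length_a     {c.a:.4f}",
        f"_cell.length_b     {c.b:.4f}",
        f"_cell.length_c     {c.c:.4f}",
        f"_cell.angle_alpha  {c.alpha:.4f}",
        f"_cell.angle_beta   {c.beta:.4f}",
        f"_cell.angle_gamma  {c.gamma:.4f}",
        f"_symmetry.space_group_name_H-M  '{hkl_data.spacegroup.name}'",
        "#",
        "loop_",
        "_refln.index_h",
        "_refln.index_k",
        "_refln.index_l",
        "_refln.F_calc",
        "_refln.phase_calc",
    ]
    for (h, k, l), f, phi in zip(hkl_data.hkl, hkl_data.f, hkl_data.phi):
        f_str = "?" if np.isnan(f) else f"{f:.6g}"
        lines.append(f"{h} {k} {l} {f_str} {phi:.6g}")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise MessageFatal(f"cannot write mmCIF file {path}: {exc}") from exc


def write_mtz(hkl_data: HKL_data_F_Phi, path,
              f_label: str = "FWT", phi_label: str = "PHWT") -> None:
    """Write an MTZ file via the delegated I/O library (gemmi)."""
    gemmi = _import_gemmi()
    mtz = gemmi.Mtz(with_base=True)
    c = hkl_data.cell
    mtz.set_cell_for_all(gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
    mtz.spacegroup = gemmi.SpaceGroup(_gemmi_sg_name(hkl_data.spacegroup.name))
    mtz.add_dataset("xtalkit")
    mtz.add_column(f_label, "F")
    mtz.add_column(phi_label, "P")
    data = np.column_stack([hkl_data.hkl.astype(float), hkl_data.f, hkl_data.phi])
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def read_mtz(path, f_label: str = "FWT", phi_label: str = "PHWT") -> HKL_data_F_Phi:
    """Read (F, phi) columns from an MTZ file via gemmi."""
    gemmi = _import_gemmi()
    mtz = gemmi.Mtz()
    try:
        mtz = gemmi.read_mtz_file(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise MessageFatal(f"cannot read MTZ file {path}: {exc}") from exc
    uc = mtz.cell
    cell = Cell(uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma)
    sg_name = mtz.spacegroup.short_name().replace(" ", "") if mtz.spacegroup else "P1"
    try:
        spacegroup = Spacegroup.from_name(sg_name)
    except ValueError:
        spacegroup = Spacegroup.from_name("P1")
    hkl = np.array([mtz.column_with_label(lbl).array for lbl in ("H", "K", "L")]).T
    f = mtz.column_with_label(f_label).array
    phi = mtz.column_with_label(phi_label).array
    d_min = float(mtz.resolution_high()) if len(hkl) else 1.0
    return HKL_data_F_Phi(cell, spacegroup, d_min, hkl.astype(int), f, phi)


def _import_gemmi():
    try:
        import gemmi
    except ImportError as exc:  # pragma: no cover - gemmi is an optional extra
        raise MessageFatal("MTZ I/O requires the optional 'gemmi' package") from exc
    return gemmi


def _gemmi_sg_name(compact: str) -> str:
    return {
        "P1": "P 1", "P-1": "P -1", "P21": "P 1 21 1", "C2": "C 1 2 1",
        "P212121": "P 21 21 21", "P43212": "P 43 21 2", "P6322": "P 63 2 2",
    }.get(compact, compact)
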