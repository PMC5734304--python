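"""Synthetic test structures and maps.

Everything the test-suite and the reproduction script consume is
generated here at run time: small protein-fragment-like models placed
inside a unit cell, Gaussian-atom density rendered from them in real
space, and random symmetrised maps.  The real-space Gaussian render is
deliberately *independent* of the reciprocal-space structure-factor
code, so the two routes can cross-check each other.

What these fixtures emulate: atoms as isotropic Gaussians of width set
by their displacement parameter, crystallographic symmetry and lattice
periodicity.  What they do not emulate: solvent, disorder, form-factor
fall-off beyond the constant-electron-count model, or experimental
noise — conclusions from tests on them are about the code's algebra,
not about fit to real data.
"""

from __future__ import annotations

import math

import numpy as np

from .cell_symmetry import Cell, Grid_sampling, Spacegroup
from .crystal_maps import Xmap
from .errors import InvalidArgument
from .model_hierarchy import (Atom_list, MAtom, MiniMol, MModel, MMonomer,
                              MPolymer, u_to_b)

__all__ = [
    "make_toy_model",
    "toy_minimol",
    "render_gaussian_map",
    "random_symmetric_xmap",
]

_DEFAULT_ELEMENTS = ("C", "N", "O", "C", "S")


def make_toy_model(cell: Cell, n_atoms: int = 5, rng=None,
                   u_iso: float = 0.3, span: tuple[float, float] = (0.15, 0.45),
                   elements=None) -> Atom_list:
    """A small random model placed well inside the unit cell.

    Atoms are drawn uniformly in the fractional sub-box ``span`` (so a
    compact blob, not scattered through the whole cell), with unit
    occupancy and a common ``u_iso`` of 0.3 A^2 (B ~ 24 A^2, a typical
    mid-resolution protein displacement).
    """
    rng = np.random.default_rng(rng)
    if n_atoms < 1:
        raise InvalidArgument("n_atoms must be >= 1")
    frac = rng.uniform(span[0], span[1], size=(n_atoms, 3))
    elements = list(elements) if elements else [
        _DEFAULT_ELEMENTS[i % len(_DEFAULT_ELEMENTS)] for i in range(n_atoms)]
    return Atom_list(
        elements=elements[:n_atoms],
        coords=cell.orthogonalize(frac),
        occupancies=np.ones(n_atoms),
        u_isos=np.full(n_atoms, u_iso),
    )


def toy_minimol(cell: Cell, atom_list: Atom_list,
                spacegroup_name: str = "P1") -> MiniMol:
    """Wrap a flat atom list as a one-chain, one-residue-per-3-atoms model."""
    names = ("N", "CA", "C", "O", "CB")
    model = MModel()
    chain = MPolymer("A")
    model.append(chain)
    for i in range(0, len(atom_list), 3):
        mono = MMonomer("ALA", i // 3 + 1)
        for j in range(i, min(i + 3, len(atom_list))):
            mono.append(MAtom(names[(j - i) % len(names)], atom_list.elements[j],
                              atom_list.coords[j],
                              occupancy=float(atom_list.occupancies[j]),
                              u_iso=float(atom_list.u_isos[j])))
        chain.append(mono)
    return MiniMol(model, cell=cell, spacegroup_name=spacegroup_name)


def render_gaussian_map(atom_list: Atom_list, cell: Cell, spacegroup: Spacegroup,
                        grid: Grid_sampling, tail: float = 1e-7) -> Xmap:
    """Render atoms as real-space isotropic Gaussians on a cell grid.

    Each atom of scattering weight f (its electron count, times
    occupancy) and displacement B = 8 pi^2 u_iso contributes

    .. math:: \\rho(r) = f\\,(4\\pi/B)^{3/2} \\exp(-4\\pi^2 r^2 / B),

    the exact Fourier mate of the reciprocal damping ``exp(-B|s|^2/4)``
    used by the structure-factor code, summed over all symmetry images
    and lattice translations until the tail falls below ``tail`` of
    the peak.  Atoms need ``u_iso > 0``.
    """
    if np.any(atom_list.u_isos <= 0):
        raise InvalidArgument("Gaussian rendering requires u_iso > 0 for every atom")
    values = np.zeros(tuple(grid.nuvw))
    n = grid.nuvw
    frac = cell.fractionalize(atom_list.coords)
    weights = atom_list.electrons() * atom_list.occupancies
    bs = np.asarray(u_to_b(atom_list.u_isos))
    # frac-units reach per axis covering |dr| <= r_cut
    row_norms = np.linalg.norm(cell.frac_matrix, axis=1)
    for symop in spacegroup:
        imgs = symop.apply(frac)
        for x0, w, b in zip(imgs, weights, bs):
            r_cut = math.sqrt(b * math.log(1.0 / tail)) / (2.0 * math.pi)
            du = row_norms * r_cut * n  # grid-unit reach per axis
            gm = x0 * n
            ranges = [np.arange(int(math.floor(gm[i] - du[i])),
                                int(math.ceil(gm[i] + du[i])) + 1) for i in range(3)]
            gu, gv, gw = np.meshgrid(*ranges, indexing="ij")
            pts = np.stack([gu, gv, gw], axis=-1).reshape(-1, 3)
            d_orth = cell.orthogonalize(pts / n - x0)
            r2 = np.sum(d_orth * d_orth, axis=1)
            peak = w * (4.0 * math.pi / b) ** 1.5
            contrib = peak * np.exp(-4.0 * math.pi**2 * r2 / b)
            idx = np.mod(pts, n)
            np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), contrib)
    return Xmap(cell, spacegroup, grid, values)


def random_symmetric_xmap(cell: Cell, spacegroup: Spacegroup, grid: Grid_sampling,
                          rng=None) -> Xmap:
    """A random map made exactly symmetric by orbit averaging."""
    rng = np.random.default_rng(rng)
    xmap = Xmap(cell, spacegroup, grid, rng.standard_normal(tuple(grid.nuvw)))
    xmap.symmetrize("mean")
    return xmap
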