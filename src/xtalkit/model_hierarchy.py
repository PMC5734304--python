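"""Atomic models: the iterable model/chain/residue/atom hierarchy,
bulk array-backed atom lists, and fixed-column PDB I/O.

Two complementary views of the same atoms are provided.  The
:class:`MiniMol` hierarchy (model > polymer > monomer > atom) is
convenient for per-residue logic and mirrors the file structure; every
level is iterable and index-addressable in file order.  The
:class:`Atom_list` is a flat, array-backed view for bulk numerical
work: parallel numpy arrays of coordinates, occupancies and
displacement parameters, with copy-on-get / validate-on-set semantics.

Displacement parameters are isotropic ``u_iso`` in square angstroms;
the crystallographic B-factor in PDB files is ``B = 8 pi^2 u_iso``.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

from .cell_symmetry import Cell
from .errors import InvalidArgument, LengthError, MessageFatal

__all__ = [
    "MAtom",
    "MMonomer",
    "MPolymer",
    "MModel",
    "MiniMol",
    "Atom_list",
    "read_pdb",
    "write_pdb",
    "make_atom_list",
    "b_to_u",
    "u_to_b",
    "ELEMENT_ELECTRONS",
]

EIGHT_PI_SQ = 8.0 * math.pi * math.pi

# The 118 IUPAC element symbols, in atomic-number order.
_ELEMENT_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
    "Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In "
    "Sn Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf "
    "Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am "
    "Cm Bk Cf Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split()

#: element symbol -> electron count (atomic number)
ELEMENT_ELECTRONS = {sym: z + 1 for z, sym in enumerate(_ELEMENT_SYMBOLS)}
_NORMALIZED = {sym.upper(): sym for sym in _ELEMENT_SYMBOLS}


def normalize_element(symbol: str) -> str | None:
    """Case-normalised IUPAC symbol, or None if unknown."""
    return _NORMALIZED.get(symbol.strip().upper())


def u_to_b(u_iso):
    """Isotropic displacement (A^2) -> B-factor: B = 8 pi^2 u."""
    return EIGHT_PI_SQ * np.asarray(u_iso, dtype=float)


def b_to_u(b_factor):
    """B-factor -> isotropic displacement (A^2): u = B / (8 pi^2)."""
    return np.asarray(b_factor, dtype=float) / EIGHT_PI_SQ


class MAtom:
    """One atom: name, element, orthogonal coordinate (A), occupancy,
    isotropic displacement u_iso (A^2) and optional anisotropic U (6-vector)."""

    __slots__ = ("id", "element", "coord_orth", "occupancy", "u_iso", "u_aniso")

    def __init__(self, id: str, element: str, coord_orth, occupancy: float = 1.0,
                 u_iso: float = 0.0, u_aniso=None):
        if not 0.0 <= occupancy <= 1.0:
            raise InvalidArgument(f"occupancy {occupancy} outside [0, 1]")
        if u_iso < 0.0:
            raise InvalidArgument(f"u_iso must be non-negative, got {u_iso}")
        self.id = id
        self.element = element
        self.coord_orth = np.asarray(coord_orth, dtype=float).reshape(3)
        self.occupancy = float(occupancy)
        self.u_iso = float(u_iso)
        self.u_aniso = None if u_aniso is None else np.asarray(u_aniso, dtype=float).reshape(6)

    def format(self) -> str:
        x, y, z = self.coord_orth
        return (f"{self.element:>2s} {x:8.3f} {y:8.3f} {z:8.3f} "
                f"{self.occupancy:5.2f} {self.u_iso:7.4f}")

    def __str__(self):
        return f"{self.id} {self.format()}"

    def __repr__(self):
        return f"MAtom({self.id!r}, {self.element!r})"


class MMonomer:
    """A residue: type, sequence number (+ optional insertion code), atoms."""

    def __init__(self, type: str, seqnum: int, icode: str = "", atoms=None):
        self.type = type
        self.seqnum = int(seqnum)
        self.icode = icode.strip()
        self._atoms: list[MAtom] = list(atoms) if atoms else []

    @property
    def id(self) -> str:
        return f"{self.seqnum}{self.icode}"

    def append(self, atom: MAtom):
        self._atoms.append(atom)

    def __len__(self):
        return len(self._atoms)

    def __iter__(self) -> Iterator[MAtom]:
        return iter(self._atoms)

    def __getitem__(self, i) -> MAtom:
        return self._atoms[i]

    def __repr__(self):
        return f"MMonomer({self.type!r}, {self.id!r}, {len(self)} atoms)"


class MPolymer:
    """A chain: id plus its residues in file order."""

    def __init__(self, id: str, monomers=None):
        self.id = id
        self._monomers: list[MMonomer] = list(monomers) if monomers else []

    def append(self, monomer: MMonomer):
        self._monomers.append(monomer)

    def __len__(self):
        return len(self._monomers)

    def __iter__(self) -> Iterator[MMonomer]:
        return iter(self._monomers)

    def __getitem__(self, i) -> MMonomer:
        return self._monomers[i]

    def __repr__(self):
        return f"MPolymer({self.id!r}, {len(self)} monomers)"


class MModel:
    """The top hierarchy level: a list of polymers (chains)."""

    def __init__(self, polymers=None):
        self._polymers: list[MPolymer] = list(polymers) if polymers else []

    def append(self, polymer: MPolymer):
        self._polymers.append(polymer)

    def __len__(self):
        return len(self._polymers)

    def __iter__(self) -> Iterator[MPolymer]:
        return iter(self._polymers)

    def __getitem__(self, i) -> MPolymer:
        return self._polymers[i]

    def atoms(self) -> Iterator[MAtom]:
        for polymer in self:
            for monomer in polymer:
                yield from monomer

    def __repr__(self):
        return f"MModel({len(self)} polymers)"


class MiniMol:
    """An atomic model plus the crystal frame it sits in (when known)."""

    def __init__(self, model: MModel | None = None,
                 cell: Cell | None = None, spacegroup_name: str | None = None):
        self._model = model if model is not None else MModel()
        self.cell = cell
        self.spacegroup_name = spacegroup_name

    def model(self) -> MModel:
        return self._model

    def __len__(self):
        return len(self._model)

    def __iter__(self):
        return iter(self._model)

    def __getitem__(self, i):
        return self._model[i]

    def atom_list(self) -> "Atom_list":
        """Flatten the hierarchy into a bulk :class:`Atom_list` (file order)."""
        atoms = list(self._model.atoms())
        if not atoms:
            raise InvalidArgument("model contains no atoms")
        u_anisos = np.array([
            a.u_aniso if a.u_aniso is not None
            else [a.u_iso, a.u_iso, a.u_iso, 0.0, 0.0, 0.0]
            for a in atoms
        ])
        return Atom_list(
            elements=[a.element for a in atoms],
            coords=np.array([a.coord_orth for a in atoms]),
            occupancies=np.array([a.occupancy for a in atoms]),
            u_isos=np.array([a.u_iso for a in atoms]),
            u_anisos=u_anisos,
            allow_unknown_atoms=True,
        )


class Atom_list:
    """Bulk array-backed atoms: parallel arrays sharing one length n.

    Getters return detached copies; setters replace a property in full
    and validate the shape.  A ``u_anisos`` row equal to
    ``(u, u, u, 0, 0, 0)`` marks a purely isotropic atom.
    """

    def __init__(self, elements: Sequence[str], coords, occupancies, u_isos,
                 u_anisos=None, allow_unknown_atoms: bool = False):
        elements = list(elements)
        n = len(elements)
        if n == 0:
            raise InvalidArgument("atom list must not be empty")
        if not allow_unknown_atoms:
            for sym in elements:
                if normalize_element(sym) is None:
                    raise InvalidArgument(f"unknown chemical element {sym!r} "
                                          "(allow_unknown_atoms is False)")
        self._elements = [str(e) for e in elements]
        self._coords = self._check(coords, (n, 3), "coords")
        self._occupancies = self._check(occupancies, (n,), "occupancies")
        self._u_isos = self._check(u_isos, (n,), "u_isos")
        if u_anisos is None:
            u_anisos = np.zeros((n, 6))
            u_anisos[:, :3] = self._u_isos[:, None]
        self._u_anisos = self._check(u_anisos, (n, 6), "u_anisos")

    @staticmethod
    def _check(values, shape, name) -> np.ndarray:
        arr = np.array(values, dtype=float)
        if arr.shape != shape:
            raise LengthError(f"{name} must have shape {shape}, got {arr.shape}")
        return arr

    def __len__(self):
        return len(self._elements)

    @property
    def elements(self) -> list[str]:
        return list(self._elements)

    @elements.setter
    def elements(self, values):
        values = [str(v) for v in values]
        if len(values) != len(self):
            raise LengthError(f"elements must have length {len(self)}, got {len(values)}")
        self._elements = values

    @property
    def coords(self) -> np.ndarray:
        """n x 3 orthogonal coordinates in angstroms (a copy)."""
        return self._coords.copy()

    @coords.setter
    def coords(self, values):
        self._coords = self._check(values, (len(self), 3), "coords")

    @property
    def occupancies(self) -> np.ndarray:
        return self._occupancies.copy()

    @occupancies.setter
    def occupancies(self, values):
        self._occupancies = self._check(values, (len(self),), "occupancies")

    @property
    def u_isos(self) -> np.ndarray:
        return self._u_isos.copy()

    @u_isos.setter
    def u_isos(self, values):
        self._u_isos = self._check(values, (len(self),), "u_isos")

    @property
    def u_anisos(self) -> np.ndarray:
        return self._u_anisos.copy()

    @u_anisos.setter
    def u_anisos(self, values):
        self._u_anisos = self._check(values, (len(self), 6), "u_anisos")

    def electrons(self) -> np.ndarray:
        """Per-atom electron counts (used as constant scattering weights)."""
        out = np.empty(len(self))
        for i, sym in enumerate(self._elements):
            norm = normalize_element(sym)
            if norm is None:
                raise InvalidArgument(f"unknown chemical element {sym!r}")
            out[i] = ELEMENT_ELECTRONS[norm]
        return out

    def __repr__(self):
        return f"Atom_list({len(self)} atoms)"


def make_atom_list(elements, coords, occupancies, u_isos, u_anisos=None,
                   allow_unknown_atoms: bool = False) -> Atom_list:
    """Build an :class:`Atom_list` from parallel arrays."""
    return Atom_list(elements, coords, occupancies, u_isos, u_anisos,
                     allow_unknown_atoms)


# ---------------------------------------------------------------------------
# PDB I/O — minimal fixed-column dialect: ATOM/HETATM/TER/CRYST1/END.

# compacted full Hermann-Mauguin symbol -> short symbol of the built-in table
_SG_FULL_TO_SHORT = {
    "P1": "P1", "P-1": "P-1", "P1211": "P21", "C121": "C2",
    "P212121": "P212121", "P43212": "P43212", "P6322": "P6322",
}


def _guess_element(name: str) -> str:
    name = name.strip()
    if len(name) >= 2 and normalize_element(name[:2]):
        # two-letter symbols only when the name starts in column 13
        two = normalize_element(name[:2])
        if two and not name[0].isdigit():
            return two
    for ch in name:
        if ch.isalpha():
            one = normalize_element(ch)
            if one:
                return one
    return name[:2]


def read_pdb(path) -> MiniMol:
    """Read a PDB file into a :class:`MiniMol`.

    Parses ATOM/HETATM records (first alternate conformer only) and the
    CRYST1 record into a :class:`Cell` plus space-group name.  Raises a
    runtime-category error if the file cannot be opened and a
    value-category error, with the line number, for a malformed
    mandatory column.
    """
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise MessageFatal(f"cannot read PDB file {path}: {exc}") from exc

    mol = MiniMol()
    model = mol.model()
    polymer = None
    monomer = None
    first_altloc: dict[tuple, str] = {}

    for lineno, line in enumerate(lines, start=1):
        record = line[:6].strip()
        if record == "CRYST1":
            try:
                mol.cell = Cell(float(line[6:15]), float(line[15:24]), float(line[24:33]),
                                float(line[33:40]), float(line[40:47]), float(line[47:54]))
            except (ValueError, InvalidArgument) as exc:
                raise InvalidArgument(f"line {lineno}: bad CRYST1 record: {exc}") from exc
            sg_raw = line[55:66].strip().replace(" ", "")
            mol.spacegroup_name = _SG_FULL_TO_SHORT.get(sg_raw, sg_raw) or None
        elif record in ("ATOM", "HETATM"):
            line = line.rstrip("\n").ljust(80)
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                restype = line[17:20].strip()
                chain = line[21].strip()
                seqnum = int(line[22:26])
                icode = line[26].strip()
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
                element = line[76:78].strip() or _guess_element(name)
            except ValueError as exc:
                raise InvalidArgument(f"line {lineno}: malformed atom record: {exc}") from exc
            reskey = (chain, seqnum, icode)
            if altloc:
                first = first_altloc.setdefault(reskey + (name,), altloc)
                if altloc != first:
                    continue  # keep the first conformer only
            if polymer is None or polymer.id != chain:
                polymer = MPolymer(chain)
                model.append(polymer)
                monomer = None
            if monomer is None or (monomer.seqnum, monomer.icode) != (seqnum, icode):
                monomer = MMonomer(restype, seqnum, icode)
                polymer.append(monomer)
            element_norm = normalize_element(element) or element
            monomer.append(MAtom(name, element_norm, xyz,
                                 occupancy=min(max(occ, 0.0), 1.0),
                                 u_iso=max(float(b_to_u(bfac)), 0.0)))
        elif record == "TER":
            polymer = None
            monomer = None
    return mol


def read_mmcif(path) -> MiniMol:
    """Read an mmCIF model via the delegated I/O library (gemmi),
    normalised into the same :class:`MiniMol` hierarchy as PDB input."""
    try:
        import gemmi
    except ImportError as exc:  # pragma: no cover - optional extra
        raise MessageFatal("mmCIF reading requires the optional 'gemmi' package") from exc
    try:
        st = gemmi.read_structure(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise MessageFatal(f"cannot read mmCIF file {path}: {exc}") from exc
    mol = MiniMol()
    if st.cell and st.cell.a > 0:
        mol.cell = Cell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
        sg_raw = (st.spacegroup_hm or "").replace(" ", "")
        mol.spacegroup_name = _SG_FULL_TO_SHORT.get(sg_raw, sg_raw) or None
    if not len(st):
        return mol
    for chain in st[0]:
        polymer = MPolymer(chain.name)
        mol.model().append(polymer)
        for residue in chain:
            monomer = MMonomer(residue.name, residue.seqid.num,
                               (residue.seqid.icode or "").strip())
            polymer.append(monomer)
            for atom in residue:
                monomer.append(MAtom(
                    atom.name, atom.element.name,
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    u_iso=max(float(b_to_u(atom.b_iso)), 0.0)))
    return mol


_COORD_LIMIT = 9999.999  # largest value the %8.3f PDB field can hold


def write_pdb(minimol: MiniMol, path) -> None:
    """Write a :class:`MiniMol` as fixed-column PDB (v3.3 subset).

    Emits CRYST1 (when the model has a cell), ATOM records with
    occupancy and B-factor as %6.2f (B = 8 pi^2 u_iso), TER per chain
    and END.
    """
    model = minimol.model()
    if len(model) == 0:
        raise InvalidArgument("refusing to write an empty model")
    out = []
    if minimol.cell is not None:
        c = minimol.cell
        sg = minimol.spacegroup_name or "P1"
        sg_field = _expand_sg_symbol(sg)
        out.append(f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
                   f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg_field:<11s}{1:4d}")
    serial = 0
    for polymer in model:
        for monomer in polymer:
            for atom in monomer:
                serial += 1
                x, y, z = atom.coord_orth
                if max(abs(x), abs(y), abs(z)) > _COORD_LIMIT:
                    raise InvalidArgument(
                        f"coordinate {atom.coord_orth} overflows the fixed-width PDB field")
                name = atom.id if len(atom.id) >= 4 else f" {atom.id:<3s}"
                out.append(
                    f"ATOM  {serial:5d} {name:<4.4s} {monomer.type:<3.3s} "
                    f"{polymer.id[:1] or 'A'}{monomer.seqnum:4d}{(monomer.icode or ' '):1.1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{float(u_to_b(atom.u_iso)):6.2f}          {atom.element:>2.2s}  ")
        serial += 1
        out.append(f"TER   {serial:5d}")
    out.append("END")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(out) + "\n")
    except OSError as exc:
        raise MessageFatal(f"cannot write PDB file {path}: {exc}") from exc


def _expand_sg_symbol(compact: str) -> str:
    """``P212121`` -> ``P 21 21 21`` (best-effort spacing for CRYST1)."""
    known = {
        "P1": "P 1", "P-1": "P -1", "P21": "P 1 21 1", "C2": "C 1 2 1",
        "P212121": "P 21 21 21", "P43212": "P 43 21 2", "P6322": "P 63 2 2",
    }
    return known.get(compact, compact)
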