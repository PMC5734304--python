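# Methods and conventions

This note records the models, conventions and numerical choices behind
xtalkit, in the order a reader meets them in the code.

## Coordinate frames and the cell metric

Three frames are used throughout: integer **grid** coordinates
(0-based indices into a map grid), **fractional** coordinates (cell
fractions) and **orthogonal** coordinates (ångströms). The
orthogonalisation matrix follows the PDB convention — **a** along x,
**b** in the x–y plane — so

    O = [[a, b·cosγ, c·cosβ],
         [0, b·sinγ, c·(cosα − cosβ·cosγ)/sinγ],
         [0, 0,      c·v/sinγ]],

with v² = 1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ and
volume V = abc·v. Cells with v² ≤ 0 (inconsistent angle cosines) are
rejected as degenerate. Angles are degrees in every public signature;
radians never appear in a contract. Fractional → grid conversion
rounds to the nearest point with halves away from zero; this rule is
fixed because several tests (and any caller caching grid indices)
need bit-exact behaviour.

## Symmetry operators and space groups

An operator is an integer 3×3 rotation acting on fractional
coordinates plus a translation reduced mod 1 to [0, 1). Exact
comparison uses translations quantised to 24ths — every translation
arising in conventional settings of the supported groups is a
multiple of 1/12, so 1/24 quantisation is exact with headroom.
Triplet strings (`-x,y+1/2,-z`) parse case- and
whitespace-insensitively, with fractions or decimals; the formatter
emits a canonical form that round-trips through the parser.

Groups are generated to closure under composition mod lattice
translations from a small built-in generator table (P1, P-1, P21, C2,
P212121, P43212, P6322 — one group per common protein crystal class
plus a hexagonal case with axis mixing). Closure is bounded at 1000
elements, after which the generators are reported as bad. Operator
order is canonical: identity first, then lexicographic on (flattened
rotation, translation). The test suite verifies every generated group
operator-for-operator against an independent crystallographic tables
implementation. Full 230-group coverage from Hall symbols,
non-standard settings and magnetic groups are out of scope; triplet
generators accommodate any further group a caller needs.

## Grid sampling

`grid_from_resolution` chooses divisions per axis of at least
⌈2·rate·length/d_min⌉ (rate = Shannon oversampling factor, default
1.5), rounded up to 2,3,5-smooth sizes for FFT efficiency. When a
space group is supplied the divisions are additionally forced to be
divisible by the denominators of the group's translations along each
axis (so screw translations land on grid points) and axes mixed by
any rotation share one count (hexagonal a/b).

## Maps

`Xmap` stores one full unit cell of values, indexed [u, v, w]. The
infinite-indexing contract — a lookup at *any* integer coordinate
succeeds and symmetry-equivalent points agree — is implemented by
lattice wrapping over symmetrised full-cell storage, not by
ASU-compressed storage; the compression is an optimisation invisible
to the contract and was skipped for simplicity. Writes go through to
all symmetry images; `symmetrize` makes an arbitrary value array
consistent either by orbit averaging (default) or by propagating the
canonical representative. Grid/space-group compatibility (every
rotation entry R_ij·N_i/N_j and translation t_i·N_i integral) is
validated at construction.

`NXmap` is finite and symmetry-free, placed in space by an affine
transform (origin + per-axis step vectors). Out-of-extent access is
an index-category error rather than a clamp or wrap — with no
periodicity there is no principled fill value, so erroring is the
conservative choice.

Section export (`export_section`) fills the inclusive box
[start, end] on the map's native axes — inclusivity is a deliberate
choice where "between two coordinates" would be ambiguous. `rot='zyx'`
reverses the axis order of the output array, `order` selects C or
Fortran memory layout, and a supplied target buffer is re-filled in
place without reallocation. Cartesian export
(`export_interpolated_box`) uses trilinear interpolation only; it is
exact for fields affine in the fractional coordinates and carries the
usual smoothing bias otherwise. Higher-order (cubic) interpolation is
a known extension, not present in v1, and trilinear resampling is
substantially slower than native-axis section export — use sections
where the crystallographic axes are acceptable.

Map files are CCP4/MRC 2014, mode 2 (float32) only; reading honours
the MAPC/MAPR/MAPS axis permutation, start offsets and both byte
orders, writing always emits x-fastest little-endian with correct
header statistics, NXSTART-style offsets in grid units and the ORIGIN
field mirrored for cryo-EM consumers. A file covering exactly one
unit cell with zero offsets and a crystallographic ISPG returns an
`Xmap`; anything else returns an `NXmap`.

## Atomic models

The `MiniMol` hierarchy (model ⊃ polymer ⊃ monomer ⊃ atom) is
iterable and index-addressable at every level, in file order. The
PDB dialect is deliberately minimal: ATOM/HETATM/TER/CRYST1/END,
first alternate conformer kept, insertion codes appended to the
sequence number, hydrogens never filtered (filtering is a caller
decision). Everything else in a file is pass-through text. B-factors
convert as B = 8π²·u_iso. Element symbols are validated against the
118 IUPAC symbols, case-normalised; `Atom_list` construction rejects
unknown symbols unless `allow_unknown_atoms` is set. Bulk array
access returns detached copies and validates shapes on set; a
`u_anisos` row (u, u, u, 0, 0, 0) marks a purely isotropic atom.
The single-atom string form collates the atom id with a fixed-format
record (element, coordinates, occupancy, u_iso); it is a convenience
contract, not a parseable format. mmCIF models are read through
gemmi and normalised into the same hierarchy; PDB is the natively
tested path.

## Reflection data and Fourier conventions

Reflections are kept symmetry- and Friedel-unique. The canonical
hemisphere is h>0 ∨ (h=0 ∧ k>0) ∨ (h=k=0 ∧ l>0), and the orbit
representative is the lexicographically greatest index over all
point-group images and Friedel mates; the list is sorted by (h, k, l).
Both rules are arbitrary but must be fixed for deterministic export
order. Systematic absences (h·R = h with non-integral h·t) are
excluded at generation and come out below 1e-8 of the maximum
amplitude when computed from a symmetric structure.

Scattering weights are constant per element — the electron count —
rather than 4-Gaussian form-factor tables. This keeps every oracle in
the test suite exact (a point scatterer at the origin gives F equal
to its electron count at all resolutions) and is the documented
extension point for callers who need Cromer–Mann accuracy; relative
amplitudes at resolutions coarser than ~2 Å are qualitatively
realistic because the B-factor damping dominates.

Conventions: F(**h**) = Σ f·occ·exp(−B|s|²/4)·exp(+2πi **h**·**x**),
ρ(**x**) = (1/V)·Σ F(**h**)·exp(−2πi **h**·**x**). Phases are degrees
at the array-export surface ((n, 2) arrays with F in column 0, φ in
column 1) and radians internally. Missing data is NaN amplitude and
is skipped by every transform. Synthesis expands the unique set to
the full sphere (F(hR) = F(h)·e^(−2πi h·t), Friedel conjugates),
requires every index within ±(N−1)/2 per axis (otherwise the grid is
reported too coarse), and evaluates one complex FFT; analysis is the
exact adjoint, so analysis∘synthesis is the identity to FFT rounding
(~1e-8 relative in the tests, with Parseval Σ|F|² = (V²/N)·Σρ²
holding to 1e-10). Patterson coefficients square the unique
amplitudes and zero the phases; squaring before or after symmetry
expansion is equivalent because amplitudes are symmetry-invariant.
Patterson map non-negativity is *not* asserted anywhere: it holds
only for complete data.

B-factor scaling multiplies by exp(−B|s|²/4); negative B sharpens.
An optional resolution limit drops reflections with d < d_min.

## Packing search

`Unit_Cell` defines the reference box as the smallest grid-aligned
parallelepiped containing the model (floor/ceil of per-axis extremes
of the atoms' real-valued grid coordinates) and precomputes
`symops_cell`: every (operator, whole-cell lattice shift) whose image
of the reference box intersects [0, 1)³, found by transforming the 8
box corners and enumerating the geometrically possible shifts per
axis. The reference coordinate (typically the model centroid) is
used only to pick the canonical lattice shift of the identity when
the caller forces the identity into a result.

`all_symops_in_box` implements the stepped search: the target box
(origin in Å, size in grid units — the mixed frames match the
argument names) is sampled in steps of (shortest reference-box
side)/sample_frequency along each axis, with the box corners, the
far faces and any unit-cell boundary crossings always included. For
each sample point, all (S, n) with (S, n)⁻¹·p inside the closed
reference box are collected: writing m = R⁻¹n, the per-axis integer
range of m is read directly off q₀ − box bounds, and n = R·m. The
shift enumeration is therefore bounded by the geometry of the box and
reference box, nothing else. Duplicates are culled on the exact key
(operator index, shift) and the result is sorted on that key, so
identical inputs give identical operator order. The search is
deliberately inclusive-biased; at low sample frequencies it can still
miss operators whose preimage slips between sample points, which is
the accuracy/speed trade-off the algorithm accepts. The test suite
measures this against `brute_force_symops_in_box` (every grid point
of the box, ≤ 10⁶ points): sampled ⊇ brute force in all tested cases
at sample_frequency 2, equality at dense sampling on grid-aligned
boxes. Growing the box never removes operators.

Affine export: fractional matrices are [R | t + n]; orthogonal
matrices conjugate by the cell orthogonalisation, O·R·O⁻¹ with
translation O·(t + n). Matrices act on column vectors; '4x4' appends
the row (0, 0, 0, 1).

## The cut-by-model pipeline

Stages: read model → read map (a finite symmetry-free map is promoted
to a P1 crystallographic map on its full-cell grid) → mask → Fourier
analysis at the requested resolution → B-factor scaling → write
outputs (MRC map re-synthesised from the scaled coefficients on the
input grid; coefficients as tab text, mmCIF, and MTZ when gemmi is
available). Masking happens *before* resolution truncation — the
tool cuts density, then band-limits the result — and the mask is
hard (binary) with distances computed in orthogonal space as the
minimum over all symmetry images and lattice translations of each
atom, so masked maps remain crystallographically consistent. A
radius covering the whole cell provably keeps every point and
short-circuits. A feathered mask edge is a possible extension,
default off.

The run report serialises to a fixed XML schema — a `program` element
with name/user/date/ok attributes, one `parameters` element, and one
`input_file`/`output_file` element per file with name/type/ok — and
to a JSON twin in which attribute keys carry a `-` prefix and
single-element lists collapse to plain objects. Conversion in either
direction is lossless and idempotent. Dates use the
`%a %b %d %H:%M:%S %Y` format. The pipeline records every file it
reads or writes with an ok flag; on a stage failure the offending
entry is marked `ok="no"`, the report is still written, and the
stage's error propagates.

## Error taxonomy

All failures fall into four host categories: unrecoverable library
failures → `RuntimeError`, out-of-range access → `IndexError`,
length/argument violations → `ValueError`, anything else →
`UnknownError`. Internal exception types subclass the corresponding
built-ins so ordinary `except` clauses work, and the `guard` context
manager converts unclassified exceptions to the catch-all at API
boundaries — an embedding session never sees an unclassified failure.
The CLI exits non-zero with the category named in the message.

## Synthetic data

All test inputs are generated: compact random models (default five
atoms drawn in a fractional sub-box, unit occupancy, u_iso = 0.3 Å²
≈ B = 24 Å², a typical mid-resolution protein displacement), density
maps rendered from them, and random orbit-averaged symmetric maps.
The real-space render places each atom as the exact Fourier mate of
the reciprocal damping model,
ρ(r) = f·(4π/B)^{3/2}·exp(−4π²r²/B), summed over symmetry images and
lattice translations to a 1e-7 relative tail — so the render is an
independent route to the same structure factors, and the dual-route
amplitude R-factor (direct summation vs FFT of the render) lands
near 1e-8 on an adequately fine grid. The fixtures emulate symmetry,
periodicity and displacement broadening; they do not emulate solvent,
disorder, measurement noise or form-factor fall-off, so passing tests
demonstrate the correctness of the algebra, not fit to experimental
data.

## Problem sizes

Tests and the reproduction script run on cells of 16–24 Å, grids of
20–48 points per axis, reflection lists of 50–600, models of 2–7
atoms, and 20 packing-search cases per run — sizes at which every
brute-force oracle (sphere enumeration, per-point distance checks,
per-grid-point packing search) is exact and fast, chosen as the
smallest problems that still exercise every symmetry element and
wrap-around path.
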