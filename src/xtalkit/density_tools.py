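"""The cut-by-model pipeline: mask a density map around an atomic
model, sharpen or blur it with a reciprocal-space B-factor, and emit
the transformed map plus its map coefficients, with a structured
XML/JSON run report.

The pipeline is the tool a practitioner runs to extract the density
belonging to one molecule from a crystallographic or cryo-EM map:

1. read the map and the model;
2. zero every grid point farther than ``mask_radius`` (A) from any
   atom, distances taken to *all symmetry images* so the mask is
   crystallographically consistent;
3. Fourier-analyse the masked map to the requested resolution;
4. apply the B-factor correction (negative sharpens, positive blurs);
5. write the coefficient files and the re-synthesised map.

Every run produces a :class:`RunReport` that serialises to a fixed XML
schema (``program`` element with ``parameters``, ``input_file`` and
``output_file`` children) and to a structurally equivalent JSON form
(attribute keys prefixed with ``-``); the two convert losslessly in
both directions.
"""

from __future__ import annotations

import getpass
import json
import time
from pathlib import Path

import numpy as np
from lxml import etree

from .cell_symmetry import Spacegroup
from .crystal_maps import NXmap, Xmap, read_map_file, write_map_file
from .errors import InvalidArgument, MessageFatal
from .model_hierarchy import Atom_list, read_pdb
from .reflection_data import (fft_analysis, fft_synthesis, scale_coeffs,
                              write_mmcif_sf, write_mtz, write_text)

__all__ = [
    "RunReport",
    "mask_by_model",
    "cut_by_model",
    "write_report",
    "read_report",
    "convert_report",
]

_DATE_FORMAT = "%a %b %d %H:%M:%S %Y"


class RunReport:
    """Structured record of one pipeline run.

    Serialises to the XML schema ``<program name= user= date= ok=>``
    containing one ``<parameters .../>`` element and one
    ``<input_file .../>`` / ``<output_file .../>`` element per file,
    and to the JSON twin in which attribute keys carry a ``-`` prefix.
    """

    def __init__(self, program: str, user: str | None = None, date: str | None = None,
                 ok: bool = True, parameters: dict | None = None):
        self.program = program
        self.user = user if user is not None else _safe_user()
        self.date = date if date is not None else time.strftime(_DATE_FORMAT)
        self.ok = ok
        self.parameters = dict(parameters or {})
        self.input_files: list[dict] = []
        self.output_files: list[dict] = []

    def add_input(self, name: str, type: str, ok: bool = True) -> None:
        self.input_files.append({"name": str(name), "type": type, "ok": ok})

    def add_output(self, name: str, type: str, ok: bool = True) -> None:
        self.output_files.append({"name": str(name), "type": type, "ok": ok})

    # -- XML ---------------------------------------------------------------

    def to_xml_element(self) -> etree._Element:
        root = etree.Element("program", name=self.program, user=self.user,
                             date=self.date, ok=_yesno(self.ok))
        etree.SubElement(root, "parameters",
                         {k: str(v) for k, v in self.parameters.items()})
        for entry in self.input_files:
            etree.SubElement(root, "input_file", name=entry["name"],
                             type=entry["type"], ok=_yesno(entry["ok"]))
        for entry in self.output_files:
            etree.SubElement(root, "output_file", name=entry["name"],
                             type=entry["type"], ok=_yesno(entry["ok"]))
        return root

    def to_xml(self) -> str:
        return etree.tostring(self.to_xml_element(), pretty_print=True,
                              encoding="unicode")

    @classmethod
    def from_xml_element(cls, root: etree._Element) -> "RunReport":
        if root.tag != "program":
            raise InvalidArgument(f"expected <program> root element, got <{root.tag}>")
        report = cls(root.get("name", ""), user=root.get("user", ""),
                     date=root.get("date", ""), ok=root.get("ok") == "yes")
        for child in root:
            if child.tag == "parameters":
                report.parameters = dict(child.attrib)
            elif child.tag in ("input_file", "output_file"):
                entry = {"name": child.get("name", ""), "type": child.get("type", ""),
                         "ok": child.get("ok") == "yes"}
                (report.input_files if child.tag == "input_file"
                 else report.output_files).append(entry)
            else:
                raise InvalidArgument(f"unexpected element <{child.tag}> in report")
        return report

    # -- JSON --------------------------------------------------------------

    def to_json_dict(self) -> dict:
        obj: dict = {
            "-name": self.program,
            "-user": self.user,
            "-date": self.date,
            "-ok": _yesno(self.ok),
            "parameters": {f"-{k}": str(v) for k, v in self.parameters.items()},
        }
        for key, entries in (("input_file", self.input_files),
                             ("output_file", self.output_files)):
            if not entries:
                continue
            items = [{"-name": e["name"], "-type": e["type"], "-ok": _yesno(e["ok"])}
                     for e in entries]
            obj[key] = items[0] if len(items) == 1 else items
        return {"program": obj}

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=4)

    @classmethod
    def from_json_dict(cls, data: dict) -> "RunReport":
        if "program" not in data:
            raise InvalidArgument("JSON report must have a top-level 'program' object")
        obj = data["program"]
        report = cls(obj.get("-name", ""), user=obj.get("-user", ""),
                     date=obj.get("-date", ""), ok=obj.get("-ok") == "yes")
        report.parameters = {k[1:]: v for k, v in obj.get("parameters", {}).items()}
        for key, target in (("input_file", report.input_files),
                            ("output_file", report.output_files)):
            entries = obj.get(key, [])
            if isinstance(entries, dict):
                entries = [entries]
            for e in entries:
                target.append({"name": e.get("-name", ""), "type": e.get("-type", ""),
                               "ok": e.get("-ok") == "yes"})
        return report

    def __repr__(self):
        return (f"RunReport({self.program!r}, ok={self.ok}, "
                f"{len(self.input_files)} inputs, {len(self.output_files)} outputs)")


def _yesno(flag: bool) -> str:
    return "yes" if flag else "no"


def _safe_user() -> str:
    try:
        return getpass.getuser()
    except (KeyError, OSError):
        return "unknown"


def write_report(report: RunReport, path, format: str = "xml") -> None:
    """Write a run report as XML or JSON."""
    if format not in ("xml", "json"):
        raise InvalidArgument(f"report format must be 'xml' or 'json', got {format!r}")
    text = report.to_xml() if format == "xml" else report.to_json()
    try:
        Path(path).write_text(text)
    except OSError as exc:
        raise MessageFatal(f"cannot write report {path}: {exc}") from exc


def read_report(path) -> RunReport:
    """Read a report, auto-detecting XML or JSON."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise MessageFatal(f"cannot read report {path}: {exc}") from exc
    stripped = text.lstrip()
    try:
        if stripped.startswith("<"):
            return RunReport.from_xml_element(etree.fromstring(text.encode()))
        return RunReport.from_json_dict(json.loads(text))
    except (etree.XMLSyntaxError, json.JSONDecodeError) as exc:
        raise InvalidArgument(f"malformed report file {path}: {exc}") from exc


def convert_report(path, target_format: str, out_path=None) -> Path:
    """Convert a report file between XML and JSON (losslessly)."""
    if target_format not in ("xml", "json"):
        raise InvalidArgument(f"target format must be 'xml' or 'json', got {target_format!r}")
    report = read_report(path)
    if out_path is None:
        out_path = Path(path).with_suffix(f".{target_format}")
    write_report(report, out_path, target_format)
    return Path(out_path)


# ---------------------------------------------------------------------------
# Masking and the pipeline

def mask_by_model(xmap: Xmap, atom_list: Atom_list, mask_radius: float) -> Xmap:
    """Keep density within ``mask_radius`` (A) of any atom, zero the rest.

    Distances are orthogonal-space, taken as the minimum over all
    symmetry images and lattice translations of each atom, so the
    resulting map remains crystallographically consistent.  The mask is
    hard (binary); map dimensions are unchanged.
    """
    if mask_radius <= 0:
        raise InvalidArgument(f"mask_radius must be positive, got {mask_radius}")
    if len(atom_list) == 0:
        raise InvalidArgument("atom list must not be empty")
    n = xmap.grid.nuvw
    # radius covering the whole cell: every point is within reach of a
    # lattice image of some atom, so the map is unchanged
    cell_diameter = np.linalg.norm(xmap.cell.orth_matrix, axis=0).sum()
    if mask_radius >= cell_diameter:
        return Xmap(xmap.cell, xmap.spacegroup, xmap.grid, xmap.values)
    mask = np.zeros(tuple(n), dtype=bool)
    frac = xmap.cell.fractionalize(atom_list.coords)
    row_norms = np.linalg.norm(xmap.cell.frac_matrix, axis=1)
    reach = row_norms * mask_radius * n  # grid-unit reach per axis
    r2_max = mask_radius * mask_radius
    for symop in xmap.spacegroup:
        for x0 in symop.apply(frac):
            gm = x0 * n
            ranges = [np.arange(int(np.floor(gm[i] - reach[i])),
                                int(np.ceil(gm[i] + reach[i])) + 1) for i in range(3)]
            gu, gv, gw = np.meshgrid(*ranges, indexing="ij")
            pts = np.stack([gu, gv, gw], axis=-1).reshape(-1, 3)
            d_orth = xmap.cell.orthogonalize(pts / n - x0)
            near = np.sum(d_orth * d_orth, axis=1) <= r2_max
            idx = np.mod(pts[near], n)
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return Xmap(xmap.cell, xmap.spacegroup, xmap.grid,
                np.where(mask, xmap.values, 0.0))


def _as_xmap(mapobj) -> Xmap:
    """Promote a finite symmetry-free map to a P1 crystallographic map."""
    if isinstance(mapobj, Xmap):
        return mapobj
    if isinstance(mapobj, NXmap):
        if mapobj.cell is None or mapobj.grid_full is None:
            raise InvalidArgument("NXmap lacks a cell-grid placement; cannot promote")
        p1 = Spacegroup.from_name("P1")
        xmap = Xmap(mapobj.cell, p1, mapobj.grid_full)
        s = mapobj.start_grid
        shp = mapobj.shape
        idx = [np.mod(np.arange(s[i], s[i] + shp[i]), mapobj.grid_full.nuvw[i])
               for i in range(3)]
        xmap.values[np.ix_(*idx)] = mapobj.values
        return xmap
    raise InvalidArgument(f"expected a map object, got {type(mapobj).__name__}")


def cut_by_model(mapin_path, pdbin_path, b_factor: float, resolution: float,
                 mask_radius: float, out_prefix,
                 report_format: str = "xml", write_mtz_file: bool = True,
                 log=None) -> tuple[dict, RunReport]:
    """Run the full cut-by-model pipeline.

    Reads the map and model, masks the density around the model,
    Fourier-analyses to ``resolution`` (A), applies the ``b_factor``
    correction (A^2; negative sharpens), and writes the transformed
    map (MRC), map coefficients (tab text + mmCIF, plus MTZ when the
    delegated I/O library is available) and the run report.

    Returns ``(outputs, report)`` where ``outputs`` maps short names to
    file paths.  On a stage failure the report marks the offending file
    ``ok="no"``, is still written, and the stage's error propagates.
    """
    if resolution <= 0:
        raise InvalidArgument(f"resolution must be positive, got {resolution}")
    out_prefix = Path(out_prefix)
    report = RunReport("cut_by_model", parameters={
        "mapin": str(mapin_path), "pdbin": str(pdbin_path),
        "b_factor": _fmt_num(b_factor), "resolution": _fmt_num(resolution),
        "mask_radius": _fmt_num(mask_radius),
    })
    outputs: dict[str, Path] = {}
    t0 = time.perf_counter()

    def _stage(msg):
        if log is not None:
            print(f"cut_by_model: {msg} [{time.perf_counter() - t0:.2f} s]",
                  file=log)

    try:
        try:
            minimol = read_pdb(pdbin_path)
            report.add_input(pdbin_path, "PDB", True)
        except Exception:
            report.add_input(pdbin_path, "PDB", False)
            raise
        _stage("model read")
        try:
            xmap = _as_xmap(read_map_file(mapin_path))
            report.add_input(mapin_path, "xmap", True)
        except Exception:
            report.add_input(mapin_path, "xmap", False)
            raise
        _stage("map read")

        atoms = minimol.atom_list()
        masked = mask_by_model(xmap, atoms, mask_radius)
        _stage("density masked")
        coeffs = fft_analysis(masked, resolution)
        coeffs = scale_coeffs(coeffs, b_factor)
        _stage(f"coefficients computed ({len(coeffs)} reflections)")

        out_map = out_prefix.with_suffix(".mrc")
        out_tsv = out_prefix.with_suffix(".tsv")
        out_cif = out_prefix.with_suffix(".cif")
        _write_output(report, outputs, "map", out_map, "xmap",
                      lambda p: write_map_file(
                          fft_synthesis(coeffs, xmap.grid), p))
        _write_output(report, outputs, "coeffs_text", out_tsv, "text coefficients",
                      lambda p: write_text(coeffs, p))
        _write_output(report, outputs, "coeffs_mmcif", out_cif, "mmCIF coefficients",
                      lambda p: write_mmcif_sf(coeffs, p))
        if write_mtz_file:
            try:
                out_mtz = out_prefix.with_suffix(".mtz")
                write_mtz(coeffs, out_mtz)
                outputs["coeffs_mtz"] = out_mtz
                report.add_output(out_mtz, "mini MTZ", True)
            except MessageFatal:
                pass  # MTZ layer unavailable; text + mmCIF already written
        _stage("outputs written")
        report.ok = True
    except Exception:
        report.ok = False
        raise
    finally:
        report_path = Path(f"{out_prefix}_report.{report_format}")
        write_report(report, report_path, report_format)
        outputs["report"] = report_path
    return outputs, report


def _write_output(report, outputs, key, path, type_name, writer) -> None:
    try:
        writer(path)
    except Exception:
        report.add_output(path, type_name, False)
        raise
    outputs[key] = path
    report.add_output(path, type_name, True)


def _fmt_num(x) -> str:
    return f"{float(x):g}" if float(x) != int(x) else f"{float(x):.1f}"
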