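"""Readers and writers for every external representation the workflow touches.

Formats handled here:

* Gaussian **cube** volumetric grids (read/write) — electron density in
  e bohr^-3 or electrostatic potential in hartree/e on a regular voxel
  lattice, geometry in bohr.
* Simple 3D structures: **XYZ** and a minimal **CML** subset
  (``molecule/atomArray/atom`` with ``elementType`` and ``x3/y3/z3``).
* The **SSIP XML** dialect (read/write) carrying a molecule's atoms and
  its surface site interaction points (position + signed epsilon).
* The **phase tsv** dialect: one solvent phase per line, temperature in
  the first column, then (component name, mole fraction) pairs.

Cube geometry is kept in bohr at this layer; conversion to angstrom
happens at the surface-module boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .units import BOHR_TO_ANGSTROM

__all__ = [
    "VolumetricGrid",
    "MoleculeStructure",
    "PhaseSpec",
    "CubeParseError",
    "StructureParseError",
    "PhaseTsvError",
    "SSIPXMLError",
    "read_cube",
    "write_cube",
    "read_structure",
    "write_ssip_xml",
    "read_ssip_xml",
    "read_phase_tsv",
    "write_phase_tsv",
    "structure_from_grid",
]

ELEMENTS = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

_SYMBOL_TO_Z = {s.upper(): i + 1 for i, s in enumerate(ELEMENTS)}


def canonical_element(symbol: str) -> str:
    """Return the canonical-case element symbol, or raise for unknowns."""
    z = _SYMBOL_TO_Z.get(symbol.strip().upper())
    if z is None:
        raise StructureParseError(f"unknown element symbol {symbol!r}")
    return ELEMENTS[z - 1]


class CubeParseError(ValueError):
    """Raised for malformed cube files; the message names the faulty line."""


class StructureParseError(ValueError):
    """Raised for malformed XYZ/CML structure files."""


class PhaseTsvError(ValueError):
    """Raised for malformed phase tsv files; the message names the line."""


class SSIPXMLError(ValueError):
    """Raised for malformed SSIP XML files."""


@dataclass
class VolumetricGrid:
    """A 3D scalar field on a regular voxel lattice (Gaussian cube semantics).

    Parameters
    ----------
    origin : (3,) float array
        Position of grid point (0, 0, 0), in bohr.
    axes : (3, 3) float array
        Row ``k`` is the voxel step vector along grid axis ``k``, in bohr.
    values : (nx, ny, nz) float array
        Scalar values, x slowest / z fastest (cube file order).
    atoms : list of (int, float, ndarray)
        ``(atomic_number, nuclear_charge, position_bohr)`` records.
    extra_header : bool
        True when the file used the negative-atom-count dialect that
        carries one extra header line before the data block.
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: list = field(default_factory=list)
    extra_header: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if abs(np.linalg.det(self.axes)) < 1e-300:
            raise ValueError("axis vectors are linearly dependent")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape

    def grid_points_bohr(self) -> np.ndarray:
        """All lattice-point coordinates, shape (nx, ny, nz, 3), in bohr."""
        nx, ny, nz = self.counts
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                        indexing="ij"),
            axis=-1,
        )
        return self.origin + idx @ self.axes


@dataclass
class MoleculeStructure:
    """Atoms of one molecule: (element symbol, position in angstrom)."""

    atoms: list  # list of (str, ndarray shape (3,))
    charge: int = 0
    title: str = ""

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("a structure needs at least one atom")
        atoms = []
        for sym, pos in self.atoms:
            pos = np.asarray(pos, dtype=float).reshape(3)
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite position for atom {sym}")
            atoms.append((canonical_element(sym), pos))
        self.atoms = atoms


@dataclass
class PhaseSpec:
    """A solvent phase: temperature plus (component, mole fraction) pairs."""

    temperature: float
    components: list  # ordered list of (name, mole fraction)

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.components:
            raise ValueError("a phase needs at least one component")
        for name, x in self.components:
            if not (0.0 < x <= 1.0):
                raise ValueError(
                    f"mole fraction for {name!r} must be in (0, 1], got {x}")
        total = sum(x for _, x in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mole fractions sum to {total}, not 1")


# ---------------------------------------------------------------------------
# Gaussian cube

def _cube_float(tok: str, lineno: int):
    try:
        return float(tok)
    except ValueError:
        raise CubeParseError(
            f"line {lineno}: non-numeric token {tok!r}") from None


def read_cube(path) -> VolumetricGrid:
    """Read a Gaussian cube file.

    Handles the common dialect in which a negative atom count signals one
    extra header line (e.g. orbital ids) before the data block; the grid's
    ``extra_header`` flag records this.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise CubeParseError(
            f"line {len(lines) + 1}: file truncated before the header")

    def toks(i):
        return lines[i].split()

    hdr = toks(2)
    if len(hdr) < 4:
        raise CubeParseError("line 3: expected atom count and origin")
    natoms_raw = int(_cube_float(hdr[0], 3))
    extra_header = natoms_raw < 0
    natoms = abs(natoms_raw)
    origin = np.array([_cube_float(t, 3) for t in hdr[1:4]])

    counts = np.empty(3, dtype=int)
    axes = np.empty((3, 3))
    for k in range(3):
        row = toks(3 + k)
        if len(row) < 4:
            raise CubeParseError(f"line {4 + k}: expected count and axis vector")
        counts[k] = int(_cube_float(row[0], 4 + k))
        axes[k] = [_cube_float(t, 4 + k) for t in row[1:4]]
    if np.any(counts <= 0):
        raise CubeParseError("lines 4-6: voxel counts must be positive")

    atoms = []
    first_atom_line = 6
    if len(lines) < first_atom_line + natoms:
        raise CubeParseError(
            f"line {len(lines) + 1}: file truncated inside the atom block")
    for a in range(natoms):
        lineno = first_atom_line + a + 1
        row = toks(first_atom_line + a)
        if len(row) < 5:
            raise CubeParseError(f"line {lineno}: expected Z, charge, x, y, z")
        z = int(_cube_float(row[0], lineno))
        charge = _cube_float(row[1], lineno)
        pos = np.array([_cube_float(t, lineno) for t in row[2:5]])
        atoms.append((z, charge, pos))

    data_start = first_atom_line + natoms
    if extra_header:
        data_start += 1  # DSET ids line

    nvalues = int(np.prod(counts))
    values = []
    for i in range(data_start, len(lines)):
        for tok in lines[i].split():
            values.append(_cube_float(tok, i + 1))
    if len(values) != nvalues:
        raise CubeParseError(
            f"line {len(lines)}: expected {nvalues} data values, found {len(values)}")
    grid = np.asarray(values).reshape(tuple(counts))
    return VolumetricGrid(origin, axes, grid, atoms, extra_header=extra_header)


def write_cube(grid: VolumetricGrid, path, comment: str = "ssipkit cube") -> None:
    """Write ``grid`` in standard cube layout, re-readable by :func:`read_cube`.

    Values are written with 6 significant figures.
    """
    nx, ny, nz = grid.counts
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by ssipkit\n")
        natoms = len(grid.atoms)
        if grid.extra_header:
            natoms = -natoms
        ox, oy, oz = grid.origin
        fh.write(f"{natoms:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        for k, n in zip(range(3), (nx, ny, nz)):
            ax = grid.axes[k]
            fh.write(f"{n:5d}{ax[0]:12.6f}{ax[1]:12.6f}{ax[2]:12.6f}\n")
        for z, charge, pos in grid.atoms:
            fh.write(f"{z:5d}{charge:12.6f}"
                     f"{pos[0]:12.6f}{pos[1]:12.6f}{pos[2]:12.6f}\n")
        if grid.extra_header:
            fh.write("    1    1\n")
        flat = grid.values.reshape(-1)
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            fh.write("".join(f"{v:13.5E}" for v in chunk) + "\n")


def structure_from_grid(grid: VolumetricGrid, title: str = "") -> MoleculeStructure:
    """Build a :class:`MoleculeStructure` from a cube's atom records (bohr -> angstrom)."""
    if not grid.atoms:
        raise ValueError("grid carries no atom records")
    atoms = [(ELEMENTS[z - 1], pos * BOHR_TO_ANGSTROM)
             for z, _charge, pos in grid.atoms]
    return MoleculeStructure(atoms, title=title)


# ---------------------------------------------------------------------------
# XYZ / minimal CML structures

def _read_xyz(path) -> MoleculeStructure:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines()]
    if not lines:
        raise StructureParseError("empty XYZ file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError("line 1: expected the atom count") from None
    title = lines[1].strip() if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != declared:
        raise StructureParseError(
            f"declared {declared} atoms but found {len(atom_lines)}")
    atoms = []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 4:
            raise StructureParseError(f"malformed atom line: {ln!r}")
        try:
            pos = [float(p) for p in parts[1:4]]
        except ValueError:
            raise StructureParseError(f"non-numeric coordinate in {ln!r}") from None
        atoms.append((parts[0], pos))
    return MoleculeStructure(atoms, title=title)


def _localname(el) -> str:
    return etree.QName(el).localname


def _read_cml(path) -> MoleculeStructure:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise StructureParseError(f"malformed XML: {exc}") from None
    root = tree.getroot()
    atoms = []
    title = root.get("id", "") or root.get("title", "")
    for el in root.iter():
        if _localname(el) != "atom":
            continue
        sym = el.get("elementType")
        if sym is None:
            raise StructureParseError("atom element without elementType")
        try:
            pos = [float(el.get(k)) for k in ("x3", "y3", "z3")]
        except (TypeError, ValueError):
            raise StructureParseError(
                f"atom {sym}: x3/y3/z3 attributes missing or non-numeric") from None
        atoms.append((sym, pos))
    if not atoms:
        raise StructureParseError("no atom elements found")
    return MoleculeStructure(atoms, title=title)


def read_structure(path, format_hint: str | None = None) -> MoleculeStructure:
    """Read an XYZ or minimal-CML structure; positions in angstrom.

    ``format_hint`` may be ``"xyz"`` or ``"cml"``; otherwise it is taken
    from the file extension.
    """
    fmt = (format_hint or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt in ("cml", "xml"):
        return _read_cml(path)
    raise StructureParseError(f"unknown structure format {fmt!r}")


# ---------------------------------------------------------------------------
# SSIP XML dialect (documented in docs/formats.md)

def write_ssip_xml(ssips, structure: MoleculeStructure | None, path) -> None:
    """Write an :class:`~ssipkit.footprint.SSIPSet` (and optional structure) as XML.

    One ``<ssip>`` element per site carries position (angstrom), the signed
    interaction parameter ``epsilon``, the footprint area and the source
    MEPS value.  :func:`read_ssip_xml` inverts this exactly (epsilon to six
    decimals).
    """
    root = etree.Element("ssipMolecule")
    root.set("title", ssips.molecule_title or (structure.title if structure else ""))
    root.set("surfaceArea", f"{ssips.total_surface_area:.6f}")
    root.set("ssipArea", f"{ssips.parameters.ssip_area:.6f}")
    root.set("isoLevel", f"{ssips.parameters.iso_level:.6g}")
    atoms_el = etree.SubElement(root, "atoms")
    if structure is not None:
        for sym, pos in structure.atoms:
            a = etree.SubElement(atoms_el, "atom")
            a.set("element", sym)
            a.set("x", f"{pos[0]:.6f}")
            a.set("y", f"{pos[1]:.6f}")
            a.set("z", f"{pos[2]:.6f}")
    ssips_el = etree.SubElement(root, "ssips")
    for s in ssips.ssips:
        el = etree.SubElement(ssips_el, "ssip")
        el.set("x", f"{s.position[0]:.6f}")
        el.set("y", f"{s.position[1]:.6f}")
        el.set("z", f"{s.position[2]:.6f}")
        el.set("epsilon", f"{s.epsilon:.6f}")
        el.set("area", f"{s.footprint_area:.6f}")
        el.set("meps", f"{s.source_meps:.6f}")
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def read_ssip_xml(path):
    """Read the SSIP XML dialect back into an :class:`~ssipkit.footprint.SSIPSet`."""
    from .footprint import SSIP, SSIPSet, FootprintConfig

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SSIPXMLError(f"malformed XML: {exc}") from None
    root = tree.getroot()
    if _localname(root) != "ssipMolecule":
        raise SSIPXMLError(f"unexpected root element {_localname(root)!r}")
    ssips = []
    for i, el in enumerate(root.iter()):
        if _localname(el) != "ssip":
            continue
        idx = len(ssips)
        eps = el.get("epsilon")
        if eps is None:
            raise SSIPXMLError(f"ssip element {idx}: missing epsilon attribute")
        try:
            pos = np.array([float(el.get(k)) for k in ("x", "y", "z")])
        except (TypeError, ValueError):
            raise SSIPXMLError(
                f"ssip element {idx}: missing or non-numeric position") from None
        area = float(el.get("area", "nan"))
        meps = float(el.get("meps", "nan"))
        ssips.append(SSIP(position=pos, epsilon=float(eps),
                          footprint_area=area, source_meps=meps))
    config = FootprintConfig(
        ssip_area=float(root.get("ssipArea", "9.35")),
        iso_level=float(root.get("isoLevel", "0.002")),
    )
    total = float(root.get("surfaceArea",
                           sum(s.footprint_area for s in ssips)))
    return SSIPSet(ssips=ssips, molecule_title=root.get("title", ""),
                   total_surface_area=total, parameters=config,
                   validate=False)


# ---------------------------------------------------------------------------
# Phase tsv (one phase per line; temperature, then name/fraction pairs)

def read_phase_tsv(path) -> list[PhaseSpec]:
    """Parse the phase-definition tsv dialect.

    UTF-8, tab-separated; ``#``-prefixed and blank lines are ignored.
    Errors name the offending line.  Mole fractions must sum to 1 within
    1e-6 — a hard error, not a renormalisation.
    """
    phases = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            try:
                temperature = float(cols[0])
            except ValueError:
                raise PhaseTsvError(
                    f"line {lineno}: temperature {cols[0]!r} is not a number"
                ) from None
            if temperature <= 0:
                raise PhaseTsvError(
                    f"line {lineno}: temperature must be positive, got {temperature}")
            rest = [c for c in cols[1:]]
            if len(rest) == 0 or len(rest) % 2 != 0:
                raise PhaseTsvError(
                    f"line {lineno}: expected (name, fraction) column pairs, "
                    f"found {len(rest)} trailing columns")
            components = []
            for name, frac in zip(rest[0::2], rest[1::2]):
                try:
                    x = float(frac)
                except ValueError:
                    raise PhaseTsvError(
                        f"line {lineno}: mole fraction {frac!r} is not a number"
                    ) from None
                components.append((name.strip(), x))
            total = sum(x for _, x in components)
            if abs(total - 1.0) > 1e-6:
                raise PhaseTsvError(
                    f"line {lineno}: mole fractions sum to {total:.8f}, not 1")
            try:
                phases.append(PhaseSpec(temperature, components))
            except ValueError as exc:
                raise PhaseTsvError(f"line {lineno}: {exc}") from None
    return phases


def write_phase_tsv(phases: list[PhaseSpec], path) -> None:
    """Write phase specs in the same tsv dialect (inverse of :func:`read_phase_tsv`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in phases:
            cols = [repr(p.temperature) if not float(p.temperature).is_integer()
                    else str(int(p.temperature))]
            for name, x in p.components:
                cols.append(name)
                cols.append(repr(float(x)))
            fh.write("\t".join(cols) + "\n")
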