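"""Structures, trajectories, multi-model PDB I/O, and atom selections.

Unit convention: every coordinate held in memory is in nanometres; PDB files
store ångströms, and the conversion happens only at the file boundary. Times
are in picoseconds. Author residue numbering from input files is preserved
verbatim (the literature names residues such as W755 or E723 by the numbers
printed in the deposited structures, so renumbering would make every
downstream selection wrong).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, SelectionError, StructureError

NM_PER_ANGSTROM = 0.1

#: Standard atomic masses (amu) by element symbol; extend as needed.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "ZN": 65.38, "BR": 79.904, "I": 126.904, "SE": 78.971,
}
DEFAULT_MASS = 12.011  # fallback for unrecognised elements

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL HSD HSE HSP HID HIE HIP".split()
)
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``resid`` is the author residue number exactly as read from the source
    file (1-based, possibly with gaps). ``charge`` is a partial charge in
    units of the elementary charge and is optional.
    """

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    mass: float
    charge: float | None = None

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise StructureError(f"atom serial must be positive, got {self.serial}")
        if self.mass <= 0:
            raise StructureError(f"atom {self.serial} ({self.name}): mass must be > 0")
        if not self.element:
            raise StructureError(f"atom {self.serial} ({self.name}): element is empty")


class Topology:
    """Ordered atom list with a (chain, resid) -> atom-index lookup."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serials in topology")
        index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            index.setdefault((a.chain, a.resid), []).append(i)
        self.residue_index: dict[tuple[str, int], tuple[int, ...]] = {
            k: tuple(v) for k, v in index.items()
        }

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        """Residues in order of first appearance."""
        return list(self.residue_index)

    def atom_indices(self, chain: str, resid: int) -> tuple[int, ...]:
        try:
            return self.residue_index[(chain, resid)]
        except KeyError:
            raise SelectionError(f"no residue (chain={chain!r}, resid={resid})") from None

    def find_atom(self, chain: str, resid: int, name: str) -> int:
        for i in self.atom_indices(chain, resid):
            if self.atoms[i].name == name:
                return i
        raise SelectionError(
            f"residue (chain={chain!r}, resid={resid}) has no atom named {name!r}"
        )


@dataclass
class Frame:
    """One set of coordinates (nm) with an optional periodic box and a time stamp (ps)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"coordinates must be (n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3, 3):
                raise StructureError(f"box must be (3, 3) vectors, got {self.box.shape}")
            if abs(np.linalg.det(self.box)) <= 0.0:
                raise StructureError("box has non-positive volume")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """A topology plus time-ordered frames sharing that topology's atom count."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        self.topology = topology
        self.frames: list[Frame] = list(frames)
        n = topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise StructureError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise StructureError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3), nm."""
        return np.stack([f.coordinates for f in self.frames])

    def frame_spacing(self) -> float:
        """Median time step in ps (0.0 for trajectories of fewer than 2 frames)."""
        if len(self.frames) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class SelectionMask:
    """Ordered, duplicate-free atom indices into a topology."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError("selection mask contains duplicate indices")
        if any(i < 0 for i in self.indices):
            raise SelectionError("selection mask contains negative indices")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def validate(self, top: Topology) -> "SelectionMask":
        if self.indices and max(self.indices) >= top.n_atoms:
            raise SelectionError(
                f"mask index {max(self.indices)} out of range for "
                f"{top.n_atoms}-atom topology"
            )
        return self


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    """Guess the element from a PDB atom name (columns 13-16)."""
    stripped = name.strip()
    letters = re.sub(r"[^A-Za-z]", "", stripped)
    if not letters:
        return ""
    two = letters[:2].upper()
    # Two-letter elements only when the name starts in column 13 (4-char names
    # are ambiguous); common biomolecular cases resolved by lookup.
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE") and len(stripped) <= 2:
        return two
    return letters[0].upper()


def _mass_for(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    if len(line.rstrip("\n")) < 54:
        raise ParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
    except ValueError:
        raise ParseError(f"line {lineno}: bad atom serial {line[6:11]!r}") from None
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    try:
        resid = int(line[22:26])
    except ValueError:
        raise ParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from None
    try:
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    except ValueError:
        raise ParseError(f"line {lineno}: bad coordinate field") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    if not element:
        raise ParseError(f"line {lineno}: cannot determine element for atom {name!r}")
    record = AtomRecord(
        serial=serial, name=name, resname=resname, resid=resid, chain=chain,
        element=element, mass=_mass_for(element),
    )
    return record, xyz * NM_PER_ANGSTROM, altloc


def _parse_cryst1(line: str) -> np.ndarray | None:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
    except (ValueError, IndexError):
        return None
    if min(a, b, c) <= 0:
        return None
    if not all(abs(ang - 90.0) < 1e-6 for ang in (alpha, beta, gamma)):
        return None  # only orthorhombic boxes carried through
    return np.diag([a, b, c]) * NM_PER_ANGSTROM


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    One frame per MODEL block; a file without MODEL records yields a single
    frame. Coordinates are converted Å -> nm; author residue numbers, chain
    identifiers and atom names are preserved verbatim. Only the first altloc
    of each atom is kept. An orthorhombic CRYST1 record becomes the frame box.
    """
    path = Path(path)
    box: np.ndarray | None = None
    model_atoms: list[AtomRecord] = []
    model_coords: list[np.ndarray] = []
    frames_coords: list[np.ndarray] = []
    reference_atoms: list[AtomRecord] | None = None
    seen_altloc: set[tuple[str, str, int, str]] = set()
    n_models_closed = 0

    def close_model(lineno: int) -> None:
        nonlocal reference_atoms, model_atoms, model_coords, n_models_closed
        if not model_coords:
            return
        if reference_atoms is None:
            reference_atoms = model_atoms
        elif len(model_atoms) != len(reference_atoms):
            raise StructureError(
                f"{path.name}: MODEL {n_models_closed + 1} has "
                f"{len(model_atoms)} atoms, expected {len(reference_atoms)}"
            )
        frames_coords.append(np.array(model_coords))
        n_models_closed += 1
        model_atoms, model_coords = [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                parsed = _parse_cryst1(line)
                if parsed is not None:
                    box = parsed
            elif rec == "MODEL":
                close_model(lineno)
                seen_altloc.clear()
            elif rec == "ENDMDL":
                close_model(lineno)
                seen_altloc.clear()
            elif rec in ("ATOM", "HETATM"):
                record, xyz, altloc = _parse_atom_line(line, lineno)
                if altloc:
                    key = (record.chain, record.name, record.resid, record.resname)
                    if key in seen_altloc:
                        continue
                    seen_altloc.add(key)
                model_atoms.append(record)
                model_coords.append(xyz)
    close_model(-1)

    if reference_atoms is None or not frames_coords:
        raise ParseError(f"{path.name}: no ATOM/HETATM records found")
    top = Topology(reference_atoms)
    frames = [
        Frame(coords, box=box, time=float(i)) for i, coords in enumerate(frames_coords)
    ]
    return Trajectory(top, frames)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB.

    Coordinates are written in Å with three decimals; Python's float
    formatting rounds half-to-even, which is the documented rounding rule.
    """
    if traj.n_frames == 0:
        raise StructureError("cannot write an empty trajectory")
    path = Path(path)
    lines: list[str] = []
    first_box = traj.frames[0].box
    if first_box is not None and np.allclose(first_box, np.diag(np.diag(first_box))):
        a, b, c = np.diag(first_box) / NM_PER_ANGSTROM
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for imodel, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {imodel:4d}")
        ang = frame.coordinates / NM_PER_ANGSTROM
        for atom, (x, y, z) in zip(traj.topology.atoms, ang):
            name = atom.name
            # PDB alignment: 1-3 char names start in column 14 unless the
            # element symbol is two letters.
            if len(name) < 4 and len(atom.element) < 2:
                name_field = f" {name:<3s}"
            else:
                name_field = f"{name:<4s}"
            record = "HETATM" if atom.resname in WATER_RESNAMES else "ATOM  "
            lines.append(
                f"{record}{atom.serial:5d} {name_field} {atom.resname:<3s} "
                f"{atom.chain:1s}{atom.resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(
    topology_path: str | Path, trajectory_path: str | Path | None = None
) -> Trajectory:
    """Read standard MD formats (GRO/XTC/TRR/DCD/...) via MDAnalysis.

    Multi-model PDB goes through :func:`read_pdb`; everything else is
    delegated to MDAnalysis (an optional dependency) and converted into this
    package's containers under the same unit convention (nm, ps).
    """
    topology_path = Path(topology_path)
    if trajectory_path is None and topology_path.suffix.lower() in (".pdb", ".ent"):
        return read_pdb(topology_path)
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading binary trajectory formats requires MDAnalysis "
            "(pip install lbdkit[traj])"
        ) from exc
    args = (str(topology_path),) if trajectory_path is None else (
        str(topology_path), str(trajectory_path))
    u = mda.Universe(*args)
    atoms = []
    for i, a in enumerate(u.atoms):
        element = getattr(a, "element", "") or _guess_element(a.name)
        mass = float(a.mass) if float(a.mass) > 0 else _mass_for(element)
        chain = (getattr(a, "chainID", "") or getattr(a, "segid", "") or "A")[:1]
        atoms.append(AtomRecord(
            serial=int(getattr(a, "id", i + 1)), name=str(a.name),
            resname=str(a.resname), resid=int(a.resid), chain=chain,
            element=element or "C", mass=mass,
        ))
    top = Topology(atoms)
    frames = []
    for ts in u.trajectory:
        box = None
        if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
            from MDAnalysis.lib.mdamath import triclinic_vectors
            box = triclinic_vectors(ts.dimensions) * NM_PER_ANGSTROM
        frames.append(Frame(ts.positions * NM_PER_ANGSTROM, box=box, time=float(ts.time)))
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := term ("and" term)*
#   term     := "alphacarbon" | "protein" | "water"
#             | "name" <atomname> | "resid" <a>[-<b>] | "chain" <c>
#
# "and" binds tighter than "or". Masks are ordered by atom index, so repeated
# evaluation of the same expression is bit-identical.

_TOKEN_RE = re.compile(r"\S+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _SelectionParser:
    def __init__(self, top: Topology, expression: str):
        self.top = top
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self, expect: str) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise ParseError(
                f"selection {self.expression!r}: expected {expect} at position "
                f"{len(self.expression)} (end of expression)"
            )
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self.pos < len(self.tokens):
            tok, col = self.tokens[self.pos]
            raise ParseError(
                f"selection {self.expression!r}: unexpected token {tok!r} at position {col}"
            )
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self._next("or")
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() == "and":
            self._next("and")
            mask = mask & self._term()
        return mask

    def _term(self) -> np.ndarray:
        tok, col = self._next("a selection keyword")
        atoms = self.top.atoms
        if tok == "alphacarbon":
            return np.array(
                [a.name == "CA" and a.resname in STANDARD_AMINO_ACIDS for a in atoms]
            )
        if tok == "protein":
            return np.array([a.resname in STANDARD_AMINO_ACIDS for a in atoms])
        if tok == "water":
            return np.array([a.resname in WATER_RESNAMES for a in atoms])
        if tok == "name":
            value, _ = self._next("an atom name after 'name'")
            return np.array([a.name == value for a in atoms])
        if tok == "chain":
            value, _ = self._next("a chain id after 'chain'")
            return np.array([a.chain == value for a in atoms])
        if tok == "resid":
            value, vcol = self._next("a residue number or range after 'resid'")
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", value)
            if not m:
                raise ParseError(
                    f"selection {self.expression!r}: bad resid range {value!r} "
                    f"at position {vcol}"
                )
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return np.array([lo <= a.resid <= hi for a in atoms])
        raise ParseError(
            f"selection {self.expression!r}: unknown keyword {tok!r} at position {col}"
        )


def select(top: Topology, expression: str) -> SelectionMask:
    """Resolve a selection expression into an ordered atom-index mask.

    Grammar: ``alphacarbon | protein | water | name <x> | resid <a>[-<b>] |
    chain <c>``, combined with ``and`` / ``or`` (``and`` binds tighter).
    An empty result is allowed.
    """
    if not expression.strip():
        raise ParseError("empty selection expression")
    boolean = _SelectionParser(top, expression).parse()
    return SelectionMask(tuple(int(i) for i in np.flatnonzero(boolean)))


def mask_from_indices(indices: Iterable[int]) -> SelectionMask:
    return SelectionMask(tuple(int(i) for i in indices))
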