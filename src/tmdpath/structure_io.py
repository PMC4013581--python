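"""Structures, trajectories and segment tables.

The analyses in this package are defined over three carriers:

* :class:`Structure` — one conformer: an ordered atom table with
  coordinates (Å) and masses (Da).
* :class:`Trajectory` — ordered frames of coordinates over a fixed atom
  table, with strictly increasing time stamps (ps).
* :class:`SegmentTable` — named secondary-structure elements (helices,
  strands, sheet groups, loops) as closed 1-based residue intervals.

The only on-disk dialect is PDB v3.3: single-model for structures and
multi-model (MODEL/ENDMDL) for trajectories, with frame times carried in
``REMARK 250 TIME_PS`` records.  The packaged default segment tables are
those of the two native folds of Mad2, the spindle-checkpoint protein
whose open→closed conversion this toolkit models at coarse-grained scale:
open Mad2 carries three helices (αA 18–37, αB 61–75, αC 122–142) and eight
strands (β1 11–13 … β8 184–191); closed Mad2 rearranges the β-sheet into
β6–β4–β5–β8″–β8′ with αA extended to 12–37.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Segment",
    "SegmentTable",
    "Trajectory",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "default_segments",
    "load_segment_table",
    "element_mass",
]

# Masses in Da for the elements that occur in protein PDB files.
_ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845, "MN": 54.938, "CU": 63.546,
}
_DEFAULT_MASS = 12.011  # unknown elements fall back to carbon-like

# Two-letter elements that can appear as the first characters of an atom
# name; checked before the single-letter fallback.
_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE"}


class PDBFormatError(ValueError):
    """Raised for malformed PDB records, with the offending line number."""


def element_mass(element: str) -> float:
    """Mass (Da) for an element symbol from the packaged table."""
    return _ELEMENT_MASSES.get(element.upper().strip(), _DEFAULT_MASS)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_index: int      # 1-based residue sequence number
    res_name: str
    chain: str
    mass: float         # Da


@dataclass
class Structure:
    """One conformer: an ordered atom table plus coordinates.

    Invariants: residue indices non-decreasing within a chain, finite
    coordinates, positive masses, at least one atom.
    """

    atoms: list[Atom]
    coords: np.ndarray          # (n_atoms, 3) Å
    title: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atoms) == 0:
            raise ValueError("Structure needs at least one atom")
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if any(a.mass <= 0 for a in self.atoms):
            raise ValueError("non-positive atom mass")
        prev: dict[str, int] = {}
        for a in self.atoms:
            if a.res_index < prev.get(a.chain, -(10 ** 9)):
                raise ValueError(
                    f"residue indices decrease within chain {a.chain!r}"
                )
            prev[a.chain] = a.res_index

    # -- derived views ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def res_indices(self) -> np.ndarray:
        return np.array([a.res_index for a in self.atoms])

    def atom_indices(self, residues) -> np.ndarray:
        """Indices of atoms whose residue number is in ``residues``."""
        residues = set(int(r) for r in residues)
        idx = np.array(
            [i for i, a in enumerate(self.atoms) if a.res_index in residues],
            dtype=int,
        )
        return idx

    def find_atom(self, res_index: int, name: str) -> int:
        """Index of the atom ``name`` in residue ``res_index`` (first match)."""
        for i, a in enumerate(self.atoms):
            if a.res_index == res_index and a.name == name:
                return i
        raise KeyError(f"atom {name!r} in residue {res_index} not found")

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        return Structure(
            atoms=self.atoms,
            coords=np.asarray(coords, dtype=float),
            title=self.title if title is None else title,
        )


@dataclass(frozen=True)
class Segment:
    name: str
    kind: str                        # helix | strand | sheet-group | loop
    ranges: tuple[tuple[int, int], ...]  # closed 1-based intervals

    def residues(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.ranges:
            out |= set(range(lo, hi + 1))
        return out


_SEGMENT_KINDS = {"helix", "strand", "sheet-group", "loop"}


@dataclass
class SegmentTable:
    """Named secondary-structure elements over 1-based residue intervals."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(names) != len(set(names)):
            raise ValueError("duplicate segment names")
        for s in self.segments:
            if s.kind not in _SEGMENT_KINDS:
                raise ValueError(f"unknown segment class {s.kind!r}")
            if not s.ranges or any(hi < lo for lo, hi in s.ranges):
                raise ValueError(f"segment {s.name!r} has an empty range")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def __getitem__(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment {name!r}")

    def residues(self, name: str) -> set[int]:
        return self[name].residues()


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed atom table.

    ``frames`` is (n_frames, n_atoms, 3) in Å; ``times`` (ps) strictly
    increasing.  The atom table is shared by reference with ``topology``.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise ValueError("trajectory has no frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Atom-name fallback when columns 77–78 are absent or junk.

    PDB convention right-justifies the element in the first two columns of
    the name field; digits and primes are stripped first.
    """
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "C"
    two = stripped[:2].upper()
    if two in _TWO_LETTER and len(name.strip()) > 1 and not name[:1].strip().isdigit():
        # Names like "CL1"; but "CA"/"CD" in a protein are carbons, so only
        # accept two-letter elements when the name occupies column 13 (the
        # slot PDB reserves for two-letter elements).
        if name[:1] != " ":
            return two
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float], str]:
    try:
        name = line[12:16].strip()
        altloc = line[16:17]
        res_name = line[17:20].strip()
        chain = line[21:22]
        res_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if element and element.upper() in _ELEMENT_MASSES:
        element = element.upper()
    else:
        inferred = _element_from_name(line[12:16])
        if element:
            warnings.warn(
                f"line {lineno}: unknown element {element!r}, "
                f"using {inferred!r} from atom name"
            )
        element = inferred
    atom = Atom(
        name=name,
        element=element,
        res_index=res_index,
        res_name=res_name,
        chain=chain,
        mass=element_mass(element),
    )
    return atom, (x, y, z), altloc


def _read_pdb_models(path, first_chain_only: bool, altloc: str):
    """Parse every MODEL block: (title, times, [(atoms, coords) per model])."""
    title = ""
    models: list[tuple[list[Atom], list[tuple[float, float, float]]]] = []
    times: list[float] = []
    cur_atoms: list[Atom] = []
    cur_coords: list[tuple[float, float, float]] = []
    in_model = False
    seen_any = False
    chain_seen: str | None = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("TITLE"):
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                if cur_atoms:
                    models.append((cur_atoms, cur_coords))
                    cur_atoms, cur_coords = [], []
                in_model = True
                chain_seen = None
            elif rec == "ENDMDL":
                if cur_atoms:
                    models.append((cur_atoms, cur_coords))
                cur_atoms, cur_coords = [], []
                in_model = False
            elif line.startswith("REMARK 250 TIME_PS"):
                try:
                    times.append(float(line.split()[-1]))
                except ValueError:
                    raise PDBFormatError(
                        f"malformed TIME_PS remark at line {lineno}"
                    ) from None
            elif rec in ("ATOM  ", "HETATM") and rec == "ATOM  ":
                atom, xyz, alt = _parse_atom_line(line, lineno)
                if alt not in (" ", "", altloc):
                    continue
                if first_chain_only:
                    if chain_seen is None:
                        chain_seen = atom.chain
                    elif atom.chain != chain_seen:
                        continue
                cur_atoms.append(atom)
                cur_coords.append(xyz)
                seen_any = True
    if cur_atoms:
        models.append((cur_atoms, cur_coords))
    if not seen_any:
        raise PDBFormatError(f"no ATOM records found in {path}")
    # `in_model` deliberately unused beyond flow control
    return title, times, models


def read_pdb(
    path,
    model: int | None = None,
    first_chain_only: bool = True,
    altloc: str = "A",
) -> Structure:
    """Read one model of a PDB v3.3 file into a :class:`Structure`.

    Parameters
    ----------
    path : file path
    model : int, optional
        1-based MODEL number for multi-model files; default first model.
    first_chain_only : bool
        Keep only the first chain encountered (the default: the systems
        modelled here are monomers).
    altloc : str
        Alternate-location indicator to keep besides blank.

    Masses are assigned from a packaged element-mass table; the element is
    taken from columns 77–78, falling back to atom-name heuristics (with a
    warning) when that field is absent or unknown.
    """
    title, _times, models = _read_pdb_models(path, first_chain_only, altloc)
    which = 1 if model is None else int(model)
    if which < 1 or which > len(models):
        raise ValueError(
            f"model {which} not present ({len(models)} model(s) in {path})"
        )
    atoms, coords = models[which - 1]
    return Structure(atoms=atoms, coords=np.array(coords), title=title)


def read_trajectory(path, topology: Structure | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Frame times come from ``REMARK 250 TIME_PS`` records (one per MODEL);
    files without them get 1 ps spacing starting at 0.
    """
    title, times, models = _read_pdb_models(path, first_chain_only=False, altloc="A")
    frames = np.array([coords for _, coords in models])
    if topology is None:
        topology = Structure(atoms=models[0][0], coords=frames[0], title=title)
    if len(times) == len(models):
        t = np.asarray(times, dtype=float)
    else:
        t = np.arange(len(models), dtype=float)
    return Trajectory(topology=topology, frames=frames, times=t)


def _format_atom_line(i: int, atom: Atom, xyz) -> str:
    name = atom.name
    # PDB alignment: 1–3 char names start in column 14 unless the element
    # symbol itself is two letters.
    if len(name) < 4 and len(atom.element) < 2:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {i % 100000:5d} {name_field} {atom.res_name:<3s} "
        f"{atom.chain:1s}{atom.res_index:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for i, (atom, xyz) in enumerate(zip(structure.atoms, structure.coords), 1):
            fh.write(_format_atom_line(i, atom, xyz))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB, one MODEL block per frame.

    Frame times are preserved in ``REMARK 250 TIME_PS`` records so that
    ``read_trajectory`` round-trips both coordinates (to the fixed-width
    0.001 Å precision) and time stamps.
    """
    top = traj.topology
    with open(path, "w") as fh:
        if top.title:
            fh.write(f"TITLE     {top.title}\n")
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            fh.write(f"REMARK 250 TIME_PS {traj.times[m]:.6f}\n")
            for i, (atom, xyz) in enumerate(zip(top.atoms, traj.frames[m]), 1):
                fh.write(_format_atom_line(i, atom, xyz))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

def _seg(name, kind, *ranges):
    return Segment(name=name, kind=kind, ranges=tuple(ranges))


def default_segments(state: str) -> SegmentTable:
    """Packaged segment tables for the open and closed Mad2 folds.

    ``state`` is ``"open"`` or ``"closed"``.  Both tables include the
    composite sheet groups (β7/8, β6/4/5, β8″/8′) used by the mass-center
    distance and network analyses, and the β5-αC loop defined as the
    inter-element gap 106–121.  The closed table has no β1 entry: in the
    closed fold the N-terminal strand has merged into the extended αA
    helix (12–37).
    """
    if state == "open":
        return SegmentTable([
            _seg("β1", "strand", (11, 13)),
            _seg("β2", "strand", (43, 49)),
            _seg("β3", "strand", (53, 58)),
            _seg("β4", "strand", (81, 90)),
            _seg("β5", "strand", (97, 105)),
            _seg("β6", "strand", (150, 160)),
            _seg("β7", "strand", (170, 174)),
            _seg("β8", "strand", (184, 191)),
            _seg("αA", "helix", (18, 37)),
            _seg("αB", "helix", (61, 75)),
            _seg("αC", "helix", (122, 142)),
            _seg("β7/8", "sheet-group", (170, 174), (184, 191)),
            _seg("β6/4/5", "sheet-group", (150, 160), (81, 90), (97, 105)),
            _seg("β5-αC loop", "loop", (106, 121)),
        ])
    if state == "closed":
        return SegmentTable([
            _seg("β2", "strand", (43, 49)),
            _seg("β3", "strand", (53, 58)),
            _seg("β4", "strand", (81, 90)),
            _seg("β5", "strand", (97, 105)),
            _seg("β6", "strand", (150, 160)),
            _seg("β8′", "strand", (177, 188)),
            _seg("β8″", "strand", (190, 200)),
            _seg("αA", "helix", (12, 37)),
            _seg("αB", "helix", (61, 75)),
            _seg("αC", "helix", (122, 142)),
            _seg("β8″/8′", "sheet-group", (177, 188), (190, 200)),
            _seg("β6/4/5", "sheet-group", (150, 160), (81, 90), (97, 105)),
            _seg("β5-αC loop", "loop", (106, 121)),
        ])
    raise ValueError(f"unknown state {state!r}: expected 'open' or 'closed'")


def load_segment_table(path) -> SegmentTable:
    """Load a segment table from plain text.

    One line per segment: ``name<TAB or spaces>class<TAB>ranges`` where
    ranges are comma-separated ``lo-hi`` closed intervals, e.g.::

        β7/8    sheet-group   170-174,184-191

    Blank lines and ``#`` comments are skipped.
    """
    segs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'name class ranges', got {line!r}"
                )
            name, kind, ranges_str = parts
            ranges = []
            for token in ranges_str.split(","):
                lo, _, hi = token.partition("-")
                ranges.append((int(lo), int(hi)))
            segs.append(Segment(name=name, kind=kind, ranges=tuple(ranges)))
    return SegmentTable(segs)
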