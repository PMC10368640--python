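"""Multi-model PDB trajectories: parsing, validation, atom selection, writing.

A trajectory is a topology (the first MODEL) plus an ``(F, N, 3)`` coordinate
array in Å and a frame interval in ns.  The frame interval travels inside the
file as ``REMARK 250 FRAME_INTERVAL_NS <x>``; files without it default to
1 ns (one structure per nanosecond, the sampling used throughout).

Internal length unit is Å (native PDB).  Derived statistics are reported in
nm; the conversion lives in :mod:`phenodyn.units` and nowhere else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "PDBFormatError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
]


class PDBFormatError(ValueError):
    """Raised for malformed or inconsistent multi-model PDB input."""


class SelectionError(ValueError):
    """Raised for selection-grammar violations or empty selections."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    Residue numbering is 1-based as in PDB files (Gly62, Glu968 of the
    DID-DAD complex are addressed by these numbers); atom indices into the
    coordinate array are 0-based.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered list of atoms with a title."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("Structure must contain at least one atom")
        keys = [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "duplicate (chain, residue, atom name) triple after altloc resolution"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number), None)
        return list(seen)


@dataclass
class Trajectory:
    """Topology plus frames.  ``frames`` is (F, N, 3) in Å; ``frame_interval`` ns."""

    topology: Structure
    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def times(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class AtomSelection:
    """Ordered unique 0-based atom indices plus the expression that made them."""

    indices: tuple[int, ...]
    descriptor: str = ""

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise SelectionError("selection is empty")
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


# --- PDB reading -----------------------------------------------------------

_REMARK_INTERVAL = re.compile(r"^REMARK\s+\d*\s*FRAME_INTERVAL_NS\s+([0-9.eE+-]+)")


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord | None, str]:
    """Parse an ATOM/HETATM line; returns (record, altloc).

    Returns ``(None, altloc)`` for skipped alternate locations.
    """
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        altloc = line[16]
        residue_name = line[17:20].strip()
        chain_id = line[21]
        icode = line[26]
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    if icode != " ":
        raise PDBFormatError(f"insertion codes unsupported (line {lineno})")
    if altloc not in (" ", "A"):
        return None, altloc
    rec = AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        position=np.array([x, y, z]),
    )
    return rec, altloc


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    The topology comes from the first MODEL; alternate locations keep
    altloc ' ' or 'A' and drop the rest.  Every subsequent MODEL must carry
    the same number of atoms, otherwise the offending MODEL is named in the
    error.  A file without MODEL records is read as a single frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    title = ""
    frame_interval: float | None = None
    models: list[list[AtomRecord]] = []
    model_numbers: list[int] = []
    current: list[AtomRecord] | None = None
    bare: list[AtomRecord] = []
    n_dropped_altloc = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rectype = line[:6]
            if rectype == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif line.startswith("REMARK"):
                m = _REMARK_INTERVAL.match(line)
                if m:
                    frame_interval = float(m.group(1))
            elif rectype == "MODEL ":
                try:
                    model_numbers.append(int(line[6:].split()[0]))
                except (ValueError, IndexError):
                    model_numbers.append(len(models) + 1)
                current = []
            elif rectype == "ENDMDL":
                if current is None:
                    raise PDBFormatError(f"ENDMDL without MODEL at line {lineno}")
                models.append(current)
                current = None
            elif rectype in ("ATOM  ", "HETATM"):
                rec, _ = _parse_atom_line(line, lineno)
                if rec is None:
                    n_dropped_altloc += 1
                    continue
                if current is not None:
                    current.append(rec)
                else:
                    bare.append(rec)

    if current is not None:  # trailing MODEL without ENDMDL
        models.append(current)

    if not models:
        if not bare:
            raise PDBFormatError(f"{path}: no coordinates found")
        models = [bare]
        model_numbers = [1]

    if n_dropped_altloc:
        logger.info("dropped %d alternate-location atoms", n_dropped_altloc)

    n0 = len(models[0])
    for i, model in enumerate(models[1:], start=1):
        if len(model) != n0:
            num = model_numbers[i] if i < len(model_numbers) else i + 1
            raise PDBFormatError(
                f"MODEL {num} has {len(model)} atoms, expected {n0} (as in MODEL "
                f"{model_numbers[0] if model_numbers else 1})"
            )

    order = np.argsort(model_numbers, kind="stable")
    models = [models[i] for i in order]

    topology = Structure(atoms=models[0], title=title)
    frames = np.array([[a.position for a in m] for m in models], dtype=float)

    if frame_interval is None:
        logger.warning(
            "%s: no FRAME_INTERVAL_NS remark; assuming 1 ns between frames", path
        )
        frame_interval = 1.0

    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


# --- PDB writing -----------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # Standard PDB convention: 1-2 char element names start in column 14.
    if len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as MODEL/ENDMDL blocks, coordinates at 3 decimals."""
    path = Path(path)
    atoms = traj.topology.atoms
    with open(path, "w") as fh:
        if traj.topology.title:
            fh.write(f"TITLE     {traj.topology.title}\n")
        fh.write(f"REMARK 250 FRAME_INTERVAL_NS {traj.frame_interval:g}\n")
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, rec in enumerate(atoms):
                x, y, z = traj.frames[f, a]
                fh.write(
                    f"ATOM  {rec.serial % 100000:5d} {_format_atom_name(rec.atom_name)}"
                    f" {rec.residue_name:<3s} {rec.chain_id}{rec.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --- atom selection --------------------------------------------------------

_TOKEN = re.compile(r"\s*(and\b|chain\b|resid\b|name\b|resname\b|[^\s]+)", re.I)


def _parse_selection(expr: str) -> list[tuple[str, object]]:
    """Parse a conjunction of ``chain X``, ``resid a[-b]``, ``name A[,B]``,
    ``resname AA`` clauses into (keyword, payload) pairs."""
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            break
        tokens.append(m.group(1))
        pos = m.end()
    clauses: list[tuple[str, object]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "and":
            i += 1
            continue
        if tok not in ("chain", "resid", "name", "resname"):
            raise SelectionError(
                f"selection grammar error at token {i} ({tokens[i]!r}) in {expr!r}"
            )
        if i + 1 >= len(tokens):
            raise SelectionError(f"missing argument for {tok!r} in {expr!r}")
        arg = tokens[i + 1]
        if tok == "resid":
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
            if not m:
                raise SelectionError(f"bad resid range {arg!r} in {expr!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            clauses.append(("resid", (lo, hi)))
        elif tok == "name":
            clauses.append(("name", tuple(a.upper() for a in arg.split(",") if a)))
        elif tok == "resname":
            clauses.append(("resname", tuple(a.upper() for a in arg.split(",") if a)))
        else:
            clauses.append(("chain", arg))
        i += 2
    if not clauses:
        raise SelectionError(f"empty selection expression {expr!r}")
    return clauses


def _matches(atom: AtomRecord, clauses: Iterable[tuple[str, object]]) -> bool:
    for kw, payload in clauses:
        if kw == "chain" and atom.chain_id != payload:
            return False
        if kw == "resid":
            lo, hi = payload  # type: ignore[misc]
            if not (lo <= atom.residue_number <= hi):
                return False
        if kw == "name" and atom.atom_name.upper() not in payload:  # type: ignore[operator]
            return False
        if kw == "resname" and atom.residue_name.upper() not in payload:  # type: ignore[operator]
            return False
    return True


def select_atoms(traj: Trajectory | Structure, expr: str) -> AtomSelection:
    """Select atoms by a conjunction expression, in topology order.

    Grammar: ``chain <id>``, ``resid <a>[-<b>]``, ``name <A>[,<B>...]``,
    ``resname <AA>`` joined by ``and``.  Empty results are an error —
    a silently empty selection would corrupt every downstream statistic.
    """
    topo = traj.topology if isinstance(traj, Trajectory) else traj
    clauses = _parse_selection(expr)
    idx = tuple(i for i, a in enumerate(topo.atoms) if _matches(a, clauses))
    if not idx:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return AtomSelection(indices=idx, descriptor=expr)
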