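"""Reading, selecting and writing coordinate ensembles.

The pipeline's universal currency is the :class:`CoordinateEnsemble`: F frames
of N atoms in Cartesian angstroms, sharing one atom table.  Structures come
from PDB files (via biotite); trajectories come either from multi-model PDB
files or from the plain-text "xyz-frames" format (one block per frame: an
atom-count line followed by one ``x y z`` line per atom, fixed atom order).

Conventions: residue numbers are kept exactly as authored in the source file
(1-based author numbering, e.g. Btk 392-659); internal atom indices are
0-based; coordinates are angstroms throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

logger = logging.getLogger(__name__)

__all__ = [
    "AtomModel",
    "CoordinateEnsemble",
    "ResidueSelection",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "select",
    "write_report",
    "write_matrix",
    "read_matrix",
    "write_table",
]

_ATOM_COLUMNS = ["atom_name", "residue_number", "residue_name", "chain_id"]


@dataclass(frozen=True)
class AtomModel:
    """A single structural model: labelled atoms plus coordinates (A).

    ``(chain_id, residue_number, atom_name)`` must be unique within a model
    and all coordinates must be finite.
    """

    atom_table: pd.DataFrame  # columns: atom_name, residue_number, residue_name, chain_id
    coords: np.ndarray  # (N, 3) float64, angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if len(self.atom_table) != len(coords):
            raise ValueError("atom table and coordinates disagree on atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in model")
        key = self.atom_table[["chain_id", "residue_number", "atom_name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate atom identifier "
                f"({dup['chain_id']}, {dup['residue_number']}, {dup['atom_name']})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_table)

    def to_ensemble(self) -> "CoordinateEnsemble":
        return CoordinateEnsemble(self.coords[None, :, :].copy(), self.atom_table)


@dataclass
class CoordinateEnsemble:
    """F frames x N atoms x 3 coordinates (A) over one shared atom table."""

    coords: np.ndarray  # (F, N, 3) float64
    atom_table: pd.DataFrame
    frame_times: np.ndarray | None = None  # optional, ns, monotone

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atom_table):
            raise ValueError("frames and atom table disagree on atom count")
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != self.n_frames or np.any(np.diff(t) < 0):
                raise ValueError("frame_times must be one monotone value per frame")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def window(self, start: int, stop: int) -> "CoordinateEnsemble":
        """Sub-ensemble over frames [start, stop)."""
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(
                f"window [{start}, {stop}) invalid for {self.n_frames} frames"
            )
        times = None if self.frame_times is None else self.frame_times[start:stop]
        return CoordinateEnsemble(self.coords[start:stop].copy(), self.atom_table, times)

    def first_model(self) -> AtomModel:
        return AtomModel(self.atom_table, self.coords[0].copy())


@dataclass(frozen=True)
class ResidueSelection:
    """An ordered residue selection resolved to atom indices for one atom name."""

    residues: tuple  # ordered ((chain_id, residue_number), ...)
    atom_indices: np.ndarray  # 0-based, one atom per residue
    atom_name: str
    labels: tuple  # per-residue display labels, e.g. "LEU522"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "atom_indices", np.asarray(self.atom_indices, dtype=int)
        )
        if len(self.residues) != len(self.atom_indices):
            raise ValueError("residues and atom_indices length mismatch")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in selection")

    def __len__(self) -> int:
        return len(self.atom_indices)


def _atom_array_to_model(arr: struc.AtomArray) -> AtomModel:
    table = pd.DataFrame(
        {
            "atom_name": arr.atom_name.astype(str),
            "residue_number": arr.res_id.astype(int),
            "residue_name": arr.res_name.astype(str),
            "chain_id": arr.chain_id.astype(str),
        }
    )
    return AtomModel(table, np.asarray(arr.coord, dtype=float))


def _filter_altloc(arr: struc.AtomArray, path) -> struc.AtomArray:
    altloc = getattr(arr, "altloc_id", None)
    if altloc is None:
        return arr
    keep = np.isin(altloc, ("", " ", ".", "A"))
    if not keep.all():
        dropped = sorted(set(altloc[~keep]))
        logger.warning(
            "%s: discarding %d alternate-location atoms (altloc %s); keeping 'A'/blank",
            path, int((~keep).sum()), ",".join(dropped),
        )
    return arr[keep]


def read_structure(path, model_index: int = 0) -> AtomModel:
    """Read one model of a PDB file as an :class:`AtomModel`.

    All ATOM/HETATM records are kept with author labels preserved.  Insertion
    codes are rejected (the pipeline's residue addressing is purely numeric);
    alternate locations other than "A"/blank are discarded with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"structure file not found: {path}")
    pdb_file = pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if not (0 <= model_index < n_models):
        raise ValueError(
            f"model_index {model_index} absent: {path} has {n_models} model(s)"
        )
    arr = pdb_file.get_structure(model=model_index + 1, altloc="all")
    ins = getattr(arr, "ins_code", None)
    if ins is not None and np.any(ins != ""):
        bad = arr.res_id[ins != ""][0]
        raise ValueError(
            f"{path}: insertion-coded residue {bad} not supported; "
            "renumber the structure first"
        )
    arr = _filter_altloc(arr, path)
    return _atom_array_to_model(arr)


def _read_xyz_frames(path, n_atoms: int) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = [ln for ln in (line.strip() for line in fh) if ln]
    pos = 0
    frame_no = 0
    while pos < len(lines):
        try:
            count = int(lines[pos])
        except ValueError as exc:
            raise ValueError(
                f"{path}: frame {frame_no}: expected atom-count line, got {lines[pos]!r}"
            ) from exc
        if count != n_atoms:
            raise ValueError(
                f"{path}: frame {frame_no} has {count} atoms, topology has {n_atoms}"
            )
        block = lines[pos + 1 : pos + 1 + count]
        if len(block) < count:
            raise ValueError(f"{path}: frame {frame_no} truncated")
        try:
            xyz = np.array([[float(v) for v in ln.split()] for ln in block])
        except ValueError as exc:
            raise ValueError(f"{path}: frame {frame_no}: malformed coordinate line") from exc
        if xyz.shape != (count, 3):
            raise ValueError(f"{path}: frame {frame_no}: expected 3 values per line")
        frames.append(xyz)
        pos += 1 + count
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: zero frames")
    return np.stack(frames)


def read_ensemble(topology, trajectory=None, format: str = "multimodel-pdb") -> CoordinateEnsemble:
    """Read a coordinate ensemble.

    ``multimodel-pdb``: every model of ``trajectory`` (default: the topology
    file itself) becomes a frame.  ``xyz-frames``: plain-text frame blocks,
    atom order fixed by the topology.  Frames are kept in file order and the
    atom table is taken from the topology.
    """
    topo = read_structure(topology, model_index=0)
    if format == "multimodel-pdb":
        traj_path = Path(trajectory if trajectory is not None else topology)
        pdb_file = pdbio.PDBFile.read(str(traj_path))
        n_models = pdb_file.get_model_count()
        if n_models < 1:
            raise ValueError(f"{traj_path}: zero frames")
        frames = []
        for m in range(n_models):
            model = read_structure(traj_path, model_index=m)
            if model.n_atoms != topo.n_atoms:
                raise ValueError(
                    f"{traj_path}: frame {m} has {model.n_atoms} atoms, "
                    f"topology has {topo.n_atoms}"
                )
            frames.append(model.coords)
        coords = np.stack(frames)
    elif format == "xyz-frames":
        if trajectory is None:
            raise ValueError("xyz-frames format requires a trajectory path")
        coords = _read_xyz_frames(trajectory, topo.n_atoms)
    else:
        raise ValueError(f"unknown trajectory format: {format!r}")
    return CoordinateEnsemble(coords, topo.atom_table)


def _model_to_atom_array(table: pd.DataFrame, coords: np.ndarray) -> struc.AtomArray:
    n = len(table)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = table["atom_name"].to_numpy(dtype="U6")
    arr.res_id = table["residue_number"].to_numpy(dtype=int)
    arr.res_name = table["residue_name"].to_numpy(dtype="U5")
    arr.chain_id = table["chain_id"].to_numpy(dtype="U4")
    arr.element = np.array(
        [re.sub(r"[^A-Za-z]", "", n_)[:1] or "C" for n_ in table["atom_name"]],
        dtype="U2",
    )
    return arr


def write_ensemble(ensemble: CoordinateEnsemble, path, format: str = "xyz-frames") -> None:
    """Write an ensemble as xyz-frames text or as a multi-model PDB.

    xyz-frames coordinates are written with ``repr`` so a write-then-read
    round trip reproduces them bit-identically.
    """
    path = Path(path)
    if format == "xyz-frames":
        with open(path, "w") as fh:
            for frame in ensemble.coords:
                fh.write(f"{ensemble.n_atoms}\n")
                for x, y, z in frame:
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
    elif format == "multimodel-pdb":
        stack = struc.stack(
            [_model_to_atom_array(ensemble.atom_table, f) for f in ensemble.coords]
        )
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    else:
        raise ValueError(f"unknown trajectory format: {format!r}")


def write_structure_pdb(model: AtomModel, path) -> None:
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_model_to_atom_array(model.atom_table, model.coords))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _parse_residue_expression(expr) -> list[int]:
    """Parse "439-451,460" style range expressions (inclusive ranges)."""
    if isinstance(expr, (list, tuple, np.ndarray)):
        numbers = [int(v) for v in expr]
    else:
        numbers = []
        for part in str(expr).split(","):
            part = part.strip()
            if not part:
                continue
            m = re.fullmatch(r"(-?\d+)\s*-\s*(-?\d+)", part)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if hi < lo:
                    raise ValueError(f"descending range {part!r}")
                numbers.extend(range(lo, hi + 1))
            else:
                numbers.append(int(part))
    seen = set()
    for n in numbers:
        if n in seen:
            raise ValueError(f"residue {n} specified more than once")
        seen.add(n)
    return numbers


def residue_label(residue_name: str, residue_number: int, chain_id: str = "",
                  multi_chain: bool = False) -> str:
    base = f"{residue_name}{residue_number}"
    return f"{chain_id}:{base}" if multi_chain else base


def select(obj, residues, atom_name: str = "CA", chain_id: str | None = None) -> ResidueSelection:
    """Resolve a residue-range expression to atom indices.

    ``obj`` is an :class:`AtomModel` or :class:`CoordinateEnsemble`.  Every
    residue must resolve to exactly one atom of the requested name.  Multi-
    chain inputs must name a chain; single-chain inputs default to it.
    """
    table = obj.atom_table
    chains = sorted(table["chain_id"].unique())
    if chain_id is None:
        if len(chains) > 1:
            raise ValueError(
                f"model has chains {chains}; selection must name one"
            )
        chain_id = chains[0]
    elif chain_id not in chains:
        raise ValueError(f"chain {chain_id!r} not present (have {chains})")
    multi = len(chains) > 1
    numbers = _parse_residue_expression(residues)
    sub = table[(table["chain_id"] == chain_id) & (table["atom_name"] == atom_name)]
    by_resnum = dict(zip(sub["residue_number"], sub.index))
    indices, labels, res_keys = [], [], []
    for num in numbers:
        if num not in by_resnum:
            raise ValueError(
                f"residue {num} (chain {chain_id}, atom {atom_name}) not found"
            )
        idx = by_resnum[num]
        indices.append(idx)
        row = table.loc[idx]
        labels.append(residue_label(row["residue_name"], num, chain_id, multi))
        res_keys.append((chain_id, num))
    return ResidueSelection(tuple(res_keys), np.array(indices), atom_name, tuple(labels))


def atoms_of_residue(obj, residue_number: int, chain_id: str | None = None,
                     atom_names: Sequence[str] | None = None,
                     sidechain_only: bool = False) -> np.ndarray:
    """Atom indices of one residue, optionally restricted by name/side chain."""
    table = obj.atom_table
    chains = sorted(table["chain_id"].unique())
    if chain_id is None:
        if len(chains) > 1:
            raise ValueError("multi-chain model: chain_id required")
        chain_id = chains[0]
    mask = (table["chain_id"] == chain_id) & (table["residue_number"] == residue_number)
    if atom_names is not None:
        mask &= table["atom_name"].isin(list(atom_names))
    if sidechain_only:
        mask &= ~table["atom_name"].isin(["N", "CA", "C", "O", "OXT", "H", "HA"])
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) == 0:
        raise ValueError(f"no atoms matched residue {residue_number}")
    return idx


# ---------------------------------------------------------------------------
# plain-text outputs
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with one header line; floats via repr for determinism."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_matrix(values: np.ndarray, labels: Sequence[str], path) -> None:
    """Square matrix as a whitespace grid with a label header row/column.

    Masked (absent) entries are written as ``nan``.
    """
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise ValueError("matrix/labels shape mismatch")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("label " + " ".join(labels) + "\n")
        for lab, row in zip(labels, values):
            fh.write(lab + " " + " ".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().split()
        labels = header[1:]
        rows = []
        for line in fh:
            parts = line.split()
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows), labels


def write_report(results: dict, out_dir) -> list[Path]:
    """Write pipeline products as deterministic plain-text tables.

    ``results`` maps product names to pandas DataFrames (written as TSV) or
    to ``(matrix, labels)`` pairs (written as labelled grids).  Returns the
    written paths.  Identical inputs yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not results:
        raise ValueError("nothing to report")
    written = []
    for name in sorted(results):
        value = results[name]
        if isinstance(value, pd.DataFrame):
            if len(value) == 0:
                raise ValueError(f"product {name!r} is empty; nothing to report")
            target = out_dir / f"{name}.tsv"
            write_table(value, target)
        else:
            matrix, labels = value
            target = out_dir / f"{name}.txt"
            write_matrix(matrix, labels, target)
        written.append(target)
    return written
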