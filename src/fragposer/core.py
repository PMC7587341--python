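"""Structure/trajectory data model, PDB and XYZ I/O, rigid superposition and RMSD.

Coordinates are in angstroms throughout.  Atom correspondence is by input
order unless an explicit index mapping is given.  Water molecules are
recognised by a configurable residue-name whitelist (TIP3P-style waters).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bstinfo
import biotite.structure.io.pdb as bstpdb

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

# fallback masses (u) for elements biotite does not know
_FALLBACK_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                    "S": 32.06, "P": 30.974, "NA": 22.990, "CL": 35.45}


class StructureError(ValueError):
    """Contract violation in a structure-level operation."""


@dataclass
class Structure:
    """A molecular structure: parallel per-atom arrays.

    Invariants: coordinates finite, ``atom_id`` unique, all arrays share
    the same length.
    """

    atom_id: np.ndarray          # int
    atom_name: np.ndarray       # str
    element: np.ndarray         # str, upper case
    res_name: np.ndarray        # str
    res_id: np.ndarray          # int
    chain: np.ndarray           # str
    coords: np.ndarray          # (n, 3) float, Å
    occupancy: np.ndarray       # float in [0, 1]
    b_factor: np.ndarray        # float, Å² scale
    water_resnames: frozenset = WATER_RESNAMES

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("atom_id", "atom_name", "element", "res_name",
                     "res_id", "chain", "occupancy", "b_factor"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise StructureError(f"field {name!r} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if len(np.unique(self.atom_id)) != n:
            raise StructureError("atom ids are not unique")

    def __len__(self) -> int:
        return len(self.coords)

    # ---- role masks -------------------------------------------------
    def is_water(self) -> np.ndarray:
        return np.isin(self.res_name, list(self.water_resnames))

    def water_oxygen_indices(self) -> np.ndarray:
        return np.where(self.is_water() & (self.element == "O"))[0]

    def heavy_indices(self) -> np.ndarray:
        return np.where(self.element != "H")[0]

    # ---- subsetting -------------------------------------------------
    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices)
        return Structure(
            atom_id=self.atom_id[idx], atom_name=self.atom_name[idx],
            element=self.element[idx], res_name=self.res_name[idx],
            res_id=self.res_id[idx], chain=self.chain[idx],
            coords=self.coords[idx], occupancy=self.occupancy[idx],
            b_factor=self.b_factor[idx], water_resnames=self.water_resnames)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def transformed(self, sup: "Superposition") -> "Structure":
        return self.with_coords(sup.apply(self.coords))


def select_atoms(structure: Structure, *, name=None, resname=None,
                 chain=None, element=None, res_id=None,
                 within_of: np.ndarray | None = None,
                 radius: float | None = None) -> np.ndarray:
    """Index array of atoms matching all given criteria.

    ``within_of``/``radius`` restricts to atoms within ``radius`` Å of any
    point in ``within_of``.
    """
    mask = np.ones(len(structure), dtype=bool)
    for value, arr in ((name, structure.atom_name), (resname, structure.res_name),
                       (chain, structure.chain), (element, structure.element),
                       (res_id, structure.res_id)):
        if value is not None:
            values = [value] if np.isscalar(value) or isinstance(value, str) else list(value)
            mask &= np.isin(arr, values)
    if within_of is not None:
        pts = np.asarray(within_of, dtype=float).reshape(-1, 3)
        d2 = ((structure.coords[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        mask &= (d2.min(axis=1) <= float(radius) ** 2)
    return np.where(mask)[0]


@dataclass
class Trajectory:
    """An ordered frame sequence over a fixed topology.

    Every frame has the same atom count as ``topology``; ``frame_interval``
    is the time between frames (ps by convention).  ``box`` holds periodic
    box edge lengths when present.
    """

    topology: Structure
    frames: np.ndarray                    # (n_frames, n_atoms, 3)
    frame_interval: float = 1.0
    box: np.ndarray | None = None         # (3,) edge lengths Å

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise StructureError(
                f"frames shape {self.frames.shape} incompatible with topology "
                f"of {len(self.topology)} atoms")
        if not self.frame_interval > 0:
            raise StructureError("frame_interval must be > 0")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Superposition:
    """Rigid transform (proper rotation + translation) with the post-fit RMSD."""

    rotation: np.ndarray      # (3, 3), orthogonal, det +1
    translation: np.ndarray   # (3,)
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two point sets, no refitting.

    Correspondence is positional: ``a[i]`` pairs with ``b[i]``.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise StructureError(f"point count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise StructureError("empty point sets")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> Superposition:
    """Least-squares optimal rigid superposition (Kabsch, via SVD).

    Returns the transform taking ``mobile`` onto ``reference`` and the
    post-fit (weighted) RMSD.  Degenerate (collinear or coincident) point
    sets are rejected.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise StructureError(f"point count mismatch: {mob.shape[0]} vs {ref.shape[0]}")
    if mob.shape[0] < 3:
        raise StructureError("need at least 3 points for superposition")
    if weights is None:
        w = np.ones(mob.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mob.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise StructureError("weights must be nonnegative with positive sum")
    w = w / w.sum()

    cm = w @ mob
    cr = w @ ref
    mc, rc = mob - cm, ref - cr
    # collinearity check: rank of the centred mobile set
    if np.linalg.matrix_rank(mc * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise StructureError("degenerate geometry: points are collinear or coincident")
    h = (mc * w[:, None]).T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = mob @ rot.T + trans
    fit = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum()))
    return Superposition(rotation=rot, translation=trans, fit_rmsd=fit)


def element_mass(element: str) -> float:
    el = element.capitalize()
    try:
        m = bstinfo.mass(el)
    except Exception:
        m = None
    if m is None or not np.isfinite(m):
        m = _FALLBACK_MASSES.get(element.upper())
    if m is None:
        raise StructureError(f"unknown element {element!r}")
    return float(m)


def center_of_mass(structure: Structure, indices=None) -> np.ndarray:
    """Mass-weighted mean position of an atom subset (all atoms by default)."""
    sub = structure if indices is None else structure.subset(indices)
    if len(sub) == 0:
        raise StructureError("center of mass of an empty atom subset")
    masses = np.array([element_mass(e) for e in sub.element])
    return masses @ sub.coords / masses.sum()


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(arr: bst.AtomArray, water_resnames=WATER_RESNAMES) -> Structure:
    n = arr.array_length()
    atom_id = (arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, n + 1))
    occ = (arr.get_annotation("occupancy") if "occupancy" in arr.get_annotation_categories()
           else np.ones(n))
    bf = (arr.get_annotation("b_factor") if "b_factor" in arr.get_annotation_categories()
          else np.zeros(n))
    if len(np.unique(atom_id)) != n:     # duplicated serials in sloppy files
        atom_id = np.arange(1, n + 1)
    return Structure(
        atom_id=np.asarray(atom_id, dtype=int), atom_name=arr.atom_name.astype(str),
        element=np.char.upper(arr.element.astype(str)), res_name=arr.res_name.astype(str),
        res_id=np.asarray(arr.res_id, dtype=int), chain=arr.chain_id.astype(str),
        coords=arr.coord, occupancy=np.asarray(occ, dtype=float),
        b_factor=np.asarray(bf, dtype=float), water_resnames=water_resnames)


def _to_atom_array(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(len(s))
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = s.chain.astype("U4")
    arr.res_id = s.res_id.astype(int)
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.hetero = s.is_water() | ~np.isin(
        s.res_name, np.array(sorted(_STANDARD_RESNAMES)))
    arr.set_annotation("atom_id", s.atom_id.astype(int))
    arr.set_annotation("occupancy", s.occupancy.astype(float))
    arr.set_annotation("b_factor", s.b_factor.astype(float))
    return arr


_STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}


def read_structure(path, model_index: int = 0,
                   water_resnames=WATER_RESNAMES) -> Structure:
    """Read one model of a PDB file.

    When alternate locations are present only the highest-occupancy
    alternate of each residue is retained.  Waters, ions and hetero groups
    are kept.
    """
    try:
        pdb_file = bstpdb.PDBFile.read(path)
    except (OSError, UnicodeDecodeError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise IOError(f"{path}: no atom records (empty or not a PDB file)")
    if not 0 <= model_index < n_models:
        raise IndexError(f"model_index {model_index} out of range ({n_models} models)")
    arr = pdb_file.get_structure(model=model_index + 1, altloc="occupancy",
                                 extra_fields=["atom_id", "occupancy", "b_factor"])
    return _from_atom_array(arr, water_resnames)


def read_model_count(path) -> int:
    return bstpdb.PDBFile.read(path).get_model_count()


def write_structure(structure: Structure, path) -> None:
    if len(structure) == 0:   # biotite rejects empty arrays; write END only
        with open(path, "w") as fh:
            fh.write("END\n")
        return
    pdb_file = bstpdb.PDBFile()
    pdb_file.set_structure(_to_atom_array(structure))
    pdb_file.write(path)


def read_trajectory(path, frame_interval: float = 1.0,
                    water_resnames=WATER_RESNAMES) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a trajectory."""
    path = os.fspath(path)
    if path.lower().endswith(".xyz"):
        return _read_xyz(path, frame_interval)
    pdb_file = bstpdb.PDBFile.read(path)
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise IOError(f"{path}: no atom records")
    top = _from_atom_array(
        pdb_file.get_structure(model=1, altloc="occupancy",
                               extra_fields=["atom_id", "occupancy", "b_factor"]),
        water_resnames)
    frames = np.stack([pdb_file.get_coord(model=m) for m in range(1, n_models + 1)])
    return Trajectory(topology=top, frames=frames, frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (or XYZ if path ends in .xyz)."""
    path = os.fspath(path)
    if path.lower().endswith(".xyz"):
        _write_xyz(traj, path)
        return
    stack = bst.AtomArrayStack(traj.n_frames, len(traj.topology))
    template = _to_atom_array(traj.topology)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.frames.astype(np.float32)
    pdb_file = bstpdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


# XYZ: minimal multi-frame reader/writer (element symbol + 3 coordinates)

def _read_xyz(path, frame_interval: float) -> Trajectory:
    frames, elements = [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise IOError(f"{path}: truncated XYZ frame")
        els = [ln.split()[0] for ln in block]
        xyz = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        if elements is None:
            elements = els
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise IOError(f"{path}: empty XYZ file")
    n = len(elements)
    top = Structure(
        atom_id=np.arange(1, n + 1), atom_name=np.array(elements),
        element=np.char.upper(np.array(elements)), res_name=np.array(["UNK"] * n),
        res_id=np.ones(n, dtype=int), chain=np.array(["A"] * n),
        coords=frames[0], occupancy=np.ones(n), b_factor=np.zeros(n))
    return Trajectory(topology=top, frames=np.stack(frames),
                      frame_interval=frame_interval)


def _write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.frames):
            fh.write(f"{len(traj.topology)}\nframe {f}\n")
            for el, (x, y, z) in zip(traj.topology.element, frame):
                fh.write(f"{el:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def align_trajectory(traj: Trajectory, selection: np.ndarray,
                     reference_frame: int = 0) -> Trajectory:
    """Superpose every frame onto a reference frame using a fixed atom selection."""
    sel = np.asarray(selection)
    ref = traj.frames[reference_frame][sel]
    out = np.empty_like(traj.frames)
    for i, frame in enumerate(traj.frames):
        sup = kabsch_superpose(frame[sel], ref)
        out[i] = sup.apply(frame)
    return Trajectory(topology=traj.topology, frames=out,
                      frame_interval=traj.frame_interval, box=traj.box)
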