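"""Seeded synthetic-fixture generators with machine-readable ground truth.

Every generator is a pure function of its arguments plus a seed
(regenerating with the same seed is bit-identical) and returns the fixture
together with a JSON-serialisable truth record sufficient to score the
downstream analysis without re-deriving anything.  A 20-residue
polyalanine helix stands in for the protein so PDB selections and
superpositions are exercised realistically without any downloads; none of
the fixtures aim at physically realistic water structure or energetics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import Structure, StructureError, Trajectory
from .hydration import DEFAULT_EDGE
from .poses import PoseEnsemble
from .sumd import LangevinPropagator, LigandState, SuMDConfig

MIN_WATER_SEPARATION = 2.8   # Å, minimum O–O contact distance


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

def polyalanine_scaffold(n_res: int = 20, origin=(0.0, 0.0, 0.0)) -> Structure:
    """Idealised polyalanine α-helix (N, CA, C, O, CB per residue).

    Geometry is schematic (helical CA trace with fixed local offsets), good
    enough to exercise name-based selections and superposition.
    """
    rise, radius, turn = 1.5, 2.3, np.deg2rad(100.0)
    offsets = {"N": np.array([-1.20, -0.60, -0.50]),
               "CA": np.zeros(3),
               "C": np.array([1.20, 0.60, 0.50]),
               "O": np.array([1.40, 1.70, 0.30]),
               "CB": np.array([-0.40, 1.30, -0.80])}
    names, coords, res_ids = [], [], []
    for i in range(n_res):
        ca = np.array([radius * np.cos(i * turn), radius * np.sin(i * turn),
                       i * rise]) + np.asarray(origin, dtype=float)
        for name in ("N", "CA", "C", "O", "CB"):
            names.append(name)
            coords.append(ca + offsets[name])
            res_ids.append(i + 1)
    n = len(names)
    return Structure(
        atom_id=np.arange(1, n + 1), atom_name=np.array(names),
        element=np.array([nm[0] for nm in names]), res_name=np.array(["ALA"] * n),
        res_id=np.array(res_ids), chain=np.array(["A"] * n),
        coords=np.array(coords), occupancy=np.ones(n),
        b_factor=np.full(n, 15.0))


def _water_structure(n_waters: int, coords: np.ndarray, b_factors=None,
                     start_atom_id: int = 1, start_res_id: int = 1001
                     ) -> Structure:
    b = np.zeros(n_waters) if b_factors is None else np.asarray(b_factors)
    return Structure(
        atom_id=np.arange(start_atom_id, start_atom_id + n_waters),
        atom_name=np.array(["O"] * n_waters), element=np.array(["O"] * n_waters),
        res_name=np.array(["HOH"] * n_waters),
        res_id=np.arange(start_res_id, start_res_id + n_waters),
        chain=np.array(["W"] * n_waters), coords=coords,
        occupancy=np.ones(n_waters), b_factor=b)


def _concat(a: Structure, b: Structure) -> Structure:
    return Structure(
        atom_id=np.concatenate([a.atom_id, a.atom_id.max(initial=0) + 1
                                + np.arange(len(b))]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        element=np.concatenate([a.element, b.element]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        res_id=np.concatenate([a.res_id, b.res_id]),
        chain=np.concatenate([a.chain, b.chain]),
        coords=np.concatenate([a.coords, b.coords]),
        occupancy=np.concatenate([a.occupancy, b.occupancy]),
        b_factor=np.concatenate([a.b_factor, b.b_factor]))


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# water trajectory with planted stationary sites
# ---------------------------------------------------------------------------

def gen_water_trajectory(n_frames: int = 500, n_tethered: int = 3,
                         tether_sd: float = 0.3, n_bulk: int = 50,
                         box: float = 24.0, seed: int = 0,
                         frame_interval: float = 20.0,
                         bulk_step_sd: float = 1.0,
                         site_positions=None,
                         include_protein: bool = True
                         ) -> tuple[Trajectory, dict]:
    """Water trajectory with ``n_tethered`` stationary sites amid diffusing bulk.

    Tethered waters jitter (Gaussian, ``tether_sd`` Å) around fixed points
    placed near centers of the canonical analysis grid (origin at the box
    corner, 1.5 Å edge) so a small tether spread keeps each site inside a
    single cell; bulk waters random-walk (``bulk_step_sd`` Å per axis per
    frame) and wrap in the periodic box.  The truth record carries the
    planted positions and their canonical grid cells.
    """
    rng = np.random.default_rng(seed)
    if site_positions is None:
        sites = _sample_tether_points(rng, n_tethered, box)
    else:
        sites = np.asarray(site_positions, dtype=float).reshape(-1, 3)
    if len(sites) > 1:
        d = np.linalg.norm(sites[:, None] - sites[None, :], axis=-1)
        if d[np.triu_indices(len(sites), 1)].min() < MIN_WATER_SEPARATION:
            raise StructureError(
                f"planted sites closer than {MIN_WATER_SEPARATION} Å")

    n_tethered = len(sites)
    teth = (sites[None, :, :]
            + rng.normal(0.0, tether_sd, size=(n_frames, n_tethered, 3))
            if n_tethered else np.empty((n_frames, 0, 3)))
    if n_bulk:
        start = rng.uniform(0.0, box, size=(n_bulk, 3))
        steps = rng.normal(0.0, bulk_step_sd, size=(n_frames, n_bulk, 3))
        steps[0] = 0.0
        bulk = np.mod(start[None] + np.cumsum(steps, axis=0), box)
    else:
        bulk = np.empty((n_frames, 0, 3))
    water_frames = np.concatenate([teth, bulk], axis=1)

    waters = _water_structure(n_tethered + n_bulk, water_frames[0])
    if include_protein:
        scaffold = polyalanine_scaffold(origin=(box + 6.0, 0.0, 0.0))
        top = _concat(scaffold, waters)
        prot = np.broadcast_to(scaffold.coords, (n_frames,) + scaffold.coords.shape)
        frames = np.concatenate([prot, water_frames], axis=1)
    else:
        top = waters
        frames = water_frames
    traj = Trajectory(topology=top, frames=frames,
                      frame_interval=frame_interval,
                      box=np.array([box, box, box]))
    truth = {"kind": "water_trajectory", "seed": int(seed),
             "n_frames": int(n_frames), "n_tethered": int(n_tethered),
             "tether_sd": float(tether_sd), "n_bulk": int(n_bulk),
             "box": float(box), "frame_interval": float(frame_interval),
             "bulk_step_sd": float(bulk_step_sd),
             "site_positions": sites,
             "site_cells": np.floor(sites / DEFAULT_EDGE).astype(int)}
    return traj, truth


def _sample_tether_points(rng, n: int, box: float) -> np.ndarray:
    """Tether points near canonical-grid cell centers, mutually separated."""
    n_cells = int(box / DEFAULT_EDGE)
    if n == 0:
        return np.empty((0, 3))
    pts = []
    for _ in range(10000):
        cell = rng.integers(1, n_cells - 1, size=3)
        p = (cell + 0.5) * DEFAULT_EDGE + rng.uniform(-0.25, 0.25, size=3)
        if all(np.linalg.norm(p - q) >= 2 * MIN_WATER_SEPARATION for q in pts):
            pts.append(p)
        if len(pts) == n:
            return np.array(pts)
    raise StructureError("could not place tether points with required separation")


# ---------------------------------------------------------------------------
# crystal ensemble with conserved waters
# ---------------------------------------------------------------------------

def gen_crystal_ensemble(n_structures: int = 11, n_conserved: int = 4,
                         n_random_per_structure: int = 20,
                         jitter_sd: float = 0.3, seed: int = 0,
                         missing_rate: float = 0.0
                         ) -> tuple[list[Structure], Structure, dict]:
    """Crystal ensemble: a shared scaffold, ``n_conserved`` waters present
    (jittered) in every structure, plus random spurious waters, the whole
    structure under a random rigid transform per crystal.

    ``missing_rate`` drops each conserved water from a structure with that
    probability (for partial-conservation tests).  Conserved waters get low
    B-factors (5–20), random waters high ones (30–80).  Returns
    (structures, reference, truth); the reference is the untransformed
    scaffold + conserved waters.
    """
    rng = np.random.default_rng(seed)
    scaffold = polyalanine_scaffold()
    lo = scaffold.coords.min(axis=0) - 3.0
    hi = scaffold.coords.max(axis=0) + 3.0
    cons = []
    for _ in range(10000):
        if len(cons) == n_conserved:
            break
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= 5.0 for q in cons):
            cons.append(p)
    cons = np.array(cons).reshape(-1, 3)
    if len(cons) != n_conserved:
        raise StructureError("could not place conserved water positions")

    ref_waters = _water_structure(n_conserved, cons,
                                  b_factors=rng.uniform(5, 20, n_conserved))
    reference = _concat(scaffold, ref_waters)

    structures, membership = [], []
    for si in range(n_structures):
        present = rng.random(n_conserved) >= missing_rate
        c_pos = cons[present] + rng.normal(0, jitter_sd, size=(present.sum(), 3))
        c_b = rng.uniform(5, 20, int(present.sum()))
        r_pos = rng.uniform(lo - 2.0, hi + 2.0, size=(n_random_per_structure, 3))
        r_b = rng.uniform(30, 80, n_random_per_structure)
        waters = _water_structure(
            int(present.sum()) + n_random_per_structure,
            np.concatenate([c_pos, r_pos]), np.concatenate([c_b, r_b]))
        s = _concat(scaffold, waters)
        rot = _random_rotation(rng)
        trans = rng.uniform(-10, 10, 3)
        s = s.with_coords(s.coords @ rot.T + trans)
        structures.append(s)
        membership.append(present.astype(int))
    truth = {"kind": "crystal_ensemble", "seed": int(seed),
             "n_structures": int(n_structures), "n_conserved": int(n_conserved),
             "n_random_per_structure": int(n_random_per_structure),
             "jitter_sd": float(jitter_sd), "missing_rate": float(missing_rate),
             "conserved_positions": cons,
             "membership": np.array(membership)}
    return structures, reference, truth


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


# ---------------------------------------------------------------------------
# funnel ligand-recognition system
# ---------------------------------------------------------------------------

#: Documented funnel preset for supervision-effectiveness studies: a
#: Gaussian well (depth 5 kcal/mol, width 3 Å) whose capture radius is
#: small against the 30 Å start distance, diffusion kT/gamma = 0.6 Å²/ps.
#: Under the paired supervision budget (5 ps steps, 5 checkpoints, 400
#: attempted steps = 2 ns attempted time) plain dynamics rarely reaches
#: the 5 Å binding distance (unsupervised binding probability < 0.2,
#: estimated over 50 seeds by brute-force simulation) while the
#: supervised controller almost always does.
FUNNEL_PRESET = {
    "well_depth": 5.0, "sigma": 3.0, "gamma": 1.0, "kT": 0.6, "dt": 0.05,
    "start_distance": 30.0, "step_duration": 5.0, "n_checkpoints": 5,
    "max_attempted_steps": 400, "binding_distance": 5.0,
    "extension_duration": 25.0,
}


def gen_funnel_system(well_depth: float = FUNNEL_PRESET["well_depth"],
                      sigma: float = FUNNEL_PRESET["sigma"],
                      gamma: float = FUNNEL_PRESET["gamma"],
                      kT: float = FUNNEL_PRESET["kT"],
                      start_distance: float = FUNNEL_PRESET["start_distance"],
                      dt: float = FUNNEL_PRESET["dt"],
                      seed: int = 0
                      ) -> tuple[LangevinPropagator, LigandState, dict]:
    """Funnel-potential system: a Langevin propagator with the well at the
    origin and a point ligand started ``start_distance`` Å away in a
    seed-determined random direction."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    prop = LangevinPropagator(well_depth=well_depth, sigma=sigma,
                              gamma=gamma, kT=kT, dt=dt)
    state = LigandState(position=direction * start_distance)
    truth = {"kind": "funnel_system", "seed": int(seed),
             "well_depth": float(well_depth), "sigma": float(sigma),
             "gamma": float(gamma), "kT": float(kT), "dt": float(dt),
             "start_distance": float(start_distance),
             "center": prop.center, "start_position": state.position}
    return prop, state, truth


def funnel_config(seed: int = 0, **overrides) -> SuMDConfig:
    """Supervision config paired with :data:`FUNNEL_PRESET`."""
    kw = dict(step_duration=FUNNEL_PRESET["step_duration"],
              n_checkpoints=FUNNEL_PRESET["n_checkpoints"],
              max_attempted_steps=FUNNEL_PRESET["max_attempted_steps"],
              binding_distance=FUNNEL_PRESET["binding_distance"],
              start_distance=FUNNEL_PRESET["start_distance"],
              extension_duration=FUNNEL_PRESET["extension_duration"],
              rng_seed=seed)
    kw.update(overrides)
    return SuMDConfig(**kw)


# ---------------------------------------------------------------------------
# pose ensemble with planted clusters
# ---------------------------------------------------------------------------

def gen_pose_ensemble(k_true: int = 3, center_sep: float = 8.0,
                      sigma: float = 0.5, n_per_cluster: int = 100,
                      n_noise: int = 15, n_atoms: int = 8, seed: int = 0
                      ) -> tuple[PoseEnsemble, dict]:
    """Pose sets forming ``k_true`` planted Gaussian clusters plus noise.

    Cluster members are a fixed ligand template translated to its cluster
    center with per-atom Gaussian jitter (``sigma`` Å); noise poses have
    every atom uniform in the bounding box — dense nowhere.  Truth labels:
    cluster index per member, −1 for noise.
    """
    rng = np.random.default_rng(seed)
    template = rng.uniform(-1.5, 1.5, size=(n_atoms, 3))
    centers = np.zeros((k_true, 3))
    for i in range(1, k_true):
        centers[i] = centers[i - 1]
        centers[i, (i - 1) % 3] += center_sep
    sets, labels = [], []
    for c in range(k_true):
        jitter = rng.normal(0, sigma, size=(n_per_cluster, n_atoms, 3))
        for j in range(n_per_cluster):
            sets.append(template + centers[c] + jitter[j])
            labels.append(c)
    lo = centers.min(axis=0) - 2 * center_sep
    hi = centers.max(axis=0) + 2 * center_sep
    for _ in range(n_noise):
        sets.append(rng.uniform(lo, hi, size=(n_atoms, 3)))
        labels.append(-1)
    ens = PoseEnsemble(coords=np.stack(sets), source_ids=np.zeros(len(sets), int))
    truth = {"kind": "pose_ensemble", "seed": int(seed), "k_true": int(k_true),
             "center_sep": float(center_sep), "sigma": float(sigma),
             "n_per_cluster": int(n_per_cluster), "n_noise": int(n_noise),
             "n_atoms": int(n_atoms), "template": template,
             "centers": centers, "labels": np.array(labels)}
    return ens, truth
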