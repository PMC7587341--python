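"""Grid-based hydration-site mapping over an MD trajectory.

For every cell of a fixed 3-D grid two occupancy percentages are computed:

* ``%Oall`` — fraction of frames in which the cell contains any water
  oxygen;
* ``%O_RMSF`` — the same fraction counting only *stationary* waters, i.e.
  waters whose positional root-mean-square fluctuation over a centred time
  window is below a cutoff (default 1.4 Å).

Cells whose ``%O_RMSF`` exceeds a threshold (default 25) are exported as
hydration sites and can be cross-checked against low-B-factor
crystallographic waters.

The trajectory must already be aligned on the protein (the grid is fixed in
space); :func:`fragposer.core.align_trajectory` does this.  When periodic
box lengths are present, water positions are wrapped into the primary box
before cell assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Structure, Trajectory, StructureError, write_structure

OUTSIDE = -1   # sentinel cell index for oxygens outside the grid

#: default cell edge, Å.  1.5 < 2.8/sqrt(3) so two water oxygens at contact
#: distance (O–O >= 2.8 Å) can never share a cell.
DEFAULT_EDGE = 1.5
DEFAULT_RMSF_CUTOFF = 1.4    # Å
DEFAULT_SITE_THRESHOLD = 25.0  # %O_RMSF


@dataclass
class GridSpec:
    """Axis-aligned analysis grid: origin, cell edge (Å) and cell counts."""

    origin: np.ndarray
    edge: float = DEFAULT_EDGE
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        if not self.edge > 0:
            raise StructureError("grid edge must be > 0")
        if any(d <= 0 for d in self.dims):
            raise StructureError("grid dims must be positive")

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 3) array of cell centers in C (row-major) flat order."""
        nx, ny, nz = self.dims
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + (idx + 0.5) * self.edge

    def flat_index(self, ijk: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.dims
        return (ijk[..., 0] * ny + ijk[..., 1]) * nz + ijk[..., 2]

    @classmethod
    def around(cls, center, radius: float, edge: float = DEFAULT_EDGE) -> "GridSpec":
        """Cubic grid covering a sphere of ``radius`` Å around ``center``."""
        center = np.asarray(center, dtype=float)
        n = int(np.ceil(2 * radius / edge))
        origin = center - n * edge / 2.0
        return cls(origin=origin, edge=edge, dims=(n, n, n))


@dataclass
class OccupancyMap:
    grid: GridSpec
    occ_all: np.ndarray      # (nx, ny, nz), percent 0–100
    occ_rmsf: np.ndarray     # (nx, ny, nz), percent 0–100
    n_frames: int
    rmsf_cutoff: float
    window: int              # frames used for the RMSF window

    def to_frame(self, nonzero_only: bool = True) -> pd.DataFrame:
        """Tabular dump: cell indices, centers and both occupancies."""
        idx = np.indices(self.grid.dims).reshape(3, -1).T
        df = pd.DataFrame(idx, columns=["ix", "iy", "iz"])
        centers = self.grid.cell_centers()
        df[["x", "y", "z"]] = centers
        df["occ_all"] = self.occ_all.ravel()
        df["occ_rmsf"] = self.occ_rmsf.ravel()
        if nonzero_only:
            df = df[df["occ_all"] > 0].reset_index(drop=True)
        return df


@dataclass
class HydrationSite:
    cell_center: np.ndarray
    occ_rmsf: float
    occ_all: float


def assign_waters(frame_coords: np.ndarray, grid: GridSpec,
                  box: np.ndarray | None = None) -> np.ndarray:
    """Flat cell index per water oxygen; ``OUTSIDE`` for oxygens off-grid.

    The convention is half-open: a coordinate exactly on a cell boundary
    belongs to the higher-index cell (floor of ``(xyz - origin)/edge``).
    """
    xyz = np.asarray(frame_coords, dtype=float).reshape(-1, 3)
    if box is not None:
        xyz = np.mod(xyz, np.asarray(box, dtype=float))
    ijk = np.floor((xyz - grid.origin) / grid.edge).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(grid.dims)), axis=1)
    out = np.full(len(xyz), OUTSIDE, dtype=int)
    out[inside] = grid.flat_index(ijk[inside])
    return out


def water_rmsf(traj: Trajectory, water_index: int, window: int) -> np.ndarray:
    """Per-frame positional RMSF of one atom over a centred window.

    For frame ``t`` the window is the ``window`` frames centred on ``t``,
    truncated at the trajectory edges; the value is
    ``sqrt(mean_t' |x_t' - <x>|^2)`` over the window.
    """
    _check_window(window, traj.n_frames)
    x = traj.frames[:, water_index, :]
    return _windowed_rmsf(x, window)


def _check_window(window: int, n_frames: int) -> None:
    if window < 3 or window % 2 == 0 or window > n_frames:
        raise StructureError(
            f"window must be odd, >= 3 and <= n_frames ({n_frames}); got {window}")


def _windowed_rmsf(x: np.ndarray, window: int) -> np.ndarray:
    """Vectorised truncated-centred-window RMSF for one atom track (n, 3)."""
    n = x.shape[0]
    half = window // 2
    s1 = np.concatenate([np.zeros((1, 3)), np.cumsum(x, axis=0)])
    s2 = np.concatenate([np.zeros((1, 3)), np.cumsum(x * x, axis=0)])
    t = np.arange(n)
    lo = np.maximum(t - half, 0)
    hi = np.minimum(t + half + 1, n)
    cnt = (hi - lo).astype(float)[:, None]
    mean = (s1[hi] - s1[lo]) / cnt
    mean_sq = (s2[hi] - s2[lo]) / cnt
    var = np.clip(mean_sq - mean ** 2, 0.0, None).sum(axis=1)
    return np.sqrt(var)


def default_window(traj: Trajectory, span: float = 1000.0) -> int:
    """Window (frames, odd) spanning ``span`` time units (1 ns at ps base)."""
    w = int(round(span / traj.frame_interval))
    w = max(3, min(w, traj.n_frames))
    if w % 2 == 0:
        w -= 1
    return max(w, 3)


def compute_occupancy(traj: Trajectory, grid: GridSpec,
                      rmsf_cutoff: float = DEFAULT_RMSF_CUTOFF,
                      window: int | None = None,
                      frame_range: tuple[int, int] | None = None) -> OccupancyMap:
    """Per-cell %Oall and %O_RMSF over the trajectory.

    ``occ_all`` counts frames in which the cell holds any water oxygen;
    ``occ_rmsf`` counts only frames where the occupying water's windowed
    RMSF is below ``rmsf_cutoff``.  ``frame_range`` restricts the analysis
    to ``[start, stop)`` frames (RMSF windows still see the full track).
    """
    ox = traj.topology.water_oxygen_indices()
    if len(ox) == 0:
        raise StructureError("trajectory topology contains no water oxygens")
    if window is None:
        window = default_window(traj)
    _check_window(window, traj.n_frames)

    rmsf = np.stack([_windowed_rmsf(traj.frames[:, i, :], window) for i in ox],
                    axis=1)  # (n_frames, n_waters)
    start, stop = frame_range if frame_range is not None else (0, traj.n_frames)
    if not (0 <= start < stop <= traj.n_frames):
        raise StructureError(f"invalid frame_range {frame_range}")

    count_all = np.zeros(grid.n_cells, dtype=int)
    count_rmsf = np.zeros(grid.n_cells, dtype=int)
    for t in range(start, stop):
        cells = assign_waters(traj.frames[t][ox], grid, traj.box)
        inside = cells >= 0
        occ_cells = np.unique(cells[inside])
        count_all[occ_cells] += 1
        stat_cells = np.unique(cells[inside & (rmsf[t] < rmsf_cutoff)])
        count_rmsf[stat_cells] += 1
    n_used = stop - start
    return OccupancyMap(
        grid=grid,
        occ_all=(100.0 * count_all / n_used).reshape(grid.dims),
        occ_rmsf=(100.0 * count_rmsf / n_used).reshape(grid.dims),
        n_frames=n_used, rmsf_cutoff=rmsf_cutoff, window=window)


def extract_sites(occ_map: OccupancyMap,
                  threshold: float = DEFAULT_SITE_THRESHOLD) -> list[HydrationSite]:
    """All cells with ``%O_RMSF`` strictly above ``threshold``, best first."""
    centers = occ_map.grid.cell_centers()
    occ_rmsf = occ_map.occ_rmsf.ravel()
    occ_all = occ_map.occ_all.ravel()
    keep = np.where(occ_rmsf > threshold)[0]
    order = keep[np.argsort(-occ_rmsf[keep], kind="stable")]
    return [HydrationSite(cell_center=centers[i], occ_rmsf=float(occ_rmsf[i]),
                          occ_all=float(occ_all[i])) for i in order]


def compare_to_crystal_waters(sites: list[HydrationSite], structure: Structure,
                              b_cutoff: float = 25.0,
                              dist_cutoff: float = 1.5) -> pd.DataFrame:
    """Match low-B-factor crystal waters to the nearest predicted site.

    Only crystal waters with B-factor strictly below ``b_cutoff`` enter the
    comparison; a water is flagged ``matched`` when its nearest site lies
    within ``dist_cutoff`` Å.
    """
    ox = structure.water_oxygen_indices()
    keep = ox[structure.b_factor[ox] < b_cutoff]
    rows = []
    site_pos = np.array([s.cell_center for s in sites]) if sites else np.empty((0, 3))
    for i in keep:
        pos = structure.coords[i]
        if len(site_pos):
            d = np.linalg.norm(site_pos - pos, axis=1)
            j = int(np.argmin(d))
            rows.append({"water_atom_id": int(structure.atom_id[i]),
                         "water_res_id": int(structure.res_id[i]),
                         "b_factor": float(structure.b_factor[i]),
                         "nearest_site": j, "distance": float(d[j]),
                         "matched": bool(d[j] <= dist_cutoff)})
        else:
            rows.append({"water_atom_id": int(structure.atom_id[i]),
                         "water_res_id": int(structure.res_id[i]),
                         "b_factor": float(structure.b_factor[i]),
                         "nearest_site": -1, "distance": np.inf, "matched": False})
    return pd.DataFrame(rows, columns=["water_atom_id", "water_res_id", "b_factor",
                                       "nearest_site", "distance", "matched"])


def sites_to_structure(sites: list[HydrationSite]) -> Structure:
    """Sites as water-oxygen pseudo-atoms; %O_RMSF goes in the B-factor
    column so standard viewers colour by occupancy."""
    n = len(sites)
    coords = np.array([s.cell_center for s in sites]).reshape(n, 3)
    return Structure(
        atom_id=np.arange(1, n + 1), atom_name=np.array(["O"] * n),
        element=np.array(["O"] * n), res_name=np.array(["HOH"] * n),
        res_id=np.arange(1, n + 1), chain=np.array(["W"] * n),
        coords=coords, occupancy=np.array([s.occ_all / 100.0 for s in sites]),
        b_factor=np.array([s.occ_rmsf for s in sites]))


def write_sites_pdb(sites: list[HydrationSite], path) -> None:
    write_structure(sites_to_structure(sites), path)
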