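"""Representative-pose extraction from merged bound-state trajectories.

Pipeline, mirroring pose selection after binding simulations: align every
trajectory on a common reference and pool the ligand coordinates, discard
frames flagged as noise by density-reachability (OPTICS), partition the
rest with K-means (k = 3 by default, matching the three poses a docking
run produces), take each cluster's medoid — the actual member nearest the
cluster mean, so representatives are always physical geometries — and rank
the medoids with a pluggable scorer (lower = better).  A simple
contact-count scorer is shipped as the default stand-in for end-point
binding-energy rescoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans, OPTICS

from .core import (Structure, StructureError, Trajectory, kabsch_superpose,
                   rmsd)

DEFAULT_K = 3
DEFAULT_MIN_CLUSTER_SIZE = 20
DEFAULT_REACHABILITY_QUANTILE = 0.99
CONTACT_CUTOFF = 4.0   # Å
CLASH_CUTOFF = 2.0     # Å; pairs closer than this are penalised


class NoDenseRegionError(ValueError):
    """Every pose was flagged as noise — no dense region exists."""


@dataclass
class PoseEnsemble:
    """Pooled ligand coordinate sets in a common reference frame."""

    coords: np.ndarray              # (n_sets, n_atoms, 3)
    source_ids: np.ndarray          # per-set trajectory/run id

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise StructureError("pose coordinates must be (n_sets, n_atoms, 3)")
        self.source_ids = np.asarray(self.source_ids)
        if len(self.source_ids) != len(self.coords):
            raise StructureError("one source id per coordinate set required")

    def __len__(self) -> int:
        return len(self.coords)

    def flattened(self) -> np.ndarray:
        return self.coords.reshape(len(self), -1)

    def subset(self, indices) -> "PoseEnsemble":
        idx = np.asarray(indices)
        return PoseEnsemble(coords=self.coords[idx],
                            source_ids=self.source_ids[idx])


@dataclass
class Pose:
    coords: np.ndarray
    cluster_id: int
    population: int
    score: float | None = None


@dataclass
class RankedPoses:
    poses: list[Pose]
    k: int


def merge_trajectories(trajs: list[Trajectory], reference: Structure,
                       protein_selection: np.ndarray,
                       ligand_selection: np.ndarray) -> PoseEnsemble:
    """Superpose every frame of every trajectory onto the reference via the
    protein selection and pool the ligand coordinates."""
    sel = np.asarray(protein_selection)
    lig = np.asarray(ligand_selection)
    ref_pts = reference.coords[sel]
    n_atoms = None
    sets, ids = [], []
    for ti, traj in enumerate(trajs):
        if n_atoms is None:
            n_atoms = len(lig)
        if len(lig) != n_atoms:
            raise StructureError("inconsistent ligand atom count across trajectories")
        for frame in traj.frames:
            sup = kabsch_superpose(frame[sel], ref_pts)
            sets.append(sup.apply(frame[lig]))
            ids.append(ti)
    if not sets:
        raise StructureError("no frames to merge")
    return PoseEnsemble(coords=np.stack(sets), source_ids=np.array(ids))


def ensemble_from_states(states: list, source_ids=None) -> PoseEnsemble:
    """Pose ensemble from toy-propagator states (point ligands)."""
    coords = np.stack([np.atleast_2d(s.position) for s in states])
    ids = np.zeros(len(states), dtype=int) if source_ids is None else source_ids
    return PoseEnsemble(coords=coords, source_ids=ids)


def denoise(ensemble: PoseEnsemble,
            min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
            reachability_quantile: float = DEFAULT_REACHABILITY_QUANTILE
            ) -> tuple[PoseEnsemble, np.ndarray]:
    """Density-based noise removal on flattened pose coordinates.

    A pose is flagged noise when OPTICS leaves it outside every cluster of
    at least ``min_cluster_size`` members, or when its reachability exceeds
    the ``reachability_quantile`` quantile of the finite reachabilities.
    Returns the retained subset and the boolean noise flags.
    """
    n = len(ensemble)
    if n < min_cluster_size:
        raise StructureError(
            f"need at least min_cluster_size={min_cluster_size} pose sets, got {n}")
    x = ensemble.flattened()
    # min_samples stays at the OPTICS default scale (5): tying it to
    # min_cluster_size makes xi extraction absorb trailing outliers
    optics = OPTICS(min_samples=min(5, n - 1),
                    min_cluster_size=min_cluster_size)
    labels = optics.fit_predict(x)
    noise = labels < 0
    # drop residual clusters smaller than min_cluster_size
    for lab in np.unique(labels[labels >= 0]):
        members = labels == lab
        if members.sum() < min_cluster_size:
            noise |= members
    reach = optics.reachability_
    finite = np.isfinite(reach)
    if reachability_quantile < 1.0 and finite.any():
        thr = np.quantile(reach[finite], reachability_quantile)
        noise |= finite & (reach > thr)
        # absolute density check: xi extraction is purely relative and will
        # call a uniform scatter one cluster; a point that cannot even reach
        # min_samples neighbours within thr is not in a dense region
        noise |= optics.core_distances_ > thr
    if noise.all():
        raise NoDenseRegionError("all pose sets flagged as noise")
    return ensemble.subset(np.where(~noise)[0]), noise


def cluster_and_select(ensemble: PoseEnsemble, k: int = DEFAULT_K,
                       seed: int = 0) -> RankedPoses:
    """K-means partition of the retained poses and one medoid per cluster.

    The representative of each cluster is the member coordinate set
    nearest the K-means center (never an averaged geometry).  Deterministic
    for a fixed seed.  If fewer sets than ``k`` are given, k is reduced
    with a warning.
    """
    n = len(ensemble)
    if n == 0:
        raise StructureError("empty pose ensemble")
    if n < k:
        warnings.warn(f"only {n} pose sets; reducing k from {k} to {n}")
        k = n
    x = ensemble.flattened()
    if np.allclose(x, x[0]):
        warnings.warn("all pose sets identical; clusters are degenerate")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    poses = []
    for lab in range(k):
        members = np.where(labels == lab)[0]
        if len(members) == 0:
            continue
        d = np.linalg.norm(x[members] - km.cluster_centers_[lab], axis=1)
        medoid = members[int(np.argmin(d))]
        poses.append(Pose(coords=ensemble.coords[medoid], cluster_id=int(lab),
                          population=int(len(members))))
    return RankedPoses(poses=poses, k=k)


def cluster_labels(ensemble: PoseEnsemble, k: int = DEFAULT_K,
                   seed: int = 0) -> np.ndarray:
    """K-means labels only (for partition-recovery checks)."""
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(ensemble.flattened())


def contact_score(pose_coords: np.ndarray, protein: Structure,
                  cutoff: float = CONTACT_CUTOFF,
                  clash_cutoff: float = CLASH_CUTOFF) -> float:
    """Stand-in pose scorer: minus the heavy-atom contact count.

    Each ligand-heavy-atom/protein-heavy-atom pair within ``cutoff``
    scores −1; pairs closer than ``clash_cutoff`` are clashes and add +10
    each instead.  Lower is better.
    """
    lig = np.asarray(pose_coords, dtype=float).reshape(-1, 3)
    prot = protein.coords[protein.heavy_indices()]
    if len(prot) == 0:
        return 0.0
    tree = cKDTree(prot)
    pairs = tree.query_ball_point(lig, r=cutoff)
    score = 0.0
    for i, neigh in enumerate(pairs):
        if not neigh:
            continue
        d = np.linalg.norm(prot[neigh] - lig[i], axis=1)
        n_clash = int((d < clash_cutoff).sum())
        score += 10.0 * n_clash - float((d >= clash_cutoff).sum())
    return score


def rank_poses(ranked: RankedPoses, scorer, context: Structure) -> RankedPoses:
    """Score each pose and sort ascending (better first); ties broken by
    cluster population descending.  Poses whose scoring fails are dropped
    with a warning."""
    scored = []
    for p in ranked.poses:
        try:
            s = float(scorer(p.coords, context))
        except Exception as exc:  # scorer contract: any failure drops the pose
            warnings.warn(f"scorer failed on cluster {p.cluster_id}: {exc}")
            continue
        scored.append(Pose(coords=p.coords, cluster_id=p.cluster_id,
                           population=p.population, score=s))
    scored.sort(key=lambda p: (p.score, -p.population))
    return RankedPoses(poses=scored, k=ranked.k)
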