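"""Conserved crystallographic waters across an aligned crystal ensemble.

A consensus strategy: the ensemble is rigidly superposed onto a reference,
all water oxygens are pooled and single-linkage clustered at a hard
distance cutoff, and clusters present in at least a minimum fraction of
the structures are reported as conserved hydration positions.  Such waters
mediate fragment binding in systems like the HSP90 N-terminal domain and
are retained during water-aware docking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import (Structure, StructureError, Superposition, kabsch_superpose,
                   select_atoms, write_structure)

DEFAULT_CUTOFF = 2.4          # Å, inter-water single-linkage cutoff
DEFAULT_MIN_CONSERVATION = 1.0


@dataclass
class ConservedWater:
    position: np.ndarray                   # cluster representative, Å
    conservation: float                    # fraction of structures contributing
    members: list                          # (structure index, water res_id, distance Å)
    mean_b_factor: float


def _matched_selection(structure: Structure, reference: Structure,
                       selection) -> tuple[np.ndarray, np.ndarray]:
    """Pair selected reference atoms with structure atoms by
    (chain, res_id, atom_name).  Raises listing any unmatched atoms."""
    ref_idx = selection(reference) if callable(selection) else np.asarray(selection)
    key = {}
    for i in range(len(structure)):
        key[(structure.chain[i], int(structure.res_id[i]), structure.atom_name[i])] = i
    mob, ref, missing = [], [], []
    for i in ref_idx:
        k = (reference.chain[i], int(reference.res_id[i]), reference.atom_name[i])
        if k in key:
            mob.append(key[k])
            ref.append(i)
        else:
            missing.append(k)
    if missing:
        raise StructureError(f"selection atoms missing from structure: {missing[:10]}")
    return np.asarray(mob), np.asarray(ref)


def ca_selection(structure: Structure) -> np.ndarray:
    return select_atoms(structure, name="CA")


def align_ensemble(structures: list[Structure], reference: Structure,
                   selection=ca_selection
                   ) -> tuple[list[Structure], list[Superposition]]:
    """Superpose each structure onto the reference via a common atom
    selection (default: all Cα atoms, matched by chain/residue/atom name)."""
    aligned, sups = [], []
    for s in structures:
        mob_idx, ref_idx = _matched_selection(s, reference, selection)
        if len(mob_idx) < 3:
            raise StructureError("selection resolves to fewer than 3 common atoms")
        sup = kabsch_superpose(s.coords[mob_idx], reference.coords[ref_idx])
        aligned.append(s.transformed(sup))
        sups.append(sup)
    return aligned, sups


def _one_pass(pos, struct_of, cutoff):
    """Single-linkage clustering at a hard cutoff; one water kept per
    structure per cluster (the nearest to the cluster centroid); displaced
    waters are returned for re-clustering."""
    n = len(pos)
    if n == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pos, method="single"), t=cutoff,
                          criterion="distance")
    clusters, leftovers = [], []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        centroid = pos[members].mean(axis=0)
        kept = {}
        for m in members:
            d = float(np.linalg.norm(pos[m] - centroid))
            sid = struct_of[m]
            if sid not in kept or d < kept[sid][1]:
                if sid in kept:
                    leftovers.append(kept[sid][0])
                kept[sid] = (m, d)
            else:
                leftovers.append(m)
        clusters.append(sorted(v[0] for v in kept.values()))
    return clusters, leftovers


def cluster_conserved_waters(aligned: list[Structure],
                             distance_cutoff: float = DEFAULT_CUTOFF,
                             min_conservation: float = DEFAULT_MIN_CONSERVATION,
                             b_max: float | None = None) -> list[ConservedWater]:
    """Consensus water positions across an aligned ensemble.

    Water oxygens from all structures are pooled and single-linkage
    clustered at ``distance_cutoff``; each structure contributes at most
    one water per cluster (the nearest; displaced waters are re-clustered
    among themselves).  Clusters with conservation >= ``min_conservation``
    (and mean B-factor <= ``b_max`` if given) are returned, representative
    = member centroid, sorted by conservation descending then mean B
    ascending then position.
    """
    if len(aligned) < 2:
        raise StructureError("need at least 2 structures for a consensus")
    pos, struct_of, res_of, b_of = [], [], [], []
    for si, s in enumerate(aligned):
        for i in s.water_oxygen_indices():
            pos.append(s.coords[i])
            struct_of.append(si)
            res_of.append(int(s.res_id[i]))
            b_of.append(float(s.b_factor[i]))
    if not pos:
        warnings.warn("no crystallographic waters in any structure")
        return []
    pos = np.asarray(pos)
    struct_of = np.asarray(struct_of)

    final_clusters = []
    pool = np.arange(len(pos))
    while len(pool):
        clusters, leftovers = _one_pass(pos[pool], struct_of[pool], distance_cutoff)
        final_clusters.extend([[int(pool[m]) for m in c] for c in clusters])
        if not leftovers:
            break
        pool = pool[np.asarray(leftovers, dtype=int)]

    n_structs = len(aligned)
    out = []
    for members in final_clusters:
        cons = len(members) / n_structs
        if cons < min_conservation:
            continue
        mean_b = float(np.mean([b_of[m] for m in members]))
        if b_max is not None and mean_b > b_max:
            continue
        rep = pos[members].mean(axis=0)
        mem = [(int(struct_of[m]), res_of[m], float(np.linalg.norm(pos[m] - rep)))
               for m in sorted(members, key=lambda m: struct_of[m])]
        out.append(ConservedWater(position=rep, conservation=cons,
                                  members=mem, mean_b_factor=mean_b))
    out.sort(key=lambda w: (-w.conservation, w.mean_b_factor, tuple(w.position)))
    return out


def conserved_to_structure(conserved: list[ConservedWater]) -> Structure:
    """Representatives as HOH oxygens; conservation (as a fraction) in the
    occupancy column, mean B-factor in the B column."""
    n = len(conserved)
    coords = np.array([w.position for w in conserved]).reshape(n, 3)
    return Structure(
        atom_id=np.arange(1, n + 1), atom_name=np.array(["O"] * n),
        element=np.array(["O"] * n), res_name=np.array(["HOH"] * n),
        res_id=np.arange(1, n + 1), chain=np.array(["W"] * n),
        coords=coords,
        occupancy=np.array([w.conservation for w in conserved]),
        b_factor=np.array([w.mean_b_factor for w in conserved]))


def write_waters_pdb(conserved: list[ConservedWater], path) -> None:
    write_structure(conserved_to_structure(conserved), path)
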