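"""Pose-accuracy metrics and protocol comparison.

Per-pose RMSD against the crystallographic reference (after superposing on
the binding site, no refitting on the ligand), top-1/top-N success curves
(fraction of complexes whose best-ranked poses fall below an RMSD
threshold, as a function of the threshold), a strict 2 Å correctness call,
and per-ligand RMSD heatmap tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (Structure, StructureError, kabsch_superpose, rmsd,
                   select_atoms)

DEFAULT_CORRECTNESS_CUTOFF = 2.0   # Å
DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 6.0 + 1e-9, 0.1), 10)

RECORD_COLUMNS = ["complex", "protocol", "rank", "rmsd"]


def make_records(rows) -> pd.DataFrame:
    """RMSD record table: one row per (complex, protocol, pose rank)."""
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if (df["rmsd"] < 0).any():
        raise StructureError("negative RMSD in records")
    for (c, p), grp in df.groupby(["complex", "protocol"]):
        ranks = sorted(grp["rank"])
        if ranks != list(range(1, len(ranks) + 1)):
            raise StructureError(
                f"ranks for complex {c!r}/protocol {p!r} not contiguous from 1: {ranks}")
    return df


def default_site_selection(reference: Structure, ligand_idx: np.ndarray,
                           radius: float = 8.0) -> np.ndarray:
    """Cα atoms within ``radius`` Å of the reference ligand."""
    return select_atoms(reference, name="CA",
                        within_of=reference.coords[ligand_idx], radius=radius)


def _match_by_name(pred: Structure, ref: Structure, pred_idx, ref_idx,
                   name_map: dict | None = None):
    """Pair atoms between structures by atom name within the selections."""
    pred_idx = np.asarray(pred_idx)
    ref_idx = np.asarray(ref_idx)
    pred_names = [name_map.get(n, n) if name_map else n
                  for n in pred.atom_name[pred_idx]]
    lookup = {}
    for i, n in zip(pred_idx, pred_names):
        lookup.setdefault(n, []).append(i)
    ordered, missing = [], []
    for j in ref_idx:
        n = ref.atom_name[j]
        if lookup.get(n):
            ordered.append(lookup[n].pop(0))
        else:
            missing.append(n)
    if missing:
        raise StructureError(f"unmatched ligand atoms (by name): {missing}")
    return np.asarray(ordered), ref_idx


def pose_rmsd(predicted: Structure, reference: Structure,
              ligand_selection, site_selection=None,
              name_map: dict | None = None) -> float:
    """Ligand heavy-atom RMSD after binding-site superposition.

    The predicted complex is superposed onto the reference via the site
    selection (default: reference Cα within 8 Å of the ligand, matched by
    chain/residue/atom name); the RMSD is then computed over ligand heavy
    atoms matched by atom name, with no refitting on the ligand.  An
    optional ``name_map`` declares manual atom-name equivalences (e.g. for
    symmetric ligands); no symmetry correction is applied by default.
    """
    ref_lig = (ligand_selection(reference) if callable(ligand_selection)
               else np.asarray(ligand_selection))
    pred_lig = (ligand_selection(predicted) if callable(ligand_selection)
                else np.asarray(ligand_selection))
    if site_selection is None:
        ref_site = default_site_selection(reference, ref_lig)
    elif callable(site_selection):
        ref_site = site_selection(reference)
    else:
        ref_site = np.asarray(site_selection)
    # site atoms matched by (chain, res_id, atom_name)
    key = {(predicted.chain[i], int(predicted.res_id[i]), predicted.atom_name[i]): i
           for i in range(len(predicted))}
    pred_site, missing = [], []
    for j in ref_site:
        k = (reference.chain[j], int(reference.res_id[j]), reference.atom_name[j])
        if k in key:
            pred_site.append(key[k])
        else:
            missing.append(k)
    if missing:
        raise StructureError(f"site atoms missing from predicted structure: {missing[:10]}")
    pred_site = np.asarray(pred_site)

    sup = kabsch_superpose(predicted.coords[pred_site], reference.coords[ref_site])
    moved = sup.apply(predicted.coords)

    heavy_ref = ref_lig[reference.element[ref_lig] != "H"]
    heavy_pred = pred_lig[predicted.element[pred_lig] != "H"]
    pi, ri = _match_by_name(predicted, reference, heavy_pred, heavy_ref, name_map)
    return rmsd(moved[pi], reference.coords[ri])


def success_curve(records: pd.DataFrame, top_n: int = 1,
                  thresholds: np.ndarray = DEFAULT_THRESHOLDS,
                  protocol=None) -> pd.DataFrame:
    """Fraction of complexes whose best top-``top_n`` pose has RMSD <= t.

    The best pose of a complex is the minimum RMSD among its poses of rank
    <= ``top_n``; top-1 uses the rank-1 pose only.  Returns a table with
    ``threshold`` and ``fraction`` columns (fraction nondecreasing).
    """
    df = records if protocol is None else records[records["protocol"] == protocol]
    if df.empty:
        raise StructureError("no records for the requested protocol")
    best = (df[df["rank"] <= top_n].groupby("complex")["rmsd"].min())
    missing = set(df["complex"].unique()) - set(best.index)
    if missing:
        raise StructureError(f"complexes without top-{top_n} poses: {sorted(missing)}")
    thresholds = np.asarray(thresholds, dtype=float)
    frac = [(best.values <= t).mean() for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction": frac})


def correctness_call(records: pd.DataFrame,
                     cutoff: float = DEFAULT_CORRECTNESS_CUTOFF,
                     protocol=None) -> pd.Series:
    """Per-complex boolean: correct iff the rank-1 RMSD is strictly below
    ``cutoff`` (poses at exactly the cutoff are not correct)."""
    df = records if protocol is None else records[records["protocol"] == protocol]
    top1 = df[df["rank"] == 1].groupby("complex")["rmsd"].min()
    return top1 < cutoff


def heatmap_table(records: pd.DataFrame) -> pd.DataFrame:
    """Complex × (protocol, rank) RMSD matrix, ranks ordered so pose 1 is
    the best-scored pose."""
    return records.pivot_table(index="complex", columns=["protocol", "rank"],
                               values="rmsd").sort_index(axis=1)
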