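"""Superposition and residue-to-cluster proximity filtering.

Candidate sites are the focal-pair-differing alignment columns whose
residue sits within a distance cutoff (default 5 Å) of any named cofactor
cluster. Distances use all heavy atoms of the residue; hydrogens are
ignored. The catalytic 2Fe subcluster and its bridged cubane are collapsed
into a single "H-cluster" region label for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_io import Alignment, Atom, Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSite",
    "DEFAULT_REGION_ALIASES",
    "kabsch_superpose",
    "apply_transform",
    "superpose_models",
    "min_cluster_distance",
    "candidate_sites",
    "sites_table",
    "build_column_mapping",
]

#: Cluster label -> reported region. The 2Fe subcluster and its cubane are
#: one catalytic region; accessory clusters report under their own name.
DEFAULT_REGION_ALIASES: dict[str, str] = {
    "H2Fe": "H-cluster",
    "H4Fe": "H-cluster",
    "HCLUSTER": "H-cluster",
}

DEFAULT_CUTOFF = 5.0  # Å


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 corresponding atom pairs")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    p = mobile - mu_m
    q = target - mu_t
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) atom configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_t - rotation @ mu_m
    moved = p @ rotation.T + mu_t
    rmsd = float(np.sqrt(((moved - target) ** 2).sum() / n))
    return rotation, translation, rmsd


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def superpose_models(
    mobile: StructureModel,
    target: StructureModel,
    pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    atom_name: str = "CA",
) -> tuple[StructureModel, float]:
    """Superpose `mobile` onto `target` using one atom per residue pair.

    ``pairs`` lists ((mobile chain, mobile resnum), (target chain, target
    resnum)) correspondences. Returns the transformed mobile model and the
    fit RMSD.
    """

    def pick(model: StructureModel, chain: str, number: int) -> Atom:
        res = model.get_residue(chain, number)
        for atom in res.atoms:
            if atom.name == atom_name:
                return atom
        raise ValueError(f"no {atom_name} atom in {chain}/{number}")

    m = np.array([pick(mobile, *mk).coord for mk, _ in pairs])
    t = np.array([pick(target, *tk).coord for _, tk in pairs])
    rotation, translation, rmsd = kabsch_superpose(m, t)

    def move(atom: Atom) -> Atom:
        x, y, z = rotation @ atom.coord + translation
        return Atom(atom.name, atom.element, float(x), float(y), float(z))

    residues = [
        Residue(r.chain, r.number, r.name, [move(a) for a in r.atoms])
        for r in mobile.residues
    ]
    groups = {
        label: [move(a) for a in atoms]
        for label, atoms in mobile.cluster_groups.items()
    }
    return StructureModel(residues, groups), rmsd


def min_cluster_distance(residue: Residue, cluster_atoms: Sequence[Atom]) -> float:
    """Minimum heavy-atom-to-cluster-atom Euclidean distance in Å."""
    if not cluster_atoms:
        raise ValueError("cluster group is empty")
    coords = residue.heavy_coords()
    if coords.size == 0:
        raise ValueError(f"residue {residue.chain}/{residue.number} has no heavy atoms")
    cluster = np.array([a.coord for a in cluster_atoms])
    return float(cdist(coords, cluster).min())


@dataclass(frozen=True)
class CandidateSite:
    column: int
    res_a: str  # focal-A (reference) residue letter
    ref_number: int | None
    res_b: str  # focal-B (model) residue letter
    model_number: int | None
    distances: dict[str, float]  # min distance per cluster label
    region: str  # nearest-cluster region label
    within_cutoff: bool

    @property
    def min_distance(self) -> float:
        return min(self.distances.values())


ColumnMapping = Mapping[int, tuple[int | None, int | None]]


def build_column_mapping(
    aln: Alignment,
    ref_id: str,
    model_id: str,
    ref_offset: int = 0,
    model_offset: int = 0,
) -> dict[int, tuple[int | None, int | None]]:
    """Column -> (reference residue number, model residue number).

    Residue numbers are the alignment's 1-based ungapped indices plus the
    given offsets, for structures whose numbering is shifted relative to
    the sequence start.
    """
    mapping: dict[int, tuple[int | None, int | None]] = {}
    for col in range(1, aln.n_columns + 1):
        r = aln.col_to_res(ref_id, col)
        m = aln.col_to_res(model_id, col)
        mapping[col] = (
            r + ref_offset if r is not None else None,
            m + model_offset if m is not None else None,
        )
    return mapping


def _distances_for(
    model: StructureModel, number: int, labels: Sequence[str]
) -> dict[str, float] | None:
    res = model.find_residue(number)
    if res is None or not res.heavy_atoms:
        return None
    return {
        label: min_cluster_distance(res, model.cluster_groups[label])
        for label in labels
        if label in model.cluster_groups
    }


def candidate_sites(
    profile: pd.DataFrame,
    reference: StructureModel,
    model: StructureModel | None,
    mapping: ColumnMapping,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "either",
    region_aliases: Mapping[str, str] | None = None,
) -> list[CandidateSite]:
    """Differing columns whose residue lies within `cutoff` of a cluster.

    ``mode`` selects which structure the distance test uses: "reference",
    "model", or "either" (per-cluster minimum over both; the default).
    Sites are sorted by reference residue number (unmapped last).
    """
    if not reference.cluster_groups and not (model and model.cluster_groups):
        raise ValueError("no cluster groups on any structure")
    if mode not in {"reference", "model", "either"}:
        raise ValueError(f"unknown mode {mode!r}")
    aliases = dict(DEFAULT_REGION_ALIASES)
    if region_aliases:
        aliases.update(region_aliases)
    labels = sorted(
        set(reference.cluster_groups) | set(model.cluster_groups if model else {})
    )
    sites: list[CandidateSite] = []
    for row in profile.itertuples(index=False):
        col = int(row.column)
        ref_num, model_num = mapping.get(col, (None, None))
        dist_ref = (
            _distances_for(reference, ref_num, labels)
            if mode in {"reference", "either"} and ref_num is not None
            else None
        )
        dist_mod = (
            _distances_for(model, model_num, labels)
            if model is not None and mode in {"model", "either"} and model_num is not None
            else None
        )
        if dist_ref is None and dist_mod is None:
            logger.warning(
                "column %d: no structure residue available (ref %s, model %s); skipped",
                col, ref_num, model_num,
            )
            continue
        merged: dict[str, float] = {}
        for d in (dist_ref, dist_mod):
            if d is None:
                continue
            for label, value in d.items():
                merged[label] = min(value, merged.get(label, np.inf))
        nearest = min(sorted(merged), key=lambda l: merged[l])
        ties = [l for l in merged if merged[l] == merged[nearest] and l != nearest]
        if ties:
            logger.info(
                "column %d: cluster distance tie between %s and %s; "
                "keeping %s (label order)", col, nearest, ties, nearest,
            )
        sites.append(
            CandidateSite(
                column=col,
                res_a=str(row.res_a),
                ref_number=ref_num,
                res_b=str(row.res_b),
                model_number=model_num,
                distances=merged,
                region=aliases.get(nearest, nearest),
                within_cutoff=bool(min(merged.values()) <= cutoff),
            )
        )
    selected = [s for s in sites if s.within_cutoff]
    selected.sort(key=lambda s: (s.ref_number is None, s.ref_number, s.column))
    return selected


def sites_table(sites: Sequence[CandidateSite]) -> pd.DataFrame:
    """Flat table of candidate sites for TSV export."""
    return pd.DataFrame(
        [
            {
                "column": s.column,
                "res_a": s.res_a,
                "ref_number": s.ref_number,
                "res_b": s.res_b,
                "model_number": s.model_number,
                "region": s.region,
                "min_distance": s.min_distance,
                **{f"d_{k}": v for k, v in sorted(s.distances.items())},
            }
            for s in sites
        ]
    )
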