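"""Consensus hydration sites across crystallographically independent copies.

When an asymmetric unit holds several copies of the same molecule, each copy
carries its own, partially modelled solvation shell.  Superposing the copies
and pooling their waters in a common frame turns this redundancy into a vote:
a water position recovered near-identically in several independent copies is a
genuine hydration site rather than modelling noise.  The result is a table of
consensus sites with per-copy presence counts and coordinating-atom labels.

Also provides the supporting rigid-body machinery (Kabsch superposition) and
chain-vs-chain / ensemble-vs-model RMSD comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .hbonds import classify_polar_atoms
from .structures import StructureModel

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class ConsensusSite:
    centroid: np.ndarray
    member_waters: list[tuple[str, int, float]]  # (chain, water residue number, dist to centroid)
    chains_present: set[str] = field(default_factory=set)
    coordinating_labels: dict[str, list[str]] = field(default_factory=dict)
    label: str = ""

    @property
    def presence_count(self) -> int:
        return len(self.chains_present)


def kabsch_superpose(reference_coords: np.ndarray,
                     mobile_coords: np.ndarray) -> RigidTransform:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Returns the proper rotation (reflections corrected via the SVD sign) and
    translation minimising the RMSD of ``mobile`` onto ``reference``, along
    with the achieved RMSD.
    """
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(reference_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, fit_rmsd=rmsd)


# ---------------------------------------------------------------------------
# Atom mapping between chains
# ---------------------------------------------------------------------------

def _atom_map(model: StructureModel, chain: str, atom_filter: str,
              offset: int = 0) -> dict[tuple[int, str], int]:
    """(residue_number+offset, atom name) -> atom index, for one chain."""
    out = {}
    for i, a in enumerate(model.atoms):
        if a.chain_id != chain or a.is_water or a.is_ion or a.is_hydrogen:
            continue
        if atom_filter == "backbone" and a.name not in BACKBONE_NAMES:
            continue
        out[(a.residue_number + offset, a.name)] = i
    return out


def _common_coords(model_a: StructureModel, map_a: dict,
                   model_b: StructureModel, map_b: dict
                   ) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set(map_a) & set(map_b))
    if len(keys) < 3:
        raise ValueError("fewer than 3 common atoms between the two selections")
    xa = np.array([model_a.atoms[map_a[k]].position for k in keys])
    xb = np.array([model_b.atoms[map_b[k]].position for k in keys])
    return xa, xb


def pairwise_chain_rmsd(model: StructureModel, chains: list[str] | None = None,
                        atom_filter: str = "backbone"
                        ) -> tuple[np.ndarray, float]:
    """Post-superposition RMSD between every pair of chains.

    The comparison is restricted to residues/atoms present in both chains of
    each pair (termini disorder commonly differs between copies).  Returns the
    symmetric matrix and the mean over distinct pairs.
    """
    if chains is None:
        chains = [c for c in model.chains
                  if any(a.chain_id == c and not a.is_water and not a.is_ion
                         for a in model.atoms)]
    maps = {c: _atom_map(model, c, atom_filter) for c in chains}
    n = len(chains)
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            xa, xb = _common_coords(model, maps[chains[i]], model, maps[chains[j]])
            r = kabsch_superpose(xa, xb).fit_rmsd
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    return mat, float(np.mean(vals)) if vals else 0.0


def ensemble_vs_model_rmsd(ensemble: list[StructureModel],
                           model: StructureModel,
                           model_chains: list[str] | None = None,
                           atom_filter: str = "backbone",
                           ensemble_chain: str | None = None,
                           offset_map: dict[str, int] | None = None) -> float:
    """Mean best-fit RMSD between ensemble members and a model's chains.

    Every (ensemble member, model chain) pair is superposed over their common
    atoms and the RMSDs are averaged.  ``offset_map`` adds a per-model-chain
    residue-number offset to reconcile different numbering schemes.
    """
    if model_chains is None:
        model_chains = model.chains
    offset_map = offset_map or {}
    vals = []
    for member in ensemble:
        echain = ensemble_chain or member.chains[0]
        emap = _atom_map(member, echain, atom_filter)
        for c in model_chains:
            mmap = _atom_map(model, c, atom_filter, offset=offset_map.get(c, 0))
            xa, xb = _common_coords(member, emap, model, mmap)
            vals.append(kabsch_superpose(xa, xb).fit_rmsd)
    if not vals:
        raise ValueError("no comparable chain pairs")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Water pooling and consensus clustering
# ---------------------------------------------------------------------------

def assign_waters_to_chains(model: StructureModel,
                            chains: list[str]) -> dict[str, list[int]]:
    """Assign each water oxygen to the chain of its nearest protein atom.

    Crystallographic waters are deposited per asymmetric unit, not per copy,
    so proximity defines ownership.
    """
    chain_idx = {c: [i for i, a in enumerate(model.atoms)
                     if a.chain_id == c and not a.is_water and not a.is_ion
                     and not a.is_hydrogen] for c in chains}
    trees = {c: cKDTree(np.array([model.atoms[i].position for i in idx]))
             for c, idx in chain_idx.items() if idx}
    out: dict[str, list[int]] = {c: [] for c in chains}
    for i, a in enumerate(model.atoms):
        if not a.is_water or a.is_hydrogen:
            continue
        best_c, best_d = None, np.inf
        for c, tree in trees.items():
            d, _ = tree.query(a.position)
            if d < best_d:
                best_c, best_d = c, d
        if best_c is not None:
            out[best_c].append(i)
    return out


def pool_and_cluster_waters(model: StructureModel,
                            chains: list[str] | None = None,
                            cluster_cutoff: float = 1.2,
                            atom_filter: str = "backbone"
                            ) -> list[ConsensusSite]:
    """Pool per-copy waters in a common frame and cluster into consensus sites.

    Each chain's waters are carried by that chain's superposition onto the
    first chain; the pooled oxygens are clustered greedily: seeds in
    decreasing order of local neighbour count (within the cutoff), each water
    joining the nearest cluster centroid within the cutoff, centroids updated.
    The procedure is deterministic.  Presence count = number of distinct
    source chains contributing a member.
    """
    if cluster_cutoff <= 0:
        raise ValueError("cluster_cutoff must be positive")
    if chains is None:
        chains = [c for c in model.chains
                  if any(a.chain_id == c and not a.is_water and not a.is_ion
                         for a in model.atoms)]
    ref_map = _atom_map(model, chains[0], atom_filter)
    assignment = assign_waters_to_chains(model, chains)

    pooled: list[tuple[str, int, np.ndarray]] = []  # (chain, water atom idx, pos in ref frame)
    for c in chains:
        if c == chains[0]:
            tr = RigidTransform(np.eye(3), np.zeros(3), 0.0)
        else:
            cmap = _atom_map(model, c, atom_filter)
            xref, xmob = None, None
            keys = sorted(set(ref_map) & set(cmap))
            if len(keys) < 3:
                raise ValueError(f"chain {c} shares fewer than 3 atoms with {chains[0]}")
            xref = np.array([model.atoms[ref_map[k]].position for k in keys])
            xmob = np.array([model.atoms[cmap[k]].position for k in keys])
            tr = kabsch_superpose(xref, xmob)
        for wi in assignment[c]:
            pooled.append((c, wi, tr.apply(model.atoms[wi].position)))

    if not pooled:
        return []
    pts = np.array([p[2] for p in pooled])
    tree = cKDTree(pts)
    neighbor_counts = np.array([len(tree.query_ball_point(p, cluster_cutoff)) - 1
                                for p in pts])
    order = sorted(range(len(pooled)),
                   key=lambda k: (-neighbor_counts[k], pooled[k][0], pooled[k][1]))

    assigned = np.full(len(pooled), -1, dtype=int)
    centroids: list[np.ndarray] = []
    for k in order:
        if assigned[k] >= 0:
            continue
        members = [m for m in tree.query_ball_point(pts[k], cluster_cutoff)
                   if assigned[m] < 0]
        ci = len(centroids)
        for m in members:
            assigned[m] = ci
        centroids.append(pts[members].mean(axis=0))
    # refinement pass: each water joins the nearest centroid within the cutoff
    cent = np.array(centroids)
    ctree = cKDTree(cent)
    d, nearest = ctree.query(pts)
    moved = d <= cluster_cutoff
    assigned[moved] = nearest[moved]
    # recompute centroids
    sites: list[ConsensusSite] = []
    for ci in range(len(centroids)):
        members = np.nonzero(assigned == ci)[0]
        if len(members) == 0:
            continue
        centroid = pts[members].mean(axis=0)
        mw = []
        chains_present = set()
        for m in members:
            c, wi, p = pooled[m]
            mw.append((c, model.atoms[wi].residue_number,
                       float(np.linalg.norm(p - centroid))))
            chains_present.add(c)
        sites.append(ConsensusSite(centroid=centroid, member_waters=mw,
                                   chains_present=chains_present))
    sites.sort(key=lambda s: (-s.presence_count,
                              tuple(np.round(s.centroid, 3))))
    return sites


def annotate_coordinating_atoms(model: StructureModel, site: ConsensusSite,
                                contact_cutoff: float = 3.5) -> ConsensusSite:
    """Label a consensus site by the polar atoms coordinating its members.

    For each member water (in its original chain frame) the polar solute atoms
    within ``contact_cutoff`` are listed as ``RES###(ATOM)``; the site label
    collects the atoms shared by the majority of member chains.
    """
    if not site.member_waters:
        raise ValueError("site has no member waters")
    table = classify_polar_atoms(model)
    polar = sorted((set(table.donor_indices) | set(table.acceptors)))
    polar = [i for i in polar if not model.atoms[i].is_water]
    ppos = np.array([model.atoms[i].position for i in polar])
    ptree = cKDTree(ppos) if len(polar) else None

    water_pos = {}
    for i, a in enumerate(model.atoms):
        if a.is_water and not a.is_hydrogen:
            water_pos.setdefault((a.chain_id, a.residue_number), a.position)
    # waters may live in a solvent chain; look them up by residue number alone
    water_by_num = {}
    for (c, num), p in water_pos.items():
        water_by_num.setdefault(num, p)

    site.coordinating_labels = {}
    for chain, wnum, _d in site.member_waters:
        pos = water_pos.get((chain, wnum), water_by_num.get(wnum))
        if pos is None or ptree is None:
            labels = []
        else:
            hits = ptree.query_ball_point(pos, contact_cutoff)
            labels = sorted({model.atoms[polar[h]].label() for h in hits})
        site.coordinating_labels.setdefault(chain, [])
        site.coordinating_labels[chain] = sorted(
            set(site.coordinating_labels[chain]) | set(labels))

    n_chains = len(site.coordinating_labels)
    counts: dict[str, int] = {}
    for labels in site.coordinating_labels.values():
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    majority = [lab for lab, c in counts.items() if c > n_chains / 2]
    site.label = "/".join(sorted(majority))
    return site
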