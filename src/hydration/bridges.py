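"""Water-bridge occupancy, residency and classification analyses.

A *water bridge* is a single water simultaneously hydrogen-bonded to two or
more solute atoms.  A declared bridge site is *fully formed* in a frame when
one water satisfies the geometric H-bond criterion with every defining solute
atom at once; occupancy is the percentage of frames in which this holds, and a
*binding event* is a maximal run of frames occupied by the same water
molecule.  Binding times of ordinary surface waters are ~50–500 ps; sites with
maximum binding times of a nanosecond or more are flagged long-residency.

Water–solute bonds are evaluated in both directions (water as donor via its
hydrogens, solute donors toward the water oxygen).  All per-frame evaluation
is vectorised over frames so that multi-10⁴-frame trajectories are cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbonds import DISTANCE_ONLY, EXPLICIT, HBondCriterion, PolarTable, classify_polar_atoms
from .structures import Trajectory, minimum_image

NO_WATER = -1

LONG_RESIDENCY_NS = 1.0  # contrast: typical exchange ~50-500 ps


@dataclass(frozen=True)
class BridgeDefinition:
    """A hydration site declared by its coordinating solute atoms."""

    site_atoms: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.site_atoms) == 0:
            raise ValueError("site_atoms must be non-empty")


@dataclass
class BridgeStateSeries:
    """Per-frame occupying water id (water oxygen atom index; -1 for none)."""

    occupant: np.ndarray
    dt_ps: float

    @property
    def n_frames(self) -> int:
        return len(self.occupant)


@dataclass
class BridgeStats:
    occupancy_percent: float
    n_events: int
    max_binding_ns: float
    mean_binding_ns: float
    exchange_count: int

    @property
    def long_residency(self) -> bool:
        return self.max_binding_ns >= LONG_RESIDENCY_NS


@dataclass
class WaterClassLabels:
    """Per-frame three-group classification of every water.

    ``labels`` is (n_frames, n_waters) with values 0 = bulk, 1 = first shell,
    2 = bridging; ``water_oxygens`` gives the topology atom index of each
    column.  Bridging waters are by construction a subset of first-shell
    contact (they touch the solute), but are labelled with the stronger class.
    """

    labels: np.ndarray
    water_oxygens: np.ndarray
    CLASSES = ("bulk", "first_shell", "bridging")

    def fractions(self) -> dict[str, float]:
        total = self.labels.size
        return {name: float(np.mean(self.labels == k))
                for k, name in enumerate(self.CLASSES)} if total else {}


# ---------------------------------------------------------------------------
# Vectorised water--solute bond matrix
# ---------------------------------------------------------------------------

def _angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    denom = np.where((n1 > 0) & (n2 > 0), n1 * n2, np.inf)
    cosang = np.clip(np.einsum("...i,...i", v1, v2) / denom, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def water_solute_bond_matrix(traj: Trajectory, water_oxygens: np.ndarray,
                             solute_atoms: np.ndarray,
                             table: PolarTable | None = None,
                             criterion: HBondCriterion = HBondCriterion(),
                             ) -> tuple[np.ndarray, np.ndarray]:
    """H-bond presence and distance between waters and solute atoms, per frame.

    Returns ``(bonds, dists)`` of shape (n_frames, n_waters, n_solute):
    ``bonds[f, w, s]`` is True when water ``w`` and solute atom ``s`` are
    hydrogen-bonded in frame ``f`` in either donor direction, and ``dists``
    holds the heavy-atom distances.
    """
    if table is None:
        table = classify_polar_atoms(traj.topology)
    X = traj.coords
    box = traj.box
    water_oxygens = np.asarray(water_oxygens, dtype=int)
    solute_atoms = np.asarray(solute_atoms, dtype=int)
    F, W, S = X.shape[0], len(water_oxygens), len(solute_atoms)
    bonds = np.zeros((F, W, S), dtype=bool)
    dists = np.full((F, W, S), np.inf)
    explicit = criterion.hydrogen_mode == EXPLICIT
    acceptors = set(table.acceptors)

    for wi, w in enumerate(water_oxygens):
        w_h = table.donors.get(int(w), [])
        Ow = X[:, w, :]
        for si, s in enumerate(solute_atoms):
            s = int(s)
            delta = X[:, s, :] - Ow
            if box is not None:
                delta = minimum_image(delta, box)
            d = np.linalg.norm(delta, axis=1)
            dists[:, wi, si] = d
            close = d < criterion.d_max
            if not close.any():
                continue
            ok = np.zeros(F, dtype=bool)
            s_eff = Ow + delta  # acceptor/solute position in the water's image
            # direction 1: water donates to a solute acceptor
            if s in acceptors:
                if not explicit:
                    ok |= close
                else:
                    for h in w_h:
                        dh = X[:, h, :] - Ow
                        if box is not None:
                            dh = minimum_image(dh, box)
                        H = Ow + dh
                        ang = _angles_deg(Ow - H, s_eff - H)
                        ok |= close & (ang > criterion.theta_min)
            # direction 2: solute donor donates to the water oxygen
            if s in table.donors:
                if not explicit:
                    ok |= close
                else:
                    for h in table.donors[s]:
                        hd = X[:, h, :] - X[:, s, :]
                        if box is not None:
                            hd = minimum_image(hd, box)
                        # hydrogen placed in the water's image frame
                        H = s_eff + hd
                        ang = _angles_deg(s_eff - H, Ow - H)
                        ok |= close & (ang > criterion.theta_min)
            bonds[:, wi, si] = ok
    return bonds, dists


# ---------------------------------------------------------------------------
# Declared-site state series and statistics
# ---------------------------------------------------------------------------

def bridge_state_series(traj: Trajectory, site: BridgeDefinition,
                        criterion: HBondCriterion = HBondCriterion(),
                        table: PolarTable | None = None) -> BridgeStateSeries:
    """Which water (if any) fully forms the declared bridge in each frame.

    The occupant must H-bond *every* site atom simultaneously.  When several
    waters qualify, the one with the smallest sum of heavy-atom distances
    wins; exact ties go to the lower water id.
    """
    topo = traj.topology
    for idx in site.site_atoms:
        if topo.atoms[idx].is_water:
            raise ValueError(f"site atom {idx} is a water; bridge sites are "
                             "defined by solute atoms")
    waters = topo.water_oxygen_indices()
    occupant = np.full(traj.n_frames, NO_WATER, dtype=int)
    if len(waters) == 0:
        return BridgeStateSeries(occupant=occupant, dt_ps=traj.dt_ps)
    bonds, dists = water_solute_bond_matrix(
        traj, waters, np.array(site.site_atoms), table=table, criterion=criterion)
    all_bonded = bonds.all(axis=2)                       # (F, W)
    sumd = np.where(all_bonded, dists.sum(axis=2), np.inf)
    best = np.argmin(sumd, axis=1)                       # ties -> lower index
    has = all_bonded.any(axis=1)
    occupant[has] = waters[best[has]]
    return BridgeStateSeries(occupant=occupant, dt_ps=traj.dt_ps)


def _run_length_encode(ids: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(ids) + 1):
        if i == len(ids) or ids[i] != ids[start]:
            runs.append((int(ids[start]), i - start))
            start = i
    return runs


def bridge_statistics(series: BridgeStateSeries,
                      gap_tolerance_ps: float = 0.0) -> BridgeStats:
    """Occupancy, binding events and residence times for a state series.

    Occupancy is the raw fraction of occupied frames.  An event is a maximal
    run of the same water id; an interruption (empty or different occupant)
    shorter than ``gap_tolerance_ps`` is absorbed into the event if and only
    if the same water resumes, and absorbed gap frames count toward the
    event's duration (span from first to last occupied frame).
    """
    if gap_tolerance_ps < 0:
        raise ValueError("gap_tolerance_ps must be non-negative")
    ids = np.asarray(series.occupant)
    if ids.size == 0:
        raise ValueError("empty state series")
    dt = series.dt_ps
    occupied = ids != NO_WATER
    occupancy = float(occupied.mean() * 100.0)
    exchange = int(np.sum(occupied[1:] & occupied[:-1] & (ids[1:] != ids[:-1])))

    runs = _run_length_encode(ids)
    events: list[int] = []  # event spans in frames
    i = 0
    while i < len(runs):
        rid, rlen = runs[i]
        if rid == NO_WATER:
            i += 1
            continue
        span = rlen
        j = i + 1
        while j < len(runs):
            # accumulate interruption until rid resumes
            gap = 0
            k = j
            while k < len(runs) and runs[k][0] != rid:
                gap += runs[k][1]
                k += 1
            if k < len(runs) and gap * dt < gap_tolerance_ps:
                span += gap + runs[k][1]
                j = k + 1
            else:
                break
        events.append(span)
        i = j
    durations_ns = np.array(events, dtype=float) * dt / 1000.0
    return BridgeStats(
        occupancy_percent=occupancy,
        n_events=len(events),
        max_binding_ns=float(durations_ns.max()) if events else 0.0,
        mean_binding_ns=float(durations_ns.mean()) if events else 0.0,
        exchange_count=exchange,
    )


def event_lengths(series: BridgeStateSeries) -> np.ndarray:
    """Durations (ns) of maximal same-water runs, gap tolerance 0."""
    runs = _run_length_encode(np.asarray(series.occupant))
    return np.array([rlen for rid, rlen in runs if rid != NO_WATER],
                    dtype=float) * series.dt_ps / 1000.0


# ---------------------------------------------------------------------------
# Discovery, classification, salt bridges, per-atom profile
# ---------------------------------------------------------------------------

def _polar_solute_atoms(topo, table: PolarTable) -> np.ndarray:
    polar = sorted(set(table.donor_indices) | set(table.acceptors))
    return np.array([i for i in polar if not topo.atoms[i].is_water], dtype=int)


def discover_bridges(traj: Trajectory,
                     criterion: HBondCriterion = HBondCriterion(),
                     min_occupancy_percent: float = 10.0,
                     solute_partition: tuple | None = None,
                     table: PolarTable | None = None,
                     ) -> list[tuple[BridgeDefinition, BridgeStats]]:
    """Enumerate solute atom pairs bridged by a common water.

    Considers every pair of polar solute atoms (restricted to cross-partition
    pairs when ``solute_partition=(group_a_ids, group_b_ids)`` is given, e.g.
    protein vs RNA) and reports those whose pairwise bridge occupancy reaches
    the threshold, sorted by occupancy descending.
    """
    if not (0 < min_occupancy_percent <= 100):
        raise ValueError("min_occupancy_percent must be in (0, 100]")
    topo = traj.topology
    if table is None:
        table = classify_polar_atoms(topo)
    solute = _polar_solute_atoms(topo, table)
    waters = topo.water_oxygen_indices()
    if len(solute) < 2 or len(waters) == 0:
        return []
    bonds, dists = water_solute_bond_matrix(traj, waters, solute,
                                            table=table, criterion=criterion)
    pos = {int(a): k for k, a in enumerate(solute)}
    if solute_partition is not None:
        ga = [pos[int(i)] for i in solute_partition[0] if int(i) in pos]
        gb = [pos[int(i)] for i in solute_partition[1] if int(i) in pos]
        pairs = [(min(i, j), max(i, j)) for i in ga for j in gb if i != j]
        pairs = sorted(set(pairs))
    else:
        pairs = list(itertools.combinations(range(len(solute)), 2))

    out = []
    for i, j in pairs:
        both = bonds[:, :, i] & bonds[:, :, j]          # (F, W)
        if not both.any():
            continue
        occ = both.any(axis=1).mean() * 100.0
        if occ < min_occupancy_percent:
            continue
        sumd = np.where(both, dists[:, :, i] + dists[:, :, j], np.inf)
        occupant = np.full(traj.n_frames, NO_WATER, dtype=int)
        has = both.any(axis=1)
        occupant[has] = waters[np.argmin(sumd, axis=1)[has]]
        series = BridgeStateSeries(occupant=occupant, dt_ps=traj.dt_ps)
        a1, a2 = int(solute[i]), int(solute[j])
        label = f"{topo.atoms[a1].label()}/{topo.atoms[a2].label()}"
        out.append((BridgeDefinition(site_atoms=(a1, a2), label=label),
                    bridge_statistics(series)))
    out.sort(key=lambda t: (-t[1].occupancy_percent, t[0].site_atoms))
    return out


def classify_waters(traj: Trajectory,
                    criterion: HBondCriterion = HBondCriterion(),
                    shell_cutoff: float = 3.5,
                    table: PolarTable | None = None) -> WaterClassLabels:
    """Label every water in every frame as bulk, first-shell or bridging.

    Bridging: H-bonded to at least two distinct solute atoms.  First shell:
    within ``shell_cutoff`` of any solute heavy atom.  Bulk: the rest.
    """
    topo = traj.topology
    if table is None:
        table = classify_polar_atoms(topo)
    waters = topo.water_oxygen_indices()
    solute_heavy = topo.solute_indices(include_hydrogen=False)
    solute_polar = _polar_solute_atoms(topo, table)
    F, W = traj.n_frames, len(waters)
    labels = np.zeros((F, W), dtype=np.int8)
    if W == 0:
        return WaterClassLabels(labels=labels, water_oxygens=waters)

    if len(solute_polar):
        bonds, _ = water_solute_bond_matrix(traj, waters, solute_polar,
                                            table=table, criterion=criterion)
        bridging = bonds.sum(axis=2) >= 2
    else:
        bridging = np.zeros((F, W), dtype=bool)

    if len(solute_heavy):
        X = traj.coords
        sh = X[:, solute_heavy, :]
        for wi, w in enumerate(waters):
            delta = sh - X[:, [w], :]
            if traj.box is not None:
                delta = minimum_image(delta, traj.box)
            dmin = np.linalg.norm(delta, axis=2).min(axis=1)
            labels[dmin < shell_cutoff, wi] = 1
    labels[bridging] = 2
    return WaterClassLabels(labels=labels, water_oxygens=waters)


def saltbridge_states(traj: Trajectory, cation_atoms, anion_atoms,
                      criterion: HBondCriterion = HBondCriterion(),
                      direct_cutoff: float = 3.5,
                      table: PolarTable | None = None,
                      ) -> tuple[np.ndarray, dict[str, float]]:
    """Classify a salt bridge per frame as direct, water-mediated or separated.

    Direct: any cation–anion heavy-atom distance at most ``direct_cutoff``.
    Water-mediated: otherwise, some single water H-bonds an atom of each set.
    Returns the per-frame state labels and their percentage populations.
    """
    cation_atoms = np.asarray(list(cation_atoms), dtype=int)
    anion_atoms = np.asarray(list(anion_atoms), dtype=int)
    if len(cation_atoms) == 0 or len(anion_atoms) == 0:
        raise ValueError("cation and anion atom sets must be non-empty")
    if set(cation_atoms.tolist()) & set(anion_atoms.tolist()):
        raise ValueError("cation and anion atom sets overlap")
    topo = traj.topology
    if table is None:
        table = classify_polar_atoms(topo)
    X = traj.coords
    delta = X[:, cation_atoms, None, :] - X[:, None, anion_atoms, :]
    if traj.box is not None:
        delta = minimum_image(delta, traj.box)
    dmin = np.linalg.norm(delta, axis=3).reshape(traj.n_frames, -1).min(axis=1)
    direct = dmin <= direct_cutoff

    waters = topo.water_oxygen_indices()
    if len(waters):
        both = np.concatenate([cation_atoms, anion_atoms])
        bonds, _ = water_solute_bond_matrix(traj, waters, both,
                                            table=table, criterion=criterion)
        nc = len(cation_atoms)
        mediated_any = (bonds[:, :, :nc].any(axis=2)
                        & bonds[:, :, nc:].any(axis=2)).any(axis=1)
    else:
        mediated_any = np.zeros(traj.n_frames, dtype=bool)

    states = np.where(direct, "direct",
                      np.where(mediated_any, "water_mediated", "separated"))
    pops = {s: float(np.mean(states == s) * 100.0)
            for s in ("direct", "water_mediated", "separated")}
    return states, pops


def per_atom_hydration_profile(traj: Trajectory,
                               criterion: HBondCriterion = HBondCriterion(),
                               table: PolarTable | None = None) -> pd.DataFrame:
    """Hydration pattern of the individual solute atoms.

    One row per polar solute atom: the percentage of frames in which it
    H-bonds at least one water, and its mean number of water H-bonds.
    """
    topo = traj.topology
    if table is None:
        table = classify_polar_atoms(topo)
    solute = _polar_solute_atoms(topo, table)
    waters = topo.water_oxygen_indices()
    rows = []
    if len(solute) and len(waters):
        bonds, _ = water_solute_bond_matrix(traj, waters, solute,
                                            table=table, criterion=criterion)
        any_pct = bonds.any(axis=1).mean(axis=0) * 100.0
        mean_ct = bonds.sum(axis=1).mean(axis=0)
    else:
        any_pct = np.zeros(len(solute))
        mean_ct = np.zeros(len(solute))
    for k, idx in enumerate(solute):
        a = topo.atoms[int(idx)]
        rows.append({
            "atom_index": int(idx),
            "label": a.label(),
            "chain": a.chain_id,
            "pct_frames_hbonded": float(any_pct[k]),
            "mean_hbond_count": float(mean_ct[k]),
        })
    return pd.DataFrame(rows, columns=["atom_index", "label", "chain",
                                       "pct_frames_hbonded", "mean_hbond_count"])
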