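"""Geometric hydrogen-bond criterion and per-frame H-bond detection.

A hydrogen bond is called present when the donor/acceptor heavy-atom distance
is below ``d_max`` (default 3.5 Å) and, when hydrogens are available, the
donor–hydrogen–acceptor angle measured at the hydrogen exceeds ``theta_min``
(default 120°).  Both comparisons are strict.  Crystal structures usually lack
hydrogens, so a distance-only mode is provided and is the default for static
structures; simulation topologies carry explicit hydrogens and use the full
angular criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import StructureModel, minimum_image

logger = logging.getLogger(__name__)

EXPLICIT = "explicit"
DISTANCE_ONLY = "distance_only"


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond definition (distance ceiling, angle floor, H handling)."""

    d_max: float = 3.5
    theta_min: float = 120.0
    hydrogen_mode: str = EXPLICIT

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.theta_min < 180):
            raise ValueError("theta_min must be in (0, 180)")
        if self.hydrogen_mode not in (EXPLICIT, DISTANCE_ONLY):
            raise ValueError(f"unknown hydrogen_mode {self.hydrogen_mode!r}")


@dataclass
class PolarTable:
    """Donor and acceptor atom indices for a structure.

    ``donors`` maps each donor heavy-atom index to the indices of its attached
    hydrogens (empty in hydrogen-free structures); ``acceptors`` is a list of
    acceptor heavy-atom indices.
    """

    donors: dict[int, list[int]] = field(default_factory=dict)
    acceptors: list[int] = field(default_factory=list)

    @property
    def donor_indices(self) -> list[int]:
        return list(self.donors)


@dataclass
class HBond:
    donor: int
    acceptor: int
    distance: float
    hydrogen: int | None = None
    angle: float | None = None


# ---------------------------------------------------------------------------
# Polar-atom chemistry dictionary
# ---------------------------------------------------------------------------
# (residue name, atom name) -> "D", "A" or "DA".  Backbone handled separately.

_SIDECHAIN_POLAR: dict[tuple[str, str], str] = {}


def _add(resnames, atoms, kind):
    for r in resnames:
        for a in atoms:
            _SIDECHAIN_POLAR[(r, a)] = kind


_add(["SER"], ["OG"], "DA")
_add(["THR"], ["OG1"], "DA")
_add(["TYR"], ["OH"], "DA")
_add(["CYS"], ["SG"], "DA")
_add(["ASN"], ["OD1"], "A")
_add(["ASN"], ["ND2"], "D")
_add(["GLN"], ["OE1"], "A")
_add(["GLN"], ["NE2"], "D")
_add(["ASP"], ["OD1", "OD2"], "A")
_add(["GLU"], ["OE1", "OE2"], "A")
_add(["HIS", "HID", "HIE", "HIP"], ["ND1", "NE2"], "DA")
_add(["LYS"], ["NZ"], "D")
_add(["ARG"], ["NE", "NH1", "NH2"], "D")
_add(["TRP"], ["NE1"], "D")
_add(["MET"], ["SD"], "A")

_RNA_NAMES = ["A", "C", "G", "U", "RA", "RC", "RG", "RU",
              "A5", "C5", "G5", "U5", "A3", "C3", "G3", "U3"]
# sugar/phosphate, common to all nucleotides
_add(_RNA_NAMES, ["O2'"], "DA")
_add(_RNA_NAMES, ["O3'", "O4'", "O5'"], "A")
_add(_RNA_NAMES, ["OP1", "OP2", "O1P", "O2P"], "A")
# bases
for _r in ("A", "RA", "A5", "A3"):
    _add([_r], ["N6"], "D")
    _add([_r], ["N1", "N3", "N7"], "A")
for _r in ("G", "RG", "G5", "G3"):
    _add([_r], ["N1", "N2"], "D")
    _add([_r], ["O6", "N3", "N7"], "A")
for _r in ("C", "RC", "C5", "C3"):
    _add([_r], ["N4"], "D")
    _add([_r], ["O2", "N3"], "A")
for _r in ("U", "RU", "U5", "U3"):
    _add([_r], ["N3"], "D")
    _add([_r], ["O2", "O4"], "A")

_PROTEIN_NAMES = frozenset(
    ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HID",
     "HIE", "HIP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
     "TRP", "TYR", "VAL"])

_KNOWN_RESNAMES = (_PROTEIN_NAMES | set(_RNA_NAMES)
                   | {"HOH", "WAT", "SOL", "TIP3"})

_H_BOND_LENGTH = 1.2  # Å; a hydrogen within this of a heavy atom is bonded to it


def classify_polar_atoms(model: StructureModel) -> PolarTable:
    """Build the donor/acceptor table for a structure.

    Water oxygens are both donors (with their two hydrogens, when present) and
    acceptors; backbone amide N donates and carbonyl O accepts (proline N does
    not donate); side-chain and nucleotide polar atoms follow a built-in
    chemistry dictionary.  Atoms of unknown residues are skipped with a
    warning.
    """
    table = PolarTable()
    coords = model.coords()

    # index hydrogens by residue for donor attachment
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(model.atoms):
        by_res.setdefault((a.chain_id, a.residue_number), []).append(i)

    def attached_h(i: int) -> list[int]:
        res_atoms = by_res[(model.atoms[i].chain_id, model.atoms[i].residue_number)]
        out = []
        for j in res_atoms:
            if model.atoms[j].is_hydrogen:
                if np.linalg.norm(coords[j] - coords[i]) <= _H_BOND_LENGTH:
                    out.append(j)
        return out

    warned: set[str] = set()
    for i, a in enumerate(model.atoms):
        if a.is_hydrogen or a.is_ion:
            continue
        rname = a.residue_name.strip()
        if rname not in _KNOWN_RESNAMES:
            if rname not in warned:
                warnings.warn(f"unknown residue {rname!r}: atoms skipped",
                              stacklevel=2)
                logger.warning("unknown residue %r: atoms skipped", rname)
                warned.add(rname)
            continue
        if a.is_water:
            table.donors[i] = attached_h(i)
            table.acceptors.append(i)
            continue
        name = a.name.strip()
        if rname in _PROTEIN_NAMES:
            if name == "N" and rname != "PRO":
                table.donors[i] = attached_h(i)
                continue
            if name in ("O", "OXT"):
                table.acceptors.append(i)
                continue
        kind = _SIDECHAIN_POLAR.get((rname, name))
        if kind is None:
            continue
        if "D" in kind:
            table.donors[i] = attached_h(i)
        if "A" in kind:
            table.acceptors.append(i)
    return table


# ---------------------------------------------------------------------------
# The criterion itself
# ---------------------------------------------------------------------------

def angle_at_vertex(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a–vertex–b in degrees."""
    v1 = np.asarray(a, dtype=float) - vertex
    v2 = np.asarray(b, dtype=float) - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def hbond_present(donor_pos: np.ndarray, hydrogen_positions,
                  acceptor_pos: np.ndarray,
                  criterion: HBondCriterion = HBondCriterion(),
                  box: np.ndarray | None = None
                  ) -> tuple[bool, float, float | None]:
    """Evaluate the geometric criterion for one donor→acceptor pair.

    Returns ``(present, heavy-atom distance, best D–H–A angle or None)``.
    In explicit mode any attached hydrogen giving an angle above the floor
    qualifies the bond and the largest angle is reported.
    """
    donor_pos = np.asarray(donor_pos, dtype=float)
    acceptor_pos = np.asarray(acceptor_pos, dtype=float)
    delta = acceptor_pos - donor_pos
    if box is not None:
        delta = minimum_image(delta, box)
    dist = float(np.linalg.norm(delta))
    if criterion.hydrogen_mode == DISTANCE_ONLY:
        return dist < criterion.d_max, dist, None
    hydrogen_positions = [np.asarray(h, dtype=float) for h in hydrogen_positions]
    if not hydrogen_positions:
        raise ValueError("explicit hydrogen_mode requires at least one hydrogen")
    best = -1.0
    acc_eff = donor_pos + delta  # minimum-image position of the acceptor
    for h in hydrogen_positions:
        dh = h - donor_pos
        if box is not None:
            dh = minimum_image(dh, box)
        h_eff = donor_pos + dh
        best = max(best, angle_at_vertex(donor_pos, h_eff, acc_eff))
    present = dist < criterion.d_max and best > criterion.theta_min
    return present, dist, best


def detect_frame_hbonds(frame: np.ndarray, table: PolarTable,
                        criterion: HBondCriterion = HBondCriterion(),
                        scope=None, box: np.ndarray | None = None
                        ) -> list[HBond]:
    """All qualifying donor→acceptor H-bonds in one coordinate frame.

    ``scope`` restricts the pairs considered: either ``None`` (all pairs), a
    ``(donor_index_set, acceptor_index_set)`` pair of collections, or a
    callable ``f(donor_idx, acceptor_idx) -> bool``.  Each direction is
    evaluated once; self-pairs are excluded.  Neighbour search uses a k-d tree
    at radius ``d_max``; results are identical to exhaustive evaluation.
    """
    frame = np.asarray(frame, dtype=float)
    donor_filter = acceptor_filter = None
    pair_ok = None
    if callable(scope):
        pair_ok = scope
    elif scope is not None:
        dset, aset = scope
        donor_filter = set(int(i) for i in dset)
        acceptor_filter = set(int(i) for i in aset)

    donors = [d for d in table.donors
              if donor_filter is None or d in donor_filter]
    acceptors = [a for a in table.acceptors
                 if acceptor_filter is None or a in acceptor_filter]
    if not donors or not acceptors:
        return []

    acc_idx = np.array(acceptors, dtype=int)
    acc_pos = frame[acc_idx]
    if box is not None:
        tree = cKDTree(np.mod(acc_pos, box), boxsize=box)
    else:
        tree = cKDTree(acc_pos)
    out: list[HBond] = []
    for d in donors:
        dpos = frame[d]
        qpos = np.mod(dpos, box) if box is not None else dpos
        for k in tree.query_ball_point(qpos, criterion.d_max):
            a = int(acc_idx[k])
            if a == d:
                continue
            if pair_ok is not None and not pair_ok(d, a):
                continue
            hpos = [frame[h] for h in table.donors[d]]
            if criterion.hydrogen_mode == EXPLICIT and not hpos:
                continue  # donor without hydrogens cannot qualify in explicit mode
            ok, dist, ang = hbond_present(dpos, hpos, frame[a], criterion, box=box)
            if ok:
                hyd = None
                if ang is not None and hpos:
                    angles = [angle_at_vertex(dpos, h, frame[a]) for h in hpos] \
                        if box is None else None
                    if angles is not None:
                        hyd = table.donors[d][int(np.argmax(angles))]
                out.append(HBond(donor=d, acceptor=a, distance=dist,
                                 hydrogen=hyd, angle=ang))
    out.sort(key=lambda hb: (hb.donor, hb.acceptor))
    return out
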