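"""Structure and trajectory I/O, crystal symmetry expansion, and water filters.

Coordinates are Cartesian ångströms throughout.  Residue numbering is taken
verbatim from the input file; no renumbering is attempted (cross-referencing
between structures with different numbering is handled by user-supplied
per-chain offsets in the comparison routines).

PDB parsing and writing go through :mod:`gemmi`; the in-memory model here is a
flat, analysis-oriented atom table rather than a hierarchy, because every
downstream operation (H-bond detection, shell counting, clustering) works on
atom index arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

#: Residue names recognized as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

#: Common monatomic ions excluded from water analyses.
ION_RESNAMES = frozenset({"K", "NA", "CL", "MG", "ZN", "CA", "K+", "NA+", "CL-"})


class PDBParseError(ValueError):
    """Raised for malformed mandatory PDB record columns."""


class TrajectoryFormatError(ValueError):
    """Raised when trajectory frames are inconsistent with the topology."""


@dataclass
class Atom:
    """One atom record.

    ``position`` is a length-3 float array in Å.  ``symmetry_tag`` is empty for
    atoms read from a file and names the generating operator/lattice shift for
    atoms produced by :func:`expand_symmetry`.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    symmetry_tag: str = ""

    @property
    def is_water(self) -> bool:
        return self.residue_name.strip() in WATER_RESNAMES

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.strip().upper() in ("H", "D")
        return self.name.strip().startswith(("H", "D"))

    @property
    def is_ion(self) -> bool:
        return self.residue_name.strip() in ION_RESNAMES

    def label(self, one_letter: bool = True) -> str:
        """``S155(OG)``-style label used in hydration-site tables."""
        code = _one_letter(self.residue_name) if one_letter else self.residue_name
        return f"{code}{self.residue_number}({self.name})"


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _one_letter(resname: str) -> str:
    r = resname.strip()
    return _AA3TO1.get(r, r)


@dataclass
class StructureModel:
    """Flat atom collection with optional crystallographic metadata.

    ``unit_cell`` is ``(a, b, c, alpha, beta, gamma)`` in Å/degrees;
    ``symmetry_ops`` is a list of ``(rotation, translation)`` pairs acting on
    fractional coordinates, the identity first.
    """

    atoms: list[Atom] = field(default_factory=list)
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] | None = None

    # -- convenience views -------------------------------------------------
    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} does not "
                             f"match atom count {len(self.atoms)}")
        for a, xyz in zip(self.atoms, coords):
            a.position = xyz.copy()

    def indices(self, *, water: bool | None = None, hydrogen: bool | None = None,
                chain: str | None = None) -> np.ndarray:
        """Atom indices filtered by water/hydrogen status and chain."""
        out = []
        for i, a in enumerate(self.atoms):
            if water is not None and a.is_water != water:
                continue
            if hydrogen is not None and a.is_hydrogen != hydrogen:
                continue
            if chain is not None and a.chain_id != chain:
                continue
            out.append(i)
        return np.array(out, dtype=int)

    def water_oxygen_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if a.is_water and not a.is_hydrogen], dtype=int)

    def solute_indices(self, include_hydrogen: bool = True) -> np.ndarray:
        """Non-water, non-ion atoms (the protein/RNA solute)."""
        return np.array([i for i, a in enumerate(self.atoms)
                         if not a.is_water and not a.is_ion
                         and (include_hydrogen or not a.is_hydrogen)], dtype=int)

    def validate(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite position for atom {a.serial}")
            if not (0.0 <= a.occupancy <= 1.0):
                raise ValueError(f"occupancy {a.occupancy} outside [0,1] for atom {a.serial}")
            if a.b_factor < 0:
                raise ValueError(f"negative B-factor for atom {a.serial}")


@dataclass
class Trajectory:
    """Fixed topology plus an ordered stack of coordinate frames.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``dt_ps`` is the frame
    spacing in picoseconds; ``box`` holds orthorhombic box lengths when
    periodic minimum-image treatment is wanted.
    """

    topology: StructureModel
    coords: np.ndarray
    dt_ps: float
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryFormatError(
                f"coords shape {self.coords.shape} inconsistent with topology "
                f"({self.topology.n_atoms} atoms)")
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: str) -> None:
    """Reject truncated ATOM/HETATM records, citing the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: truncated {rec} record on line {lineno} "
                    f"(need at least 54 columns, got {len(line.rstrip())})")


def _atoms_from_gemmi_model(model: gemmi.Model) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                # keep altloc A or blank only
                if at.altloc not in ("", "A", "\x00"):
                    continue
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name if at.element else "",
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                ))
    return atoms


def _symmetry_ops_for(space_group: str) -> list[tuple[np.ndarray, np.ndarray]] | None:
    sg = gemmi.find_spacegroup_by_name(space_group)
    if sg is None:
        return None
    den = float(gemmi.Op.DEN)
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / den
        tran = np.array(op.tran, dtype=float) / den
        ops.append((rot, tran))
    # put the identity first
    ops.sort(key=lambda rt: 0 if (np.allclose(rt[0], np.eye(3)) and
                                  np.allclose(rt[1], 0)) else 1)
    return ops


def read_structure(path: str) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Parses ATOM/HETATM records (first model only), flags waters, and extracts
    the unit cell and space group from CRYST1 when present, resolving the
    space group's symmetry operators.
    """
    _validate_pdb_lines(str(path))
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports its own line numbers
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        return StructureModel()
    atoms = _atoms_from_gemmi_model(st[0])

    unit_cell = None
    space_group = None
    sym_ops = None
    cell = st.cell
    if cell and cell.a > 1.0:  # gemmi uses a dummy 1 Å cell when CRYST1 absent
        unit_cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        if st.spacegroup_hm:
            space_group = st.spacegroup_hm
            sym_ops = _symmetry_ops_for(space_group)
    return StructureModel(atoms=atoms, unit_cell=unit_cell,
                          space_group=space_group, symmetry_ops=sym_ops)


def write_structure(model: StructureModel, path: str) -> None:
    """Write a :class:`StructureModel` as a PDB file (CRYST1 included when known)."""
    st = gemmi.Structure()
    st.name = "model"
    if model.unit_cell is not None:
        st.cell = gemmi.UnitCell(*model.unit_cell)
    if model.space_group is not None:
        st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    # group atoms by (chain, residue) preserving order; gemmi's add_* copy
    # their argument, so containers are built bottom-up
    by_chain: dict[str, list[list[Atom]]] = {}
    res_key = None
    for a in model.atoms:
        cid = a.chain_id or "A"
        key = (cid, a.residue_number, a.residue_name)
        if key != res_key:
            by_chain.setdefault(cid, []).append([])
            res_key = key
        by_chain[cid][-1].append(a)
    for cid, residues in by_chain.items():
        chain = gemmi.Chain(cid)
        for res_atoms in residues:
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(res_atoms[0].residue_number, " ")
            res.het_flag = "H" if (res_atoms[0].is_water or res_atoms[0].is_ion) else "A"
            for a in res_atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[:1])
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.serial = a.serial
                res.add_atom(ga)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(topology_path: str, coords_path: str, dt_ps: float,
                    box: np.ndarray | None = None) -> Trajectory:
    """Read a trajectory from a multi-model PDB or the plain coordinate dialect.

    The plain dialect is a header line ``natoms nframes`` followed by
    ``natoms × nframes`` lines of ``x y z`` in Å, frames concatenated.
    """
    topo = read_structure(topology_path)
    with open(coords_path) as fh:
        first = fh.readline()
    if first.startswith(("MODEL", "ATOM", "HETATM", "CRYST1", "REMARK", "TITLE", "HEADER", "EXPDTA")):
        frames = _read_multimodel_pdb(coords_path, topo.n_atoms)
    else:
        frames = _read_plain_dialect(coords_path, topo.n_atoms)
    return Trajectory(topology=topo, coords=frames, dt_ps=dt_ps, box=box)


def _read_multimodel_pdb(path: str, n_atoms: int) -> np.ndarray:
    st = gemmi.read_pdb(str(path))
    frames = []
    for imodel, model in enumerate(st):
        xyz = [[at.pos.x, at.pos.y, at.pos.z]
               for chain in model for res in chain for at in res
               if at.altloc in ("", "A", "\x00")]
        if len(xyz) != n_atoms:
            raise TrajectoryFormatError(
                f"{path}: frame {imodel} has {len(xyz)} atoms, topology has {n_atoms}")
        frames.append(xyz)
    return np.array(frames, dtype=float)


def _read_plain_dialect(path: str, n_atoms: int) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise TrajectoryFormatError(f"{path}: expected header 'natoms nframes'")
        na, nf = int(header[0]), int(header[1])
        if na != n_atoms:
            raise TrajectoryFormatError(
                f"{path}: header declares {na} atoms, topology has {n_atoms}")
        values = []
        for line in fh:
            line = line.strip()
            if line:
                values.append([float(v) for v in line.split()[:3]])
    total = na * nf
    if len(values) != total:
        frame_reached = len(values) // na
        raise TrajectoryFormatError(
            f"{path}: got {len(values)} coordinate lines for {na}×{nf}; "
            f"file ends inside frame {frame_reached}")
    return np.array(values, dtype=float).reshape(nf, na, 3)


def write_trajectory_plain(traj: Trajectory, path: str) -> None:
    """Write the plain ``natoms nframes`` coordinate dialect."""
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames}\n")
        for frame in traj.coords:
            for x, y, z in frame:
                fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")


# ---------------------------------------------------------------------------
# Symmetry expansion and crystal water filters
# ---------------------------------------------------------------------------

def expand_symmetry(model: StructureModel) -> StructureModel:
    """Generate all symmetry mates in the 27 neighbouring unit cells.

    The output contains, for every symmetry operator of the space group and
    every lattice translation in {-1,0,1}³, a transformed copy of every atom,
    tagged ``op{i}_t{dx}{dy}{dz}``.  The untransformed (identity, zero-shift)
    copy comes first and preserves the input atoms.  Output size is exactly
    ``n_atoms × n_ops × 27``.
    """
    if model.unit_cell is None or not model.symmetry_ops:
        raise ValueError("expand_symmetry requires unit_cell and symmetry_ops")
    cell = gemmi.UnitCell(*model.unit_cell)
    frac_mat = np.array(cell.frac.mat.tolist())
    orth_mat = np.array(cell.orth.mat.tolist())

    xyz = model.coords()
    frac = xyz @ frac_mat.T
    shifts = [np.array(s, dtype=float)
              for s in sorted(
                  ((dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dz in (-1, 0, 1)),
                  key=lambda s: (s != (0, 0, 0), s))]

    new_atoms: list[Atom] = []
    for iop, (rot, tran) in enumerate(model.symmetry_ops):
        f_op = frac @ rot.T + tran
        for shift in shifts:
            identity_copy = (iop == 0 and np.all(shift == 0))
            cart = (f_op + shift) @ orth_mat.T
            tag = f"op{iop}_t{int(shift[0])}{int(shift[1])}{int(shift[2])}"
            for a, pos in zip(model.atoms, cart):
                if identity_copy:
                    new_atoms.append(a)
                else:
                    new_atoms.append(replace(a, position=pos.copy(), symmetry_tag=tag))
    return StructureModel(atoms=new_atoms, unit_cell=model.unit_cell,
                          space_group=model.space_group,
                          symmetry_ops=model.symmetry_ops)


def count_first_shell_waters(model: StructureModel, chain: str,
                             cutoff: float = 3.5,
                             use_symmetry: bool = False) -> int:
    """Count distinct water oxygens within ``cutoff`` of a chain's heavy atoms.

    With ``use_symmetry`` the waters of all symmetry mates (27 neighbouring
    cells) are considered, so lattice-contact waters contribute; each water
    image counts once.
    """
    if chain not in model.chains:
        raise KeyError(f"chain {chain!r} not in model (chains: {model.chains})")
    chain_idx = [i for i, a in enumerate(model.atoms)
                 if a.chain_id == chain and not a.is_water and not a.is_hydrogen]
    if not chain_idx:
        return 0
    chain_xyz = np.array([model.atoms[i].position for i in chain_idx])

    search_model = expand_symmetry(model) if use_symmetry else model
    wat = [(a.chain_id, a.residue_number, a.symmetry_tag, a.position)
           for a in search_model.atoms if a.is_water and not a.is_hydrogen]
    if not wat:
        return 0
    wxyz = np.array([w[3] for w in wat])
    tree = cKDTree(chain_xyz)
    dmin, _ = tree.query(wxyz, k=1)
    near = dmin < cutoff
    distinct = {wat[i][:3] for i in np.nonzero(near)[0]}
    return len(distinct)


def filter_refinement_waters(model: StructureModel, d_min: float = 2.0,
                             d_max: float = 4.0, b_max: float = 50.0) -> StructureModel:
    """Apply crystallographic water-modelling filters.

    Keeps only waters whose nearest non-water heavy-atom distance lies in
    ``[d_min, d_max]`` and whose B-factor is at most ``b_max``; all non-water
    atoms pass through unchanged.
    """
    if d_min >= d_max:
        raise ValueError(f"d_min ({d_min}) must be < d_max ({d_max})")
    other_idx = [i for i, a in enumerate(model.atoms)
                 if not a.is_water and not a.is_hydrogen]
    tree = cKDTree(np.array([model.atoms[i].position for i in other_idx])) \
        if other_idx else None

    kept: list[Atom] = []
    keep_water_res: set[tuple[str, int]] = set()
    for a in model.atoms:
        if not a.is_water:
            kept.append(a)
            continue
        if a.is_hydrogen:
            continue  # decided below with its oxygen
        ok = False
        if tree is not None and a.b_factor <= b_max:
            d, _ = tree.query(a.position)
            ok = d_min <= d <= d_max
        if ok:
            kept.append(a)
            keep_water_res.add((a.chain_id, a.residue_number))
    # re-attach hydrogens of retained waters, if any
    for a in model.atoms:
        if a.is_water and a.is_hydrogen and (a.chain_id, a.residue_number) in keep_water_res:
            kept.append(a)
    return StructureModel(atoms=kept, unit_cell=model.unit_cell,
                          space_group=model.space_group,
                          symmetry_ops=model.symmetry_ops)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the orthorhombic minimum image."""
    return delta - box * np.round(delta / box)
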