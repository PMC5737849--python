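"""Water-oxygen occupancy density grids on a trajectory.

After rigid superposition of every frame onto a reference, the space around
the solute is divided into small cubic voxels (edge 0.5 Å, i.e. 0.125 Å³
volume) and the presence of a water oxygen inside each voxel is tallied at
every frame.  Dividing by the expected count for bulk water (number density
0.0334 Å⁻³ at ambient conditions) converts the histogram into a fold-over-bulk
map whose local maxima are hydration-site peaks — the simulation analogue of a
crystallographic water density map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .consensus import BACKBONE_NAMES, kabsch_superpose
from .structures import Trajectory

#: Number density of pure water at ambient conditions, Å⁻³.
BULK_WATER_NUMBER_DENSITY = 0.0334


@dataclass
class DensityGrid:
    origin: np.ndarray
    voxel_edge: float
    counts: np.ndarray  # (nx, ny, nz) int
    n_frames: int

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.counts.shape)

    @property
    def voxel_volume(self) -> float:
        return self.voxel_edge ** 3

    def relative_density(self,
                         bulk_number_density: float = BULK_WATER_NUMBER_DENSITY
                         ) -> np.ndarray:
        """Per-voxel density as a fold over bulk water."""
        expected = self.n_frames * self.voxel_volume * bulk_number_density
        return self.counts / expected

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_edge


@dataclass
class DensityPeak:
    position: np.ndarray
    relative_density: float
    mean_occupancy: float


def default_fit_selection(traj: Trajectory) -> np.ndarray:
    """Protein backbone N/CA/C heavy atoms — the default superposition frame."""
    topo = traj.topology
    idx = [i for i, a in enumerate(topo.atoms)
           if not a.is_water and not a.is_ion and not a.is_hydrogen
           and a.name in ("N", "CA", "C")]
    if len(idx) < 3:
        idx = [i for i in topo.solute_indices(include_hydrogen=False)]
    return np.array(idx, dtype=int)


def superpose_trajectory(traj: Trajectory,
                         reference_selection=None) -> Trajectory:
    """Rigid-body fit every frame onto frame 0 over the given selection.

    The Kabsch rotation+translation computed on the selection is applied to
    all atoms (waters ride along), so internal geometry is untouched.
    """
    sel = (np.asarray(reference_selection, dtype=int)
           if reference_selection is not None else default_fit_selection(traj))
    if len(sel) < 3:
        raise ValueError("reference selection needs at least 3 atoms")
    ref = traj.coords[0, sel, :]
    span = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-8) < 2:
        raise ValueError("reference selection is degenerate (collinear points)")
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        tr = kabsch_superpose(ref, traj.coords[f, sel, :])
        out[f] = tr.apply(traj.coords[f])
    return Trajectory(topology=traj.topology, coords=out, dt_ps=traj.dt_ps,
                      box=None)


def accumulate_density(traj: Trajectory, voxel_edge: float = 0.5,
                       region: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> DensityGrid:
    """Histogram water-oxygen positions on a cubic voxel grid.

    ``region`` is ``(lower_corner, upper_corner)``; by default the solute
    bounding box padded by 5 Å.  Voxel intervals are half-open ``[low, high)``
    so boundary positions are assigned deterministically to the lower-index
    voxel.  The caller is responsible for superposing the trajectory first.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    if region is None:
        solute = traj.topology.solute_indices(include_hydrogen=False)
        if len(solute) == 0:
            raise ValueError("no solute atoms to derive an automatic region from")
        sx = traj.coords[0, solute, :]
        lo, hi = sx.min(axis=0) - 5.0, sx.max(axis=0) + 5.0
    else:
        lo, hi = np.asarray(region[0], dtype=float), np.asarray(region[1], dtype=float)
    dims = np.maximum(np.ceil((hi - lo) / voxel_edge).astype(int), 1)
    counts = np.zeros(tuple(dims), dtype=np.int64)

    waters = traj.topology.water_oxygen_indices()
    if len(waters):
        W = traj.coords[:, waters, :].reshape(-1, 3)
        idx = np.floor((W - lo) / voxel_edge).astype(int)
        inside = np.all((idx >= 0) & (idx < dims), axis=1)
        idx = idx[inside]
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return DensityGrid(origin=lo, voxel_edge=voxel_edge, counts=counts,
                       n_frames=traj.n_frames)


def normalize_and_find_peaks(grid: DensityGrid,
                             bulk_number_density: float = BULK_WATER_NUMBER_DENSITY,
                             threshold_fold: float = 2.0) -> list[DensityPeak]:
    """Local density maxima exceeding a fold-over-bulk threshold.

    A peak voxel is a 26-neighbourhood local maximum whose relative density is
    at least ``threshold_fold``; peaks are returned sorted by relative density
    descending (ties by voxel index).
    """
    if grid.n_frames <= 0:
        raise ValueError("grid has no frames")
    rel = grid.relative_density(bulk_number_density)
    if rel.size == 0 or rel.max() < threshold_fold:
        return []
    local_max = (ndimage.maximum_filter(rel, size=3, mode="constant") == rel)
    cand = np.argwhere(local_max & (rel >= threshold_fold) & (grid.counts > 0))
    peaks = [DensityPeak(position=grid.voxel_center(ijk),
                         relative_density=float(rel[tuple(ijk)]),
                         mean_occupancy=float(grid.counts[tuple(ijk)] / grid.n_frames))
             for ijk in cand]
    peaks.sort(key=lambda p: (-p.relative_density, tuple(p.position)))
    return peaks


# ---------------------------------------------------------------------------
# OpenDX scalar-field export / import
# ---------------------------------------------------------------------------

def export_map(grid: DensityGrid, path: str, field: str = "counts",
               bulk_number_density: float = BULK_WATER_NUMBER_DENSITY) -> None:
    """Write the grid as an OpenDX scalar field readable by PyMOL/VMD.

    ``field`` selects raw ``counts`` or the ``relative`` fold-over-bulk
    density.  Data follow the DX convention: the last (z) index varies
    fastest.
    """
    nx, ny, nz = grid.dims
    if field == "counts":
        data = grid.counts.astype(float)
    elif field == "relative":
        data = grid.relative_density(bulk_number_density)
    else:
        raise ValueError(f"unknown field {field!r}")
    e = grid.voxel_edge
    ox, oy, oz = grid.origin
    flat = data.reshape(-1)  # C order: z fastest
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6g} {oy:.6g} {oz:.6g}\n")
        fh.write(f"delta {e:.6g} 0 0\n")
        fh.write(f"delta 0 {e:.6g} 0\n")
        fh.write(f"delta 0 0 {e:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} "
                 "data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_map(path: str) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`export_map`.

    The frame count is not stored in DX, so the returned grid has
    ``n_frames=1`` and ``counts`` holding the stored values.
    """
    dims = origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[:4] == ["object", "1", "class", "gridpositions"]:
                dims = tuple(int(v) for v in tok[-3:])
            elif tok[0] == "origin":
                origin = np.array([float(v) for v in tok[1:4]])
            elif tok[0] == "delta":
                deltas.append([float(v) for v in tok[1:4]])
            elif "data" in tok and "follows" in tok:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items is not None and len(values) < n_items:
                try:
                    values.extend(float(v) for v in tok)
                except ValueError:
                    break
    if dims is None or origin is None or n_items is None:
        raise ValueError(f"{path}: not a recognisable DX scalar field")
    edge = float(deltas[0][0]) if deltas else 1.0
    counts = np.array(values[:n_items]).reshape(dims)
    return DensityGrid(origin=origin, voxel_edge=edge, counts=counts, n_frames=1)
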