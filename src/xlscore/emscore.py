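"""Simulated 3D-EM density and the map-fitness score F = (n x MI) - PS.

A structure is blurred into a density map by summing per-atom Gaussians
whose full width at half maximum equals the nominal resolution, weighted
by atomic number.  Fit to a target map is measured by the mutual
information (MI) of the joint intensity histogram, and steric
interpenetration of subunits by a clash penalty (PS).  The fitness of a
model with ``n`` subunits against a map is ``F = n x MI - PS``, and the
combined crosslink + EM score is ``F + 0.5 x cMNXL``.

The blur kernel, the 20x20 equal-width MI binning and the clash-fraction
penalty are deliberately simple, config-exposed reconstructions of the
standard density-fitting ingredients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import ComplexStructure
from .sasd import vdw_radius

__all__ = [
    "DensityMap",
    "simulate_map",
    "mutual_information",
    "clash_penalty",
    "f_score",
    "combined_score",
    "FitnessResult",
    "read_mrc",
    "write_mrc",
]

ATOMIC_NUMBERS = {"C": 6, "N": 7, "O": 8, "S": 16}
MI_BINS = 20


@dataclass
class DensityMap:
    """A cubic-voxel density map; ``values[ix, iy, iz]``, origin in A."""

    origin: np.ndarray
    voxel_size: float
    values: np.ndarray
    resolution_label: float = 0.0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")


@dataclass
class FitnessResult:
    mi: float
    ps: float
    n_subunits: int
    f: float
    combined: float | None = None

    def as_dict(self) -> dict:
        return {
            "mi": self.mi,
            "ps": self.ps,
            "n_subunits": self.n_subunits,
            "f": self.f,
            "combined": self.combined,
        }


def simulate_map(
    complex_: ComplexStructure, resolution: float, voxel_size: float = 3.0
) -> DensityMap:
    """Blur a structure into a density map at a nominal resolution.

    Each atom contributes an isotropic Gaussian with
    ``sigma = resolution / (2 sqrt(2 ln 2))`` (FWHM equal to the nominal
    resolution), weighted by its atomic number.  The map extends 2 sigma
    beyond the structure.
    """
    if resolution < 2 * voxel_size:
        raise ValueError(
            f"resolution {resolution} undersampled at voxel size {voxel_size}; "
            "need resolution >= 2 x voxel size"
        )
    coords, elements, _ = complex_.atom_table()
    sigma = resolution / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    margin = 2.0 * sigma
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    values = np.zeros(tuple(shape))
    cutoff = 3.0 * sigma
    n = int(math.ceil(cutoff / voxel_size))
    weights = np.array([ATOMIC_NUMBERS.get(e, 6) for e in elements], dtype=float)
    for xyz, w in zip(coords, weights):
        ci = np.rint((xyz - lo) / voxel_size).astype(int)
        sl = tuple(
            slice(max(0, ci[d] - n), min(shape[d], ci[d] + n + 1)) for d in range(3)
        )
        axes = [
            (np.arange(sl[d].start, sl[d].stop) * voxel_size + lo[d]) - xyz[d]
            for d in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        values[sl] += w * np.exp(-0.5 * d2 / (sigma * sigma))
    return DensityMap(origin=lo, voxel_size=voxel_size, values=values, resolution_label=resolution)


def resample_onto(source: DensityMap, target: DensityMap) -> np.ndarray:
    """Trilinearly resample ``source`` onto ``target``'s grid (outside -> 0)."""
    idx = np.indices(target.values.shape, dtype=float)
    world = target.origin[:, None, None, None] + idx * target.voxel_size
    src_idx = (world - source.origin[:, None, None, None]) / source.voxel_size
    return ndimage.map_coordinates(source.values, src_idx, order=1, mode="constant", cval=0.0)


def mutual_information(map_a: DensityMap, map_b: DensityMap, bins: int = MI_BINS) -> float:
    """MI (natural log) of the joint intensity histogram of two maps.

    Maps on different grids are first resampled onto the coarser of the
    two.  Each axis of the joint histogram uses equal-width bins over that
    map's own intensity range.
    """
    # reference grid: the coarser map; on a tie, a canonical choice by
    # extent then origin so that MI stays symmetric in its arguments
    def _rank(m):
        return (m.voxel_size, m.values.size, tuple(np.round(m.origin, 6)))

    if _rank(map_a) >= _rank(map_b):
        coarse, fine = map_a, map_b
    else:
        coarse, fine = map_b, map_a
    same_grid = (
        map_a.values.shape == map_b.values.shape
        and np.allclose(map_a.origin, map_b.origin)
        and map_a.voxel_size == map_b.voxel_size
    )
    a = coarse.values
    b = fine.values if same_grid else resample_onto(fine, coarse)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant density map: mutual information is 0")
        return 0.0
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def clash_penalty(
    complex_: ComplexStructure, scale: float = 1.0, overlap_factor: float = 0.5
) -> float:
    """Fraction of atoms in hard inter-subunit clashes, times ``scale``.

    Two atoms of different subunits clash when their centres are closer
    than ``overlap_factor`` times the sum of their van der Waals radii.
    """
    if complex_.n_subunits < 2:
        raise ValueError("clash penalty requires at least 2 subunits")
    coords, elements, sub_idx = complex_.atom_table()
    radii = np.array([vdw_radius(e) for e in elements])
    max_cut = overlap_factor * 2 * radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    inter = sub_idx[i] != sub_idx[j]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    clash = inter & (d < overlap_factor * (radii[i] + radii[j]))
    involved = np.zeros(len(coords), dtype=bool)
    involved[i[clash]] = True
    involved[j[clash]] = True
    return scale * float(involved.mean())


def f_score(
    model: ComplexStructure,
    target: DensityMap,
    voxel_size: float | None = None,
    clash_scale: float = 1.0,
    bins: int = MI_BINS,
) -> FitnessResult:
    """Fitness of a model against a target map: ``F = n x MI - PS``."""
    if model.n_subunits < 2:
        raise ValueError("fitness requires a multi-subunit model")
    sim = simulate_map(
        model, target.resolution_label, voxel_size or target.voxel_size
    )
    mi = mutual_information(target, sim, bins=bins)
    ps = clash_penalty(model, scale=clash_scale)
    n = model.n_subunits
    return FitnessResult(mi=mi, ps=ps, n_subunits=n, f=n * mi - ps)


def combined_score(f: float, cmnxl: float) -> float:
    """Crosslink + EM combination: ``F + 0.5 x cMNXL``."""
    if not (math.isfinite(f) and math.isfinite(cmnxl)):
        raise ValueError("scores must be finite")
    return f + 0.5 * cmnxl


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O


def write_mrc(density: DensityMap, path: str) -> None:
    """Write a map as MRC (mode-2 float voxels, origin in A in the header)."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(density.values, dtype=np.float32))
    nx, ny, nz = density.values.shape
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * density.voxel_size, ny * density.voxel_size, nz * density.voxel_size,
            90.0, 90.0, 90.0,
        )
    )
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    for i, val in enumerate(density.origin, start=50):  # ORIGIN words 50-52
        m.set_header_float(i, float(val))
    m.set_header_float(40, float(density.resolution_label))  # extra word: resolution
    m.write_ccp4_map(path)


def read_mrc(path: str) -> DensityMap:
    """Read an MRC/CCP4 map written by :func:`write_mrc`."""
    m = gemmi.read_ccp4_map(path)
    values = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    origin = np.array([m.header_float(i) for i in (50, 51, 52)])
    resolution = m.header_float(40)
    return DensityMap(
        origin=origin,
        voxel_size=float(voxel),
        values=values.astype(float),
        resolution_label=float(resolution),
    )
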