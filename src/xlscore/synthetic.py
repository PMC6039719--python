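"""Synthetic toy complexes, decoy ensembles and crosslink benchmarks.

Real decoy benchmarks for crosslink scoring are large external datasets;
this module builds miniature but structurally meaningful stand-ins:
irregular curved poly-alanine helices docked at a contact interface, with
surface lysines substituted at solvent-exposed positions so that a
theoretical crosslink set exists, plus decoy ensembles produced by random
rigid-body perturbation of the subunits with a main-chain clash filter
and near-uniform meanRMSD coverage.

Everything is deterministic under a seed, so fixtures are generated at
run time rather than shipped.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import ComplexStructure, Residue, StructureError, Subunit, write_pdb, write_crosslinks
from .quality import QualityMetrics, assess_quality, mean_rmsd
from .sasd import SASDCalculator, build_grid, enumerate_theoretical_crosslinks
from .benchmark import sample_recovery

__all__ = [
    "DecoyRecipe",
    "make_toy_complex",
    "make_benchmark_complex",
    "make_occlusion_fixture",
    "generate_decoys",
    "make_benchmark",
    "Benchmark",
    "write_fixture_files",
]

_HELIX_RISE = 1.5          # A per residue along the axis
_HELIX_TWIST = 100.0       # degrees per residue
_HELIX_RADIUS = 2.3        # C-alpha radius
_CB_LENGTH = 1.53
_NZ_REACH = 6.0            # approximate CA->NZ side-chain extension
_SUBUNIT_SEPARATION = 10.0  # axis-to-axis distance of adjacent subunits

MAINCHAIN_ATOMS = ("N", "CA", "C", "O")
#: Hard-clash distance between main-chain atoms of different subunits.
MAINCHAIN_CLASH_CUTOFF = 2.0


@dataclass
class DecoyRecipe:
    """Parameters of rigid-body decoy generation.

    Per decoy, each subunit is perturbed over a small number of
    iterations (geometric, mean ``mean_iterations``); each iteration
    applies a per-axis translation uniform in ``trans_range`` and a
    rotation about a random axis through the subunit centroid with an
    angle uniform in ``rot_range`` (degrees).  A per-decoy magnitude
    factor uniform in (0, 1] scales both ranges so that the ensemble
    covers the whole near-native-to-wrecked spectrum; decoys are then
    selected toward a uniform meanRMSD histogram.  Candidates with more
    than ``max_mainchain_clashes`` inter-subunit main-chain atom pairs
    closer than 2 A are rejected.
    """

    n_decoys: int = 100
    trans_range: tuple[float, float] = (-5.0, 5.0)
    rot_range: tuple[float, float] = (0.0, 180.0)
    max_mainchain_clashes: int = 20
    target_rmsd_distribution: str = "uniform"
    rng_seed: int = 0
    mean_iterations: float = 3.0
    n_bins: int = 10
    pool_factor: int = 8
    max_draw_factor: int = 200

    def __post_init__(self):
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if self.trans_range[0] > self.trans_range[1] or self.rot_range[0] > self.rot_range[1]:
            raise ValueError("invalid perturbation ranges")
        if self.target_rmsd_distribution not in ("uniform", "none"):
            raise ValueError("target_rmsd_distribution must be 'uniform' or 'none'")


def _curved_axis(n_res: int, rng, curvature: float):
    """Smooth seeded random space curve for the helix axis.

    The axis direction performs a small random-walk drift per residue, so
    every subunit is an irregular, non-symmetric shape — idealised
    straight helices have flip pseudo-symmetries that let completely
    wrong poses reproduce native crosslink geometry.
    """
    d = np.array([0.0, 0.0, 1.0])
    a = np.zeros(3)
    axis_pts, dirs = [], []
    for _ in range(n_res):
        axis_pts.append(a.copy())
        dirs.append(d.copy())
        perp = rng.normal(size=3)
        perp -= (perp @ d) * d
        nrm = np.linalg.norm(perp)
        if nrm > 1e-12:
            d = d + curvature * perp / nrm
            d /= np.linalg.norm(d)
        a = a + _HELIX_RISE * d
    # parallel-transport frames along the curve
    u = np.array([1.0, 0.0, 0.0])
    frames = []
    for dd in dirs:
        u = u - (u @ dd) * dd
        u /= np.linalg.norm(u)
        frames.append((u.copy(), np.cross(dd, u)))
    return np.asarray(axis_pts), frames


def _irregular_subunit(
    chain_id: str,
    n_res: int,
    lysine_positions: set[int],
    geometry_rng,
    curvature: float = 0.06,
) -> Subunit:
    """Poly-alanine helix wound around a seeded irregular axis."""
    axis, frames = _curved_axis(n_res, geometry_rng, curvature)
    ca, outward = [], []
    for i, (u, v) in enumerate(frames):
        theta = math.radians(_HELIX_TWIST * i)
        radial = math.cos(theta) * u + math.sin(theta) * v
        ca.append(axis[i] + _HELIX_RADIUS * radial)
        outward.append(radial)
    residues = []
    for i in range(n_res):
        prev_ca = ca[i - 1] if i > 0 else 2 * ca[0] - ca[1]
        next_ca = ca[i + 1] if i < n_res - 1 else 2 * ca[-1] - ca[-2]
        atoms = {
            "N": 0.65 * ca[i] + 0.35 * prev_ca,
            "CA": ca[i].copy(),
            "C": 0.65 * ca[i] + 0.35 * next_ca,
        }
        atoms["O"] = atoms["C"] + 1.23 * outward[i]
        atoms["CB"] = ca[i] + _CB_LENGTH * outward[i]
        seq = i + 1
        if seq in lysine_positions:
            atoms["NZ"] = ca[i] + _NZ_REACH * outward[i]
            residues.append(Residue(seq, "LYS", atoms))
        else:
            residues.append(Residue(seq, "ALA", atoms))
    return Subunit(chain_id, residues)


def _subunit_outwards(sub: Subunit) -> dict[int, np.ndarray]:
    """Per-residue outward unit vectors recovered from the CB direction."""
    out = {}
    for r in sub.residues:
        w = r.atoms["CB"] - r.atoms["CA"]
        out[r.seq_number] = w / np.linalg.norm(w)
    return out


_DOCK_GAP = 4.0  # closest heavy-atom approach when docking subunits (A)


def _dock_shift(placed_coords: np.ndarray, mobile_coords: np.ndarray,
                direction: np.ndarray) -> float:
    """Smallest shift along ``direction`` placing mobile at _DOCK_GAP contact."""
    tree = cKDTree(placed_coords)

    def min_dist(s):
        d, _ = tree.query(mobile_coords + s * direction, k=1)
        return d.min()

    lo, hi = 0.0, 80.0
    while min_dist(hi) < _DOCK_GAP:
        hi += 20.0
    while hi - lo > 0.01:
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < _DOCK_GAP:
            lo = mid
        else:
            hi = mid
    return hi


def make_toy_complex(
    n_subunits: int = 2,
    residues_per_subunit: int = 32,
    n_surface_lysines: int = 20,
    rng_seed: int = 0,
    identical_subunits: bool = False,
    curvature: float = 0.06,
    min_inter_pairs: int = 4,
) -> ComplexStructure:
    """Build a toy multi-subunit complex with accessible surface lysines.

    Subunits are irregular curved helices (seeded) docked side by side at
    van der Waals contact.  Lysines are substituted at positions whose
    side chains point outside the interface core, placed so that
    inter-subunit anchor distances cluster near the reference crosslink
    mean, and verified to be solvent accessible on the voxel grid;
    buried picks are swapped for spare candidates.  ``identical_subunits`` reuses one
    geometry and one lysine set for every chain, producing a symmetric
    homo-oligomer for chain-ambiguity handling.  Deterministic under
    ``rng_seed``.

    The default lysine count (10 per subunit) reflects the lysine-rich
    complexes on which crosslink-driven modelling works well; complexes
    with few surface lysines are known hard cases.  Geometries whose
    theoretical crosslink set carries fewer than ``min_inter_pairs``
    inter-subunit links are unusable as restraint benchmarks and are
    re-drawn deterministically from follow-up seeds.
    """
    if n_subunits < 2:
        raise StructureError("a complex needs at least 2 subunits")
    if identical_subunits:
        # symmetric homo-oligomers serve chain-ambiguity handling; their
        # inter-link richness is not a usability requirement
        min_inter_pairs = 0
    for attempt in range(16):
        complex_ = _make_toy_once(
            n_subunits, residues_per_subunit, n_surface_lysines,
            rng_seed + 1000003 * attempt, identical_subunits, curvature,
        )
        if min_inter_pairs <= 0:
            return complex_
        links = enumerate_theoretical_crosslinks(complex_, spacing=1.5)
        n_inter = sum(l.classification == "inter" for l in links)
        if n_inter >= min_inter_pairs:
            return complex_
    raise RuntimeError(
        f"could not realise a toy complex with >= {min_inter_pairs} "
        "inter-subunit theoretical crosslinks"
    )


def _make_toy_once(
    n_subunits, residues_per_subunit, n_surface_lysines,
    rng_seed, identical_subunits, curvature,
):
    rng = np.random.default_rng(rng_seed)
    geometry_seeds = [int(rng.integers(2**31)) for _ in range(n_subunits)]
    if identical_subunits:
        geometry_seeds = [geometry_seeds[0]] * n_subunits
        spin_angles = [180.0 * k for k in range(n_subunits)]
    else:
        spin_angles = None  # chosen below by interface-breadth scan

    # docking directions in the xy plane
    if n_subunits == 2:
        directions = [np.zeros(3), np.array([1.0, 0.0, 0.0])]
    else:
        directions = [np.zeros(3)] + [
            np.array([
                math.cos(2 * math.pi * k / n_subunits),
                math.sin(2 * math.pi * k / n_subunits),
                0.0,
            ])
            for k in range(1, n_subunits)
        ]

    if spin_angles is None:
        # Choose each subunit's spin about its axis to maximise interface
        # breadth: protein interfaces are complementary surfaces, not
        # point contacts, and a broad interface is what makes compressed
        # or slid poses clash instead of scoring well.
        spin_angles = [0.0]
        placed = None
        for k in range(n_subunits):
            sub = _irregular_subunit(
                chr(ord("A") + k),
                residues_per_subunit,
                set(),
                np.random.default_rng(geometry_seeds[k]),
                curvature=curvature,
            )
            coords = np.array([x for r in sub.residues for x in r.atoms.values()])
            centroid = coords.mean(axis=0)
            if placed is None:
                placed = coords - centroid
                continue
            best_angle, best_contacts = 0.0, -1
            for angle in np.arange(0.0, 360.0, 15.0):
                R = Rotation.from_euler("z", angle, degrees=True).as_matrix()
                local = (coords - centroid) @ R.T
                s = _dock_shift(placed, local, directions[k])
                moved = local + s * directions[k]
                n_contacts = int(
                    (cKDTree(placed).query(moved, k=1)[0] <= 5.0).sum()
                )
                if n_contacts > best_contacts:
                    best_contacts, best_angle = n_contacts, float(angle)
            spin_angles.append(best_angle)
            R = Rotation.from_euler("z", best_angle, degrees=True).as_matrix()
            local = (coords - centroid) @ R.T
            s = _dock_shift(placed, local, directions[k])
            placed = np.vstack([placed, local + s * directions[k]])

    def build(lys_sets):
        subs = []
        placed_coords = None
        for k in range(n_subunits):
            chain_id = chr(ord("A") + k)
            sub = _irregular_subunit(
                chain_id,
                residues_per_subunit,
                lys_sets[k],
                np.random.default_rng(geometry_seeds[k]),
                curvature=curvature,
            )
            R = Rotation.from_euler("z", spin_angles[k], degrees=True).as_matrix()
            coords = np.array([x for r in sub.residues for x in r.atoms.values()])
            centroid = coords.mean(axis=0)
            local = (coords - centroid) @ R.T
            if placed_coords is None:
                shift = np.zeros(3)
                placed_coords = local
            else:
                s = _dock_shift(placed_coords, local, directions[k])
                shift = s * directions[k]
                placed_coords = np.vstack([placed_coords, local + shift])
            t = shift - R @ centroid
            moved = [
                Residue(
                    r.seq_number,
                    r.res_type,
                    {n: R @ x + t for n, x in r.atoms.items()},
                    r.insertion_code,
                )
                for r in sub.residues
            ]
            subs.append(Subunit(chain_id, moved, copy_index=k))
        return ComplexStructure(subs, name=f"toy{n_subunits}x{residues_per_subunit}")

    # A pass without lysines fixes the docking geometry, so interface-facing
    # positions can be identified in world coordinates.
    bare = build([set() for _ in range(n_subunits)])
    center = np.mean(
        [s.ca_coordinates().mean(axis=0) for s in bare.subunits], axis=0
    )
    candidate_sets = []
    for k, sub in enumerate(bare.subunits):
        outwards = _subunit_outwards(sub)
        cands = []
        for r in sub.residues[1:-1]:
            w = outwards[r.seq_number]
            toward_center = center - r.atoms["CA"]
            toward_center /= np.linalg.norm(toward_center)
            if w @ toward_center < 0.4:
                # exclude only the interface core: the candidate pool then
                # spans both near-flank and wrap-around positions, so the
                # placement step can centre the realised link-length
                # distribution on the reference mean
                cands.append(r.seq_number)
        candidate_sets.append(cands)

    per_sub = [n_surface_lysines // n_subunits] * n_subunits
    for k in range(n_surface_lysines % n_subunits):
        per_sub[k] += 1
    if identical_subunits:
        per_sub = [max(per_sub)] * n_subunits
        candidate_sets = [candidate_sets[0]] * n_subunits
    for k in range(n_subunits):
        if per_sub[k] > len(candidate_sets[k]):
            raise ValueError(
                f"requested {per_sub[k]} lysines on subunit {k} but only "
                f"{len(candidate_sets[k])} outward-facing positions exist"
            )

    def spread_picks(cands, want, offset):
        step = max(1, len(cands) // want)
        picks = [cands[(offset + j * step) % len(cands)] for j in range(want)]
        seen = list(dict.fromkeys(picks))
        for c in cands:
            if len(seen) >= want:
                break
            if c not in seen:
                seen.append(c)
        return set(seen[:want])

    if identical_subunits:
        # symmetric copies: one sequence-spread lysine set reused per chain
        shared_offset = int(rng.integers(10**6))
        lys_sets = [
            spread_picks(candidate_sets[k], per_sub[k],
                         shared_offset % len(candidate_sets[k]))
            if per_sub[k] else set()
            for k in range(n_subunits)
        ]
    else:
        lys_sets = _select_crosslinkable_positions(
            build, candidate_sets, per_sub, rng
        )

    complex_ = build(lys_sets)
    from .sasd import is_accessible

    grid = build_grid(complex_)
    for k, sub in enumerate(complex_.subunits):
        buried = [
            r.seq_number
            for r in sub.residues
            if r.res_type == "LYS" and not is_accessible(grid, r)
        ]
        if buried:
            unused = [c for c in candidate_sets[k] if c not in lys_sets[k]]
            for b in buried:
                lys_sets[k].discard(b)
                if unused:
                    lys_sets[k].add(unused.pop(0))
            complex_ = build(lys_sets)
            grid = build_grid(complex_)
    return complex_


def _select_crosslinkable_positions(
    build,
    candidate_sets,
    per_sub,
    rng,
    mu: float = 21.92,
    sigma: float = 4.87,
    max_bound: float = 32.0,
):
    """Choose lysine positions whose inter-subunit surface distances
    cluster in the favourable region of the crosslink distance
    distribution.

    Crosslinks observed on native complexes concentrate around the
    reference mean SASD — that is what the expected-distance term's
    normal distribution describes — so a fixture whose restraints sit at
    the distribution's tails would not represent the data the score
    models.  Selection is greedy (positions added alternately per
    subunit, maximising the summed band density of the inter-subunit
    pairs they create) followed by a local swap refinement; implausibly
    short pairs are penalised.
    """
    from .sasd import is_accessible

    probe = build([set(c) for c in candidate_sets])
    grid = build_grid(probe, spacing=1.5)
    calc = SASDCalculator(grid, cap=max_bound + 3.0, corridor=8.0)
    cand = []  # (subunit index, seq number, residue)
    for k, sub in enumerate(probe.subunits):
        for seq in candidate_sets[k]:
            r = sub.get_residue(seq)
            if is_accessible(grid, r):
                cand.append((k, seq, r))
    D = calc.distance_matrix([r for _, _, r in cand])
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    # the placement band sits slightly above the reference mean and is
    # narrower than the reference spread, partially offsetting the
    # incidental off-band pairs that any 3-D geometry adds
    target_mu = mu
    target_sigma = 0.4 * sigma

    def fd(d, same_subunit=False):
        if same_subunit or not np.isfinite(d) or d > max_bound:
            return 0.0
        if d < 16.0:
            return -0.15  # implausibly short native crosslink
        z = (d - target_mu) / target_sigma
        return norm * math.exp(-0.5 * z * z)

    n_subunits = len(candidate_sets)
    jitter = {i: 1e-9 * rng.standard_normal() for i in range(len(cand))}
    idx_by_sub = [
        [i for i, (ks, _, _) in enumerate(cand) if ks == k]
        for k in range(n_subunits)
    ]
    selected: list[int] = []
    counts = [0] * n_subunits
    while any(counts[k] < per_sub[k] for k in range(n_subunits)):
        progressed = False
        for k in range(n_subunits):
            if counts[k] >= per_sub[k]:
                continue
            pool = [i for i in idx_by_sub[k] if i not in selected]
            if not pool:
                continue
            cross = list(selected) or [
                i for i, (ks, _, _) in enumerate(cand) if ks != k
            ]
            best = max(
                pool,
                key=lambda i: sum(
                    fd(D[i, j], cand[i][0] == cand[j][0]) for j in cross
                )
                + jitter[i],
            )
            selected.append(best)
            counts[k] += 1
            progressed = True
        if not progressed:
            break

    # local swap refinement: greedy additions cannot foresee incidental
    # pairs created by later picks
    def total(sel):
        return sum(
            fd(D[i, j], cand[i][0] == cand[j][0])
            for ii, i in enumerate(sel)
            for j in sel[ii + 1:]
        )

    improved, rounds = True, 0
    while improved and rounds < 4:
        improved = False
        rounds += 1
        for pos in range(len(selected)):
            k = cand[selected[pos]][0]
            base = total(selected)
            for alt in idx_by_sub[k]:
                if alt in selected:
                    continue
                trial = selected.copy()
                trial[pos] = alt
                if total(trial) > base + 1e-12:
                    selected, base, improved = trial, total(trial), True

    lys_sets = [set() for _ in range(n_subunits)]
    for i in selected:
        k, seq, _ = cand[i]
        lys_sets[k].add(seq)
    # pad from raw candidates if accessibility pruned too many
    for k in range(n_subunits):
        spare = [s for s in candidate_sets[k] if s not in lys_sets[k]]
        while len(lys_sets[k]) < per_sub[k] and spare:
            lys_sets[k].add(spare.pop(0))
    return lys_sets


def _count_mainchain_clashes(complex_: ComplexStructure, cutoff: float = MAINCHAIN_CLASH_CUTOFF) -> int:
    coords, subs = [], []
    for si, sub in enumerate(complex_.subunits):
        for res in sub.residues:
            for name in MAINCHAIN_ATOMS:
                if name in res.atoms:
                    coords.append(res.atoms[name])
                    subs.append(si)
    coords = np.asarray(coords)
    subs = np.asarray(subs)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    return int((subs[pairs[:, 0]] != subs[pairs[:, 1]]).sum())


def _random_decoy(native: ComplexStructure, recipe: DecoyRecipe, rng) -> ComplexStructure:
    scale = rng.uniform(0.0, 1.0)
    transforms = {}
    for sub in native.subunits:
        coords = np.concatenate([list(r.atoms.values()) for r in sub.residues])
        R_total = np.eye(3)
        t_total = np.zeros(3)
        k = max(1, int(rng.geometric(1.0 / max(recipe.mean_iterations, 1.0))))
        for _ in range(k):
            t = rng.uniform(*recipe.trans_range, size=3) * scale
            angle = rng.uniform(*recipe.rot_range) * scale
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
            centroid = coords.mean(axis=0) @ R_total.T + t_total
            # rotate about the current centroid, then translate
            R_total = R @ R_total
            t_total = R @ (t_total - centroid) + centroid + t
        transforms[sub.chain_id] = (R_total, t_total)
    return native.transformed(transforms)


def make_benchmark_complex(rng_seed: int = 0) -> ComplexStructure:
    """The canonical restraint-rich benchmark fixture.

    A two-subunit complex large relative to the crosslinker span, with a
    high surface-lysine count (the regime in which crosslink-driven
    model discrimination is reported to work; sparse-lysine or
    undersized complexes are known failure cases) and a theoretical
    crosslink set of at least 60 inter-subunit links.
    """
    return make_toy_complex(
        n_subunits=2,
        residues_per_subunit=60,
        n_surface_lysines=30,
        rng_seed=rng_seed,
        curvature=0.12,
        min_inter_pairs=40,
    )


def make_occlusion_fixture():
    """A deterministic complex with one buried crosslinkable residue.

    Subunit A is a closed shell of backbone pseudo-atoms with a lysine
    caged at its centre (solvent-inaccessible by construction) and one
    exposed lysine on the outside; subunit B carries two exposed
    lysines, one within the crosslinker bound of A's surface lysine and
    one far beyond it.  Returns ``(complex, base_link, buried_link,
    violating_link)`` — the three canonical crosslink fates (reward,
    non-accessible penalty, maximum-bound violation) on one structure.
    """
    from .core import Crosslink

    shell = []
    n_res = 1
    for theta in np.linspace(0.05, math.pi - 0.05, 14):
        n_phi = max(6, int(round(24 * math.sin(theta))))
        for phi in np.linspace(0, 2 * math.pi, n_phi, endpoint=False):
            shell.append(
                8.0
                * np.array(
                    [
                        math.sin(theta) * math.cos(phi),
                        math.sin(theta) * math.sin(phi),
                        math.cos(theta),
                    ]
                )
            )
    # close the poles
    shell.append(np.array([0.0, 0.0, 8.0]))
    shell.append(np.array([0.0, 0.0, -8.0]))
    residues_a = [Residue(1, "LYS", {"CA": np.zeros(3)})]  # caged anchor
    residues_a.append(Residue(2, "LYS", {"CA": np.array([0.0, 0.0, 11.0]),
                                         "NZ": np.array([0.0, 0.0, 14.0])}))
    for i, p in enumerate(shell):
        residues_a.append(Residue(10 + i, "GLY", {"CA": p}))
    residues_b = [
        Residue(1, "LYS", {"CA": np.array([18.0, 0.0, 14.0]),
                           "NZ": np.array([20.0, 0.0, 16.0])}),
        Residue(2, "LYS", {"CA": np.array([52.0, 0.0, 14.0]),
                           "NZ": np.array([54.0, 0.0, 16.0])}),
        Residue(3, "GLY", {"CA": np.array([35.0, 0.0, 14.0])}),
    ]
    cx = ComplexStructure(
        [Subunit("A", residues_a), Subunit("B", residues_b)], name="occlusion"
    )
    base = Crosslink(end_a=("A", 2), end_b=("B", 1), classification="inter")
    buried = Crosslink(end_a=("A", 1), end_b=("B", 1), classification="inter")
    violating = Crosslink(end_a=("A", 2), end_b=("B", 2), classification="inter")
    return cx, base, buried, violating


def generate_decoys(native: ComplexStructure, recipe: DecoyRecipe) -> list[ComplexStructure]:
    """Generate a clash-filtered rigid-body decoy ensemble.

    With the uniform target distribution, a candidate pool several times
    the requested size is drawn and decoys are picked round-robin from
    equal-width meanRMSD bins over the achieved range, flattening the
    quality histogram as far as the pool allows.
    """
    rng = np.random.default_rng(recipe.rng_seed)
    accepted: list[tuple[ComplexStructure, float]] = []
    pool_target = (
        recipe.n_decoys
        if recipe.target_rmsd_distribution == "none"
        else recipe.pool_factor * recipe.n_decoys
    )
    max_draws = recipe.max_draw_factor * recipe.n_decoys
    draws = 0
    while len(accepted) < pool_target and draws < max_draws:
        draws += 1
        cand = _random_decoy(native, recipe, rng)
        if _count_mainchain_clashes(cand) > recipe.max_mainchain_clashes:
            continue
        accepted.append((cand, mean_rmsd(cand, native)))
    if len(accepted) < recipe.n_decoys:
        raise RuntimeError(
            f"decoy generation rejected too many candidates "
            f"({len(accepted)}/{recipe.n_decoys} accepted in {draws} draws); "
            "loosen the recipe"
        )

    if recipe.target_rmsd_distribution == "none":
        chosen = accepted[: recipe.n_decoys]
    else:
        rmsds = np.array([r for _, r in accepted])
        lo, hi = rmsds.min(), rmsds.max()
        if hi - lo < 1e-9:
            chosen = accepted[: recipe.n_decoys]
        else:
            bins = np.clip(
                ((rmsds - lo) / (hi - lo) * recipe.n_bins).astype(int), 0, recipe.n_bins - 1
            )
            by_bin = [
                [i for i in range(len(accepted)) if bins[i] == b]
                for b in range(recipe.n_bins)
            ]
            picked: list[int] = []
            while len(picked) < recipe.n_decoys:
                progressed = False
                for b in range(recipe.n_bins):
                    if by_bin[b] and len(picked) < recipe.n_decoys:
                        picked.append(by_bin[b].pop(0))
                        progressed = True
                if not progressed:
                    break
            chosen = [accepted[i] for i in picked]
    decoys = []
    for i, (d, _r) in enumerate(chosen):
        d.name = f"decoy_{i:03d}"
        decoys.append(d)
    return decoys


@dataclass
class Benchmark:
    """A self-contained synthetic benchmark bundle."""

    native: ComplexStructure
    decoys: list[ComplexStructure]
    theoretical_xl: list
    sampled_xl: list
    quality: list[QualityMetrics]
    rng_seed: int = 0

    @property
    def positives(self) -> np.ndarray:
        return np.array([q.positive for q in self.quality])

    def quality_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model_id": [d.name for d in self.decoys],
                "mean_rmsd": [q.mean_rmsd for q in self.quality],
                "fnat": [q.fnat for q in self.quality],
                "positive": [q.positive for q in self.quality],
            }
        )


def make_benchmark(
    native: ComplexStructure,
    recipe: DecoyRecipe | None = None,
    recovery_rate: float = 0.15,
    rng_seed: int = 0,
    spacing: float = 1.0,
) -> Benchmark:
    """Bundle decoys, theoretical and sampled crosslinks, and quality labels.

    The theoretical crosslink set is enumerated on the native structure;
    the sampled set is a recovery draw (default 15% with at least 2
    inter-subunit links, the typical experimental regime).
    """
    recipe = recipe or DecoyRecipe(rng_seed=rng_seed)
    decoys = generate_decoys(native, recipe)
    theoretical = enumerate_theoretical_crosslinks(native, spacing=spacing)
    sampled = sample_recovery(theoretical, recovery_rate, min_inter=2, rng_seed=rng_seed)
    quality = [assess_quality(d, native) for d in decoys]
    return Benchmark(
        native=native,
        decoys=decoys,
        theoretical_xl=theoretical,
        sampled_xl=sampled,
        quality=quality,
        rng_seed=rng_seed,
    )


@dataclass
class BenchmarkEvaluation:
    """Per-model crosslink contributions of a benchmark, plus the native's.

    ``contributions[i, j]`` is decoy ``i``'s score contribution of the
    ``j``-th theoretical crosslink, so any recovery subset is scored by a
    column sum — the surface distances are computed once per model.
    """

    benchmark: Benchmark
    links: list
    contributions: np.ndarray
    native_contributions: np.ndarray
    params: object

    def scores(self, links=None) -> np.ndarray:
        cols = self._columns(links)
        return self.contributions[:, cols].sum(axis=1)

    def native_score(self, links=None) -> float:
        cols = self._columns(links)
        return float(self.native_contributions[cols].sum())

    def _columns(self, links):
        if links is None:
            return list(range(len(self.links)))
        index_of = {id(xl): j for j, xl in enumerate(self.links)}
        return [index_of[id(xl)] for xl in links]


def evaluate_benchmark(
    benchmark: Benchmark,
    params=None,
    spacing: float = 1.0,
    cap: float | None = None,
    corridor: float | None = None,
    links=None,
) -> BenchmarkEvaluation:
    """Score every decoy (and the native) against a crosslink set.

    ``links`` defaults to the benchmark's sampled (recovered) set; pass
    ``benchmark.theoretical_xl`` to precompute contributions for every
    possible link (needed for recovery-rate scans).  ``cap`` defaults to
    just above the scoring maximum bound: paths beyond it score as
    violations regardless of their exact length.
    """
    from .benchmark import contribution_matrix
    from .scoring import ScoreParams, evaluate_crosslinks

    params = params or ScoreParams()
    if cap is None:
        cap = params.max_bound + 2 * spacing
    if links is None:
        links = benchmark.sampled_xl
    links = list(links)
    evaluated = [
        evaluate_crosslinks(
            m, links, spacing=spacing, cap=cap, corridor=corridor
        )
        for m in benchmark.decoys
    ]
    C = contribution_matrix(evaluated, links, params)
    native_eval = evaluate_crosslinks(
        benchmark.native, links, spacing=spacing, cap=cap, corridor=corridor
    )
    native_C = contribution_matrix([native_eval], links, params)[0]
    return BenchmarkEvaluation(
        benchmark=benchmark,
        links=links,
        contributions=C,
        native_contributions=native_C,
        params=params,
    )


def write_fixture_files(benchmark: Benchmark, directory: str) -> dict:
    """Write native/decoy PDBs, the crosslink TSV and a manifest JSON."""
    os.makedirs(directory, exist_ok=True)
    files = {}
    native_path = os.path.join(directory, "native.pdb")
    write_pdb(benchmark.native, native_path)
    files["native"] = native_path
    decoy_paths = []
    for d in benchmark.decoys:
        p = os.path.join(directory, f"{d.name}.pdb")
        write_pdb(d, p)
        decoy_paths.append(p)
    files["decoys"] = decoy_paths
    xl_path = os.path.join(directory, "crosslinks.tsv")
    write_crosslinks(benchmark.sampled_xl, xl_path)
    files["crosslinks"] = xl_path
    manifest = {
        "seed": benchmark.rng_seed,
        "n_decoys": len(benchmark.decoys),
        "n_theoretical": len(benchmark.theoretical_xl),
        "n_sampled": len(benchmark.sampled_xl),
        "files": files,
    }
    mpath = os.path.join(directory, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    files["manifest"] = mpath
    return manifest
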