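"""The cMNXL score: crosslink restraints versus a complex model.

Each experimental crosslink contributes one of three terms:

* ``ExDist`` — an inter-subunit crosslink whose surface distance is within
  the linker maximum bound is rewarded with the value of a normal density
  fitted to observed crosslink distances, N(21.92, 4.87) on SASD up to
  32 A (N(18.35, 4.11) up to 30 A for the Euclidean variant);
* ``NoV`` — an inter-subunit crosslink whose distance exceeds the bound
  (or has no solvent path under the search cap) is penalised by -0.1;
* ``NoNA`` — any crosslink, inter or intra, with a buried endpoint is
  penalised by -0.1, and the two counts enter the total with weight 3.

The total is ``ExDist + NoV + 3 x (NoNA_inter + NoNA_intra)``.  Accessible
intra-subunit crosslinks carry no distance information about the assembly
and contribute zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ComplexStructure,
    Crosslink,
    DistanceResult,
    Residue,
    StructureError,
)
from .sasd import DEFAULT_PATH_CAP, SASDCalculator, build_grid, compute_ed

__all__ = [
    "ScoreParams",
    "ScoreBreakdown",
    "score_exdist",
    "score_violation",
    "score_nona",
    "resolve_homo_crosslink",
    "resolve_crosslinks",
    "score_cmnxl",
]


@dataclass(frozen=True)
class ScoreParams:
    """Constants of the scoring function for one distance metric.

    SASD defaults: N(21.92, 4.87) truncated at 32 A; ED defaults:
    N(18.35, 4.11) truncated at 30 A.  Both share the -0.1 flat penalties
    and the non-accessibility weight of 3.
    """

    metric: str = "SASD"
    mu: float = 21.92
    sigma: float = 4.87
    max_bound: float = 32.0
    violation_penalty: float = -0.1
    nona_penalty: float = -0.1
    nona_weight: float = 3.0

    def __post_init__(self):
        if self.metric not in ("SASD", "ED"):
            raise ValueError("metric must be 'SASD' or 'ED'")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def sasd(cls, **kw) -> "ScoreParams":
        return cls(metric="SASD", **kw)

    @classmethod
    def ed(cls, **kw) -> "ScoreParams":
        defaults = dict(metric="ED", mu=18.35, sigma=4.11, max_bound=30.0)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class ScoreBreakdown:
    """Per-term decomposition of a cMNXL evaluation."""

    exdist: float = 0.0
    nov: float = 0.0
    nona_inter_count: int = 0
    nona_intra_count: int = 0
    nona_term: float = 0.0
    total: float = 0.0
    per_crosslink: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "exdist": self.exdist,
            "nov": self.nov,
            "nona_inter_count": self.nona_inter_count,
            "nona_intra_count": self.nona_intra_count,
            "nona_term": self.nona_term,
            "total": self.total,
            "per_crosslink": [
                {
                    "end_a": list(xl.end_a),
                    "end_b": list(xl.end_b),
                    "classification": xl.classification,
                    "status": res.status,
                    "sasd": res.sasd if res.sasd is not None and math.isfinite(res.sasd) else None,
                    "ed": res.ed,
                    "contribution": contrib,
                }
                for xl, res, contrib in self.per_crosslink
            ],
        }


def score_exdist(d: float, params: ScoreParams) -> float:
    """Expected-distance reward: normal density at ``d``, zero past the bound.

    The density is unnormalised to a maximum of 1 deliberately — the
    printed penalty constants are calibrated against raw density values.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d > params.max_bound:
        return 0.0
    z = (d - params.mu) / params.sigma
    return math.exp(-0.5 * z * z) / (params.sigma * math.sqrt(2.0 * math.pi))


def score_violation(dist_result: DistanceResult, params: ScoreParams) -> float:
    """Maximum-bound violation penalty for one inter-subunit crosslink.

    A distance exactly at the bound scores under the expected-distance
    branch (the inequalities are <= / >), so the penalty applies strictly
    above it, and to accessible pairs with no solvent path under the cap.
    """
    if dist_result.status == "non_accessible":
        raise ValueError("non-accessible crosslinks are scored by the NoNA term")
    if dist_result.status == "no_path":
        return params.violation_penalty
    d = dist_result.sasd if params.metric == "SASD" else dist_result.ed
    return params.violation_penalty if d > params.max_bound else 0.0


def score_nona(crosslinks_with_status, params: ScoreParams) -> tuple[int, int, float]:
    """Count non-accessible crosslinks and return the weighted penalty term.

    Returns ``(inter_count, intra_count, score)`` with
    ``score = weight x (inter + intra) x penalty``.
    """
    inter = intra = 0
    for xl, result in crosslinks_with_status:
        if result.status != "non_accessible":
            continue
        if xl.classification == "unresolved":
            raise ValueError("resolve homo-complex crosslinks before scoring")
        if xl.classification == "inter":
            inter += 1
        else:
            intra += 1
    return inter, intra, params.nona_weight * (inter + intra) * params.nona_penalty


def _copy_chains(complex_: ComplexStructure, seq_number: int) -> list[str]:
    """Chains of the complex holding a crosslinkable residue ``seq_number``."""
    out = []
    for sub in complex_.subunits:
        res = sub.get_residue(seq_number)
        if res is not None and res.is_crosslinkable:
            out.append(sub.chain_id)
    return out


def resolve_homo_crosslink(
    complex_: ComplexStructure,
    xl: Crosslink,
    calculator: SASDCalculator,
) -> list[Crosslink]:
    """Assign a chain-ambiguous homo-complex crosslink by lowest SASD.

    All chain-copy combinations of the two residue numbers are evaluated
    on the (native) structure and the combination with the lowest SASD is
    kept — even when that SASD exceeds the maximum bound, in which case
    the crosslink will later score as a violation.  The reciprocal
    combination under swapping the two assigned chains is emitted as well,
    mirroring how identical subunits are treated as unique copies.  If no
    combination is evaluable the first combination by chain order is kept
    and will score as non-accessible.
    """
    if xl.classification != "unresolved":
        raise ValueError("crosslink is already resolved")
    seq_a, seq_b = xl.end_a[1], xl.end_b[1]
    chains_a = _copy_chains(complex_, seq_a)
    chains_b = _copy_chains(complex_, seq_b)
    if len(set(chains_a) | set(chains_b)) < 2 or not chains_a or not chains_b:
        raise StructureError(
            "homo-complex resolution requires >=2 candidate chain copies"
        )
    combos = []
    for ca in chains_a:
        for cb in chains_b:
            if (ca, seq_a) != (cb, seq_b):
                combos.append((ca, cb))
    best = None
    best_d = np.inf
    for ca, cb in combos:
        ra = complex_.get_residue(ca, seq_a)
        rb = complex_.get_residue(cb, seq_b)
        res = calculator.distance(ra, rb)
        if res.status == "ok" and res.sasd < best_d:
            best, best_d = (ca, cb), res.sasd
    if best is None:
        best = combos[0]  # everything buried: fixed arbitrary assignment

    def _mk(ca, cb):
        return Crosslink(
            end_a=(ca, seq_a),
            end_b=(cb, seq_b),
            linker_arm=xl.linker_arm,
            max_bound_sasd=xl.max_bound_sasd,
            max_bound_ed=xl.max_bound_ed,
            classification=Crosslink.classify(ca, cb),
        )

    ca, cb = best
    resolved = [_mk(ca, cb)]
    if ca != cb:
        swap = {ca: cb, cb: ca}
        rec = (swap.get(ca, ca), swap.get(cb, cb))
        if rec != best and ((rec[0], seq_a) != (rec[1], seq_b)):
            resolved.append(_mk(*rec))
    return resolved


def resolve_crosslinks(
    complex_: ComplexStructure, crosslinks, calculator: SASDCalculator
) -> list[Crosslink]:
    """Resolve every unresolved crosslink in a list against a native complex."""
    out = []
    for xl in crosslinks:
        if xl.classification == "unresolved":
            out.extend(resolve_homo_crosslink(complex_, xl, calculator))
        else:
            out.append(xl)
    return out


def evaluate_crosslinks(
    complex_: ComplexStructure,
    crosslinks,
    calculator: SASDCalculator | None = None,
    spacing: float = 1.0,
    cap: float | None = None,
    corridor: float | None = None,
    need_sasd_intra: bool = False,
) -> list[tuple[Crosslink, DistanceResult]]:
    """Compute the distance result for each crosslink on a model.

    Accessible intra-subunit crosslinks score zero regardless of their
    distance, so their surface path is skipped unless requested; their
    accessibility is still grid-determined.  A ``cap`` tighter than the
    default search cap trades the exact length of over-long paths (which
    score identically as violations) for speed.
    """
    if calculator is None:
        grid = build_grid(complex_, spacing=spacing)
        calculator = SASDCalculator(
            grid, cap=cap if cap is not None else DEFAULT_PATH_CAP, corridor=corridor
        )

    # Collect the unique residues whose SASD is actually needed.
    needed: dict[tuple[str, int], Residue] = {}
    for xl in crosslinks:
        if xl.classification == "unresolved":
            raise ValueError("resolve homo-complex crosslinks before scoring")
        if xl.classification == "inter" or need_sasd_intra:
            for chain, seq in (xl.end_a, xl.end_b):
                needed[(chain, seq)] = complex_.get_residue(chain, seq)
    keys = list(needed)
    pos = {k: i for i, k in enumerate(keys)}
    pair_idx = [
        (pos[xl.end_a], pos[xl.end_b])
        for xl in crosslinks
        if xl.end_a in pos and xl.end_b in pos
    ]
    dmat = (
        calculator.distance_matrix([needed[k] for k in keys], pairs=pair_idx)
        if keys
        else np.empty((0, 0))
    )

    results = []
    for xl in crosslinks:
        ra = complex_.get_residue(*xl.end_a)
        rb = complex_.get_residue(*xl.end_b)
        ed = compute_ed(ra, rb)
        if xl.end_a in pos and xl.end_b in pos:
            d = dmat[pos[xl.end_a], pos[xl.end_b]]
            if np.isnan(d):
                res = DistanceResult(status="non_accessible", ed=ed)
            elif np.isinf(d):
                res = DistanceResult(status="no_path", ed=ed)
            else:
                res = DistanceResult(status="ok", ed=ed, sasd=float(d))
        else:
            from .sasd import is_accessible

            if is_accessible(calculator.grid, ra) and is_accessible(calculator.grid, rb):
                # accessible intra link: its SASD is never scored, so the
                # path search is skipped and the value marked as unset
                res = DistanceResult(status="ok", ed=ed, sasd=math.nan)
            else:
                res = DistanceResult(status="non_accessible", ed=ed)
        results.append((xl, res))
    return results


def crosslink_contribution(
    xl: Crosslink, result: DistanceResult, params: ScoreParams
) -> float:
    """Score contribution of a single crosslink given its distance result."""
    if result.status == "non_accessible":
        return params.nona_weight * params.nona_penalty
    if xl.classification == "intra":
        return 0.0
    if result.status == "no_path":
        return params.violation_penalty
    d = result.sasd if params.metric == "SASD" else result.ed
    if d > params.max_bound:
        return params.violation_penalty
    return score_exdist(d, params)


def score_cmnxl(
    complex_: ComplexStructure,
    crosslinks,
    params: ScoreParams | None = None,
    calculator: SASDCalculator | None = None,
    spacing: float = 1.0,
    cap: float | None = None,
) -> ScoreBreakdown:
    """Score a complex model against a set of resolved crosslinks.

    With ``params.metric == 'ED'`` the distances entering the reward and
    violation branches are Euclidean, but accessibility is still decided
    on the voxel grid, so the non-accessibility information is retained.
    """
    params = params or ScoreParams()
    crosslinks = list(crosslinks)
    if not crosslinks:
        warnings.warn("empty crosslink set: cMNXL is 0 by convention")
        return ScoreBreakdown()
    evaluated = evaluate_crosslinks(
        complex_, crosslinks, calculator=calculator, spacing=spacing, cap=cap
    )
    bd = ScoreBreakdown()
    for xl, res in evaluated:
        contrib = crosslink_contribution(xl, res, params)
        if res.status == "non_accessible":
            if xl.classification == "inter":
                bd.nona_inter_count += 1
            else:
                bd.nona_intra_count += 1
        elif xl.classification == "inter":
            if contrib == params.violation_penalty and (
                res.status == "no_path"
                or (res.sasd if params.metric == "SASD" else res.ed) > params.max_bound
            ):
                bd.nov += contrib
            else:
                bd.exdist += contrib
        bd.per_crosslink.append((xl, res, contrib))
    bd.nona_term = (
        params.nona_weight
        * (bd.nona_inter_count + bd.nona_intra_count)
        * params.nona_penalty
    )
    bd.total = bd.exdist + bd.nov + bd.nona_term
    return bd
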