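"""Model accuracy against a native structure: meanRMSD and fnat.

``meanRMSD`` superposes the whole model onto the native once per subunit
— fitting only that subunit's C-alpha atoms by least squares — computes
the whole-model C-alpha RMSD after each fit, and averages over subunits.
A model is a *positive* (acceptable model) when meanRMSD <= 4 A and
fnat >= 0.3, matching the CAPRI medium-quality threshold.

``fnat`` is the fraction of native inter-subunit residue contacts (any
pair of atoms within 5 A, inclusive) that the model maintains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ComplexStructure, StructureError

__all__ = ["QualityMetrics", "mean_rmsd", "fnat", "assess_quality", "kabsch"]

RMSD_POSITIVE_CUTOFF = 4.0
FNAT_POSITIVE_CUTOFF = 0.3
CONTACT_CUTOFF = 5.0


@dataclass(frozen=True)
class QualityMetrics:
    mean_rmsd: float
    fnat: float

    @property
    def positive(self) -> bool:
        return self.mean_rmsd <= RMSD_POSITIVE_CUTOFF and self.fnat >= FNAT_POSITIVE_CUTOFF


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns ``(R, t)`` with
    ``R @ x + t`` minimising the RMSD of ``mobile`` onto ``target``."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def _matched_ca(model: ComplexStructure, native: ComplexStructure):
    """Per-subunit matched C-alpha coordinate arrays (model, native)."""
    out = {}
    for nsub in native.subunits:
        msub = model.get_subunit(nsub.chain_id)
        m_coords, n_coords = [], []
        for nres in nsub.residues:
            if "CA" not in nres.atoms:
                continue
            mres = msub.get_residue(nres.seq_number, nres.insertion_code)
            if mres is None or "CA" not in mres.atoms:
                raise StructureError(
                    f"subunit {nsub.chain_id}: residue {nres.seq_number} lacks a "
                    "matching C-alpha in the model"
                )
            m_coords.append(mres.atoms["CA"])
            n_coords.append(nres.atoms["CA"])
        if len(m_coords) != sum("CA" in r.atoms for r in msub.residues):
            raise StructureError(
                f"subunit {nsub.chain_id}: C-alpha count differs between model and native"
            )
        out[nsub.chain_id] = (np.asarray(m_coords), np.asarray(n_coords))
    return out


def mean_rmsd(model: ComplexStructure, native: ComplexStructure) -> float:
    """Mean over subunits of the whole-model C-alpha RMSD after fitting
    the model to the native on that single subunit."""
    matched = _matched_ca(model, native)
    m_all = np.concatenate([m for m, _ in matched.values()])
    n_all = np.concatenate([n for _, n in matched.values()])
    rmsds = []
    for chain_id, (m_sub, n_sub) in matched.items():
        R, t = kabsch(m_sub, n_sub)
        moved = m_all @ R.T + t
        rmsds.append(float(np.sqrt(np.mean(np.sum((moved - n_all) ** 2, axis=1)))))
    return float(np.mean(rmsds))


def _interface_pairs(complex_: ComplexStructure, cutoff: float):
    """Inter-subunit residue pairs with any-atom distance <= cutoff."""
    per_sub = []
    for sub in complex_.subunits:
        coords, res_ids = [], []
        for res in sub.residues:
            for xyz in res.atoms.values():
                coords.append(xyz)
                res_ids.append(res.seq_number)
        per_sub.append((sub.chain_id, np.asarray(coords), np.asarray(res_ids)))
    pairs = set()
    for i in range(len(per_sub)):
        ci, xi, ri = per_sub[i]
        tree_i = cKDTree(xi)
        for j in range(i + 1, len(per_sub)):
            cj, xj, rj = per_sub[j]
            hits = tree_i.query_ball_point(xj, cutoff)
            for bj, lst in enumerate(hits):
                for ai in lst:
                    pairs.add((ci, int(ri[ai]), cj, int(rj[bj])))
    return pairs


def fnat(model: ComplexStructure, native: ComplexStructure, cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of native inter-subunit residue contacts kept by the model."""
    native_pairs = _interface_pairs(native, cutoff)
    if not native_pairs:
        raise StructureError("native structure has no inter-subunit contacts; fnat undefined")
    model_pairs = _interface_pairs(model, cutoff)
    kept = len(native_pairs & model_pairs)
    return kept / len(native_pairs)


def assess_quality(model: ComplexStructure, native: ComplexStructure) -> QualityMetrics:
    return QualityMetrics(mean_rmsd=mean_rmsd(model, native), fnat=fnat(model, native))
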