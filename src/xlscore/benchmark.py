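"""Score-assessment statistics for decoy benchmarks.

A benchmark is a set of models of one complex, each with a score and a
positive/negative quality label (meanRMSD <= 4 A and fnat >= 0.3).  The
headline statistics are:

* precision — true positives among the 10 top-scoring models, over 10;
* false-positive rate — top-10 negatives over all negatives;
* ROC AUC — threshold sweep over the scores.

When a block of tied scores straddles the rank-10 boundary, the top 10 is
ambiguous: 10 models are drawn at random from the tied set, the statistic
computed, and the draw repeated (default 1000 times) to bootstrap a mean.

Crosslink *recovery* — the fraction of all theoretically possible
crosslinks actually observed — is emulated by sampling the theoretical
set without replacement (default 15%, requiring at least 2 inter-subunit
links, the typical experimental regime).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .core import Crosslink
from .scoring import ScoreParams, crosslink_contribution

__all__ = [
    "BenchmarkResult",
    "precision_top10",
    "fpr_top10",
    "roc_auc",
    "sample_recovery",
    "recovery_curve",
    "scan_weights",
    "paired_onesided_ttest",
    "contribution_matrix",
    "summarize_benchmark",
]

TOP_N = 10
BOOTSTRAP_REPS = 1000


@dataclass
class BenchmarkResult:
    """Summary of one scored benchmark."""

    per_model: list  # (model_id, score, QualityMetrics | bool)
    precision: float
    fpr: float
    auc: float
    roc_points: list
    top_rank_of_best: int
    seed: int | None = None


def _validate(scores, positives, n_top):
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if len(scores) < n_top:
        raise ValueError(f"need at least {n_top} models, got {len(scores)}")
    return scores, positives


def _top_counts(scores, positives, n_top, rng, reps):
    """Mean (TP, FP) in the top ``n_top`` with tie bootstrapping.

    Models strictly above the rank-``n_top`` score are always in; when the
    tied block at that score overflows the remaining slots, the slots are
    filled by uniform draws from the block and averaged over ``reps``.
    """
    order = np.argsort(-scores, kind="stable")
    thr = scores[order[n_top - 1]]
    above = scores > thr
    n_above = int(above.sum())
    tied = scores == thr
    n_tied = int(tied.sum())
    need = n_top - n_above
    tp_above = int((above & positives).sum())
    if n_above + n_tied == n_top:  # ties fit exactly: plain cut
        tp = tp_above + int((tied & positives).sum())
        return float(tp), float(n_top - tp)
    tied_pos = int((tied & positives).sum())
    draws = rng.random((reps, n_tied)).argsort(axis=1)[:, :need]
    pos_mask = np.zeros(n_tied)
    pos_mask[: tied_pos] = 1.0  # uniform draw over the block: order irrelevant
    tp_draw = pos_mask[draws].sum(axis=1)
    tp = tp_above + float(tp_draw.mean())
    return tp, n_top - tp


def precision_top10(
    scores, positives, rng_seed: int = 0, n_top: int = TOP_N, reps: int = BOOTSTRAP_REPS
) -> float:
    """TP / (TP + FP) over the 10 top-ranked models (tie-bootstrapped)."""
    scores, positives = _validate(scores, positives, n_top)
    rng = np.random.default_rng(rng_seed)
    tp, fp = _top_counts(scores, positives, n_top, rng, reps)
    return tp / n_top


def fpr_top10(
    scores, positives, rng_seed: int = 0, n_top: int = TOP_N, reps: int = BOOTSTRAP_REPS
) -> float:
    """FP / (FP + TN): top-10 negatives over all negatives (tie-bootstrapped)."""
    scores, positives = _validate(scores, positives, n_top)
    n_neg = int((~positives).sum())
    if n_neg == 0:
        raise ValueError("false-positive rate undefined: benchmark has no negatives")
    rng = np.random.default_rng(rng_seed)
    tp, fp = _top_counts(scores, positives, n_top, rng, reps)
    return fp / n_neg


def roc_auc(scores, positives) -> tuple[list[tuple[float, float]], float]:
    """ROC by systematic threshold lowering; AUC by trapezoidal integration."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    if positives.all() or (~positives).all():
        raise ValueError("ROC undefined: benchmark must contain both classes")
    fpr, tpr, _ = roc_curve(positives, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def sample_recovery(
    theoretical: list[Crosslink],
    rate: float,
    min_inter: int = 2,
    rng_seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> list[Crosslink]:
    """Sample a recovery subset of the theoretical crosslink set.

    Draws ``round(rate * N)`` links uniformly without replacement
    (round-half-up) and redraws until at least ``min_inter`` inter-subunit
    links are present.
    """
    if not (0 < rate <= 1):
        raise ValueError("recovery rate must be in (0, 1]")
    theoretical = list(theoretical)
    n_inter = sum(xl.classification == "inter" for xl in theoretical)
    if n_inter < min_inter:
        raise ValueError(
            f"theoretical set has {n_inter} inter-subunit links, need >= {min_inter}"
        )
    n = len(theoretical)
    k = int(math.floor(rate * n + 0.5))
    k = min(max(k, min_inter), n)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    for _ in range(max_attempts):
        idx = rng.choice(n, size=k, replace=False)
        subset = [theoretical[i] for i in idx]
        if sum(xl.classification == "inter" for xl in subset) >= min_inter:
            return subset
    raise RuntimeError("recovery sampling failed to satisfy the inter-link minimum")


def contribution_matrix(models_evaluated, crosslinks, params: ScoreParams) -> np.ndarray:
    """Per-model, per-crosslink contribution table.

    ``models_evaluated`` is a list (one entry per model) of lists of
    ``(Crosslink, DistanceResult)`` aligned with ``crosslinks``.  Because
    the score is additive over crosslinks, any recovery subset can then be
    scored by summing columns — the expensive surface distances are
    computed once per model.
    """
    n_models = len(models_evaluated)
    n_links = len(crosslinks)
    C = np.zeros((n_models, n_links))
    for i, evaluated in enumerate(models_evaluated):
        if len(evaluated) != n_links:
            raise ValueError("evaluated list is not aligned with the crosslink set")
        for j, (xl, res) in enumerate(evaluated):
            C[i, j] = crosslink_contribution(xl, res, params)
    return C


def recovery_curve(
    contributions: np.ndarray,
    crosslinks,
    positives,
    rates,
    reps: int = 100,
    rng_seed: int = 0,
    min_inter: int = 2,
) -> list[dict]:
    """Mean precision and AUC at each recovery rate.

    For each rate, a recovery subset is drawn ``reps`` times; each model's
    score is the sum of its contributions over the subset; precision and
    AUC are averaged over the draws.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    crosslinks = list(crosslinks)
    positives = np.asarray(positives, dtype=bool)
    rng = np.random.default_rng(rng_seed)
    index_of = {id(xl): i for i, xl in enumerate(crosslinks)}
    out = []
    for rate in rates:
        precs, aucs = [], []
        for _ in range(reps):
            subset = sample_recovery(crosslinks, rate, min_inter=min_inter, rng_seed=rng)
            cols = [index_of[id(xl)] for xl in subset]
            scores = contributions[:, cols].sum(axis=1)
            precs.append(
                precision_top10(scores, positives, rng_seed=int(rng.integers(2**31)))
            )
            try:
                aucs.append(roc_auc(scores, positives)[1])
            except ValueError:
                pass
        out.append(
            {
                "rate": rate,
                "precision": float(np.mean(precs)),
                "auc": float(np.mean(aucs)) if aucs else float("nan"),
            }
        )
    return out


@dataclass
class WeightScanResult:
    weights: np.ndarray
    precision: float
    degenerate: bool


def scan_weights(
    scored_terms,
    labels,
    grid_step: float = 0.1,
    rng_seed: int = 0,
) -> WeightScanResult:
    """Exhaustive grid scan of per-term weights maximising top-10 precision.

    ``scored_terms`` is an ``(n_models, k)`` term table for one benchmark
    case, or a list of such tables with a matching list of label vectors;
    the objective is the mean precision across cases.  Weights run from 0
    to 1 in ``grid_step`` increments; ties break toward the
    lexicographically smallest weight vector.  Weight vectors yielding a
    constant score (e.g. all-zero) are flagged degenerate and excluded
    unless nothing else exists.
    """
    if isinstance(scored_terms, np.ndarray) or not isinstance(scored_terms, (list, tuple)):
        cases = [(np.asarray(scored_terms, dtype=float), np.asarray(labels, dtype=bool))]
    elif len(scored_terms) and isinstance(scored_terms[0], (list, np.ndarray)) and np.asarray(
        scored_terms[0]
    ).ndim == 2:
        cases = [
            (np.asarray(t, dtype=float), np.asarray(l, dtype=bool))
            for t, l in zip(scored_terms, labels)
        ]
    else:
        cases = [(np.asarray(scored_terms, dtype=float), np.asarray(labels, dtype=bool))]
    k = cases[0][0].shape[1]
    n_steps = int(round(1.0 / grid_step)) + 1
    axis = np.linspace(0.0, 1.0, n_steps)
    best = None
    grids = np.meshgrid(*([axis] * k), indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)
    for w in combos:
        degenerate = False
        precs = []
        for terms, lab in cases:
            scores = terms @ w
            if np.ptp(scores) == 0:
                degenerate = True
            precs.append(precision_top10(scores, lab, rng_seed=rng_seed))
        mean_prec = float(np.mean(precs))
        cand = (not degenerate, mean_prec, tuple(-w))
        if best is None or cand > best[0]:
            best = (cand, w, degenerate, mean_prec)
    _, w, degenerate, mean_prec = best
    return WeightScanResult(weights=np.asarray(w), precision=mean_prec, degenerate=degenerate)


def paired_onesided_ttest(values_a, values_b) -> float:
    """One-sided paired t-test of mean(a) > mean(b); returns the p value.

    With zero variance of the differences the t statistic is undefined;
    the sign convention is p=0.5 for identical means, 0 for a uniformly
    greater ``a`` and 1 for a uniformly smaller one.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test requires equal-length 1-D samples")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        warnings.warn("zero variance of paired differences; p by sign convention")
        if diff[0] > 0:
            return 0.0
        if diff[0] < 0:
            return 1.0
        return 0.5
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.pvalue)


def summarize_benchmark(
    model_ids, scores, quality, rng_seed: int = 0
) -> BenchmarkResult:
    """Bundle per-model scores and labels into a :class:`BenchmarkResult`."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray([q.positive if hasattr(q, "positive") else bool(q) for q in quality])
    prec = precision_top10(scores, positives, rng_seed=rng_seed)
    try:
        fpr = fpr_top10(scores, positives, rng_seed=rng_seed)
    except ValueError:
        fpr = float("nan")
    try:
        roc_points, auc = roc_auc(scores, positives)
    except ValueError:
        roc_points, auc = [], float("nan")
    rmsds = [
        (q.mean_rmsd if hasattr(q, "mean_rmsd") else np.inf) for q in quality
    ]
    best_model = int(np.argmin(rmsds))
    order = np.argsort(-scores, kind="stable")
    top_rank_of_best = int(np.where(order == best_model)[0][0]) + 1
    return BenchmarkResult(
        per_model=list(zip(model_ids, scores.tolist(), list(quality))),
        precision=prec,
        fpr=fpr,
        auc=auc,
        roc_points=roc_points,
        top_rank_of_best=top_rank_of_best,
        seed=rng_seed,
    )
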