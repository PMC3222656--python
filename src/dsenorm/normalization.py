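"""Reference-set quantile normalization and reference-set selectors.

Quantile normalization here is driven by an arbitrary *reference set* of
variables: the target distribution is estimated from the reference
variables only, and every sample is mapped through a monotone
piecewise-linear function from its own reference quantiles to the target
quantiles.  With the reference set equal to all variables this reduces to
classic one-channel quantile normalization (sorted columns become
identical).  Restricting the reference set to variables believed to be
unaltered gives an *invariant* normalization that does not absorb genuine
treatment signal into the normalization function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import LOG2, GroupDesign, IntensityMatrix, ValidationError


@dataclass
class NormalizationResult:
    """Normalized matrix plus the reference set and method that produced it."""

    matrix: IntensityMatrix
    reference_set: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.reference_set = np.asarray(self.reference_set, dtype=bool)


def _check_reference(ref: np.ndarray, n: int) -> np.ndarray:
    ref = np.asarray(ref, dtype=bool)
    if ref.shape != (n,):
        raise ValidationError(f"reference mask length {ref.size} != {n} variables")
    if ref.sum() < 2:
        raise ValidationError("reference set needs at least 2 variables")
    return ref


def _mapping_knots(sample_ref: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Monotone knots of one sample's quantile->target mapping.

    Tied reference values collapse to a single knot whose target is the mean
    of the target values their ranks span, keeping the map well defined and
    monotone.
    """
    order = np.argsort(sample_ref, kind="mergesort")
    x = sample_ref[order]
    xu, starts = np.unique(x, return_index=True)
    if xu.size < 2:
        raise ValidationError("constant sample within the reference set (zero spread)")
    stops = np.append(starts[1:], x.size)
    csum = np.concatenate(([0.0], np.cumsum(target)))
    yu = (csum[stops] - csum[starts]) / (stops - starts)
    return xu, yu


def _apply_map(x_new: np.ndarray, xu: np.ndarray, yu: np.ndarray) -> np.ndarray:
    y = np.interp(x_new, xu, yu)
    # linear tail extrapolation with the outermost segment slopes
    lo = x_new < xu[0]
    hi = x_new > xu[-1]
    if lo.any():
        s0 = (yu[1] - yu[0]) / (xu[1] - xu[0])
        y[lo] = yu[0] + s0 * (x_new[lo] - xu[0])
    if hi.any():
        s1 = (yu[-1] - yu[-2]) / (xu[-1] - xu[-2])
        y[hi] = yu[-1] + s1 * (x_new[hi] - xu[-1])
    return y


def quantile_normalize(m: IntensityMatrix, ref: np.ndarray | None = None,
                       method: str | None = None) -> NormalizationResult:
    """Quantile-normalize all variables using only *ref* variables.

    The target distribution is the across-sample mean of each sample's
    sorted values restricted to the reference variables.  Each sample's
    values (all variables) are then mapped through that sample's
    empirical-quantile -> target-quantile function: piecewise linear
    between reference quantiles, with linear tail extrapolation.
    """
    if m.scale != LOG2:
        raise ValidationError("quantile normalization expects a log2-scale matrix")
    n = m.n_variables
    if ref is None:
        ref = np.ones(n, dtype=bool)
    ref = _check_reference(ref, n)
    if method is None:
        method = "standard" if ref.all() else "invariant"

    sub = m.values[ref]                       # (r, s)
    sorted_sub = np.sort(sub, axis=0)
    target = sorted_sub.mean(axis=1)          # (r,)

    out = np.empty_like(m.values)
    for j in range(m.n_samples):
        xu, yu = _mapping_knots(sub[:, j], target)
        out[:, j] = _apply_map(m.values[:, j], xu, yu)
    return NormalizationResult(matrix=m.with_values(out), reference_set=ref,
                               method=method)


def rank_invariant_select(m: IntensityMatrix, d: GroupDesign,
                          fraction: float = 0.5) -> np.ndarray:
    """Select the variables with the most stable ranks between arms.

    Rank instability is the absolute difference between a variable's mean
    rank across treatment samples and its mean rank across reference
    samples; the ``ceil(fraction * n)`` most stable variables are returned,
    ties broken by variable index.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if m.scale != LOG2:
        raise ValidationError("rank-invariant selection expects a log2-scale matrix")
    t_idx, r_idx = d.arm_indices(m)
    ranks = rankdata(m.values, axis=0)
    instability = np.abs(ranks[:, t_idx].mean(axis=1) - ranks[:, r_idx].mean(axis=1))
    n = m.n_variables
    k = int(np.ceil(fraction * n))
    order = np.lexsort((np.arange(n), instability))
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def ideal_reference(truth: np.ndarray) -> np.ndarray:
    """Oracle reference set: the complement of the truly altered variables."""
    truth = np.asarray(truth, dtype=bool)
    mask = ~truth
    if not mask.any():
        raise ValidationError("all variables altered: empty ideal reference set")
    return mask
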