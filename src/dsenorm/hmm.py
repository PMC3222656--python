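"""HMM-assisted invariant normalization.

Pipeline: (1) standard quantile normalization; (2) per-variable M-values
(log2 ratio of the arms' average intensities); (3) a two-state Gaussian
hidden Markov model segments the ordered M-value track into an unaltered
and an altered state — the state whose fitted mean is closest to zero is
declared unaltered; (4) the original data are re-normalized with the
unaltered variables as the reference set.

The HMM exploits the dependency structure of tiling-array/sequencing
data: altered variables come in contiguous genomic regions, so a Markov
chain over ordered variables separates regional enrichment from noise far
better than any per-variable rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

from .core import LOG2, GroupDesign, IntensityMatrix, ValidationError
from .dse import qs_coefficient
from .normalization import NormalizationResult, quantile_normalize

UNALTERED, ALTERED = 0, 1


@dataclass
class MValueTrack:
    """Ordered per-variable M-values with the matrix's block structure."""

    values: np.ndarray
    blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("M-values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def block_lengths(self) -> list[int]:
        return [stop - start for start, stop in self.blocks]


def m_values(m: IntensityMatrix, d: GroupDesign,
             average: Literal["geometric", "arithmetic"] = "geometric") -> MValueTrack:
    """Log2 ratio of group-average intensities, per variable.

    ``geometric`` (default) averages on the log2 scale, i.e. the M-value is
    the log-ratio of the arms' geometric-mean intensities; ``arithmetic``
    averages raw intensities before taking the ratio.
    """
    if m.scale != LOG2:
        raise ValidationError("M-values require a log2-scale matrix")
    t_idx, r_idx = d.arm_indices(m)
    if average == "geometric":
        track = m.values[:, t_idx].mean(axis=1) - m.values[:, r_idx].mean(axis=1)
    elif average == "arithmetic":
        raw = np.exp2(m.values)
        track = np.log2(raw[:, t_idx].mean(axis=1)) - np.log2(raw[:, r_idx].mean(axis=1))
    else:
        raise ValidationError(f"unknown averaging rule {average!r}")
    return MValueTrack(values=track, blocks=m.block_spans())


@dataclass
class HmmParams:
    """Two-state Gaussian HMM parameters (state 0 unaltered, state 1 altered)."""

    rho: float
    means: np.ndarray
    sigmas: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if not 0 < self.rho < 1:
            raise ValidationError("rho must lie in (0, 1)")
        if np.any(self.sigmas <= 0):
            raise ValidationError("state standard deviations must be positive")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValidationError("transition rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValidationError("initial distribution must sum to 1")

    def stationary(self) -> np.ndarray:
        a = self.transmat[UNALTERED, ALTERED]
        b = self.transmat[ALTERED, UNALTERED]
        return np.array([b, a]) / (a + b)


def init_hmm(track: MValueTrack, rho_guess: float = 0.1,
             expected_region_length: int = 50) -> HmmParams:
    """Moment-matching starting values for the two-state HMM.

    Assumes the M-values come from the mixture
    ``(1 - rho) * N(0, sigma^2) + rho * N(mu2, sigma^2)`` (unaltered state
    centered at zero, equal variances):  ``mu2 = mean(M) / rho`` and
    ``sigma^2 = var(M) - rho (1 - rho) mu2^2``, floored at ``var(M) / 2``
    when the moment equation turns non-positive.  Transition rates encode
    the expected altered-region length and the stationary mix
    ``(1 - rho, rho)``.
    """
    if not 0 < rho_guess < 1:
        raise ValidationError("rho_guess must lie in (0, 1)")
    if expected_region_length < 1:
        raise ValidationError("expected_region_length must be >= 1")
    m = track.values
    var = m.var()
    if var == 0:
        raise ValidationError("constant M-value track (zero variance)")
    mu2 = m.mean() / rho_guess
    sigma2 = var - rho_guess * (1.0 - rho_guess) * mu2 ** 2
    if sigma2 <= 0:
        sigma2 = var / 2.0
    sigma = float(np.sqrt(sigma2))

    p_exit_altered = min(1.0 / expected_region_length, 1.0 - 1e-6)
    p_enter_altered = min(
        rho_guess / ((1.0 - rho_guess) * expected_region_length), 1.0 - 1e-6
    )
    transmat = np.array([
        [1.0 - p_enter_altered, p_enter_altered],
        [p_exit_altered, 1.0 - p_exit_altered],
    ])
    startprob = np.array([1.0 - rho_guess, rho_guess])
    return HmmParams(rho=rho_guess, means=np.array([0.0, mu2]),
                     sigmas=np.array([sigma, sigma]),
                     transmat=transmat, startprob=startprob)


def tail_mean_init(track: MValueTrack, params: HmmParams,
                   separation: float = 0.25) -> HmmParams:
    """Replace a degenerate altered-state mean by a tail mean.

    On data that have already been quantile normalized the M-values have
    mean ~0 by construction, so the moment estimate ``mu2 = mean(M)/rho``
    collapses onto the unaltered mean.  Two identical emission states are
    an exact EM fixed point (the responsibilities carry no information and
    the means can never separate), so when ``|mu2| < separation * sd(M)``
    the altered mean is restarted at the mean of the upper (or lower,
    depending on the sign of the track's quartile skewness) ``rho``-tail of
    the M-values.  The emission variance is re-derived with the same floor
    rule as :func:`init_hmm`.
    """
    m = track.values
    sd = m.std()
    mu2 = params.means[ALTERED]
    if abs(mu2 - params.means[UNALTERED]) >= separation * sd:
        return params
    rho = params.rho
    if qs_coefficient(m) >= 0:
        cut = np.quantile(m, 1.0 - rho)
        tail = m[m >= cut]
    else:
        cut = np.quantile(m, rho)
        tail = m[m <= cut]
    mu2 = float(tail.mean())
    sigma2 = m.var() - rho * (1.0 - rho) * mu2 ** 2
    if sigma2 <= 0:
        sigma2 = m.var() / 2.0
    sigma = float(np.sqrt(sigma2))
    return HmmParams(rho=rho, means=np.array([0.0, mu2]),
                     sigmas=np.array([sigma, sigma]),
                     transmat=params.transmat.copy(),
                     startprob=params.startprob.copy())


class _TracingMonitor(ConvergenceMonitor):
    """Convergence monitor with a full log-likelihood trace and a
    *relative* tolerance criterion."""

    def __init__(self, tol: float, n_iter: int):
        super().__init__(tol=tol, n_iter=n_iter, verbose=False)
        self.trace: list[float] = []

    def report(self, log_prob: float) -> None:
        super().report(log_prob)
        self.trace.append(log_prob)

    @property
    def converged(self) -> bool:
        if self.iter == self.n_iter:
            return True
        if len(self.trace) >= 2:
            prev, cur = self.trace[-2], self.trace[-1]
            return abs(cur - prev) <= self.tol * max(1.0, abs(prev))
        return False


@dataclass
class HmmFit:
    """Fitted HMM: parameters, decoded state path, likelihood trace."""

    params: HmmParams
    states: np.ndarray
    log_likelihoods: np.ndarray
    converged: bool
    variance_floored: bool

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.log_likelihoods = np.asarray(self.log_likelihoods, dtype=float)


def fit_hmm(track: MValueTrack, init: HmmParams | None = None,
            tol: float = 1e-6, max_iter: int = 500,
            decode: Literal["viterbi", "posterior"] = "viterbi") -> HmmFit:
    """Baum-Welch fit of the two-state Gaussian HMM to an M-value track.

    Multiple order blocks are treated as independent chains sharing one
    parameter set.  The EM log-likelihood trace is recorded and is
    non-decreasing; emission variances are floored at ``(1e-4 * sd(M))^2``
    (a collapse onto the floor is flagged, not fatal).  The state path is
    obtained by Viterbi decoding (or posterior argmax).
    """
    m = track.values
    if m.size < 10:
        raise ValidationError("HMM fit needs at least 10 variables")
    if m.std() == 0:
        raise ValidationError("constant M-value track (zero variance)")
    if init is None:
        init = init_hmm(track)

    floor_sd = 1e-4 * m.std()
    model = GaussianHMM(n_components=2, covariance_type="diag",
                        n_iter=max_iter, tol=tol,
                        min_covar=floor_sd ** 2,
                        init_params="", params="stmc")
    model.monitor_ = _TracingMonitor(tol=tol, n_iter=max_iter)
    model.startprob_ = init.startprob.copy()
    model.transmat_ = init.transmat.copy()
    model.means_ = init.means.reshape(-1, 1).copy()
    model.covars_ = (init.sigmas ** 2).reshape(-1, 1).copy()

    X = m.reshape(-1, 1)
    lengths = track.block_lengths()
    model.fit(X, lengths)

    trace = np.asarray(model.monitor_.trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ArithmeticError("non-finite likelihood during EM")

    covars = np.asarray(model.covars_).reshape(2, -1)[:, 0]
    sigmas = np.sqrt(covars)
    floored = bool(np.any(covars <= 1.01 * floor_sd ** 2))
    fitted = HmmParams(rho=init.rho,
                       means=model.means_.ravel().copy(),
                       sigmas=sigmas,
                       transmat=model.transmat_.copy(),
                       startprob=model.startprob_.copy())
    if decode == "viterbi":
        states = model.predict(X, lengths)
    elif decode == "posterior":
        states = model.predict_proba(X, lengths).argmax(axis=1)
    else:
        raise ValidationError(f"unknown decoding rule {decode!r}")
    return HmmFit(params=fitted, states=states, log_likelihoods=trace,
                  converged=bool(model.monitor_.converged),
                  variance_floored=floored)


def unaltered_mask(fit: HmmFit) -> np.ndarray:
    """True where the decoded state has the fitted mean closest to zero.

    On a tie in |mean| the state with the larger stationary probability is
    taken as unaltered (unaltered variables are assumed the majority).
    """
    means = np.abs(fit.params.means)
    if np.isclose(means[0], means[1]):
        unaltered = int(np.argmax(fit.params.stationary()))
    else:
        unaltered = int(np.argmin(means))
    return fit.states == unaltered


@dataclass
class HMMNormalizationResult(NormalizationResult):
    """Invariant normalization result carrying the HMM fit and M-tracks."""

    fit: HmmFit | None = None
    track_before: MValueTrack | None = None

    def summary(self) -> str:
        n = self.reference_set.size
        lines = [
            "HMM-assisted invariant quantile normalization",
            f"  variables              : {n}",
            f"  unaltered (reference)  : {int(self.reference_set.sum())} "
            f"({100 * self.reference_set.mean():.1f}%)",
        ]
        if self.fit is None:
            lines.append("  (flat M-value track: no HMM fitted, all variables unaltered)")
            return "\n".join(lines)
        p = self.fit.params
        lines += [
            f"  state means            : {p.means[UNALTERED]:.4f} (unaltered), "
            f"{p.means[ALTERED]:.4f} (altered)",
            f"  state std deviations   : {p.sigmas[UNALTERED]:.4f}, {p.sigmas[ALTERED]:.4f}",
            f"  stationary distribution: {np.array2string(p.stationary(), precision=3)}",
            f"  EM iterations          : {self.fit.log_likelihoods.size}",
            f"  converged              : {self.fit.converged}",
            f"  final log-likelihood   : {self.fit.log_likelihoods[-1]:.2f}",
        ]
        return "\n".join(lines)


def hmm_normalize(m: IntensityMatrix, d: GroupDesign,
                  rho_guess: float = 0.1, expected_region_length: int = 50,
                  tol: float = 1e-6, max_iter: int = 500,
                  decode: Literal["viterbi", "posterior"] = "viterbi",
                  average: Literal["geometric", "arithmetic"] = "geometric",
                  ) -> HMMNormalizationResult:
    """Full HMM-assisted normalization of a log2-scale matrix.

    Standard quantile normalization, M-values, HMM segmentation, then
    invariant quantile re-normalization of the *original* data using the
    unaltered variables as the reference set.
    """
    standard = quantile_normalize(m)
    track = m_values(standard.matrix, d, average=average)
    if track.values.std() == 0:
        # no between-arm signal at all: every variable is unaltered
        mask = np.ones(m.n_variables, dtype=bool)
        result = quantile_normalize(m, ref=mask, method="hmm")
        return HMMNormalizationResult(matrix=result.matrix, reference_set=mask,
                                      method="hmm", fit=None, track_before=track)
    init = tail_mean_init(track, init_hmm(track, rho_guess, expected_region_length))
    fit = fit_hmm(track, init, tol=tol, max_iter=max_iter, decode=decode)
    mask = unaltered_mask(fit)
    if mask.sum() < 2:
        raise ValidationError(
            "HMM classified fewer than 2 variables as unaltered; "
            "cannot build a reference set"
        )
    result = quantile_normalize(m, ref=mask, method="hmm")
    return HMMNormalizationResult(matrix=result.matrix, reference_set=mask,
                                  method="hmm", fit=fit, track_before=track)


class HMMNormalizer:
    """Model-style wrapper around :func:`hmm_normalize`.

    Examples
    --------
    >>> result = HMMNormalizer(matrix, design, rho_guess=0.1).fit()
    >>> print(result.summary())
    >>> normalized = result.matrix
    """

    def __init__(self, matrix: IntensityMatrix, design: GroupDesign,
                 rho_guess: float = 0.1, expected_region_length: int = 50,
                 tol: float = 1e-6, max_iter: int = 500,
                 decode: Literal["viterbi", "posterior"] = "viterbi",
                 average: Literal["geometric", "arithmetic"] = "geometric"):
        design.validate_against(matrix)
        self.matrix = matrix
        self.design = design
        self.rho_guess = rho_guess
        self.expected_region_length = expected_region_length
        self.tol = tol
        self.max_iter = max_iter
        self.decode = decode
        self.average = average

    def fit(self) -> HMMNormalizationResult:
        return hmm_normalize(self.matrix, self.design,
                             rho_guess=self.rho_guess,
                             expected_region_length=self.expected_region_length,
                             tol=self.tol, max_iter=self.max_iter,
                             decode=self.decode, average=self.average)
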