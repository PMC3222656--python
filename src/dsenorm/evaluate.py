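"""Benchmarking: smoothing, altered-variable calling, sensitivity /
specificity / bias, relative metrics against the ideal normalization,
DSE-test power estimation, and M-value density summaries.

The downstream analysis mirrors a typical tiling-array workflow: M-values
are smoothed with a moving median of length 21 and variables whose
smoothed value exceeds ``0.7 * log2(delta)`` are called altered.  Bias is
the mean shrinkage of the altered variables' (non-smoothed) M-values
toward zero relative to their true log-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core import GroupDesign, IntensityMatrix, ValidationError, to_log2
from .dse import dse_test
from .hmm import MValueTrack, hmm_normalize, m_values
from .normalization import ideal_reference, quantile_normalize, rank_invariant_select
from .simulate import (SimulatedExperiment, SimulationConfig,
                       simulate_experiment, synth_variable_params)


@dataclass
class EvalResult:
    """Sensitivity, specificity and bias of one normalization method."""

    method: str
    sensitivity: float
    specificity: float
    bias: float
    cutoff: float


@dataclass
class RelativeResult:
    """Performance relative to the ideal (oracle) normalization."""

    relative_sensitivity: float
    relative_specificity: float
    relative_bias: float


def moving_median(values: Sequence[float], window: int = 21) -> np.ndarray:
    """Centered moving median; the window truncates at the track edges."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be an odd positive integer")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def call_altered(smoothed: Sequence[float], delta: float,
                 factor: float = 0.7) -> np.ndarray:
    """Call variables altered where the smoothed M-value is strictly above
    ``factor * log2(delta)``."""
    if delta <= 1:
        raise ValidationError("effect size delta must exceed 1")
    cutoff = factor * np.log2(delta)
    return np.asarray(smoothed, dtype=float) > cutoff


def confusion_metrics(calls: Sequence[bool], truth: Sequence[bool]) -> tuple[float, float]:
    """(sensitivity, specificity) of a boolean call set against the truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValidationError("calls and truth must have equal length")
    if not truth.any() or truth.all():
        raise ValidationError("truth must contain both classes")
    tp = np.count_nonzero(calls & truth)
    tn = np.count_nonzero(~calls & ~truth)
    sensitivity = tp / truth.sum()
    specificity = tn / (~truth).sum()
    return float(sensitivity), float(specificity)


def bias(m_track: Sequence[float], truth: Sequence[bool],
         true_log_ratio: Sequence[float]) -> float:
    """Mean signed shrinkage of altered variables' M-values toward zero.

    ``mean over altered i of sign(true_i) * (true_i - M_i)``: positive for
    both up- and down-altered variables whose observed log-ratio falls
    short of the truth.  Reduces to ``mean(log2 delta - M)`` when all
    alterations are positive.
    """
    m_track = np.asarray(m_track, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    true_log_ratio = np.asarray(true_log_ratio, dtype=float)
    if not truth.any():
        raise ValidationError("bias requires at least one altered variable")
    t = true_log_ratio[truth]
    m = m_track[truth]
    return float(np.mean(np.sign(t) * (t - m)))


def relative_metrics(method: EvalResult, ideal: EvalResult) -> RelativeResult:
    """Sensitivity/specificity ratios and bias difference vs the oracle."""
    if ideal.sensitivity <= 0:
        raise ValidationError("ideal sensitivity must be positive")
    return RelativeResult(
        relative_sensitivity=method.sensitivity / ideal.sensitivity,
        relative_specificity=method.specificity / ideal.specificity,
        relative_bias=method.bias - ideal.bias,
    )


def sensitivity_at_fpr(scores: Sequence[float], truth: Sequence[bool],
                       fpr: float = 0.005) -> float:
    """Sensitivity at a fixed false-positive rate.

    The threshold is the empirical (1 - fpr) quantile (type-7) of the null
    scores; sensitivity is the fraction of true scores strictly above it.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not truth.any() or truth.all():
        raise ValidationError("both classes must be present")
    threshold = np.quantile(scores[~truth], 1.0 - fpr)
    return float(np.mean(scores[truth] > threshold))


# ---------------------------------------------------------------------------
# Normalization benchmark harness
# ---------------------------------------------------------------------------

METHODS = ("standard", "invariant", "hmm", "ideal")


def evaluate_experiment(sim: SimulatedExperiment,
                        methods: Iterable[str] = METHODS,
                        window: int = 21, factor: float = 0.7,
                        invariant_fraction: float = 0.5,
                        rho_guess: float = 0.1,
                        expected_region_length: int | None = None,
                        ) -> dict[str, EvalResult]:
    """Normalize one simulated experiment with each method and score it.

    For every method: normalize, compute M-values, smooth with a moving
    median, call altered variables above ``factor * log2(delta)`` (the
    smallest delta when several effect sizes are mixed), and compute
    sensitivity, specificity and bias against the ground truth.
    """
    log2m = to_log2(sim.matrix)
    d = sim.design
    delta_call = float(np.min(sim.config.deltas))
    cutoff = factor * np.log2(delta_call)
    if expected_region_length is None:
        expected_region_length = sim.config.m

    results: dict[str, EvalResult] = {}
    for method in methods:
        if method == "standard":
            norm = quantile_normalize(log2m)
        elif method == "invariant":
            ref = rank_invariant_select(log2m, d, invariant_fraction)
            norm = quantile_normalize(log2m, ref=ref, method="invariant")
        elif method == "hmm":
            norm = hmm_normalize(log2m, d, rho_guess=rho_guess,
                                 expected_region_length=expected_region_length)
        elif method == "ideal":
            norm = quantile_normalize(log2m, ref=ideal_reference(sim.truth),
                                      method="ideal")
        else:
            raise ValidationError(f"unknown normalization method {method!r}")
        track = m_values(norm.matrix, d)
        smoothed = moving_median(track.values, window)
        calls = call_altered(smoothed, delta_call, factor)
        sens, spec = confusion_metrics(calls, sim.truth)
        b = bias(track.values, sim.truth, sim.true_log_ratio)
        results[method] = EvalResult(method=method, sensitivity=sens,
                                     specificity=spec, bias=b, cutoff=cutoff)
    return results


def benchmark_normalizations(cfg: SimulationConfig, n_reps: int = 3,
                             seed: int = 0, methods: Iterable[str] = METHODS,
                             **eval_kwargs) -> pd.DataFrame:
    """Average sensitivity/specificity/bias per method over replicates.

    Variable parameters are drawn once from the synthetic prior and shared
    across replicates; each replicate reseeds the intensity noise.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    vp = synth_variable_params(cfg.n, seed=int(rng.integers(2 ** 31 - 1)))
    rows = []
    for rep in range(n_reps):
        rep_cfg = SimulationConfig(n=cfg.n, k=cfg.k, alpha=cfg.alpha, m=cfg.m,
                                   delta=cfg.delta,
                                   seed=int(rng.integers(2 ** 31 - 1)))
        sim = simulate_experiment(rep_cfg, vp)
        for method, res in evaluate_experiment(sim, methods=methods,
                                               **eval_kwargs).items():
            rows.append({"replicate": rep, "method": method,
                         "sensitivity": res.sensitivity,
                         "specificity": res.specificity, "bias": res.bias})
    df = pd.DataFrame(rows)
    return df.groupby("method", sort=False)[
        ["sensitivity", "specificity", "bias"]].mean()


# ---------------------------------------------------------------------------
# DSE-test power
# ---------------------------------------------------------------------------

def dse_power(grid: Sequence[SimulationConfig], variant: str = "dependent",
              n_sims: int = 100, level: float = 0.05,
              seed: int = 0) -> pd.DataFrame:
    """Estimate the DSE-test's rejection rate over a grid of experiments.

    For each configuration, ``n_sims`` experiments are simulated and the
    power is the fraction with p below ``level`` (with alpha = 0 this
    estimates the false positive rate).  Cells infeasible for the variant
    (e.g. the independent test with fewer than 4 samples per arm) are
    marked rather than failing the whole grid.
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for cfg in grid:
        vp = synth_variable_params(cfg.n, seed=int(master.integers(2 ** 31 - 1)))
        sim_seeds = master.integers(2 ** 31 - 1, size=n_sims)
        rejections = 0
        feasible = True
        for s in sim_seeds:
            rep_cfg = SimulationConfig(n=cfg.n, k=cfg.k, alpha=cfg.alpha,
                                       m=cfg.m, delta=cfg.delta, seed=int(s))
            sim = simulate_experiment(rep_cfg, vp)
            try:
                res = dse_test(to_log2(sim.matrix), sim.design,
                               variant=variant, pre_normalize=False)
            except ValidationError:
                feasible = False
                break
            rejections += res.p_value < level
        power = rejections / n_sims if feasible else np.nan
        se = (np.sqrt(power * (1 - power) / n_sims) if feasible else np.nan)
        rows.append({"n": cfg.n, "k": cfg.k, "alpha": cfg.alpha, "m": cfg.m,
                     "delta": (tuple(cfg.deltas) if cfg.deltas.size > 1
                               else float(cfg.deltas[0])),
                     "variant": variant, "n_sims": n_sims, "level": level,
                     "power": power, "se": se, "feasible": feasible})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# M-value density summary (visual inspection of skewness)
# ---------------------------------------------------------------------------

def m_density(track: MValueTrack | Sequence[float], grid_size: int = 512,
              ) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Kernel density of the M-values plus their quartiles.

    Gaussian kernel with bandwidth ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``;
    a symmetric density (|Q1 + Q3 - 2*median| small) indicates a non-skewed
    experiment.
    """
    values = np.asarray(track.values if isinstance(track, MValueTrack) else track,
                        dtype=float)
    if values.size < 10:
        raise ValidationError("density summary needs at least 10 values")
    sd = values.std(ddof=1)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    bw = 0.9 * min(sd, iqr / 1.34) * values.size ** (-0.2)
    if bw <= 0:
        raise ValidationError("zero spread: cannot estimate a density")
    kde = gaussian_kde(values, bw_method=bw / sd)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    density = kde(grid)
    return grid, density, (float(q1), float(med), float(q3))
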