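"""Synthetic skewed experiments with region-structured alterations.

The generator emulates normalized one-channel intensity data: every
variable's reference intensity is Normal(mu_i, sigma_i) on the raw scale,
and in treated samples the mean of each altered variable is multiplied by
the effect size delta.  Altered variables are gathered in equally spaced
regions of m consecutive variables, mimicking the regional enrichment of
ChIP-chip / ChIP-seq signal.  Per-variable (mu_i, sigma_i) either come
from a real reference data set via regularized variance estimation, or
from a synthetic log-normal prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import RAW, GroupDesign, IntensityMatrix, ValidationError


@dataclass
class VariableParams:
    """Per-variable raw-scale mean and standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValidationError("mu and sigma must be 1-d arrays of equal length")
        if np.any(self.mu <= 0) or np.any(self.sigma <= 0):
            raise ValidationError("mu and sigma must be strictly positive")

    def __len__(self) -> int:
        return self.mu.size


@dataclass
class SimulationConfig:
    """Design of one simulated experiment.

    n variables, k samples per arm, fraction alpha of variables positively
    altered in regions of m consecutive variables, effect size delta
    (scalar, or a sequence cycled over regions), and the random seed.
    """

    n: int
    k: int
    alpha: float
    m: int = 50
    delta: float | Sequence[float] = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1:
            raise ValidationError("n and k must be positive")
        if not 0 <= self.alpha <= 0.5:
            raise ValidationError("alpha must lie in [0, 0.5]")
        if self.m < 1:
            raise ValidationError("region length m must be >= 1")
        deltas = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if np.any(deltas <= 0):
            raise ValidationError("effect sizes must be positive")

    @property
    def deltas(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.delta, dtype=float))


@dataclass
class SimulatedExperiment:
    """A simulated experiment: data, design, and the ground truth."""

    matrix: IntensityMatrix
    design: GroupDesign
    truth: np.ndarray
    true_log_ratio: np.ndarray
    config: SimulationConfig
    n_truncated: int = 0

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=bool)
        self.true_log_ratio = np.asarray(self.true_log_ratio, dtype=float)


def place_regions(n: int, alpha: float, m: int) -> np.ndarray:
    """Boolean mask with round(alpha*n/m) equally spaced runs of m trues.

    Region j starts at ``floor(s/2) + j*s`` with spacing ``s = floor(n/r)``
    for r regions, so consecutive regions are a constant distance apart.
    """
    if not 0 <= alpha <= 0.5:
        raise ValidationError("alpha must lie in [0, 0.5]")
    if m < 1:
        raise ValidationError("region length m must be >= 1")
    mask = np.zeros(n, dtype=bool)
    r = int(round(alpha * n / m))
    if r == 0:
        return mask
    if r * m > n:
        raise ValidationError(f"{r} regions of length {m} do not fit into {n} variables")
    s = n // r
    starts = s // 2 + s * np.arange(r)
    if starts[-1] + m > n or m > s:
        raise ValidationError("regions would overlap or overrun the variable range")
    for start in starts:
        mask[start:start + m] = True
    return mask


def estimate_variable_params(reference: IntensityMatrix, prior_df: float = 10.0,
                             window: int = 101) -> VariableParams:
    """Estimate per-variable (mu, sigma) from real raw reference data.

    Keeps the variables whose average intensity exceeds the median average
    intensity.  mu_i is the average intensity; the variance is regularized
    against a local prior,

        sigma_i^2 = (nu0 * s0_i^2 + (n_s - 1) * s_i^2) / (nu0 + n_s - 2),

    where s0_i^2 is the mean sample variance over the ``window`` kept
    variables nearest to variable i in average intensity and nu0 is the
    prior degrees of freedom.
    """
    if reference.scale != RAW:
        raise ValidationError("parameter estimation expects raw-scale intensities")
    if reference.n_samples < 2:
        raise ValidationError("need at least 2 reference samples")
    means = reference.values.mean(axis=1)
    keep = means > np.median(means)
    mu = means[keep]
    s2 = reference.values[keep].var(axis=1, ddof=1)
    n_kept = mu.size
    if n_kept < 2:
        raise ValidationError("too few variables above the median intensity")
    if window > n_kept:
        warnings.warn(
            f"window {window} exceeds {n_kept} kept variables; shrunk to fit",
            stacklevel=2,
        )
        window = n_kept
    order = np.argsort(mu, kind="mergesort")
    s2_sorted = pd.Series(s2[order])
    local = s2_sorted.rolling(window, center=True, min_periods=1).mean().to_numpy()
    s0_2 = np.empty(n_kept)
    s0_2[order] = local
    n_s = reference.n_samples
    sigma2 = (prior_df * s0_2 + (n_s - 1) * s2) / (prior_df + n_s - 2)
    return VariableParams(mu=mu, sigma=np.sqrt(sigma2))


def synth_variable_params(n: int, seed: int = 0, *,
                          mu_log2_mean: float = 9.0, mu_log2_sd: float = 0.8,
                          cv_low: float = 0.05, cv_high: float = 0.25) -> VariableParams:
    """Draw per-variable (mu, sigma) from a synthetic array-like prior.

    log2(mu) is Normal(mu_log2_mean, mu_log2_sd) and sigma = cv * mu with
    the coefficient of variation uniform on (cv_low, cv_high) — a stand-in
    for parameters estimated from a real reference data set.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if mu_log2_sd <= 0 or not 0 < cv_low < cv_high:
        raise ValidationError("invalid hyperparameter ranges")
    rng = np.random.default_rng(seed)
    mu = np.exp2(rng.normal(mu_log2_mean, mu_log2_sd, size=n))
    cv = rng.uniform(cv_low, cv_high, size=n)
    return VariableParams(mu=mu, sigma=cv * mu)


def simulate_experiment(cfg: SimulationConfig, vp: VariableParams) -> SimulatedExperiment:
    """Simulate one skewed experiment.

    Reference intensities are Normal(mu_i, sigma_i); treated intensities
    are Normal(delta_i * mu_i, sigma_i), with delta_i the configured effect
    size inside altered regions (cycled over regions when several effect
    sizes are given) and 1 elsewhere.  Draws are truncated below at one
    intensity unit so the log2 transform is defined; with realistic
    parameters this is vanishingly rare and the count is recorded.
    """
    if len(vp) < cfg.n:
        raise ValidationError(f"need parameters for {cfg.n} variables, got {len(vp)}")
    mu = vp.mu[:cfg.n]
    sigma = vp.sigma[:cfg.n]

    truth = place_regions(cfg.n, cfg.alpha, cfg.m)
    delta_i = np.ones(cfg.n)
    if truth.any():
        deltas = cfg.deltas
        region_starts = np.flatnonzero(truth & ~np.roll(truth, 1))
        if truth[0]:
            region_starts = np.unique(np.append(region_starts, 0))
        for j, start in enumerate(np.sort(region_starts)):
            delta_i[start:start + cfg.m] = deltas[j % deltas.size]

    rng = np.random.default_rng(cfg.seed)
    x_ref = rng.normal(mu[:, None], sigma[:, None], size=(cfg.n, cfg.k))
    x_trt = rng.normal((delta_i * mu)[:, None], sigma[:, None], size=(cfg.n, cfg.k))
    n_truncated = int((x_ref < 1.0).sum() + (x_trt < 1.0).sum())
    x_ref = np.maximum(x_ref, 1.0)
    x_trt = np.maximum(x_trt, 1.0)

    width = len(str(cfg.k))
    t_ids = [f"T{j + 1:0{width}d}" for j in range(cfg.k)]
    r_ids = [f"R{j + 1:0{width}d}" for j in range(cfg.k)]
    matrix = IntensityMatrix(
        values=np.hstack([x_trt, x_ref]),
        variable_ids=np.array([f"v{i}" for i in range(cfg.n)], dtype=object),
        sample_ids=t_ids + r_ids,
        scale=RAW,
    )
    design = GroupDesign({**{s: "treatment" for s in t_ids},
                          **{s: "reference" for s in r_ids}})
    true_log_ratio = np.where(truth, np.log2(delta_i), 0.0)
    return SimulatedExperiment(matrix=matrix, design=design, truth=truth,
                               true_log_ratio=true_log_ratio, config=cfg,
                               n_truncated=n_truncated)


def write_truth(sim: SimulatedExperiment, path) -> None:
    """TSV with columns: variable id, altered flag (0/1), true log2 ratio."""
    df = pd.DataFrame({
        "id": sim.matrix.variable_ids,
        "altered": sim.truth.astype(int),
        "true_log_ratio": sim.true_log_ratio,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["altered"].to_numpy(bool), df["true_log_ratio"].to_numpy(float)
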