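"""The DSE-test: Detection of Skewed Experiments.

An experiment is *skewed* when the truly altered variables' log-ratios are
asymmetrically distributed around zero (e.g. ChIP enrichment, where nearly
all signal is positive).  The test compares the Bowley quartile-skewness
coefficient of per-variable log-ratios between *heterogeneous* sample
pairs (one treated, one reference — these see the asymmetric signal) and
*homogeneous* pairs (same arm — these see technical noise only).  A Welch
t-test on the two groups of coefficients flags a skewed experiment.

Two variants exist.  The *dependent* variant reuses every sample in both a
heterogeneous and a homogeneous pair, maximizing the number of
coefficients at the cost of dependence between them; the *independent*
variant splits each arm in half so that no sample contributes twice, which
controls the false positive rate but halves the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import stats

from .core import LOG2, GroupDesign, IntensityMatrix, ValidationError
from .normalization import quantile_normalize

HETEROGENEOUS = "heterogeneous"
HOM_TREATMENT = "homogeneous-treatment"
HOM_REFERENCE = "homogeneous-reference"


@dataclass(frozen=True)
class SamplePair:
    sample_a: str
    sample_b: str
    kind: str

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValidationError("a pair must consist of two distinct samples")


@dataclass
class PairSet:
    heterogeneous: list[SamplePair]
    homogeneous: list[SamplePair]
    variant: str

    def __post_init__(self) -> None:
        for pairs in (self.heterogeneous, self.homogeneous):
            used: set[str] = set()
            for p in pairs:
                if p.sample_a in used or p.sample_b in used:
                    raise ValidationError("a sample may appear in only one pair per set")
                used.update((p.sample_a, p.sample_b))
        if self.variant == "independent":
            het = {s for p in self.heterogeneous for s in (p.sample_a, p.sample_b)}
            hom = {s for p in self.homogeneous for s in (p.sample_a, p.sample_b)}
            if het & hom:
                raise ValidationError(
                    "independent variant: no sample may appear in both sets"
                )


def qs_coefficient(values: Sequence[float]) -> float:
    """Bowley quartile skewness, (Q3 + Q1 - 2*median) / (Q3 - Q1).

    Zero for quartile-symmetric data, bounded in [-1, 1], positive for
    right skew.  Quartiles use linear interpolation of order statistics
    (the type-7 rule).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValidationError("qs-coefficient needs at least 4 finite values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    if not q3 > q1:
        raise ValidationError("degenerate spread (Q3 == Q1)")
    return float((q3 + q1 - 2.0 * med) / (q3 - q1))


def pair_log_ratios(m: IntensityMatrix, p: SamplePair) -> np.ndarray:
    """Per-variable log-ratio (sample_a minus sample_b) on the log2 scale."""
    if m.scale != LOG2:
        raise ValidationError("log-ratios require a log2-scale matrix")
    ia, ib = m.column_indices([p.sample_a, p.sample_b])
    return m.values[:, ia] - m.values[:, ib]


def _disjoint_pairs(samples: list[str], kind: str) -> list[SamplePair]:
    return [SamplePair(samples[2 * i], samples[2 * i + 1], kind)
            for i in range(len(samples) // 2)]


def build_pairs(d: GroupDesign,
                variant: Literal["dependent", "independent"] = "dependent",
                rng: np.random.Generator | None = None) -> PairSet:
    """Construct the heterogeneous and homogeneous pair sets.

    Pairing is deterministic: samples are taken in sorted-id order and
    paired first-come (pass ``rng`` for a seeded random alternative).  The
    dependent variant yields ``min(n_T, n_R)`` heterogeneous and
    ``floor(n_T/2) + floor(n_R/2)`` homogeneous pairs, reusing samples
    across the two sets.  The independent variant pairs the first half of
    each arm heterogeneously and the second half homogeneously.
    """
    t = sorted(d.treatment)
    r = sorted(d.reference)
    if rng is not None:
        t = list(rng.permutation(t))
        r = list(rng.permutation(r))

    if variant == "dependent":
        if min(len(t), len(r)) < 2:
            raise ValidationError(
                "dependent DSE-test needs at least 2 samples per arm"
            )
        k = min(len(t), len(r))
        het = [SamplePair(t[i], r[i], HETEROGENEOUS) for i in range(k)]
        hom = _disjoint_pairs(t, HOM_TREATMENT) + _disjoint_pairs(r, HOM_REFERENCE)
    elif variant == "independent":
        if len(t) < 4 or len(r) < 4:
            raise ValidationError(
                "independent DSE-test needs at least 4 samples per arm "
                "(use the dependent variant for smaller experiments)"
            )
        ht, hr = (len(t) + 1) // 2, (len(r) + 1) // 2
        t1, t2 = t[:ht], t[ht:]
        r1, r2 = r[:hr], r[hr:]
        k = min(len(t1), len(r1))
        het = [SamplePair(t1[i], r1[i], HETEROGENEOUS) for i in range(k)]
        hom = _disjoint_pairs(t2, HOM_TREATMENT) + _disjoint_pairs(r2, HOM_REFERENCE)
    else:
        raise ValidationError(f"unknown variant {variant!r}")
    return PairSet(heterogeneous=het, homogeneous=hom, variant=variant)


def enumerate_homogeneous_pairings(samples: Sequence[str]) -> Iterator[tuple[frozenset, ...]]:
    """Yield every way to build floor(n/2) non-overlapping same-arm pairs.

    For three samples there are C(3,2) = 3 ways (one pair, one sample left
    out); across two arms of three the alternatives multiply to nine.
    """
    samples = sorted(samples)
    n_pairs = len(samples) // 2

    def _matchings(avail: tuple[str, ...]) -> Iterator[tuple[frozenset, ...]]:
        if not avail:
            yield ()
            return
        first = avail[0]
        for partner in avail[1:]:
            rest = tuple(s for s in avail if s not in (first, partner))
            for tail in _matchings(rest):
                yield (frozenset((first, partner)),) + tail

    # distinct subsets of used samples yield distinct pairings, so no dedup
    for subset in combinations(samples, 2 * n_pairs):
        yield from _matchings(subset)


def welch_t(a: Sequence[float], b: Sequence[float],
            alternative: str = "two-sided") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns ``(t, df, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Welch test needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValidationError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class DSEResult:
    """Outcome of a DSE-test."""

    p_value: float
    t_statistic: float
    satterthwaite_df: float
    qs_heterogeneous: np.ndarray
    qs_homogeneous: np.ndarray
    variant: str
    pre_normalized: bool
    pairs: PairSet | None = None

    def skewed(self, level: float = 0.05) -> bool:
        return self.p_value < level

    def summary(self) -> str:
        lines = [
            "DSE-test (Detection of Skewed Experiments)",
            f"  variant             : {self.variant}",
            f"  pre-normalized      : {self.pre_normalized}",
            f"  het. qs-coefficients: {np.array2string(np.asarray(self.qs_heterogeneous), precision=4)}",
            f"  hom. qs-coefficients: {np.array2string(np.asarray(self.qs_homogeneous), precision=4)}",
            f"  Welch t             : {self.t_statistic:.4f}",
            f"  Satterthwaite df    : {self.satterthwaite_df:.3f}",
            f"  two-sided p-value   : {self.p_value:.4g}",
            f"  skewed at 5% level  : {self.skewed()}",
        ]
        return "\n".join(lines)


def dse_test(m: IntensityMatrix, d: GroupDesign,
             variant: Literal["dependent", "independent"] = "dependent",
             pre_normalize: bool = True,
             rng: np.random.Generator | None = None,
             alternative: str = "two-sided") -> DSEResult:
    """Run the DSE-test on a log2-scale matrix.

    With ``pre_normalize`` the samples are first standard quantile
    normalized (reference set = all variables), mirroring the intended use
    on raw user data; disable it for data that is already normalized.
    """
    if m.scale != LOG2:
        raise ValidationError("DSE-test expects a log2-scale matrix")
    d.validate_against(m)
    if pre_normalize:
        m = quantile_normalize(m).matrix
    pairs = build_pairs(d, variant=variant, rng=rng)
    qs_het = np.array([qs_coefficient(pair_log_ratios(m, p))
                       for p in pairs.heterogeneous])
    qs_hom = np.array([qs_coefficient(pair_log_ratios(m, p))
                       for p in pairs.homogeneous])
    t, df, p = welch_t(qs_het, qs_hom, alternative=alternative)
    return DSEResult(p_value=p, t_statistic=t, satterthwaite_df=df,
                     qs_heterogeneous=qs_het, qs_homogeneous=qs_hom,
                     variant=variant, pre_normalized=pre_normalize, pairs=pairs)


class DSETest:
    """Model-style wrapper: construct from data, ``fit()`` to test.

    Examples
    --------
    >>> result = DSETest(matrix, design).fit(variant="dependent")
    >>> print(result.summary())
    """

    def __init__(self, matrix: IntensityMatrix, design: GroupDesign):
        design.validate_against(matrix)
        self.matrix = matrix
        self.design = design

    def fit(self, variant: str = "dependent", pre_normalize: bool = True,
            rng: np.random.Generator | None = None,
            alternative: str = "two-sided") -> DSEResult:
        return dse_test(self.matrix, self.design, variant=variant,
                        pre_normalize=pre_normalize, rng=rng,
                        alternative=alternative)
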