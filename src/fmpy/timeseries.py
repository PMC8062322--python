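"""Step-encoded time series and autocorrelation analysis of turn sequences.

Each consecutive, non-overlapping block of four turns is encoded as a signed
integer *step length* ω(k) ∈ {−8…−1, +1…+8}: left-dominant tetragrams are
negative, right-dominant positive, with LLLL → −8 and RRRR → +8 at the
extremes and the two alternation motifs at ±1 (:data:`STEP_CODE`). A
session capped at 1000 arm entries therefore yields a 250-point series.
Subjects missing more than ten steps from the target length are excluded;
smaller deficits are zero-filled (0 is reserved for fill and is never a
tetragram code).

Memory of past choices is read from the autocorrelation function of the
step series or of its cumulative sum. The ACF estimator used is

    r(k) = Σ_{s=1}^{T−k} (ω(s)−ω̄)(ω(s+k)−ω̄) / Σ_{s=1}^{T} (ω(s)−ω̄)²,

with ω̄ the full-series mean — the standard biased estimator. Three 95%
bands are available: a flat ``naive`` band ±1.96/√n appropriate under white
noise; the default ``large_lag_bartlett`` band
±1.96·√((1 + 2Σ_{j<k} r(j)²)/n), Bartlett's large-lag standard error, which
widens as low-order correlation accumulates; and a diagnostic
``printed_bartlett`` band built from the Bartlett homogeneity-of-variances
statistic over a moving partition of the series (see
:func:`confidence_band`). A slowly decaying ACF with many of the first 20
lags outside the band is the long-range-memory signature; white noise
flags ≈5% of lags by chance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ingest import TurnSequence, ValidationError
from .tetragram import ALL_TETRAGRAMS, mirror_tetragram

__all__ = [
    "STEP_CODE",
    "CODE_TO_TETRAGRAM",
    "StepSeries",
    "encode_steps",
    "apply_missing_rule",
    "cumulative_sum",
    "ACFResult",
    "acf",
    "confidence_band",
    "significant_lags",
    "BartlettGroups",
    "bartlett_statistic",
]

#: Signed step length of each tetragram. Left-dominant sequences are
#: negative, right-dominant positive; 0 is reserved for missing-data fill.
STEP_CODE: dict[str, int] = {
    "LLLL": -8, "LLLR": -7, "LLRL": -6, "LRLL": -5,
    "RLLL": -4, "LLRR": -3, "LRRL": -2, "LRLR": -1,
    "RLRL": 1, "RLLR": 2, "RRLL": 3, "LRRR": 4,
    "RLRR": 5, "RRLR": 6, "RRRL": 7, "RRRR": 8,
}
CODE_TO_TETRAGRAM: dict[int, str] = {v: k for k, v in STEP_CODE.items()}

assert set(STEP_CODE) == set(ALL_TETRAGRAMS)
assert all(STEP_CODE[mirror_tetragram(t)] == -STEP_CODE[t] for t in STEP_CODE)


@dataclass
class StepSeries:
    """The discrete step-length series ω(k) for one subject.

    ``target_length`` is None until :func:`apply_missing_rule` has run; after
    it, a retained series has exactly ``target_length`` points of which the
    last ``n_missing_filled`` are zero fill.
    """

    subject_id: str
    steps: np.ndarray
    target_length: int | None = None
    n_missing_filled: int = 0
    excluded: bool = False

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        bad = set(np.unique(self.steps)) - set(range(-8, 9))
        if bad:
            raise ValidationError(f"{self.subject_id}: invalid step values {sorted(bad)}")

    @property
    def n(self) -> int:
        return int(self.steps.size)


def encode_steps(
    seq: TurnSequence, max_entries: int = 1000, overlapping: bool = False
) -> StepSeries:
    """Encode a turn sequence as signed step lengths.

    The first ``max_entries`` turns are kept (1000 for hour-long animal
    sessions; use 100 for 5-minute human sessions). By default consecutive
    *non-overlapping* blocks of four turns are encoded — the windowing under
    which 1000 turns give exactly 250 steps. ``overlapping=True`` instead
    encodes every stride-1 window (n − 3 steps), for exploratory use.
    """
    turns = seq.turns[:max_entries]
    if overlapping:
        codes = [STEP_CODE[turns[i : i + 4]] for i in range(max(0, len(turns) - 3))]
    else:
        codes = [
            STEP_CODE[turns[i : i + 4]] for i in range(0, len(turns) - 3, 4)
        ]
    return StepSeries(seq.subject_id, np.asarray(codes, dtype=int))


def apply_missing_rule(
    series: StepSeries, target_length: int = 250, max_missing: int = 10
) -> StepSeries:
    """Bring a step series to a fixed length, or exclude the subject.

    Deficit d = target_length − n. Subjects with d > ``max_missing`` are
    flagged excluded (exactly ``max_missing`` missing steps are still
    retained); 0 < d ≤ max_missing appends d zeros; surplus is truncated.
    Exclusion is a data state, not an error.
    """
    d = target_length - series.n
    if d > max_missing:
        return replace(series, target_length=target_length, excluded=True)
    if d > 0:
        steps = np.concatenate([series.steps, np.zeros(d, dtype=int)])
        return StepSeries(series.subject_id, steps, target_length, n_missing_filled=d)
    return StepSeries(series.subject_id, series.steps[:target_length], target_length)


def cumulative_sum(series: StepSeries) -> np.ndarray:
    """Running sum of steps, Σ_{j≤k} ω(j); the substrate for long-range ACF."""
    if series.excluded:
        raise ValidationError(f"{series.subject_id}: series excluded by the missing-data rule")
    return np.cumsum(series.steps, dtype=float)


@dataclass
class ACFResult:
    """Autocorrelation coefficients r(1..K) with an optional 95% band.

    ``r[k-1]`` holds lag k; lag 0 is identically 1 and not stored. The band
    is centred on zero: lag k is *significant* when r(k) falls outside
    [lower(k), upper(k)].
    """

    r: np.ndarray
    n: int
    mean: float
    series: np.ndarray = field(repr=False)
    band_method: str | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    bartlett_groups: "BartlettGroups | None" = None

    @property
    def max_lag(self) -> int:
        return int(self.r.size)

    def lag(self, k: int) -> float:
        if k == 0:
            return 1.0
        return float(self.r[k - 1])


def acf(series: Sequence[float] | np.ndarray | StepSeries, max_lag: int = 20) -> ACFResult:
    """The biased sample autocorrelation function r(1..max_lag).

    Numerator sums n − k lagged products, denominator all n squared
    deviations, both about the full-series mean. Constant series (zero
    variance) and max_lag > n − 2 are errors.
    """
    if isinstance(series, StepSeries):
        if series.excluded:
            raise ValidationError(f"{series.subject_id}: series excluded")
        x = np.asarray(series.steps, dtype=float)
    else:
        x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag < 1:
        raise ValidationError("max_lag must be >= 1")
    if n < max_lag + 2:
        raise ValidationError(f"series length {n} too short for max_lag={max_lag}")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValidationError("zero-variance (constant) series has no ACF")
    r = np.array([float(np.dot(xc[: n - k], xc[k:])) / denom for k in range(1, max_lag + 1)])
    return ACFResult(r=r, n=n, mean=float(x.mean()), series=x)


def confidence_band(result: ACFResult, method: str = "large_lag_bartlett") -> ACFResult:
    """Attach a zero-centred 95% confidence band to an ACF.

    naive
        Flat ±1.96/√n, the white-noise band.
    large_lag_bartlett (default)
        ±1.96·√((1 + 2Σ_{j<k} r(j)²)/n), Bartlett's large-lag standard
        error; equals the naive band at lag 1 and is non-decreasing in k.
    printed_bartlett
        Diagnostic only. Partitions the series into consecutive windows,
        computes the Bartlett homogeneity-of-variances statistic T over
        them, and scales the naive band by the ratio of pooled
        within-window spread to total spread. One possible moving-window
        reading of a Bartlett-test band; no fidelity claim is made.
    """
    n = result.n
    if method == "naive":
        hw = np.full(result.max_lag, 1.96 / math.sqrt(n))
        groups = None
    elif method == "large_lag_bartlett":
        cums = np.concatenate([[0.0], np.cumsum(result.r**2)])[: result.max_lag]
        hw = 1.96 * np.sqrt((1.0 + 2.0 * cums) / n)
        groups = None
    elif method == "printed_bartlett":
        groups = BartlettGroups.from_series(result.series)
        total_var = float(np.var(result.series, ddof=1))
        scale = math.sqrt(groups.pooled_variance / total_var)
        hw = np.full(result.max_lag, 1.96 / math.sqrt(n) * scale)
    else:
        raise ValidationError(f"unknown band method {method!r}")
    return replace(result, band_method=method, lower=-hw, upper=hw, bartlett_groups=groups)


def significant_lags(result: ACFResult, first: int = 20) -> int:
    """Count lags k in 1..first with r(k) outside the 95% band."""
    if result.lower is None or result.upper is None:
        raise ValidationError("no confidence band; call confidence_band first")
    if first > result.max_lag:
        raise ValidationError(f"first={first} exceeds max_lag={result.max_lag}")
    r = result.r[:first]
    return int(np.sum((r < result.lower[:first]) | (r > result.upper[:first])))


@dataclass
class BartlettGroups:
    """Group sizes and variances entering the Bartlett homogeneity statistic."""

    sizes: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.sizes.size != self.variances.size:
            raise ValidationError("sizes and variances differ in length")
        if self.k < 2:
            raise ValidationError("Bartlett statistic needs at least 2 groups")
        if (self.sizes < 2).any():
            raise ValidationError("every group needs at least 2 observations")
        if (self.variances <= 0).any():
            raise ValidationError("zero-variance group; Bartlett statistic undefined")

    @classmethod
    def from_samples(cls, samples: Sequence[np.ndarray]) -> "BartlettGroups":
        sizes = [len(s) for s in samples]
        variances = [float(np.var(np.asarray(s, float), ddof=1)) for s in samples]
        return cls(np.array(sizes), np.array(variances))

    @classmethod
    def from_series(cls, x: np.ndarray, window: int | None = None) -> "BartlettGroups":
        """Consecutive moving windows of a series as Bartlett groups.

        Default window width is n // 10, floored at 10 observations.
        """
        x = np.asarray(x, dtype=float)
        if window is None:
            window = max(10, x.size // 10)
        k = x.size // window
        if k < 2:
            raise ValidationError(f"series of {x.size} too short for window={window}")
        samples = [x[i * window : (i + 1) * window] for i in range(k)]
        return cls.from_samples(samples)

    @property
    def k(self) -> int:
        return int(self.sizes.size)

    @property
    def n(self) -> int:
        return int(self.sizes.sum())

    @property
    def pooled_variance(self) -> float:
        """Weighted mean of group variances, Σ(n_i−1)σ_i² / (n−k)."""
        return float(np.sum((self.sizes - 1) * self.variances) / (self.n - self.k))


def bartlett_statistic(groups: BartlettGroups) -> float:
    """Bartlett's homogeneity-of-variances statistic

        T = ((n−k) ln σ_p² − Σ (n_i−1) ln σ_i²)
            / (1 + (1/(3(k−1)))·(Σ 1/(n_i−1) − 1/(n−k))),

    ~χ²(k−1) under equal group variances; exactly 0 when all group
    variances coincide.
    """
    n, k = groups.n, groups.k
    sp2 = groups.pooled_variance
    num = (n - k) * math.log(sp2) - float(
        np.sum((groups.sizes - 1) * np.log(groups.variances))
    )
    den = 1.0 + (1.0 / (3.0 * (k - 1))) * (
        float(np.sum(1.0 / (groups.sizes - 1))) - 1.0 / (n - k)
    )
    return num / den
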