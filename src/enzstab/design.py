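"""Statistical design of a multi-batch storage-stability study.

The study population is a set of N vials split into strata (production
batches).  A pilot study yields a pooled standard deviation of the activity
measurement; from it the total sample size n per sampling time is chosen so
that the stratified mean estimator reaches a target half-width d at a given
confidence level, with the finite-population correction:

    n0 = (z·s/d)²,   n = ceil( n0 / (1 + n0/N) )

Samples are allocated proportionally to stratum sizes (largest-remainder
integerisation) and drawn as simple random samples within each stratum.
The stratified mean and its confidence interval use the standard
finite-population estimator

    ȳ_st = Σ W_h ȳ_h,    V̂ = Σ W_h² (1 − n_h/N_h) s_h² / n_h,

with W_h = N_h/N and half-width z·√V̂.  The normal quantile z (1.96 at 95%)
is used rather than Student-t: the design targets the large-N estimator.

Sampling continues on the planned schedule until relative activity drops
below a stop threshold (25% remaining, i.e. ~75% loss), with a minimum of
five sampling times extended whenever the trace stays measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PilotSummary",
    "DesignSpec",
    "StratifiedSample",
    "pooled_sd",
    "required_sample_size",
    "allocate_proportional",
    "draw_sample",
    "stratified_mean_ci",
    "apply_stop_rule",
    "summarize_temperature_log",
]

#: Planned sampling months: monthly for the first half year, then bimonthly.
DEFAULT_SCHEDULE: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12)


@dataclass(frozen=True)
class PilotSummary:
    """Pilot-study variability summary: per-group (replicate count, SD)."""

    groups: tuple[tuple[int, float], ...]
    pooled_sd: float

    @classmethod
    def from_groups(cls, groups: Sequence[tuple[int, float]]) -> "PilotSummary":
        return cls(groups=tuple(groups), pooled_sd=pooled_sd(groups))


@dataclass(frozen=True)
class DesignSpec:
    """Inputs of the sample-size calculation.

    population_size : total vials N per sampling time
    strata_sizes    : vials per batch, summing to N
    precision       : target CI half-width d (U L⁻¹)
    confidence      : CI confidence level, e.g. 0.95
    sd              : pilot pooled SD (U L⁻¹)
    """

    population_size: int
    strata_sizes: tuple[int, ...]
    precision: float
    confidence: float
    sd: float

    def __post_init__(self) -> None:
        if sum(self.strata_sizes) != self.population_size:
            raise ValueError("strata sizes must sum to the population size")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.precision <= 0:
            raise ValueError("precision (CI half-width) must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.confidence / 2.0))


@dataclass
class StratifiedSample:
    """A drawn stratified sample with its estimator outputs."""

    n_h: tuple[int, ...]
    vial_ids: tuple[tuple[int, ...], ...]
    stratum_means: tuple[float, ...] = ()
    stratum_sds: tuple[float, ...] = ()
    mean: float = math.nan
    ci_halfwidth: float = math.nan
    confidence: float = 0.95


def pooled_sd(groups: Sequence[tuple[int, float]]) -> float:
    """Pooled standard deviation across groups assumed homoscedastic.

    ``groups`` is a sequence of (replicate_count, sample_sd).  Uses the
    combined-variance estimator familiar from the equal-variance t-test:
    sqrt( Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1) ).
    """
    if not groups:
        raise ValueError("at least one group is required")
    num = 0.0
    dof = 0
    for n_i, s_i in groups:
        if n_i < 2:
            raise ValueError("each group needs at least 2 replicates")
        if s_i < 0:
            raise ValueError("group SD must be non-negative")
        num += (n_i - 1) * s_i**2
        dof += n_i - 1
    return math.sqrt(num / dof)


def required_sample_size(spec: DesignSpec) -> int:
    """Total sample size n meeting the precision target under the fpc.

    With sd = 0 the defined minimum (one vial per stratum) is returned.
    """
    n_strata = len(spec.strata_sizes)
    if spec.population_size < n_strata:
        raise ValueError("population smaller than the number of strata")
    if spec.sd == 0.0:
        return n_strata
    n0 = (spec.z * spec.sd / spec.precision) ** 2
    n = math.ceil(n0 / (1.0 + n0 / spec.population_size))
    return max(n, n_strata)


def allocate_proportional(n: int, strata_sizes: Sequence[int]) -> list[int]:
    """Integer allocation n_h ∝ N_h by the largest-remainder method.

    Ties in the remainders are broken toward the lower stratum index.
    Guarantees Σ n_h = n and, when n ≥ number of strata, every n_h ≥ 1.
    """
    sizes = np.asarray(strata_sizes, dtype=float)
    if n > sizes.sum():
        raise ValueError("cannot sample more vials than the population holds")
    if n < 0:
        raise ValueError("n must be non-negative")
    exact = n * sizes / sizes.sum()
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n - int(base.sum())
    # stable sort: descending remainder, ties to lower index
    order = np.argsort(-remainder, kind="stable")
    for idx in order[:short]:
        base[idx] += 1
    if n >= len(sizes):
        # promote zero-allocations from the largest-allocated strata
        while (base == 0).any():
            give = int(np.argmax(base))
            take = int(np.argmin(base))
            base[give] -= 1
            base[take] += 1
    return base.tolist()


def draw_sample(
    population: Mapping[object, Sequence[int]] | Sequence[Sequence[int]],
    n_h: Sequence[int],
    seed: int | np.random.Generator | None = None,
) -> list[list[int]]:
    """Simple random sample without replacement within each stratum.

    ``population`` maps stratum → vial ids (or is a list of id lists in
    stratum order).  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    strata = list(population.values()) if isinstance(population, Mapping) else list(population)
    if len(strata) != len(n_h):
        raise ValueError("n_h length must match the number of strata")
    out: list[list[int]] = []
    for ids, k in zip(strata, n_h):
        ids = list(ids)
        if k > len(ids):
            raise ValueError("n_h exceeds stratum size")
        picked = rng.choice(len(ids), size=k, replace=False)
        out.append([ids[i] for i in sorted(picked)])
    return out


def stratified_mean_ci(
    stratum_values: Sequence[Sequence[float]],
    strata_sizes: Sequence[int],
    confidence: float = 0.95,
) -> StratifiedSample:
    """Stratified mean and CI half-width from per-stratum observations."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    sizes = np.asarray(strata_sizes, dtype=float)
    N = sizes.sum()
    weights = sizes / N
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))

    means, sds, n_hs = [], [], []
    variance = 0.0
    for values, N_h, W_h in zip(stratum_values, sizes, weights):
        y = np.asarray(values, dtype=float)
        n_h = y.size
        if n_h == 0:
            raise ValueError("empty stratum sample")
        mean_h = float(y.mean())
        if n_h < N_h:  # variance contribution needed
            if n_h < 2:
                raise ValueError("a stratum variance requires n_h >= 2")
            s_h = float(y.std(ddof=1))
        else:  # exhaustive stratum: fpc zeroes the term
            s_h = float(y.std(ddof=1)) if n_h >= 2 else 0.0
        fpc = 1.0 - n_h / N_h
        variance += W_h**2 * fpc * s_h**2 / n_h
        means.append(mean_h)
        sds.append(s_h)
        n_hs.append(n_h)

    mean = float(np.dot(weights, means))
    half = z * math.sqrt(variance)
    return StratifiedSample(
        n_h=tuple(n_hs),
        vial_ids=(),
        stratum_means=tuple(means),
        stratum_sds=tuple(sds),
        mean=mean,
        ci_halfwidth=half,
        confidence=confidence,
    )


def apply_stop_rule(
    relative_trace: Sequence[float],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    threshold: float = 25.0,
    min_times: int = 5,
    feasibility_floor: float = 5.0,
) -> list[float]:
    """Months actually sampled, given the relative-activity trace (%).

    The schedule is truncated at the first month where relative activity
    falls strictly below ``threshold`` (75% loss).  When that happens before
    ``min_times`` sampling times, the schedule is extended toward
    ``min_times``, but only through months where the trace stays at or above
    ``feasibility_floor`` — once activity has collapsed to unmeasurable
    levels further sampling is pointless and the minimum is abandoned.
    """
    trace = list(relative_trace)
    sched = list(schedule)
    if len(trace) != len(sched):
        raise ValueError("trace must align with the schedule")
    below = [r < threshold for r in trace]
    if not any(below):
        return sched
    first = below.index(True)
    keep = first + 1
    while keep < min(min_times, len(sched)) and trace[keep] >= feasibility_floor:
        keep += 1
    return sched[:keep]


def summarize_temperature_log(
    readings: Sequence[float], unit: str = "C"
) -> tuple[float, float]:
    """Mean ± SD of a temperature log, reported in kelvin.

    ``unit`` is "C" or "K" for the whole log; a log whose values are
    implausible for the declared unit (kelvin below 100, Celsius above 200)
    is rejected as probably mixed-unit.
    """
    x = np.asarray(readings, dtype=float)
    if x.size == 0:
        raise ValueError("empty temperature log")
    if unit == "C":
        if (x > 200.0).any():
            raise ValueError("values above 200 °C look like kelvin: mixed units?")
        kelvin = x + 273.15
    elif unit == "K":
        if (x < 100.0).any():
            raise ValueError("values below 100 K look like Celsius: mixed units?")
        kelvin = x
    else:
        raise ValueError(f"unknown temperature unit {unit!r}")
    sd = float(kelvin.std(ddof=1)) if kelvin.size > 1 else 0.0
    return float(kelvin.mean()), sd
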