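"""Analytic genotype-frequency expectations, k estimation, and goodness of fit.

All closed forms are for a single biallelic locus whose male transmission is
parameterized by ``k`` = P(favored allele through pollen); the female side is
Mendelian.  ``k = 0.5`` recovers undistorted inheritance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .model_core import ContractError

__all__ = [
    "ProgenyFreq",
    "CountData",
    "GOFResult",
    "KEstimate",
    "testcross_freq",
    "selfing_freq",
    "ssd_recursion",
    "ri_fixation",
    "class_frequency",
    "estimate_k",
    "gof_test",
]

_PROB_TOL = 1e-12

# Class enumeration limit for the exact multinomial test: C(n+k-1, k-1) outcomes.
_EXACT_MAX_OUTCOMES = 2_000_000


@dataclass(frozen=True)
class ProgenyFreq:
    """Expected (II, H, JJ) genotype probabilities at one locus."""

    p_II: float
    p_H: float
    p_JJ: float

    def __post_init__(self) -> None:
        probs = (self.p_II, self.p_H, self.p_JJ)
        if any(p < -_PROB_TOL for p in probs):
            raise ContractError(f"negative probability in {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ContractError(f"probabilities {probs} do not sum to 1")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.p_II, self.p_H, self.p_JJ)


@dataclass(frozen=True)
class CountData:
    """Observed genotype counts; testcrosses use only the H and JJ classes."""

    n_H: int
    n_JJ: int
    n_II: int = 0

    def __post_init__(self) -> None:
        for label, n in (("n_H", self.n_H), ("n_JJ", self.n_JJ), ("n_II", self.n_II)):
            if int(n) != n or n < 0:
                raise ContractError(f"{label} must be a non-negative integer, got {n}")
        if self.total == 0:
            raise ContractError("total count must be positive")

    @property
    def total(self) -> int:
        return self.n_II + self.n_H + self.n_JJ


@dataclass(frozen=True)
class GOFResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ContractError("chi-square statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ContractError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class KEstimate:
    k_hat: float
    ci_low: float
    ci_high: float
    n: int
    method: str
    design: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.k_hat <= self.ci_high:
            raise ContractError("confidence interval must bracket the point estimate")


def _check_k(k: float) -> float:
    if not 0.0 <= k <= 1.0:
        raise ContractError(f"transmission parameter k must lie in [0, 1], got {k}")
    return float(k)


def testcross_freq(k: float) -> Tuple[float, float]:
    """(p_H, p_JJ) among progeny of a heterozygous male crossed to a JJ female."""
    k = _check_k(k)
    return (k, 1.0 - k)


def selfing_freq(k: float) -> ProgenyFreq:
    """Selfed-heterozygote progeny: male gametes (k, 1-k) x female gametes (1/2, 1/2)."""
    k = _check_k(k)
    return ProgenyFreq(p_II=k / 2.0, p_H=0.5, p_JJ=(1.0 - k) / 2.0)


def ssd_recursion(k: float, generations: int) -> ProgenyFreq:
    """Expected genotype frequencies after ``generations`` rounds of single-seed descent.

    Starting from an F1 heterozygote, heterozygosity halves every selfing
    generation while each 'fixation event' resolves to II with probability k:

        p_H(g)  = (1/2)^g
        p_II(g) = k (1 - (1/2)^g)
        p_JJ(g) = (1 - k)(1 - (1/2)^g)
    """
    k = _check_k(k)
    if generations < 0 or int(generations) != generations:
        raise ContractError(f"generations must be a non-negative integer, got {generations}")
    h = 0.5 ** generations
    return ProgenyFreq(p_II=k * (1.0 - h), p_H=h, p_JJ=(1.0 - k) * (1.0 - h))


def ri_fixation(k: float, n_lines: int) -> Tuple[int, int]:
    """Expected (n_II, n_JJ) counts among fully inbred lines.

    Rounds n*k half-away-from-zero so the two classes always sum to n_lines.
    """
    k = _check_k(k)
    if n_lines <= 0 or int(n_lines) != n_lines:
        raise ContractError(f"n_lines must be a positive integer, got {n_lines}")
    n_ii = int(math.floor(n_lines * k + 0.5))
    return (n_ii, n_lines - n_ii)


def class_frequency(n_class: int, n_total: int) -> float:
    """Fraction of progeny falling in one genotype class."""
    if n_total <= 0:
        raise ContractError("total count must be positive")
    if not 0 <= n_class <= n_total:
        raise ContractError(f"class count {n_class} outside [0, {n_total}]")
    return n_class / n_total


def estimate_k(counts: CountData, design: str, level: float = 0.95) -> KEstimate:
    """Maximum-likelihood k from progeny counts, with an exact binomial CI.

    Testcross: k_hat = n_H / (n_H + n_JJ).  Selfing: k_hat = n_II / (n_II +
    n_JJ); heterozygote counts are ignored because p_H = 1/2 regardless of k,
    so they carry no information about the transmission parameter.
    """
    if design == "testcross":
        successes, failures = counts.n_H, counts.n_JJ
        note = ""
    elif design == "selfing":
        successes, failures = counts.n_II, counts.n_JJ
        note = "heterozygote counts ignored: p_H = 1/2 for every k"
    else:
        raise ContractError(f"unknown design {design!r}; expected 'testcross' or 'selfing'")
    n = successes + failures
    if n == 0:
        raise ContractError(f"no informative progeny for design {design!r}")
    if not 0.0 < level < 1.0:
        raise ContractError(f"confidence level must lie in (0, 1), got {level}")
    ci = stats.binomtest(successes, n).proportion_ci(confidence_level=level, method="exact")
    return KEstimate(
        k_hat=successes / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n=n,
        method="clopper-pearson",
        design=design,
        note=note,
    )


def _compositions(total: int, k: int):
    """All length-k tuples of non-negative integers summing to total."""
    for cuts in itertools.combinations(range(total + k - 1), k - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(total + k - 2 - prev)
        yield tuple(parts)


def gof_test(counts: Sequence[int], expected_ratio: Sequence[float], method: str = "pearson") -> GOFResult:
    """Goodness of fit of observed class counts to an expected ratio.

    ``pearson``: X^2 = sum (O-E)^2 / E with df = classes - 1.
    ``exact_multinomial``: enumerates every outcome at the observed total and
    sums the probabilities of outcomes no more probable than the observed one
    (the statistic reported is still the Pearson X^2).
    """
    obs = np.asarray(counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.ndim != 1 or obs.shape != ratio.shape:
        raise ContractError(
            f"counts ({obs.shape}) and expected ratio ({ratio.shape}) must be 1-D and match"
        )
    if np.any(ratio <= 0):
        raise ContractError("expected ratio entries must be positive")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ContractError("counts must be non-negative integers")
    total = obs.sum()
    if total <= 0:
        raise ContractError("total count must be positive")

    probs = ratio / ratio.sum()
    expected = total * probs
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1

    if method == "pearson":
        p_value = float(stats.chi2.sf(statistic, df))
    elif method == "exact_multinomial":
        n = int(total)
        n_classes = len(obs)
        n_outcomes = math.comb(n + n_classes - 1, n_classes - 1)
        if n_outcomes > _EXACT_MAX_OUTCOMES:
            raise ContractError(
                f"exact test would enumerate {n_outcomes} outcomes (limit {_EXACT_MAX_OUTCOMES})"
            )
        outcomes = np.array(list(_compositions(n, n_classes)), dtype=float)
        pmf = stats.multinomial.pmf(outcomes, n=n, p=probs)
        p_obs = stats.multinomial.pmf(obs, n=n, p=probs)
        p_value = float(np.clip(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum(), 0.0, 1.0))
    else:
        raise ContractError(f"unknown method {method!r}; expected 'pearson' or 'exact_multinomial'")
    return GOFResult(statistic=statistic, df=df, p_value=p_value, method=method)
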