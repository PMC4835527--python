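"""Hardy-Weinberg heterozygote-discovery power.

How many unrelated individuals must be screened before a polymorphism is
seen in heterozygous state at least once?  Under HWE a variant with allele
frequency ``p`` is heterozygous in one person with probability ``2p(1-p)``
(1/3 averaged over common variants), so with ``n`` independent people the
chance of at least one heterozygote is ``1 - (1 - 2p(1-p))**n``.  Averaging
that over allele frequency gives the expected fraction of polymorphisms
accessible to an allele-specific screen of ``n`` people; with a uniform AF
density the integral has the closed form used below.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial
from typing import Sequence


def het_prob(af: float) -> float:
    """HWE probability that one individual is heterozygous at frequency ``af``."""
    if not (0.0 < af < 1.0):
        raise ValueError(f"af must be in (0, 1), got {af}")
    return 2.0 * af * (1.0 - af)


def prob_any_het(af: float, n: int) -> float:
    """Probability that >= 1 of ``n`` unrelated individuals is heterozygous."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return 1.0 - (1.0 - het_prob(af)) ** n


def expected_het_fraction(n: int) -> float:
    """Expected fraction of polymorphisms heterozygous in >= 1 of ``n`` people.

    Integrates ``1 - (1 - 2p(1-p))**n`` over a uniform allele-frequency
    density on (0, 1), in exact rational arithmetic via

        integral_0^1 (2p(1-p))^k dp = 2^k (k!)^2 / (2k+1)!

    and the binomial expansion of the integrand.  n=1 gives exactly 1/3.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    acc = Fraction(0)
    for k in range(n + 1):
        acc += comb(n, k) * (-1) ** k * Fraction(2**k * factorial(k) ** 2, factorial(2 * k + 1))
    return float(1 - acc)


def round_percent(x: float) -> int:
    """Round a probability to integer percent, half away from zero (0.875 -> 88)."""
    pct = 100.0 * x
    return int(pct + 0.5) if pct >= 0 else -int(-pct + 0.5)


@dataclass(frozen=True)
class PowerCurve:
    """Discovery probability across an AF grid for a fixed cohort size ``n``.

    ``auc`` is the uniform-AF average of the curve, i.e. the expected
    fraction of polymorphisms covered by ``n`` individuals.
    """

    n: int
    af_grid: tuple[float, ...]
    probabilities: tuple[float, ...]
    auc: float


def power_curve(n: int, af_grid: Sequence[float]) -> PowerCurve:
    if len(af_grid) == 0:
        raise ValueError("af_grid must be non-empty")
    probs = tuple(prob_any_het(af, n) for af in af_grid)
    return PowerCurve(n=n, af_grid=tuple(af_grid), probabilities=probs, auc=expected_het_fraction(n))
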