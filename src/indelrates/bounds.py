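"""Evaluable concentration bounds for the k-span statistics.

k-spans more than k positions apart are independent under the channel, so
the no-mutation and single-deletion counts concentrate around their
expectations with a Chernoff-type bound whose effective sample size is the
expectation divided by the dependency range:

    Pr(|N - E[N]| >= delta * E[N]) <= 3k * exp(-delta^2 E[N] / (3k))

and likewise for D.  The mutated length L' is a sum of independent
per-position contributions (a geometric insertion minus a Bernoulli
deletion), giving a sub-exponential tail on the deviation scale
delta * (L d + L pd):

    Pr(|L' - E[L']| >= delta (L d + L pd))
        <= 2 exp(-L delta^2 d^2 / ((2(d+1) - delta d)(d+1)))
         + 2 exp(-L pd delta^2 / 3).

All three are upper bounds on a deviation probability; values above 1 are
vacuous and returned untruncated so callers can flag them.  (The printed
source of the L' bound carries an inequality-direction typo — it is stated
toward the deviation event with ">="; it is implemented here as the upper
tail bound, consistent with the N and D bounds and with how it is used in
the downstream consistency result.)

The channel's full estimator-consistency theorem involves unspecified
absolute constants and is not evaluable numerically; its qualitative
content (error shrinking with L) is exercised by parameter-recovery tests
instead.
"""

from __future__ import annotations

import math


def _check_delta(delta: float) -> None:
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must be in (0, 1), got {delta}")


def bound_N(delta: float, EN: float, k: int) -> float:
    """Upper bound on Pr(|N - E[N]| >= delta * E[N])."""
    _check_delta(delta)
    if EN < 0:
        raise ValueError(f"EN must be >= 0, got {EN}")
    return 3.0 * k * math.exp(-(delta**2) * EN / (3.0 * k))


def bound_D(delta: float, ED: float, k: int) -> float:
    """Upper bound on Pr(|D - E[D]| >= delta * E[D])."""
    _check_delta(delta)
    if ED < 0:
        raise ValueError(f"ED must be >= 0, got {ED}")
    return 3.0 * k * math.exp(-(delta**2) * ED / (3.0 * k))


def bound_Lprime(delta: float, L: int, d: float, pd: float) -> float:
    """Upper bound on Pr(|L' - E[L']| >= delta * (L d + L pd)).

    Each of the two exponential terms covers one noise source (insertions
    and deletions respectively); when a rate is zero its term is dropped —
    that noise source contributes no deviation.  With both rates zero L'
    is deterministic and the bound is 0.
    """
    _check_delta(delta)
    if d < 0 or pd < 0:
        raise ValueError("d and pd must be >= 0")
    total = 0.0
    if d > 0:
        total += 2.0 * math.exp(
            -L * delta**2 * d**2 / ((2.0 * (d + 1.0) - delta * d) * (d + 1.0))
        )
    if pd > 0:
        total += 2.0 * math.exp(-L * pd * delta**2 / 3.0)
    return total


def is_vacuous(bound: float) -> bool:
    """True when a probability bound carries no information (>= 1)."""
    return bound >= 1.0
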