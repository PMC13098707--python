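"""Closed-form rate estimators from k-span observables.

Given the original sequence summary (L, fA), the mutated sequence summary
(L', fA'), and the no-mutation / single-deletion k-span counts (N, D), the
three channel parameters satisfy — in expectation — the linear system

    (i)    -pd + d                             = L'/L - 1
    (ii)   ((L - 4 fA)/3) ps - fA pd + (L/4) d = fA' - fA
    (iii)  D ps + (k N + D) pd                 = D

Substituting observations for expectations and solving the 3x3 system
yields the estimators (p̂s, p̂d, d̂).  The system is solved numerically
rather than through transcribed closed forms; the closed forms are its
unique solution and a symbolic solve cross-checks this in the test suite.

The system degenerates when 4 fA = L (the anchor base occupies exactly a
quarter of the sequence): equation (ii) then carries no information about
ps and the estimators are undefined.  Any base with count away from L/4 can
serve as the anchor; at least one base always satisfies 4 f_c <= L.

Out-of-range solutions (negative rates, rates >= 1) are reported raw with
``valid=False`` — they are a diagnostic of an ill-conditioned input, and
clamping would hide it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kspans import KSpanCounts, count_kspans_exact
from .mutation import MutatedPair


class SingularSystemError(ValueError):
    """The estimator's linear system is singular for this input."""


@dataclass(frozen=True)
class Observables:
    """Inputs to the estimator.

    ``fA`` and ``fAprime`` are the anchor-base counts in the original and
    mutated sequence (the 'A' counts by default; any base works as long as
    its original count differs from L/4).
    """

    L: int
    fA: int
    Lprime: int
    fAprime: int
    N: float
    D: float
    k: int

    def __post_init__(self) -> None:
        if self.L < self.k:
            raise ValueError(f"L = {self.L} < k = {self.k}")
        if self.N < 0 or self.D < 0:
            raise ValueError("N and D must be non-negative")
        if self.N > self.L - self.k + 1:
            raise ValueError("N exceeds the number of k-spans")


@dataclass(frozen=True)
class RateEstimates:
    """Solution of the estimator system with diagnostics.

    ``valid`` is True iff the solved triple lies in the model's parameter
    space (0 <= ps, pd < 1, ps + pd < 1, d >= 0).  ``diagnostics`` carries
    the conditioning quantities and the per-equation relative residuals.
    """

    ps_hat: float
    pd_hat: float
    d_hat: float
    valid: bool
    diagnostics: dict = field(default_factory=dict, compare=False)


#: relative residual above which a solution is considered inconsistent
RESIDUAL_TOL = 1e-9


def estimate_rates(obs: Observables) -> RateEstimates:
    """Solve the linear estimator system for (p̂s, p̂d, d̂).

    Raises :class:`SingularSystemError` when 4 fA = L or the system is
    numerically singular (e.g. N = D = 0).
    """
    L, fA, k = obs.L, obs.fA, obs.k
    if 4 * fA == L:
        raise SingularSystemError(
            f"anchor-base count fA = {fA} equals L/4 = {L // 4}: the "
            "estimator requires 4*fA != L; choose another anchor base"
        )
    A = np.array(
        [
            [0.0, -1.0, 1.0],
            [(L - 4.0 * fA) / 3.0, -float(fA), L / 4.0],
            [obs.D, k * obs.N + obs.D, 0.0],
        ]
    )
    b = np.array(
        [
            obs.Lprime / L - 1.0,
            float(obs.fAprime - fA),
            float(obs.D),
        ]
    )
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        cond = float(np.linalg.cond(A))
        raise SingularSystemError(
            f"estimator system is singular (condition number {cond:.3g}); "
            f"N = {obs.N}, D = {obs.D}"
        ) from exc
    ps_hat, pd_hat, d_hat = (float(x) for x in sol)

    scale = np.maximum(np.abs(A) @ np.abs(sol) + np.abs(b), 1e-30)
    residuals = np.abs(A @ sol - b) / scale
    valid = (
        0.0 <= ps_hat < 1.0
        and 0.0 <= pd_hat < 1.0
        and ps_hat + pd_hat < 1.0
        and d_hat >= 0.0
        and bool(np.all(residuals < RESIDUAL_TOL))
    )
    diagnostics = {
        "L_minus_4fA": L - 4 * fA,
        "D_plus_4kN": obs.D + 4.0 * k * obs.N,
        "residuals": residuals.tolist(),
        "condition_number": float(np.linalg.cond(A)),
    }
    return RateEstimates(
        ps_hat=ps_hat, pd_hat=pd_hat, d_hat=d_hat, valid=valid,
        diagnostics=diagnostics,
    )


def estimate_smm(N: float, K: float, k: int) -> float:
    """Substitution-only ("simple mutation model") rate estimate.

    Under a substitution-only channel the expected number of unmutated
    k-spans is K (1-q)^k, so q̂ = 1 - (N/K)^(1/k).  With indels present
    this estimator absorbs insertion and deletion signal into q̂ and
    overestimates the substitution rate.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if N <= 0:
        raise ValueError("SMM estimate undefined for N = 0")
    if N > K:
        raise ValueError(f"N = {N} exceeds K = {K}")
    return 1.0 - (N / K) ** (1.0 / k)


def observables_from_pair(
    pair: MutatedPair, k: int | None = None, anchor_base: str = "A"
) -> Observables:
    """Build estimator inputs from an annotated pair using exact counts."""
    if k is None:
        k = pair.params.k
    counts = count_kspans_exact(pair.annotation, k)
    return Observables(
        L=pair.original.L,
        fA=pair.original.count(anchor_base),
        Lprime=pair.mutated.L,
        fAprime=pair.mutated.count(anchor_base),
        N=counts.N,
        D=counts.D,
        k=k,
    )


def pick_anchor_base(record_counts: dict[str, int], L: int) -> str:
    """Pick the base whose count deviates most from L/4 (anchor 'auto').

    Ties break alphabetically so the choice is deterministic.
    """
    return min(record_counts, key=lambda b: (-abs(record_counts[b] - L / 4.0), b))


def estimate_exact(
    pair: MutatedPair, k: int | None = None, anchor_base: str = "A"
) -> tuple[RateEstimates, Observables, KSpanCounts]:
    """Exact-count estimation pipeline on an annotated pair.

    Convenience composition: annotation -> k-span counts -> linear solve.
    ``anchor_base`` may be 'auto'.
    """
    if k is None:
        k = pair.params.k
    if anchor_base == "auto":
        anchor_base = pick_anchor_base(pair.original.freqs, pair.original.L)
    counts = count_kspans_exact(pair.annotation, k)
    obs = Observables(
        L=pair.original.L,
        fA=pair.original.count(anchor_base),
        Lprime=pair.mutated.L,
        fAprime=pair.mutated.count(anchor_base),
        N=counts.N,
        D=counts.D,
        k=k,
    )
    return estimate_rates(obs), obs, counts
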