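"""k-span statistics: exact classification and closed-form expectations.

A k-span is the coordinate interval [i, i+k-1] of the *original* sequence
(1-based, inclusive) — the positional footprint of a k-mer.  Unlike a
k-mer, a k-span carries context, so mutation events can be attributed to it
unambiguously from the channel annotation; no sequence content is
consulted.  The "interior" insertion slots of a span are the k-1 slots
strictly inside it (the slots before positions i+1 .. i+k-1); the slot
before position i and anything outside the span do not affect its class.

Classes counted:

* no-mutation (N): all k actions are Stay and all interior slots insert
  nothing;
* single deletion (D): exactly one Del, the other k-1 positions Stay, no
  interior insertions;
* single substitution (S): exactly one Sub, the rest Stay, no interior
  insertions;
* single insertion (I): all k positions Stay and exactly one interior slot
  inserts exactly one character (the remaining interior slots insert
  nothing).  The length-exactly-1 reading is forced by the d/(d+1)^k factor
  in the closed-form expectation; see docs/methods.md.

With q = 1 - ps - pd, K = L - k + 1 and t = 1/(1+d):

    E[N] = K q^k t^(k-1)
    E[S] = K k q^(k-1) ps t^(k-1)
    E[D] = K k q^(k-1) pd t^(k-1)
    E[I] = K (k-1) q^k d / (1+d)^k

and for the mutated sequence itself:

    E[L']   = L (1 + d - pd)
    Var[L'] = L (d(d+1) + pd(1-pd))
    E[fA']  = fA (1-ps-pd) + ps (L-fA)/3 + d L / 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mutation import DEL, SUB, MutationAnnotation, MutationParams


@dataclass(frozen=True)
class KSpanCounts:
    """Observed (or expected) counts of k-span classes.

    ``K`` is the total number of k-spans (L - k + 1); ``N``, ``D``,
    ``S_sub`` and ``I_ins`` are the no-mutation, single-deletion,
    single-substitution and single-insertion counts.
    """

    K: int
    N: int
    D: int
    S_sub: int
    I_ins: int

    def __post_init__(self) -> None:
        if self.N + self.D + self.S_sub + self.I_ins > self.K:
            raise ValueError("class counts exceed the number of k-spans")


@dataclass(frozen=True)
class ExpectedStats:
    """Closed-form expectations of the channel's observable statistics."""

    K: int
    EL: float
    VarL: float
    EfA: float
    EN: float
    ED: float
    ES: float
    EI: float


def _window_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of width ``w`` (length len(x)-w+1)."""
    c = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return c[w:] - c[:-w]


def count_kspans_exact(annotation: MutationAnnotation, k: int) -> KSpanCounts:
    """Classify every k-span of the original sequence from its annotation.

    Runs in O(L) with vectorised prefix sums.  Raises ``ValueError`` when
    the sequence is shorter than k.
    """
    L = annotation.L
    if L < k:
        raise ValueError(f"sequence length {L} < k = {k}")
    a = annotation.actions
    li = annotation.insert_lengths

    subs = _window_sum(a == SUB, k)
    dels = _window_sum(a == DEL, k)
    if k == 1:
        ins_total = np.zeros(L, dtype=np.int64)
    else:
        # interior slots of span starting at 0-based s: li[s+1 .. s+k-1]
        ins_total = _window_sum(li[1:], k - 1)[: L - k + 1]

    clean = (subs == 0) & (dels == 0)
    N = int(np.count_nonzero(clean & (ins_total == 0)))
    D = int(np.count_nonzero((dels == 1) & (subs == 0) & (ins_total == 0)))
    S = int(np.count_nonzero((subs == 1) & (dels == 0) & (ins_total == 0)))
    # total interior insertion of exactly 1 <=> one slot with l=1, rest 0
    I = int(np.count_nonzero(clean & (ins_total == 1)))
    return KSpanCounts(K=L - k + 1, N=N, D=D, S_sub=S, I_ins=I)


def expected_stats(
    params: MutationParams, L: int, fA: int, k: int | None = None
) -> ExpectedStats:
    """Evaluate the closed-form expectations for given channel parameters."""
    if k is None:
        k = params.k
    if L < k:
        raise ValueError(f"L = {L} < k = {k}")
    if not (0 <= fA <= L):
        raise ValueError(f"fA must be in [0, L], got {fA}")
    ps, pd, d = params.ps, params.pd, params.d
    q = 1.0 - ps - pd
    K = L - k + 1
    t = 1.0 / (1.0 + d)

    EL = L * (1.0 + d - pd)
    VarL = L * (d * (d + 1.0) + pd * (1.0 - pd))
    EfA = fA * q + ps * (L - fA) / 3.0 + d * L / 4.0
    EN = K * q**k * t ** (k - 1)
    ES = K * k * q ** (k - 1) * ps * t ** (k - 1)
    ED = K * k * q ** (k - 1) * pd * t ** (k - 1)
    EI = K * (k - 1) * q**k * d / (1.0 + d) ** k
    return ExpectedStats(K=K, EL=EL, VarL=VarL, EfA=EfA, EN=EN, ED=ED, ES=ES, EI=EI)
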