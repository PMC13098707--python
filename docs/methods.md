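# Methods

## The mutation channel

`indelrates` models the divergence of a nucleotide sequence S (length L,
alphabet {A, C, G, T}) under an indel channel with three parameters:

* **ps** — per-site substitution probability, 0 ≤ ps < 1;
* **pd** — per-site deletion probability, 0 ≤ pd < 1, ps + pd < 1;
* **d** — mean insertion length per slot (nucleotides), d ≥ 0.

Each position independently receives one action: Sub (probability ps),
Del (pd) or Stay (1 − ps − pd). A substituted character is replaced by a
uniform draw from the other three bases (no transition/transversion
asymmetry). Independently, each of the L insertion slots — the slot
*before* position i, for i = 1..L — receives l_i inserted characters,
where l_i is geometric on {0, 1, 2, ...} with mean d (success probability
1/(1+d)), each inserted character uniform over the four bases. Operations
are applied as: substitutions, then insertions, then deletions, with
original coordinates resolved through a position-tracking map.

Two conventions deserve emphasis because they fix the algebra:

* **Slot convention.** There are exactly L slots and none after the final
  character. This gives E[L′] = L(1 + d − pd) exactly; a trailing slot
  would add d to the expectation. The channel's insertion step never uses
  the "prepend" (i = 0) branch of the insert operation, which is
  implemented and tested anyway for API completeness.
* **Geometric parameterisation.** Support starting at 0 with success
  probability 1/(1+d) is the only geometric with mean d on {0, 1, ...};
  it also reproduces Var[L′] = L(d(d+1) + pd(1 − pd)).

The simulator assembles S′ in one vectorised left-to-right pass (for each
position: emit the slot's inserted string, then the post-substitution
character unless the action is Del). Because every event is attached to a
distinct original position, this is equivalent to the literal
track-mediated order of operations; the test suite asserts byte-for-byte
agreement with a naive executor that maintains the track map explicitly,
both on random inputs and exhaustively over all small annotations.

## k-span statistics

A **k-span** is the interval [i, i+k−1] of the *original* sequence — the
positional footprint of a k-mer. There are K = L − k + 1 of them.
Classification is purely positional (from the channel annotation, never
from sequence content):

* **no-mutation (N)** — all k actions Stay, nothing inserted at any of
  the k−1 *interior* slots (the slots before positions i+1..i+k−1; the
  slot before position i is exterior);
* **single deletion (D)** — exactly one Del, k−1 Stay, no interior
  insertions;
* **single substitution (S)** — one Sub analogously;
* **single insertion (I)** — all Stay, exactly one interior slot with
  exactly **one** inserted character, the rest empty.

With q = 1 − ps − pd:

    E[N] = K q^k (1+d)^-(k-1)            E[S] = K k q^(k-1) ps (1+d)^-(k-1)
    E[D] = K k q^(k-1) pd (1+d)^-(k-1)   E[I] = K (k-1) q^k d (1+d)^-k
    E[fA'] = fA q + ps (L - fA)/3 + d L / 4

Two readings in the span-class definitions are not spelled out by the
formulas' prose and were fixed by the algebra itself:

* "interior positions" must mean the k−1 slots strictly inside the span —
  the only reading that yields the (1+d)^−(k−1) factor;
* "single insertion" must mean exactly one inserted character — one slot
  with l = 1 yields the d/(1+d)^k factor, whereas "one slot with any
  l > 0" would yield d/(1+d)^(k−1), larger by a factor (1+d). A dedicated
  test counts both definitions in simulation and shows only the first
  matches E[I].

An exhaustive micro-oracle validates the counter and the closed forms
together at L = 5, k ∈ {2, 3}: every action vector and every per-slot
insertion *category* (0, 1, or ≥2 characters — the classification depends
on nothing finer) is enumerated with its exact probability, and the
weighted class counts agree with the formulas to 10+ significant digits.

## The estimators

Writing the observations (L′, fA′, N, D) in place of their expectations,
the parameters solve the linear system

    (i)    −pd + d                              = L′/L − 1
    (ii)   ((L − 4 fA)/3) ps − fA pd + (L/4) d  = fA′ − fA
    (iii)  D ps + (k N + D) pd                  = D

Equation (iii) is the ratio identity E[D]/E[N] = k pd / q rearranged to be
linear. The implementation solves the 3×3 system numerically
(`numpy.linalg.solve`) rather than transcribing closed forms; the closed
forms are the system's unique solution, and a `sympy` exact-arithmetic
solve cross-checks the numeric route in the tests. Feeding exact
expectations back through the solve recovers the generating triple to ten
significant digits across the whole grid {0, 0.01, ..., 0.1}³ × k ∈
{11, 21, 31, 41} — the defining correctness property of the estimators.

Degeneracies and their handling:

* **4 fA = L** makes equation (ii) carry no substitution information; the
  solver raises a `SingularSystemError` naming the condition. Any base
  whose count differs from L/4 can serve as the composition anchor
  (`anchor_base="auto"` picks the most skewed base, ties broken
  alphabetically); at least one base always satisfies 4 f_c ≤ L.
* **D = 0** forces p̂d = 0 through equation (iii); the system remains
  solvable as long as N > 0.
* **Out-of-range solutions** (negative rates, etc. — expected near the
  composition singularity) are reported raw with `valid=False`; clamping
  would hide the diagnostic.
* A solution is accepted as consistent when each equation's relative
  residual is below 1e−9.

The substitution-only baseline ("simple mutation model", SMM) inverts
E[N] = K (1 − q)^k for a pure-substitution channel: q̂ = 1 − (N/K)^(1/k).
The exact form of the baseline used in the original comparison is not
restated there; this standard inversion is our reading. With indels
present it absorbs all three signals and grossly overestimates the
substitution rate — the comparison tests reproduce this ordering.

## Estimating N and D from sequences alone

When only the two FASTA files are available, N and D are estimated by:

1. **Unitigs.** Build the node-centric de Bruijn graph on the distinct
   k-mers of each sequence (forward strand only, no reverse-complement
   canonicalisation — the channel is strand-specific, and canonical
   k-mers would merge spans the model distinguishes; this is also why no
   canonical-mode flag is offered) and extract maximal non-branching
   paths. Unitigs restore context beyond k characters, which bare k-mer
   sets lack. Isolated cycles are broken at their first-seen k-mer for
   determinism.
2. **Infix alignment.** Align every unitig pair with unit-cost
   semi-global (infix) alignment via `edlib` (an in-house DP aligner is
   the fallback backend and the oracle in tests). The shorter sequence is
   the query (ties: the mutated unitig), so its ends align free inside
   the longer one.
3. **Window classification.** Slide a window covering exactly k
   reference characters along each accepted alignment; all-match columns
   with no interior insertion column → no-mutation; exactly one deletion
   column, rest matches, no interior insertion → single deletion.

Three procedural choices are ours (the original description leaves them
open) and are therefore configurable or documented:

* **Acceptance threshold.** An alignment is used only if its normalised
  edit distance (distance / query length) ≤ 0.35 (`max_norm_dist`). The
  value comfortably exceeds the per-base divergence at the highest total
  mutation rate studied (~15%) while rejecting spurious unitig pairs.
* **Deduplication.** Accepted alignments are processed in ascending
  (normalised distance, ref index, mut index) order and each reference
  window is classified by the first alignment covering it; without this,
  N̂ could exceed K when several mutated unitigs align to one reference
  unitig.
* **Orientation** of query/target as above.

Content coincidences — e.g. an inserted character identical to an
adjacent deleted one — are invisible to the aligner and bias the window
counts slightly relative to the exact annotation-based counts; at total
rates ≤ 6% the pipeline's (N̂, D̂) land within a few percent of exact.
The implementation optimises for fidelity, not throughput: all-vs-all
unitig alignment is quadratic in the number of unitigs and intended for
megabase-scale inputs, not genome collections.

## Concentration bounds

k-spans more than k positions apart are independent, giving Chernoff-type
bounds 3k·exp(−δ²E/(3k)) on the relative deviation of N and D, and L′
obeys a two-term sub-exponential bound on the deviation scale
δ(Ld + Lpd). The printed source of the L′ bound contains an
inequality-direction typo (stated with "≥" toward a sum of vanishing
terms); it is implemented as an upper bound on the deviation probability,
consistent with its companions and its downstream use. When pd = 0 (or
d = 0) the corresponding term is dropped — that noise source contributes
no deviation — and with both zero L′ is deterministic, so the bound is 0.
Bounds above 1 are vacuous and returned untruncated with a flag in the
CLI. The full consistency theorem for p̂s involves unspecified absolute
constants and is deliberately not exposed as a numeric function; its
qualitative content — estimator error vanishing with L — is verified
empirically by the length-sweep tests.

## Synthetic data and what the tests show

The generator draws i.i.d. bases with P(A) = `a_fraction` (default 0.30,
the composition used throughout the reference experiments) and the rest
split equally — matching the channel's assumptions exactly. Real genomes
violate them in known ways: repeats (which fragment unitigs and create
ambiguous alignments), composition heterogeneity, and context-dependent
mutation. Passing the recovery tests therefore demonstrates correctness
of the estimators *under the model*, and the pipeline tests demonstrate
that sequence-level counting approximates span-level truth when k-mers
are mostly unique; neither certifies accuracy on arbitrary real data.

Default problem sizes are desk-scale choices: 1 Mbp × 10 replicates for
the recovery suites (the channel simulator is vectorised, so a 1 Mbp
realisation takes well under a second), 100 kbp for pipeline-based
checks, 500 replicates at 100 kbp for bound coverage. The experiment
presets default to 100 kbp / 10 replicates with `--full` switching to the
1 Mbp / 20-replicate configurations.

## Known limitations

* Rates are global and context-free; no transition/transversion bias,
  no heterogeneity along the sequence, single round of mutation only.
* The estimator's variance grows quickly with k and blows up as
  fA → L/4; estimates are reported raw with `valid=False` there.
* The unitig pipeline is strand-specific and quadratic in unitig count;
  highly repetitive genomes will fragment unitigs and degrade (N̂, D̂).
* pd ≈ 0 is ill-conditioned for *estimating* pd from noisy D (exact
  D = 0 is handled exactly).
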