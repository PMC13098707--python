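"""Estimating k-span counts from two sequences alone.

The exact span counts require the channel annotation, which is unavailable
when all we have are the original and mutated FASTA files.  The pipeline
here recovers approximate counts (N̂, D̂) from sequence content:

1. build the node-centric de Bruijn graph over the distinct k-mers of each
   sequence and extract its unitigs (maximal non-branching paths) — these
   restore context beyond k characters, which a bare k-mer set lacks;
2. align every unitig of the mutated sequence against every unitig of the
   original with semi-global (infix) edit-distance alignment, the shorter
   sequence acting as the query so its ends align for free inside the
   longer one;
3. slide a window covering exactly k original-sequence characters along
   each accepted alignment and classify it from the alignment columns:
   all-match with no interior insertion column -> no-mutation; exactly one
   deletion column, the rest matches, no interior insertion ->
   single-deletion.

Alignments are accepted when their normalised edit distance (distance /
query length) is at most ``max_norm_dist`` and processed in ascending
order of normalised distance; each reference window is classified by the
first accepted alignment that covers it, so no window is double-counted.

Everything is strand-specific: no reverse-complement canonicalisation, as
the channel itself is strand-specific.  Content coincidences (e.g. an
inserted character identical to an adjacent deleted one) are invisible to
the aligner and are a known, small source of bias relative to the exact
annotation-based counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:
    import edlib

    HAVE_EDLIB = True
except ImportError:  # pragma: no cover - edlib is a hard dependency in practice
    HAVE_EDLIB = False

from .estimators import (
    Observables,
    RateEstimates,
    estimate_rates,
    estimate_smm,
    pick_anchor_base,
)
from .seqio import SequenceRecord, pooled_composition, read_fasta

#: default cap on normalised edit distance for an alignment to be "relevant"
DEFAULT_MAX_NORM_DIST = 0.35


@dataclass(frozen=True)
class UnitigSet:
    """Unitigs (maximal non-branching de Bruijn paths) of one sequence set."""

    unitigs: tuple[str, ...]
    k: int
    source: str


@dataclass(frozen=True)
class WindowCounts:
    """Pipeline-estimated k-span class counts."""

    N_hat: int
    D_hat: int
    windows_scanned: int
    alignments_used: int


@dataclass(frozen=True)
class InfixAlignment:
    """Semi-global alignment of ``query`` inside ``target``.

    ``ops`` is the expanded column string over {=, X, I, D}: '=' match,
    'X' mismatch, 'I' consumes query only, 'D' consumes target only.
    ``target_start``/``target_end`` delimit the aligned target infix
    (0-based, end exclusive).
    """

    query: str
    target: str
    distance: int
    ops: str
    target_start: int
    target_end: int


def _kmer_iter(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def build_unitigs(
    seq: SequenceRecord | str, k: int, source: str | None = None
) -> UnitigSet:
    """Extract the unitigs of the node-centric de Bruijn graph of ``seq``.

    Nodes are the distinct k-mers of the sequence (forward strand only);
    there is an edge x -> y whenever x's (k-1)-suffix equals y's
    (k-1)-prefix.  Unitigs are maximal paths whose interior nodes have
    in-degree and out-degree 1.  The union of k-mers over the returned
    unitigs equals the sequence's distinct k-mer set.
    """
    if isinstance(seq, SequenceRecord):
        s, name = seq.seq, seq.name
    else:
        s, name = seq, source or "seq"
    if len(s) < k:
        raise ValueError(f"sequence length {len(s)} < k = {k}")

    # dict preserves first-occurrence order -> deterministic output
    kmers: dict[str, None] = dict.fromkeys(_kmer_iter(s, k))

    def successors(x: str) -> list[str]:
        suf = x[1:]
        return [suf + c for c in "ACGT" if suf + c in kmers]

    def predecessors(x: str) -> list[str]:
        pre = x[:-1]
        return [c + pre for c in "ACGT" if c + pre in kmers]

    visited: set[str] = set()
    unitigs: list[str] = []

    def walk(start: str) -> str:
        chars = [start]
        visited.add(start)
        cur = start
        while True:
            nxt_list = successors(cur)
            if len(nxt_list) != 1:
                break
            nxt = nxt_list[0]
            if nxt in visited or len(predecessors(nxt)) != 1:
                break
            visited.add(nxt)
            chars.append(nxt[-1])
            cur = nxt
        return chars[0] + "".join(chars[1:])

    for x in kmers:
        if x in visited:
            continue
        preds = predecessors(x)
        if len(preds) != 1 or len(successors(preds[0])) != 1:
            unitigs.append(walk(x))
    # leftover nodes lie on isolated simple cycles; break each at the
    # first-seen node for determinism
    for x in kmers:
        if x not in visited:
            unitigs.append(walk(x))
    return UnitigSet(unitigs=tuple(unitigs), k=k, source=name)


def _expand_cigar(cigar: str) -> str:
    out: list[str] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append(ch * int(num))
            num = ""
    return "".join(out)


def _dp_infix(query: str, target: str) -> InfixAlignment:
    """Plain O(mn) dynamic-programming infix aligner.

    Unit costs, free leading and trailing gaps in the target.  Used as the
    backend when edlib is unavailable and as the independent oracle in
    tests.  Tie-breaking prefers diagonal moves, then consuming the query.
    """
    m, n = len(query), len(target)
    dp = np.zeros((m + 1, n + 1), dtype=np.int32)
    dp[:, 0] = np.arange(m + 1)
    for i in range(1, m + 1):
        qc = query[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (qc != target[j - 1])
            row[j] = min(sub, prev[j] + 1, row[j - 1] + 1)
    end = int(np.argmin(dp[m]))
    dist = int(dp[m, end])
    # traceback
    ops: list[str] = []
    i, j = m, end
    while i > 0:
        if j > 0 and dp[i, j] == dp[i - 1, j - 1] + (query[i - 1] != target[j - 1]):
            ops.append("=" if query[i - 1] == target[j - 1] else "X")
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i - 1, j] + 1:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    return InfixAlignment(
        query=query,
        target=target,
        distance=dist,
        ops="".join(reversed(ops)),
        target_start=j,
        target_end=end,
    )


def align_infix(query: str, target: str, backend: str = "auto") -> InfixAlignment:
    """Semi-global (infix) alignment of ``query`` against ``target``.

    The query aligns end-to-end; gaps before and after it in the target
    are free.  Returns the minimal unit-cost edit distance and the full
    column path.
    """
    if not query or not target:
        raise ValueError("align_infix requires non-empty sequences")
    if backend == "auto":
        backend = "edlib" if HAVE_EDLIB else "dp"
    if backend == "dp":
        return _dp_infix(query, target)
    res = edlib.align(query, target, mode="HW", task="path")
    start, end = res["locations"][0]
    return InfixAlignment(
        query=query,
        target=target,
        distance=int(res["editDistance"]),
        ops=_expand_cigar(res["cigar"]),
        target_start=int(start),
        target_end=int(end) + 1,
    )


def count_windows(
    ref_unitigs: UnitigSet,
    mut_unitigs: UnitigSet,
    k: int | None = None,
    max_norm_dist: float = DEFAULT_MAX_NORM_DIST,
) -> WindowCounts:
    """Estimate (N, D) by classifying k-wide windows of unitig alignments.

    All unitig pairs are aligned; alignments with normalised edit distance
    above ``max_norm_dist`` are discarded.  Accepted alignments are
    processed in ascending (normalised distance, ref index, mut index)
    order and each reference window is classified at most once.
    """
    if k is None:
        k = ref_unitigs.k
    if ref_unitigs.k != mut_unitigs.k or k != ref_unitigs.k:
        raise ValueError(
            f"k mismatch: ref k={ref_unitigs.k}, mut k={mut_unitigs.k}, asked k={k}"
        )
    accepted = []
    for ui, u in enumerate(ref_unitigs.unitigs):
        for vi, v in enumerate(mut_unitigs.unitigs):
            # shorter sequence is the query; ties -> mutated unitig
            if len(u) < len(v):
                aln = align_infix(u, v)
                ref_is_query = True
            else:
                aln = align_infix(v, u)
                ref_is_query = False
            norm = aln.distance / len(aln.query)
            if norm <= max_norm_dist:
                accepted.append((norm, ui, vi, aln, ref_is_query))
    accepted.sort(key=lambda t: (t[0], t[1], t[2]))

    seen = {
        ui: np.zeros(len(u) - k + 1, dtype=bool)
        for ui, u in enumerate(ref_unitigs.unitigs)
        if len(u) >= k
    }
    N_hat = D_hat = scanned = 0
    for _, ui, _vi, aln, ref_is_query in accepted:
        if ui not in seen:
            continue
        cols = np.frombuffer(aln.ops.encode(), dtype=np.uint8)
        if ref_is_query:
            del_code, ins_code = ord("I"), ord("D")
            ref_start = 0
        else:
            del_code, ins_code = ord("D"), ord("I")
            ref_start = aln.target_start
        is_ref = cols != ins_code
        ref_idx = np.flatnonzero(is_ref)
        if len(ref_idx) < k:
            continue
        cum_mis = np.concatenate(([0], np.cumsum(cols == ord("X"))))
        cum_del = np.concatenate(([0], np.cumsum(cols == del_code)))
        cum_ins = np.concatenate(([0], np.cumsum(cols == ins_code)))
        j0 = ref_idx[: len(ref_idx) - k + 1]
        j1 = ref_idx[k - 1 :]
        mis_in = cum_mis[j1 + 1] - cum_mis[j0]
        del_in = cum_del[j1 + 1] - cum_del[j0]
        ins_in = cum_ins[j1 + 1] - cum_ins[j0]  # strictly interior: I cols are non-ref

        wpos = ref_start + np.arange(len(j0))
        fresh = ~seen[ui][wpos]
        seen[ui][wpos] = True
        scanned += int(np.count_nonzero(fresh))
        clean = fresh & (mis_in == 0) & (ins_in == 0)
        N_hat += int(np.count_nonzero(clean & (del_in == 0)))
        D_hat += int(np.count_nonzero(clean & (del_in == 1)))
    return WindowCounts(
        N_hat=N_hat,
        D_hat=D_hat,
        windows_scanned=scanned,
        alignments_used=len(accepted),
    )


def estimate_from_fasta(
    ref: str | Path,
    mut: str | Path,
    k: int = 21,
    max_norm_dist: float = DEFAULT_MAX_NORM_DIST,
    anchor_base: str = "A",
    drop_non_acgt: bool = False,
) -> tuple[RateEstimates, dict]:
    """End-to-end alignment-free estimation from two FASTA files.

    Unitigs are built per FASTA record and pooled per file; length and
    base counts are summed over records.  Returns the rate estimates and a
    diagnostics dict (unitig counts, window totals, the substitution-only
    baseline estimate, and the anchor base used).
    """
    ref_records = read_fasta(ref, drop_non_acgt=drop_non_acgt)
    mut_records = read_fasta(mut, drop_non_acgt=drop_non_acgt)
    L, ref_counts = pooled_composition(ref_records)
    Lp, mut_counts = pooled_composition(mut_records)
    if anchor_base == "auto":
        anchor_base = pick_anchor_base(ref_counts, L)

    ref_uts: list[str] = []
    for r in ref_records:
        ref_uts.extend(build_unitigs(r, k).unitigs)
    mut_uts: list[str] = []
    for r in mut_records:
        mut_uts.extend(build_unitigs(r, k).unitigs)
    ref_set = UnitigSet(unitigs=tuple(ref_uts), k=k, source=str(ref))
    mut_set = UnitigSet(unitigs=tuple(mut_uts), k=k, source=str(mut))

    wc = count_windows(ref_set, mut_set, k, max_norm_dist=max_norm_dist)
    obs = Observables(
        L=L,
        fA=ref_counts[anchor_base],
        Lprime=Lp,
        fAprime=mut_counts[anchor_base],
        N=wc.N_hat,
        D=wc.D_hat,
        k=k,
    )
    est = estimate_rates(obs)
    K = L - k + 1
    diagnostics = {
        "anchor_base": anchor_base,
        "n_ref_unitigs": len(ref_uts),
        "n_mut_unitigs": len(mut_uts),
        "alignments_used": wc.alignments_used,
        "windows_scanned": wc.windows_scanned,
        "N_hat": wc.N_hat,
        "D_hat": wc.D_hat,
        "K": K,
        "smm_q_hat": estimate_smm(wc.N_hat, K, k) if wc.N_hat > 0 else None,
        "max_norm_dist": max_norm_dist,
    }
    return est, diagnostics
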