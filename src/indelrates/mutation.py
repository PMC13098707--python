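"""The substitution + indel mutation channel.

The process takes a string S of length L and three parameters: a per-site
substitution probability ``ps``, a per-site deletion probability ``pd``
(with ps + pd < 1), and a mean insertion length ``d >= 0``.  Every position
independently receives one action — Sub with probability ps, Del with
probability pd, Stay otherwise.  Substituted characters are replaced by a
uniform draw from the other three bases.  Independently, each of the L
insertion slots (the slot *before* position i, for i = 1..L; there is no
slot after the final character) receives a geometrically distributed number
of inserted characters with mean d (support {0, 1, 2, ...}, success
probability 1/(1+d)), each inserted character uniform over {A, C, G, T}.

Operations are applied in the order: substitutions, then insertions, then
deletions, with original coordinates resolved through a position-tracking
map.  Because all events are attached to distinct original positions, the
mutated string can equivalently be assembled in a single left-to-right pass
(for each position: emit the inserted string for its slot, then the
post-substitution character unless the action is Del); that is what the
vectorised implementation does, and tests assert its equivalence with a
naive splice-based executor.

Every event is recorded in a :class:`MutationAnnotation`, which is the
ground truth used for exact k-span classification downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as _pd

from .seqio import BASE_CODES, SequenceRecord

STAY, SUB, DEL = 0, 1, 2
ACTION_NAMES = {STAY: "Stay", SUB: "Sub", DEL: "Del"}
ACTION_CODES = {v: k for k, v in ACTION_NAMES.items()}

# ASCII code -> base index 0..3; 255 marks non-ACGT
_CODE_TO_IDX = np.full(256, 255, dtype=np.uint8)
_CODE_TO_IDX[BASE_CODES] = np.arange(4, dtype=np.uint8)


@dataclass(frozen=True)
class MutationParams:
    """Parameters (ps, pd, d) of the mutation channel plus the k-mer size.

    ``ps``: substitution probability per site; ``pd``: deletion probability
    per site; ``d``: mean inserted length per slot (nucleotides); ``k``:
    k-mer length used by the span statistics.
    """

    ps: float
    pd: float
    d: float
    k: int = 21

    def __post_init__(self) -> None:
        if not (0.0 <= self.ps < 1.0 and 0.0 <= self.pd < 1.0):
            raise ValueError(f"ps and pd must be in [0, 1): ps={self.ps}, pd={self.pd}")
        if self.ps + self.pd >= 1.0:
            raise ValueError(f"ps + pd must be < 1, got {self.ps + self.pd}")
        if self.d < 0.0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


@dataclass
class MutationAnnotation:
    """Complete record of the events of one channel realisation.

    ``actions[i]`` is the action at original position i+1 (0-based arrays,
    1-based biology).  ``insert_lengths[i]`` is the number of characters
    inserted at the slot immediately before position i+1.  ``sub_chars``
    holds the replacement character's ASCII code at Sub positions (0
    elsewhere); ``ins_chars`` concatenates all inserted characters in slot
    order.
    """

    actions: np.ndarray          # int8, length L, values in {STAY, SUB, DEL}
    insert_lengths: np.ndarray   # int64, length L
    sub_chars: np.ndarray        # uint8, length L; ASCII code or 0
    ins_chars: np.ndarray        # uint8, flat, length = insert_lengths.sum()

    def __post_init__(self) -> None:
        L = len(self.actions)
        if len(self.insert_lengths) != L or len(self.sub_chars) != L:
            raise ValueError("annotation arrays must all have length L")
        if len(self.ins_chars) != int(self.insert_lengths.sum()):
            raise ValueError("ins_chars length inconsistent with insert_lengths")

    @property
    def L(self) -> int:
        return len(self.actions)

    def insertion_at(self, i: int) -> str:
        """Inserted string at the slot before 1-based position ``i``."""
        ends = np.cumsum(self.insert_lengths)
        start = int(ends[i - 1] - self.insert_lengths[i - 1])
        return self.ins_chars[start:int(ends[i - 1])].tobytes().decode()


@dataclass(frozen=True)
class MutatedPair:
    """An (original, mutated) sequence pair with its generating annotation."""

    original: SequenceRecord
    mutated: SequenceRecord
    annotation: MutationAnnotation
    params: MutationParams

    @property
    def Lprime(self) -> int:
        return self.mutated.L

    @property
    def fAprime(self) -> int:
        return self.mutated.fA


def substitute_op(s: str, i: int, c: str) -> str:
    """Replace the 1-based position ``i`` of ``s`` by character ``c``."""
    return s[: i - 1] + c + s[i:]


def delete_op(s: str, i: int) -> str:
    """Remove the 1-based position ``i`` of ``s``."""
    return s[: i - 1] + s[i:]


def insert_op(s: str, i: int, piece: str) -> str:
    """Insert ``piece`` between positions ``i-1`` and ``i`` (1-based).

    ``i = 0`` prepends to the start of the string.  The per-position
    mutation process only uses slots i = 1..L, but the i = 0 branch is part
    of the operation's definition and kept for completeness.
    """
    if i <= 0:
        return piece + s
    return s[: i - 1] + piece + s[i - 1 :]


def sample_insertion_lengths(
    d: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample insertion lengths: geometric on {0, 1, 2, ...} with mean ``d``.

    P(l = j) = (1/(1+d)) * (d/(1+d))**j, so the mean is d and the variance
    d(1+d).  ``d = 0`` degenerates to all zeros.
    """
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    if d == 0:
        return np.zeros(size, dtype=np.int64)
    # numpy's geometric counts trials until first success (support {1,...})
    return rng.geometric(1.0 / (1.0 + d), size=size).astype(np.int64) - 1


def sample_insertion_length(d: float, rng: np.random.Generator) -> int:
    """Single draw from the mean-``d`` geometric insertion-length law."""
    return int(sample_insertion_lengths(d, 1, rng)[0])


def _assemble(codes: np.ndarray, ann: MutationAnnotation) -> np.ndarray:
    """Left-to-right assembly of the mutated string from an annotation."""
    post_sub = codes.copy()
    sub_mask = ann.actions == SUB
    post_sub[sub_mask] = ann.sub_chars[sub_mask]

    keep = ann.actions != DEL
    li = ann.insert_lengths
    piece_len = li + keep
    starts = np.zeros(len(codes), dtype=np.int64)
    np.cumsum(piece_len[:-1], out=starts[1:])
    out = np.empty(int(piece_len.sum()), dtype=np.uint8)

    out[starts[keep] + li[keep]] = post_sub[keep]
    total_ins = int(li.sum())
    if total_ins:
        ins_starts = np.repeat(starts, li)
        within = np.arange(total_ins) - np.repeat(np.cumsum(li) - li, li)
        out[ins_starts + within] = ann.ins_chars
    return out


def mutate(
    seq: SequenceRecord,
    params: MutationParams,
    seed: int | np.random.Generator | None = None,
) -> MutatedPair:
    """Run the mutation channel once and return the annotated pair.

    The returned annotation is faithful: replaying it through
    :func:`replay` reproduces the mutated sequence byte-for-byte, and the
    exact length identity L' = L - #Del + sum(l_i) always holds.
    """
    if seq.L < 1:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    L = seq.L
    codes = seq.as_codes()

    u = rng.random(L)
    actions = np.full(L, STAY, dtype=np.int8)
    actions[u < params.ps + params.pd] = DEL
    actions[u < params.ps] = SUB

    sub_chars = np.zeros(L, dtype=np.uint8)
    sub_idx = np.flatnonzero(actions == SUB)
    if len(sub_idx):
        orig = _CODE_TO_IDX[codes[sub_idx]]
        repl = (orig + rng.integers(1, 4, size=len(sub_idx))) % 4
        sub_chars[sub_idx] = BASE_CODES[repl]

    insert_lengths = sample_insertion_lengths(params.d, L, rng)
    total_ins = int(insert_lengths.sum())
    ins_chars = BASE_CODES[rng.integers(0, 4, size=total_ins)]

    ann = MutationAnnotation(
        actions=actions,
        insert_lengths=insert_lengths,
        sub_chars=sub_chars,
        ins_chars=ins_chars,
    )
    mutated_codes = _assemble(codes, ann)
    mutated = SequenceRecord(name=seq.name + "_mut", seq=mutated_codes.tobytes().decode())
    return MutatedPair(original=seq, mutated=mutated, annotation=ann, params=params)


def replay(seq: SequenceRecord, annotation: MutationAnnotation) -> SequenceRecord:
    """Deterministically re-execute a recorded annotation on ``seq``."""
    if annotation.L != seq.L:
        raise ValueError(
            f"annotation length {annotation.L} != sequence length {seq.L}"
        )
    out = _assemble(seq.as_codes(), annotation)
    return SequenceRecord(name=seq.name + "_mut", seq=out.tobytes().decode())


def write_annotation(
    annotation: MutationAnnotation,
    path: str | Path,
    params: MutationParams | None = None,
    seed: int | None = None,
) -> None:
    """Write the annotation sidecar TSV.

    First line is a ``#``-prefixed JSON header with (L, params, seed);
    then a header row and one row per original position:
    ``pos  action  sub_char  ins_len  ins_seq`` (1-based positions, empty
    fields where not applicable).
    """
    meta = {"L": annotation.L}
    if params is not None:
        meta["params"] = {"ps": params.ps, "pd": params.pd, "d": params.d, "k": params.k}
    if seed is not None:
        meta["seed"] = seed

    L = annotation.L
    action_col = _pd.Series(annotation.actions).map(ACTION_NAMES)
    sub_col = np.where(
        annotation.actions == SUB,
        annotation.sub_chars.view("S1").astype("U1"),
        "",
    )
    li = annotation.insert_lengths
    ins_col = np.array([""] * L, dtype=object)
    nz = np.flatnonzero(li)
    if len(nz):
        ends = np.cumsum(li)
        for i in nz:
            ins_col[i] = annotation.ins_chars[ends[i] - li[i]: ends[i]].tobytes().decode()
    df = _pd.DataFrame(
        {
            "pos": np.arange(1, L + 1),
            "action": action_col,
            "sub_char": sub_col,
            "ins_len": li,
            "ins_seq": ins_col,
        }
    )
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(meta) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_annotation(path: str | Path) -> tuple[MutationAnnotation, dict]:
    """Read an annotation sidecar TSV written by :func:`write_annotation`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        meta = json.loads(first[1:])
        df = _pd.read_csv(fh, sep="\t", keep_default_na=False, dtype={"sub_char": str, "ins_seq": str})
    L = meta["L"]
    if len(df) != L:
        raise ValueError(f"{path}: expected {L} rows, found {len(df)}")
    actions = df["action"].map(ACTION_CODES).to_numpy(dtype=np.int8)
    insert_lengths = df["ins_len"].to_numpy(dtype=np.int64)
    sub_chars = np.zeros(L, dtype=np.uint8)
    sub_rows = np.flatnonzero(actions == SUB)
    if len(sub_rows):
        sub_chars[sub_rows] = [ord(c) for c in df["sub_char"].iloc[sub_rows]]
    ins_chars = np.frombuffer("".join(df["ins_seq"]).encode(), dtype=np.uint8).copy()
    ann = MutationAnnotation(
        actions=actions,
        insert_lengths=insert_lengths,
        sub_chars=sub_chars,
        ins_chars=ins_chars,
    )
    return ann, meta
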