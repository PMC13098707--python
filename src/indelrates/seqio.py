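"""FASTA I/O and synthetic sequence generation.

Sequences live on the 4-letter DNA alphabet {A, C, G, T}; every formula in
the rate-estimation machinery assumes exactly four equally-sized character
classes, so anything else (N, IUPAC ambiguity codes, gaps) is rejected by
default.  ``read_fasta`` can optionally drop such characters instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("indelrates")

ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)

#: byte codes for A, C, G, T used by the vectorised simulator
BASE_CODES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide string with its base-composition summary.

    Attributes
    ----------
    name:
        FASTA identifier.
    seq:
        Uppercase string over {A, C, G, T}.
    """

    name: str
    seq: str
    freqs: dict[str, int] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        counts = {b: self.seq.count(b) for b in ALPHABET}
        object.__setattr__(self, "freqs", counts)
        if sum(counts.values()) != len(self.seq):
            bad = next(
                (i, c) for i, c in enumerate(self.seq) if c not in _ALPHABET_SET
            )
            raise ValueError(
                f"record {self.name!r}: non-ACGT character {bad[1]!r} "
                f"at position {bad[0] + 1}"
            )

    @property
    def L(self) -> int:
        """Sequence length in nucleotides."""
        return len(self.seq)

    @property
    def fA(self) -> int:
        """Count of 'A' characters."""
        return self.freqs["A"]

    def count(self, base: str) -> int:
        """Count of a given base (one of A, C, G, T)."""
        return self.freqs[base]

    def as_codes(self) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (for vectorised work)."""
        return np.frombuffer(self.seq.encode(), dtype=np.uint8)


def read_fasta(path: str | Path, drop_non_acgt: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Entries are returned in file order, sequences uppercased.  Non-ACGT
    characters raise ``ValueError`` unless ``drop_non_acgt`` is set, in
    which case they are removed and the removal count is logged.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if drop_non_acgt:
            cleaned = "".join(c for c in seq if c in _ALPHABET_SET)
            if len(cleaned) != len(seq):
                logger.warning(
                    "record %s: dropped %d non-ACGT character(s)",
                    entry.id, len(seq) - len(cleaned),
                )
            seq = cleaned
        records.append(SequenceRecord(name=entry.id, seq=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records to ``path`` as standard FASTA with 60-column wrapping."""
    if not records:
        raise ValueError("cannot write an empty record list")
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def generate_sequence(
    L: int,
    a_fraction: float = 0.30,
    seed: int | np.random.Generator | None = None,
    name: str = "synthetic",
) -> SequenceRecord:
    """Generate an i.i.d. random sequence with a prescribed 'A' fraction.

    Characters are drawn independently with P(A) = ``a_fraction`` and the
    remaining mass split equally over C, G and T — the composition used in
    the synthetic-genome experiments (default 30% 'A').

    Parameters
    ----------
    L:
        Sequence length, at least 1.
    a_fraction:
        Probability of 'A' per position, in [0, 1).
    seed:
        Integer seed or a ``numpy.random.Generator``; same seed, same sequence.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if not (0.0 <= a_fraction < 1.0):
        raise ValueError(f"a_fraction must be in [0, 1), got {a_fraction}")
    rng = np.random.default_rng(seed)
    other = (1.0 - a_fraction) / 3.0
    idx = rng.choice(4, size=L, p=[a_fraction, other, other, other])
    seq = BASE_CODES[idx].tobytes().decode()
    return SequenceRecord(name=name, seq=seq)


def pooled_composition(records: Iterable[SequenceRecord]) -> tuple[int, dict[str, int]]:
    """Total length and summed base counts over several records."""
    total = 0
    counts = {b: 0 for b in ALPHABET}
    for r in records:
        total += r.L
        for b in ALPHABET:
            counts[b] += r.freqs[b]
    return total, counts
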