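import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelrates import (
    MutationParams,
    SequenceRecord,
    generate_sequence,
    mutate,
    replay,
)
from indelrates.mutation import (
    DEL,
    STAY,
    SUB,
    MutationAnnotation,
    delete_op,
    insert_op,
    read_annotation,
    sample_insertion_lengths,
    substitute_op,
    write_annotation,
)


def naive_apply(seq: str, ann: MutationAnnotation) -> str:
    """Literal execution of the channel's step sequence.

    Applies substitutions first, then insertions, then deletions, each at
    positions resolved through an explicitly maintained track map — the
    independent oracle for the vectorised single-pass assembly.
    """
    L = len(seq)
    s = list(seq)
    for i in range(L):
        if ann.actions[i] == SUB:
            s[i] = chr(ann.sub_chars[i])
    # track[i] = current 0-based index of original position i
    track = list(range(L))
    ends = np.cumsum(ann.insert_lengths)
    for i in range(L):
        li = int(ann.insert_lengths[i])
        if li == 0:
            continue
        piece = ann.ins_chars[ends[i] - li : ends[i]].tobytes().decode()
        pos = track[i]  # insert immediately before original position i+1
        s = s[:pos] + list(piece) + s[pos:]
        for j in range(L):
            if track[j] >= pos:
                track[j] += li
    for i in range(L):
        if ann.actions[i] == DEL:
            pos = track[i]
            del s[pos]
            for j in range(L):
                if track[j] > pos:
                    track[j] -= 1
    return "".join(s)


def make_annotation(actions, insert_lengths, sub_chars=None, ins_chars=b""):
    L = len(actions)
    subs = np.zeros(L, dtype=np.uint8)
    if sub_chars:
        for i, c in sub_chars.items():
            subs[i] = ord(c)
    return MutationAnnotation(
        actions=np.asarray(actions, dtype=np.int8),
        insert_lengths=np.asarray(insert_lengths, dtype=np.int64),
        sub_chars=subs,
        ins_chars=np.frombuffer(ins_chars, dtype=np.uint8).copy(),
    )


class TestParams:
    @pytest.mark.parametrize(
        "ps,pd,d",
        [(-0.1, 0, 0), (1.0, 0, 0), (0, 1.0, 0), (0.6, 0.5, 0), (0, 0, -1.0)],
    )
    def test_invalid(self, ps, pd, d):
        with pytest.raises(ValueError):
            MutationParams(ps=ps, pd=pd, d=d)

    def test_boundaries_allowed(self):
        MutationParams(ps=0.0, pd=0.0, d=0.0)
        MutationParams(ps=0.5, pd=0.49, d=10.0)


class TestPrimitiveOps:
    def test_substitute(self):
        assert substitute_op("ACGT", 2, "T") == "ATGT"

    def test_delete(self):
        assert delete_op("ACGT", 3) == "ACT"

    def test_insert_interior(self):
        assert insert_op("ACGT", 2, "TT") == "ATTCGT"

    def test_insert_prepend_branch(self):
        # i = 0 prepends; unreachable in the per-position process but part
        # of the operation's definition
        assert insert_op("ACGT", 0, "GG") == "GGACGT"


class TestMutate:
    def test_identity_channel(self):
        seq = generate_sequence(500, 0.3, seed=1)
        pair = mutate(seq, MutationParams(0, 0, 0), seed=2)
        assert pair.mutated.seq == seq.seq
        assert np.all(pair.annotation.actions == STAY)
        assert np.all(pair.annotation.insert_lengths == 0)

    def test_hand_traced_example(self):
        """Del at position 3 plus a 1-char insertion before position 2.

        Tracing the process by hand on S=ACGT: substitutions none; insert
        "T" between S1 and S2 -> ATCGT; delete original position 3 (now at
        index 4) -> ATCT.
        """
        ann = make_annotation(
            actions=[STAY, STAY, DEL, STAY],
            insert_lengths=[0, 1, 0, 0],
            ins_chars=b"T",
        )
        out = replay(SequenceRecord("s", "ACGT"), ann)
        assert out.seq == "ATCT"

    def test_single_substitution(self):
        ann = make_annotation([SUB], [0], sub_chars={0: "C"})
        assert replay(SequenceRecord("s", "A"), ann).seq == "C"

    def test_replay_reproduces_mutate(self):
        seq = generate_sequence(3000, 0.3, seed=3)
        pair = mutate(seq, MutationParams(0.1, 0.05, 0.2), seed=4)
        assert replay(seq, pair.annotation).seq == pair.mutated.seq

    def test_length_mismatch_errors(self):
        ann = make_annotation([STAY, STAY], [0, 0])
        with pytest.raises(ValueError, match="length"):
            replay(SequenceRecord("s", "ACGT"), ann)

    def test_length_identity_exact(self):
        seq = generate_sequence(10_000, 0.3, seed=5)
        for seed in range(5):
            pair = mutate(seq, MutationParams(0.05, 0.08, 0.3), seed=seed)
            ann = pair.annotation
            expected = seq.L - int(np.sum(ann.actions == DEL)) + int(
                ann.insert_lengths.sum()
            )
            assert pair.Lprime == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_assembly_matches_naive_track_oracle(self, data):
        L = data.draw(st.integers(1, 40))
        seq = "".join(data.draw(st.sampled_from("AC")) for _ in range(L))
        actions = [data.draw(st.sampled_from([STAY, SUB, DEL])) for _ in range(L)]
        lis = [data.draw(st.integers(0, 2)) for _ in range(L)]
        subs = {i: "G" for i in range(L) if actions[i] == SUB}
        ins = "".join("T" * l for l in lis).encode()
        ann = make_annotation(actions, lis, subs, ins)
        rec = SequenceRecord("s", seq)
        assert replay(rec, ann).seq == naive_apply(seq, ann)

    def test_exhaustive_small_annotations(self):
        """All annotations on a length-3 string over a 2-letter alphabet."""
        seq = "ACA"
        rec = SequenceRecord("s", seq)
        for actions in itertools.product([STAY, SUB, DEL], repeat=3):
            for lis in itertools.product([0, 1], repeat=3):
                subs = {i: "G" for i in range(3) if actions[i] == SUB}
                ins = ("T" * sum(lis)).encode()
                ann = make_annotation(list(actions), list(lis), subs, ins)
                assert replay(rec, ann).seq == naive_apply(seq, ann)

    def test_substitution_only_is_hamming_channel(self):
        seq = generate_sequence(100_000, 0.3, seed=6)
        ps = 0.07
        pair = mutate(seq, MutationParams(ps, 0, 0), seed=7)
        assert pair.Lprime == seq.L
        ham = sum(a != b for a, b in zip(seq.seq, pair.mutated.seq))
        se = np.sqrt(ps * (1 - ps) / seq.L)
        assert abs(ham / seq.L - ps) < 3 * se

    def test_moments_match_closed_forms(self):
        """Mean/variance of L' and mean of fA' match the channel's moments."""
        L, reps = 100_000, 20
        params = MutationParams(0.05, 0.05, 0.05)
        seq = generate_sequence(L, 0.30, seed=8)
        Lp = np.empty(reps)
        fAp = np.empty(reps)
        for r in range(reps):
            pair = mutate(seq, params, seed=100 + r)
            Lp[r], fAp[r] = pair.Lprime, pair.fAprime
        EL = L * (1 + params.d - params.pd)
        VarL = L * (params.d * (params.d + 1) + params.pd * (1 - params.pd))
        EfA = (
            seq.fA * 0.9 + params.ps * (L - seq.fA) / 3 + params.d * L / 4
        )
        assert abs(Lp.mean() - EL) < 3 * np.sqrt(VarL / reps)
        # sample variance of a near-Gaussian sum: SE ~ Var * sqrt(2/(reps-1))
        assert abs(Lp.var(ddof=1) - VarL) < 3 * VarL * np.sqrt(2 / (reps - 1))
        assert abs(fAp.mean() - EfA) < 3 * fAp.std(ddof=1) / np.sqrt(reps)


class TestInsertionLengths:
    def test_zero_mean_degenerates(self, rng):
        assert np.all(sample_insertion_lengths(0.0, 1000, rng) == 0)

    def test_mean_matches(self, rng):
        d = 0.05
        draws = sample_insertion_lengths(d, 1_000_000, rng)
        se = np.sqrt(d * (1 + d) / len(draws))
        assert abs(draws.mean() - d) < 3 * se

    def test_p_zero_at_mean_one(self, rng):
        draws = sample_insertion_lengths(1.0, 200_000, rng)
        p0 = np.mean(draws == 0)
        se = np.sqrt(0.5 * 0.5 / len(draws))
        assert abs(p0 - 0.5) < 3 * se

    def test_negative_mean_errors(self, rng):
        with pytest.raises(ValueError):
            sample_insertion_lengths(-0.1, 10, rng)


class TestAnnotationSidecar:
    def test_round_trip(self, tmp_path):
        seq = generate_sequence(300, 0.3, seed=9)
        params = MutationParams(0.1, 0.1, 0.3)
        pair = mutate(seq, params, seed=10)
        path = tmp_path / "ann.tsv"
        write_annotation(pair.annotation, path, params=params, seed=10)
        back, meta = read_annotation(path)
        assert meta["L"] == 300
        assert meta["params"]["ps"] == 0.1
        np.testing.assert_array_equal(back.actions, pair.annotation.actions)
        np.testing.assert_array_equal(
            back.insert_lengths, pair.annotation.insert_lengths
        )
        assert replay(seq, back).seq == pair.mutated.seq
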