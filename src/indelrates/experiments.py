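"""Reproducible parameter-recovery sweeps.

Each sweep varies one quantity (k, L, a_fraction, ps, pd or d) over a
grid, holding the others fixed, simulates ``replicates`` mutated genomes
per grid point, estimates the three rates (plus the substitution-only
baseline) and returns one tidy row per (grid value, replicate).  Counts
come either from the channel annotation (``exact``) or from the
unitig-alignment pipeline (``pipeline``).

Defaults are desk-scale (L = 1e5, 10 replicates); ``full=True`` in the
preset builders switches to the 1 Mbp / 20-replicate configurations.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import SingularSystemError, estimate_exact, estimate_smm
from .mutation import MutationParams, mutate
from .seqio import generate_sequence, write_fasta
from .unitigs import estimate_from_fasta

_VARIABLES = ("k", "L", "a_fraction", "ps", "pd", "d")

_DEFAULT_FIXED = {
    "L": 100_000,
    "a_fraction": 0.30,
    "ps": 0.05,
    "pd": 0.05,
    "d": 0.05,
    "k": 21,
}


@dataclass(frozen=True)
class SweepConfig:
    """One single-variable sweep: which knob varies, over what grid."""

    variable: str
    grid: tuple
    fixed: dict = field(default_factory=dict)
    replicates: int = 10
    seeds: tuple[int, ...] = ()
    count_mode: str = "exact"
    label: str = ""

    def __post_init__(self) -> None:
        if self.variable not in _VARIABLES:
            raise ValueError(f"variable must be one of {_VARIABLES}")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.count_mode not in ("exact", "pipeline"):
            raise ValueError("count_mode must be 'exact' or 'pipeline'")
        if not self.seeds:
            object.__setattr__(
                self, "seeds", tuple(range(1, self.replicates + 1))
            )
        if len(self.seeds) != self.replicates:
            raise ValueError("seeds length must equal replicates")

    def setting(self, value) -> dict:
        s = dict(_DEFAULT_FIXED)
        s.update(self.fixed)
        s[self.variable] = value
        return s


def _run_one(setting: dict, seed: int, count_mode: str) -> dict:
    params = MutationParams(
        ps=setting["ps"], pd=setting["pd"], d=setting["d"], k=int(setting["k"])
    )
    rng = np.random.default_rng(seed)
    seq = generate_sequence(
        int(setting["L"]), setting["a_fraction"], seed=rng, name=f"syn{seed}"
    )
    pair = mutate(seq, params, seed=rng)
    row = {
        "seed": seed,
        "L": seq.L,
        "a_fraction": setting["a_fraction"],
        "k": params.k,
        "ps_true": params.ps,
        "pd_true": params.pd,
        "d_true": params.d,
        "fA": seq.fA,
        "Lprime": pair.Lprime,
        "fAprime": pair.fAprime,
    }
    try:
        if count_mode == "exact":
            est, obs, counts = estimate_exact(pair)
            N, D, K = counts.N, counts.D, counts.K
            smm = estimate_smm(N, K, params.k) if N > 0 else np.nan
        else:
            with tempfile.TemporaryDirectory() as tmp:
                ref_fa = Path(tmp) / "ref.fa"
                mut_fa = Path(tmp) / "mut.fa"
                write_fasta([seq], ref_fa)
                write_fasta([pair.mutated], mut_fa)
                est, diag = estimate_from_fasta(ref_fa, mut_fa, k=params.k)
            N, D, K = diag["N_hat"], diag["D_hat"], diag["K"]
            smm = diag["smm_q_hat"] if diag["smm_q_hat"] is not None else np.nan
        row.update(
            N=N, D=D, K=K,
            ps_hat=est.ps_hat, pd_hat=est.pd_hat, d_hat=est.d_hat,
            smm_q_hat=smm, valid=est.valid, error="",
        )
    except SingularSystemError as exc:
        row.update(
            N=np.nan, D=np.nan, K=np.nan,
            ps_hat=np.nan, pd_hat=np.nan, d_hat=np.nan,
            smm_q_hat=np.nan, valid=False, error=str(exc),
        )
    return row


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run a sweep and return one row per (grid value, replicate).

    Grid values are validated against the channel's parameter space before
    any simulation starts; re-running with the same config (same seeds)
    reproduces the table exactly.
    """
    for value in config.grid:  # fail fast on invalid grids
        s = config.setting(value)
        MutationParams(ps=s["ps"], pd=s["pd"], d=s["d"], k=int(s["k"]))
        if not (0 <= s["a_fraction"] < 1):
            raise ValueError(f"invalid a_fraction {s['a_fraction']}")

    rows = []
    for value in config.grid:
        setting = config.setting(value)
        for seed in config.seeds:
            row = _run_one(setting, seed, config.count_mode)
            row["variable"] = config.variable
            row["value"] = value
            row["label"] = config.label or config.variable
            rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["label", "variable", "value", "seed"]
    return df[lead + [c for c in df.columns if c not in lead]]


def preset_sweeps(name: str, full: bool = False) -> list[SweepConfig]:
    """Named sweep presets mirroring the synthetic-genome experiments.

    ``fig1``: vary k at fixed rates; ``fig2``: vary L; ``fig3``: vary the
    'A' fraction through the unstable 25% point; ``fig4``: vary each rate
    with the other two fixed low (0.01) and high (0.05); ``fig6``:
    pipeline-counted substitution sweep for the substitution-only
    baseline comparison.
    """
    L = 1_000_000 if full else 100_000
    reps = 20 if full else 10
    if name == "fig1":
        return [
            SweepConfig(
                variable="k", grid=tuple(range(11, 42, 2)),
                fixed={"L": L}, replicates=reps, label="fig1",
            )
        ]
    if name == "fig2":
        return [
            SweepConfig(
                variable="L", grid=(10_000, 100_000, 1_000_000),
                replicates=reps if full else 10, label="fig2",
            )
        ]
    if name == "fig3":
        return [
            SweepConfig(
                variable="a_fraction",
                grid=tuple(round(0.21 + 0.01 * i, 2) for i in range(9)),
                fixed={"L": L}, replicates=reps, label="fig3",
            )
        ]
    if name == "fig4":
        rate_grid = (0.01, 0.02, 0.03, 0.04, 0.05)
        sweeps = []
        for varied in ("ps", "pd", "d"):
            for level, tag in ((0.01, "low"), (0.05, "high")):
                fixed = {"L": L, "ps": level, "pd": level, "d": level}
                fixed.pop(varied)
                fixed = {**fixed}
                sweeps.append(
                    SweepConfig(
                        variable=varied, grid=rate_grid,
                        fixed={**fixed}, replicates=reps,
                        label=f"fig4_{varied}_fixed_{tag}",
                    )
                )
        return sweeps
    if name == "fig6":
        return [
            SweepConfig(
                variable="ps", grid=(0.01, 0.03, 0.05),
                fixed={"L": 100_000, "pd": 0.05, "d": 0.05},
                replicates=5 if full else 3,
                count_mode="pipeline", label="fig6",
            )
        ]
    raise ValueError(f"unknown preset {name!r}")
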