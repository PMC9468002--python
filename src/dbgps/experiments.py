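"""Desk-scale in-silico comparisons: error sweeps of the assembler against
the CL-MA baseline, storage-density bookkeeping, and fixture generation.

A sweep corrupts one designed pool per replicate at each grid point, decodes
it with both methods, and reports the strand recovery rate S_r per
(method, grid value, replicate).  Copy-number sweeps reuse a single
``copies = max(grid)`` read set and take nested prefixes, so the reported
trend is a common-random-numbers comparison rather than independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import ma_baseline
from .channel import ChannelParams, ChannelResult, simulate_channel
from .dna import arr_to_seq
from .decoder import reconstruct_all
from .strand import BASES, StrandLayout, build_strand

ERROR_TYPES = ("breaks", "rearrangements", "indels", "substitutions", "mixed", "copies")


# ---------------------------------------------------------------------------
# Storage-density bookkeeping

def chunk_count(file_bytes: int, chunk_size: int = 35) -> int:
    """Number of outer-code chunks a file of this size occupies."""
    if file_bytes <= 0:
        raise ValueError("file size must be positive")
    return -(-file_bytes // chunk_size)


def strand_redundancy(n_strands: int, n_chunks: int) -> float:
    """Outer redundancy fraction implied by a pool size."""
    return n_strands / n_chunks - 1.0


def logical_density(file_bytes: int, n_strands: int, strand_len: int = 200) -> float:
    """Information bits stored per base-synthesis cycle, primers included."""
    return file_bytes * 8.0 / (n_strands * strand_len)


# ---------------------------------------------------------------------------
# Fixtures and pools

def make_fixture(kind: str, size: int, seed: int = 0) -> bytes:
    """Deterministic pseudo-random test file of a given byte size."""
    if size <= 0 or size > 10 * 2**20:
        raise ValueError("size must be in (0, 10 MiB]")
    rng = np.random.default_rng(seed)
    if kind == "random":
        return rng.integers(0, 256, size=size, dtype=np.uint8).tobytes()
    if kind == "text":
        words = [b"the", b"quick", b"brown", b"fox", b"jumps", b"over", b"lazy", b"dogs"]
        picks = rng.integers(0, len(words), size=size)
        out = b" ".join(words[i] for i in picks)
        return out[:size] if len(out) >= size else out + b" " * (size - len(out))
    if kind == "image-like":
        steps = rng.integers(-4, 5, size=size).astype(np.int64)
        return (np.cumsum(steps) % 256).astype(np.uint8).tobytes()
    raise ValueError(f"unknown fixture kind {kind!r}")


def random_pool(n_strands: int, layout: StrandLayout | None = None, seed: int = 0) -> list:
    """Designed strands with uniform random payloads (for S_r sweeps)."""
    layout = layout or StrandLayout()
    rng = np.random.default_rng(seed)
    pool = []
    for m in range(n_strands):
        payload = arr_to_seq(rng.integers(0, 4, size=layout.payload_len, dtype=np.uint8))
        pool.append(build_strand(m, payload, layout))
    return pool


# ---------------------------------------------------------------------------
# One-shot comparison of the two decoders on a corrupted pool

def recovery_rates(
    pool: Sequence,
    result: ChannelResult,
    k: int,
    layout: StrandLayout | None = None,
    cutoff=2,
    copies: int | None = None,
    methods: Sequence[str] = ("dbgps", "ma"),
) -> dict:
    """Exact-recovery S_r per method for one corrupted read set."""
    layout = layout or StrandLayout()
    truth = {rec.m: rec.payload for rec in pool}
    indices = sorted(truth)
    out = {}
    if "dbgps" in methods:
        rep = reconstruct_all(
            result.reads, indices=indices, k=k, layout=layout,
            cutoff=cutoff, copies=copies,
        )
        good = sum(1 for m, p in rep.payloads.items() if truth.get(m) == p)
        out["dbgps"] = good / len(indices)
    if "ma" in methods:
        rec = ma_baseline(result.read_seqs, layout, indices)
        good = sum(1 for m, p in rec.items() if truth.get(m) == p)
        out["ma"] = good / len(indices)
    return out


# ---------------------------------------------------------------------------
# Sweeps

@dataclass
class SweepConfig:
    """Grid specification for one error sweep.

    ``error_type`` selects the channel knob the grid drives: per-base rates
    for substitutions/indels/mixed, per-molecule expected break counts for
    breaks, fragment-join fractions for rearrangements, or the copy number
    itself (at 3% mixed point errors) for ``copies``.
    """

    error_type: str
    grid: Sequence[float]
    copies: int = 20
    n_strands: int = 200
    replicates: int = 3
    cutoff: int = 2
    seed: int = 0
    point_rate: float = 0.03   # fixed total point-error rate for copies sweeps
    min_breaks: int = 0
    methods: Sequence[str] = ("dbgps", "ma")

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"error_type must be one of {ERROR_TYPES}")
        if len(self.grid) == 0:
            raise ValueError("empty sweep grid")


@dataclass
class SweepResult:
    config: SweepConfig
    table: pd.DataFrame

    def mean_s_r(self) -> pd.DataFrame:
        """Mean and SD of S_r per (method, grid value) across replicates."""
        g = self.table.groupby(["method", "value"])["s_r"]
        return g.agg(["mean", "std"]).reset_index()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for method, df in self.mean_s_r().groupby("method"):
            ax.errorbar(df["value"], df["mean"], yerr=df["std"], marker="o",
                        capsize=3, label=method.upper())
        ax.set_xlabel(self.config.error_type)
        ax.set_ylabel("strand recovery rate $S_r$")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _params_for(cfg: SweepConfig, value: float, seed: int) -> ChannelParams:
    if cfg.error_type == "breaks":
        return ChannelParams(copies=cfg.copies, break_rate=value,
                             min_breaks=cfg.min_breaks, seed=seed)
    if cfg.error_type == "rearrangements":
        return ChannelParams(copies=cfg.copies, break_rate=1.0,
                             min_breaks=cfg.min_breaks, rearr_rate=value, seed=seed)
    if cfg.error_type == "indels":
        return ChannelParams(copies=cfg.copies, ins_rate=value / 2,
                             del_rate=value / 2, seed=seed)
    if cfg.error_type == "substitutions":
        return ChannelParams(copies=cfg.copies, sub_rate=value, seed=seed)
    if cfg.error_type == "mixed":
        return ChannelParams.mixed(value, copies=cfg.copies, seed=seed)
    if cfg.error_type == "copies":
        return ChannelParams(copies=int(value), sub_rate=cfg.point_rate / 2,
                             ins_rate=cfg.point_rate / 4,
                             del_rate=cfg.point_rate / 4, seed=seed)
    raise AssertionError(cfg.error_type)


def run_error_sweep(cfg: SweepConfig, k: int = 17, layout: StrandLayout | None = None) -> SweepResult:
    """Encode → channel → both decoders across the grid; deterministic per seed."""
    layout = layout or StrandLayout()
    rows = []
    for rep in range(cfg.replicates):
        pool_seed = hash((cfg.seed, rep)) % (2**31)
        pool = random_pool(cfg.n_strands, layout, seed=pool_seed)
        if cfg.error_type == "copies":
            # one read set at max copies; nested prefixes per grid value
            cmax = int(max(cfg.grid))
            params = _params_for(cfg, cmax, seed=pool_seed + 1)
            full = simulate_channel(pool, params)
            for value in cfg.grid:
                sub = ChannelResult(reads_by_copy=full.reads_by_copy[: int(value)])
                rates = recovery_rates(pool, sub, k, layout, cutoff=cfg.cutoff,
                                       copies=int(value), methods=cfg.methods)
                for method, s_r in rates.items():
                    rows.append((cfg.error_type, value, rep, method, s_r))
        else:
            for value in cfg.grid:
                params = _params_for(cfg, value, seed=pool_seed + 1)
                res = simulate_channel(pool, params)
                rates = recovery_rates(pool, res, k, layout, cutoff=cfg.cutoff,
                                       copies=cfg.copies, methods=cfg.methods)
                for method, s_r in rates.items():
                    rows.append((cfg.error_type, value, rep, method, s_r))
    table = pd.DataFrame(rows, columns=["error_type", "value", "replicate", "method", "s_r"])
    return SweepResult(config=cfg, table=table)
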