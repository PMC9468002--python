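"""Simulated DNA data-storage channel.

Each designed strand is amplified into ``copies`` molecules, and each
molecule is corrupted in the order the physical channel acts: strand breaks
(hydrolysis/degradation), then rearrangements (breakage–rejoining into
chimeras, as unspecific PCR produces), then per-base point errors
(substitutions and indels accrued in amplification and sequencing).  Reads
are finally emitted in random orientation, as a sequencer would.

Break counts are Poisson per molecule with uniform breakpoints;
rearrangements pair a chosen fraction of the per-copy fragment pool into
chimeric reads (total base count is conserved); point errors are independent
per position, substitutions drawing a different base uniformly and
insertions adding a uniform base after the position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .dna import arr_to_seq, seq_to_arr


@dataclass
class ChannelParams:
    """Copy number and corruption rates for one simulated channel run.

    ``break_rate`` is the expected number of breaks per molecule (Poisson);
    ``min_breaks`` optionally forces at least that many breaks per molecule
    (used for guaranteed-fragmentation stress runs).  ``rearr_rate`` is the
    fraction of fragments joined pairwise into chimeras.  ``revcomp=False``
    keeps every read in the designed orientation (useful in unit tests).
    """

    copies: int = 10
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    break_rate: float = 0.0
    min_breaks: int = 0
    rearr_rate: float = 0.0
    revcomp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate, self.rearr_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.break_rate < 0:
            raise ValueError("break_rate must be >= 0")

    @classmethod
    def mixed(
        cls,
        total_rate: float,
        copies: int,
        strand_len: int = 200,
        weights: Sequence[float] = (1.0, 1.0, 2.0, 1.0, 1.0),
        seed: int = 0,
        revcomp: bool = True,
    ) -> "ChannelParams":
        """Split a total per-base error budget across the five error types.

        ``weights`` are (breaks : rearrangements : substitutions : insertions
        : deletions).  Substitution/insertion/deletion weights become per-base
        rates; break and rearrangement weights become per-molecule expected
        event counts drawn from the same budget of ``total_rate × strand_len``
        events per molecule, with each rearrangement event consuming two
        fragments.
        """
        w = np.asarray(weights, dtype=float)
        if w.min() < 0 or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
        share = w / w.sum()
        budget = total_rate * strand_len          # expected events per molecule
        break_rate = budget * share[0]
        rearr_events = budget * share[1]
        exp_frags = 1.0 + break_rate
        rearr_rate = min(1.0, 2.0 * rearr_events / exp_frags)
        return cls(
            copies=copies,
            sub_rate=total_rate * share[2],
            ins_rate=total_rate * share[3],
            del_rate=total_rate * share[4],
            break_rate=break_rate,
            rearr_rate=rearr_rate,
            seed=seed,
            revcomp=revcomp,
        )


def apply_point_errors(
    arr: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent per-position substitutions, insertions and deletions.

    A substituted base is drawn uniformly from the three alternatives; an
    insertion places a uniform base after the position; events combine
    independently, so the expected edit count is len × (sub+ins+del).
    """
    L = arr.size
    if L == 0 or (sub_rate == 0 and ins_rate == 0 and del_rate == 0):
        return arr
    u = rng.random((3, L))
    sub = u[0] < sub_rate
    dele = u[1] < del_rate
    ins = u[2] < ins_rate
    vals = arr.copy()
    if sub.any():
        vals[sub] = (vals[sub] + rng.integers(1, 4, size=int(sub.sum()), dtype=np.uint8)) % 4
    reps = (~dele).astype(np.intp) + ins.astype(np.intp)
    out = np.repeat(vals, reps)
    if ins.any():
        ends = np.cumsum(reps)
        out[ends[ins] - 1] = rng.integers(0, 4, size=int(ins.sum()), dtype=np.uint8)
    return out


def apply_breaks(
    arr: np.ndarray,
    break_rate: float,
    rng: np.random.Generator,
    min_breaks: int = 0,
) -> list:
    """Fragment one molecule at Poisson-many uniform breakpoints.

    The ordered fragments concatenate back to the input; fragments shorter
    than any k are still emitted (k-mer counting skips them naturally).
    """
    if break_rate < 0:
        raise ValueError("break_rate must be >= 0")
    n = max(min_breaks, int(rng.poisson(break_rate)))
    n = min(n, arr.size - 1) if arr.size > 1 else 0
    if n <= 0:
        return [arr]
    cuts = np.sort(rng.choice(np.arange(1, arr.size), size=n, replace=False))
    return np.split(arr, cuts)


def apply_rearrangements(
    fragments: list,
    rearr_rate: float,
    rng: np.random.Generator,
    parents: Sequence[int] | None = None,
) -> list:
    """Join a fraction of the pooled fragments pairwise into chimeric reads.

    Pairs are drawn uniformly from the pool (across different parent strands
    when possible); unpaired fragments pass through; the total base count is
    conserved because joining is concatenation only.
    """
    if not 0.0 <= rearr_rate <= 1.0:
        raise ValueError("rearr_rate must lie in [0, 1]")
    nfrag = len(fragments)
    n_join = int(round(rearr_rate * nfrag))
    n_join -= n_join % 2
    if n_join < 2:
        return list(fragments)
    chosen = rng.choice(nfrag, size=n_join, replace=False)
    if parents is not None:
        # pair fragments from different parents when possible: sorting the
        # chosen set by parent and folding it in half avoids same-parent pairs
        # unless one parent dominates the draw
        order = np.argsort(np.asarray(parents)[chosen], kind="stable")
        chosen = chosen[order]
        half = n_join // 2
        pairs = list(zip(chosen[:half], chosen[half:]))
    else:
        pairs = list(zip(chosen[0::2], chosen[1::2]))
    joined = set()
    out = []
    for a, b in pairs:
        out.append(np.concatenate([fragments[a], fragments[b]]))
        joined.update((int(a), int(b)))
    out.extend(f for i, f in enumerate(fragments) if i not in joined)
    return out


@dataclass
class ChannelResult:
    """Reads grouped by copy round, plus a log of realized event counts."""

    reads_by_copy: list
    log: dict = field(default_factory=dict)

    @property
    def reads(self) -> list:
        return [r for grp in self.reads_by_copy for r in grp]

    @property
    def read_seqs(self) -> list:
        return [arr_to_seq(r) for r in self.reads]


def simulate_channel(pool, params: ChannelParams) -> ChannelResult:
    """Corrupt every strand of a designed pool into a read set.

    ``pool`` is a sequence of strand sequences (strings, uint8 arrays, or
    objects with a ``sequence`` attribute).  For each of ``params.copies``
    rounds every strand is broken, the round's fragment pool is rearranged,
    and point errors plus random orientation are applied per read.  Fully
    deterministic given ``params.seed``.
    """
    seqs = []
    for p in pool:
        if hasattr(p, "sequence"):
            p = p.sequence
        seqs.append(seq_to_arr(p) if isinstance(p, str) else np.asarray(p, dtype=np.uint8))

    root = np.random.SeedSequence(params.seed)
    copy_seeds = root.spawn(params.copies)
    reads_by_copy = []
    n_breaks = n_chimeras = n_bases_in = n_bases_out = 0
    for cs in copy_seeds:
        rng = np.random.default_rng(cs)
        frags: list = []
        parents: list = []
        for si, arr in enumerate(seqs):
            n_bases_in += arr.size
            pieces = apply_breaks(arr, params.break_rate, rng, params.min_breaks)
            n_breaks += len(pieces) - 1
            frags.extend(pieces)
            parents.extend([si] * len(pieces))
        before = len(frags)
        frags = apply_rearrangements(frags, params.rearr_rate, rng, parents)
        n_chimeras += before - len(frags)
        reads = []
        for f in frags:
            r = apply_point_errors(f, params.sub_rate, params.ins_rate, params.del_rate, rng)
            if params.revcomp and rng.random() < 0.5:
                r = (3 - r)[::-1]
            n_bases_out += r.size
            reads.append(r)
        reads_by_copy.append(reads)
    log = {
        "params": asdict(params),
        "n_strands": len(seqs),
        "n_reads": sum(len(g) for g in reads_by_copy),
        "n_breaks": int(n_breaks),
        "n_chimeric_joins": int(n_chimeras),
        "bases_in": int(n_bases_in),
        "bases_out": int(n_bases_out),
    }
    return ChannelResult(reads_by_copy=reads_by_copy, log=log)
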