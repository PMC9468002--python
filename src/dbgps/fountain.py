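"""Outer erasure code: Luby-transform droplets over fixed-size chunks.

The file is split into 35-byte chunks (140 bases at 2 bits/base — one strand
payload).  Each droplet XORs a pseudo-random subset of chunks; the subset is
fully reproducible from the droplet seed, which doubles as the strand index
``m`` stored in DNA.  Candidate strands whose cores would share a (k−1)-mer
with an already accepted strand ("entangled" strands) are rejected at design
time, because a repeated (k−1)-mer is exactly a fork in the decoder's de
Bruijn graph.  Decoding is classic peeling (belief propagation) plus an
optional Gaussian-elimination inactivation step on the residual system, which
recovers the file from a near-optimal number of droplets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dna import kmer_codes, revcomp_arr, seq_to_arr
from .strand import StrandLayout, StrandRecord, build_strand, bytes_to_bases

CHUNK_SIZE = 35  # bytes; 140 payload bases at 2 bits per base

# Full-period LCG over the 32-bit index space (Numerical Recipes constants).
# Probing seeds in this order instead of 0,1,2,… spreads strand indexes over
# the whole space, so the index bases carry full entropy: consecutive small
# integers would give near-all-A indexes whose (k−1)-mers crowd a tiny code
# space and inflate entanglement rejections at every scale.
_PROBE_A, _PROBE_C, _PROBE_MOD = 1664525, 1013904223, 2**32


def probe_seeds(start: int = 0):
    """Deterministic full-period probe order over the 32-bit seed space."""
    x = start
    while True:
        yield x
        x = (_PROBE_A * x + _PROBE_C) % _PROBE_MOD


class CapacityError(RuntimeError):
    """The seed space cannot supply enough entanglement-free strands."""


class PartialDecodeError(RuntimeError):
    """Not enough droplets to resolve every chunk."""

    def __init__(self, missing: Sequence[int]):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} chunks unresolved "
            f"(first few: {self.missing[:10]})"
        )


# ---------------------------------------------------------------------------
# Degree distribution

class RobustSoliton:
    """Robust soliton degree distribution over 1..K.

    Ideal soliton rho(1)=1/K, rho(d)=1/(d(d-1)); the robust correction adds
    tau(d)=R/(dK) for d < d*, tau(d*)=R ln(R/delta)/K with R = c ln(K/delta)
    sqrt(K) and d* = round(K/R), then normalises.  Defaults follow common DNA
    storage practice (c=0.025, delta=0.001).
    """

    def __init__(self, K: int, c: float = 0.025, delta: float = 0.001):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K, self.c, self.delta = K, c, delta
        rho = np.zeros(K + 1)
        rho[1] = 1.0 / K
        d = np.arange(2, K + 1)
        rho[2:] = 1.0 / (d * (d - 1.0))
        tau = np.zeros(K + 1)
        if K > 1:
            R = c * math.log(K / delta) * math.sqrt(K)
            d_star = min(K, max(1, round(K / R))) if R > 0 else K
            if R > 0:
                dd = np.arange(1, d_star)
                tau[1:d_star] = R / (dd * K)
                tau[d_star] = R * math.log(R / delta) / K if R > delta else 0.0
        pmf = rho + tau
        self.pmf = pmf / pmf.sum()          # index 0 unused (prob 0)
        self.cdf = np.cumsum(self.pmf)

    def sample(self, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self.cdf, rng.random(), side="right"))


# ---------------------------------------------------------------------------
# Droplets

@dataclass(frozen=True)
class Droplet:
    seed: int
    degree: int
    chunk_ids: tuple
    payload: bytes  # CHUNK_SIZE bytes, XOR of the selected chunks


def _droplet_ids(seed: int, n_chunks: int, soliton: RobustSoliton) -> tuple:
    """Degree and chunk subset for one seed (deterministic 64-bit PRNG)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    d = soliton.sample(rng)
    if d * d >= n_chunks:
        ids = rng.permutation(n_chunks)[:d]
    else:
        while True:
            ids = rng.integers(0, n_chunks, size=d)
            if np.unique(ids).size == d:
                break
    return tuple(int(i) for i in ids)


def chunk_file(data: bytes, chunk_size: int = CHUNK_SIZE) -> np.ndarray:
    """Split bytes into fixed-size chunks, one row per chunk.

    The tail of the last chunk is padded with a fixed pseudo-random byte
    stream rather than zeros: a zero tail maps to a homopolymer run whose
    repeated (k−1)-mers the entanglement filter would reject outright.  The
    pad is deterministic, and the decoder discards it by truncating to the
    manifest's true byte length.
    """
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    if len(data) == 0:
        raise ValueError("cannot encode an empty input")
    n = -(-len(data) // chunk_size)
    buf = np.empty(n * chunk_size, dtype=np.uint8)
    buf[: len(data)] = np.frombuffer(data, dtype=np.uint8)
    pad = n * chunk_size - len(data)
    if pad:
        buf[len(data) :] = np.random.Generator(np.random.PCG64(0x0DBA)).integers(
            0, 256, size=pad, dtype=np.uint8
        )
    return buf.reshape(n, chunk_size)


def droplet_from_seed(seed: int, chunks: np.ndarray, soliton: RobustSoliton | None = None) -> Droplet:
    """Build the droplet a given seed defines over a chunk matrix."""
    n_chunks = chunks.shape[0]
    soliton = soliton or RobustSoliton(n_chunks)
    ids = _droplet_ids(seed, n_chunks, soliton)
    payload = np.bitwise_xor.reduce(chunks[list(ids)], axis=0)
    return Droplet(seed=seed, degree=len(ids), chunk_ids=ids, payload=payload.tobytes())


# ---------------------------------------------------------------------------
# Pool design with the entangled-strand filter

@dataclass
class PoolDesign:
    chunk_size: int
    n_chunks: int
    redundancy: float
    k: int
    strands: list = field(default_factory=list)       # list[StrandRecord]
    seeds: list = field(default_factory=list)         # accepted seeds, in order
    rejected_seeds: list = field(default_factory=list)
    layout: StrandLayout = field(default_factory=StrandLayout)
    soliton_c: float = 0.025
    soliton_delta: float = 0.001


def generate_pool(
    chunks: np.ndarray,
    redundancy: float,
    k: int,
    layout: StrandLayout | None = None,
    soliton_c: float = 0.025,
    soliton_delta: float = 0.001,
) -> PoolDesign:
    """Probe the seed space in a fixed order, accepting entanglement-free strands.

    A candidate is rejected when any (k−1)-mer of its core — in either
    orientation — already occurs in an accepted core (or twice within its own
    core): repeated (k−1)-mers are forks in the decode-time de Bruijn graph.
    The strand index stored in DNA is the accepted seed itself, so the decoder
    regenerates every droplet without a side table.
    """
    if redundancy < 0:
        raise ValueError("redundancy must be >= 0")
    layout = layout or StrandLayout()
    n_chunks = chunks.shape[0]
    target = round(n_chunks * (1 + redundancy))
    soliton = RobustSoliton(n_chunks, soliton_c, soliton_delta)
    design = PoolDesign(
        chunk_size=chunks.shape[1], n_chunks=n_chunks, redundancy=redundancy,
        k=k, layout=layout, soliton_c=soliton_c, soliton_delta=soliton_delta,
    )
    used: set[int] = set()
    km1 = k - 1
    max_probes = min(_PROBE_MOD, 64 * target + 10_000)
    probes = 0
    for seed in probe_seeds():
        if len(design.seeds) >= target:
            break
        if probes >= max_probes:
            raise CapacityError(
                f"seed space exhausted after {len(design.seeds)} strands; "
                f"data volume too large for k={k}"
            )
        probes += 1
        drop = droplet_from_seed(seed, chunks, soliton)
        rec = build_strand(seed, bytes_to_bases(drop.payload), layout)
        core_arr = seq_to_arr(rec.core)
        fwd = kmer_codes(core_arr, km1)
        rc = kmer_codes(revcomp_arr(core_arr), km1)
        fwd_set = set(fwd.tolist())
        cand = fwd_set | set(rc.tolist())
        entangled = (
            len(fwd_set) < fwd.size            # repeated (k-1)-mer within core
            or len(cand) < 2 * fwd.size        # own forward/reverse overlap
            or not cand.isdisjoint(used)
        )
        if entangled:
            design.rejected_seeds.append(seed)
        else:
            used.update(fwd_set)
            design.seeds.append(seed)
            design.strands.append(rec)
    return design


# ---------------------------------------------------------------------------
# Manifest: everything the decoder needs besides the reads

@dataclass
class Manifest:
    file_len: int
    chunk_size: int
    n_chunks: int
    k: int
    n_probed: int              # probe-order prefix length that was consumed
    rejected_seeds: list
    layout: StrandLayout = field(default_factory=StrandLayout)
    soliton_c: float = 0.025
    soliton_delta: float = 0.001

    @property
    def seeds(self) -> list:
        """Accepted strand indexes, regenerated from the probe order."""
        skip = set(self.rejected_seeds)
        out = []
        for i, s in enumerate(probe_seeds()):
            if i >= self.n_probed:
                break
            if s not in skip:
                out.append(s)
        return out

    @classmethod
    def from_pool(cls, design: PoolDesign, file_len: int) -> "Manifest":
        n_probed = len(design.seeds) + len(design.rejected_seeds)
        return cls(
            file_len=file_len, chunk_size=design.chunk_size,
            n_chunks=design.n_chunks, k=design.k,
            n_probed=n_probed, rejected_seeds=list(design.rejected_seeds),
            layout=design.layout,
            soliton_c=design.soliton_c, soliton_delta=design.soliton_delta,
        )

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["layout"] = self.layout.to_dict()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        d = json.loads(text)
        d["layout"] = StrandLayout.from_dict(d["layout"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Manifest":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Decoding: peeling + optional inactivation (Gaussian elimination)

def decode_pool(
    recovered: Iterable[tuple[int, bytes]],
    n_chunks: int,
    chunk_size: int = CHUNK_SIZE,
    soliton_c: float = 0.025,
    soliton_delta: float = 0.001,
    solve: str = "inactivation",
) -> bytes:
    """Rebuild the chunk stream from recovered (seed, payload) pairs.

    ``solve="peel"`` runs pure belief propagation; the default additionally
    solves the post-peeling residual by GF(2) Gaussian elimination, which
    succeeds whenever the received droplets span all chunks.  Raises
    :class:`PartialDecodeError` (listing unresolved chunk ids) otherwise.
    """
    soliton = RobustSoliton(n_chunks, soliton_c, soliton_delta)
    chunks = np.zeros((n_chunks, chunk_size), dtype=np.uint8)
    known = np.zeros(n_chunks, dtype=bool)

    payloads: list[np.ndarray] = []
    unknowns: list[set] = []
    by_chunk: dict[int, list[int]] = {}
    ready: list[int] = []

    for seed, payload in recovered:
        ids = _droplet_ids(seed, n_chunks, soliton)
        arr = np.frombuffer(bytes(payload), dtype=np.uint8).copy()
        if arr.size != chunk_size:
            raise ValueError(f"droplet payload must be {chunk_size} bytes")
        di = len(payloads)
        payloads.append(arr)
        unknowns.append(set(ids))
        for cid in ids:
            by_chunk.setdefault(cid, []).append(di)
        if len(ids) == 1:
            ready.append(di)

    def resolve(cid: int, value: np.ndarray) -> None:
        chunks[cid] = value
        known[cid] = True
        for di in by_chunk.get(cid, ()):
            u = unknowns[di]
            if cid in u:
                payloads[di] ^= value
                u.discard(cid)
                if len(u) == 1:
                    ready.append(di)

    while ready:
        di = ready.pop()
        u = unknowns[di]
        if not u:
            continue
        cid = next(iter(u))
        u.clear()
        if not known[cid]:
            resolve(cid, payloads[di])

    if not known.all() and solve == "inactivation":
        _ge_solve(payloads, unknowns, chunks, known, resolve)

    if not known.all():
        raise PartialDecodeError(np.flatnonzero(~known).tolist())
    return chunks.tobytes()


def _ge_solve(payloads, unknowns, chunks, known, resolve) -> None:
    """GF(2) elimination over the chunks peeling could not reach."""
    missing = np.flatnonzero(~known)
    col = {int(c): i for i, c in enumerate(missing)}
    rows: list[tuple[int, np.ndarray]] = []
    for di, u in enumerate(unknowns):
        if u:
            mask = 0
            for cid in u:
                mask |= 1 << col[cid]
            rows.append((mask, payloads[di].copy()))
    pivots: dict[int, tuple[int, np.ndarray]] = {}
    for mask, pay in rows:
        while mask:
            p = mask.bit_length() - 1
            if p in pivots:
                pm, pp = pivots[p]
                mask ^= pm
                pay = pay ^ pp
            else:
                pivots[p] = (mask, pay)
                break
    # back-substitute in decreasing pivot order
    solved: dict[int, np.ndarray] = {}
    for p in sorted(pivots, reverse=False):
        mask, pay = pivots[p]
        rest = mask & ~(1 << p)
        ok = True
        while rest:
            q = rest.bit_length() - 1
            if q not in solved:
                ok = False
                break
            pay = pay ^ solved[q]
            rest &= ~(1 << q)
        if ok:
            solved[p] = pay
    for p, pay in solved.items():
        cid = int(missing[p])
        if not known[cid]:
            resolve(cid, pay)


def assemble_file(chunk_bytes: bytes, file_len: int) -> bytes:
    """Truncate the decoded chunk stream to the manifest's true byte length."""
    return chunk_bytes[:file_len]
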