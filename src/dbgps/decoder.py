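"""De novo strand reconstruction: k-mer counting, coverage filtering, and
index-seeded greedy path search with CRC path selection.

Stage 1 builds the de Bruijn graph implicitly as a k-mer count table —
connections are never materialised; the (k−1)-base prefix of a k-mer
positions a node and its terminal base extends a path.  Low-coverage k-mers
are excluded as noise: individual errors are rare events, so erroneous
k-mers sit far below the copy-number coverage of correct ones.

Stage 2 reconstructs each designed strand independently.  The strand index
``m`` is re-encoded into bases to seed the search; live paths are extended by
every base whose k-mer is present in the filtered table; paths reaching the
designed core length become candidates; and the embedded CRC selects the
single correct candidate — zero or multiple CRC-passing paths are failures,
never guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dna import arr_to_seq, code_of, kmer_codes, seq_to_arr
from .strand import (
    StrandLayout,
    bases_to_bytes,
    check_strand,
    encode_index,
    strip_block_checks,
    verify_block,
)

K_MIN, K_MAX = 17, 33

STATUS_RECOVERED = "recovered"
STATUS_DEAD_END = "dead-end"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_CRC = "no-CRC-pass"


class CapacityError(RuntimeError):
    """No admissible k-mer size can index this many strands."""


class DecodeAbort(RuntimeError):
    """The k-mer table is unusable (e.g. empty after coverage filtering)."""


class FrontierOverflow(RuntimeError):
    """Greedy search exceeded the live-path cap (too many graph forks)."""


# ---------------------------------------------------------------------------
# k selection

def choose_k(n_strands: int, core_len: int = 164) -> int:
    """Smallest odd k in [17, 33] keeping expected (k−1)-mer collisions low.

    Each strand core contributes ``core_len − k + 2`` (k−1)-mers; a birthday
    bound on ``n_total`` draws from the 4^(k−1) possibilities must stay below
    1% of the strand count, since every collision is a graph fork the
    design-time filter would otherwise have to reject.  Odd k avoids
    palindromic self-reverse-complement k-mers.
    """
    if n_strands < 1:
        raise ValueError("n_strands must be >= 1")
    for k in range(K_MIN, K_MAX + 1, 2):
        n_total = n_strands * (core_len - k + 2)
        expected = n_total * (n_total - 1) / (2.0 * 4 ** (k - 1))
        if expected < 0.01 * n_strands:
            return k
    raise CapacityError(f"no k in [{K_MIN},{K_MAX}] can index {n_strands} strands")


# ---------------------------------------------------------------------------
# Stage 1: counting and coverage filtering

@dataclass
class KmerTable:
    """Directed k-mer counts (both read orientations, stored separately)."""

    k: int
    codes: np.ndarray      # sorted uint64 packed k-mers
    counts: np.ndarray     # occurrence of each code
    cutoff: int = 1
    _filtered: np.ndarray | None = field(default=None, repr=False)
    _members: set | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return int(np.count_nonzero(self.counts >= self.cutoff))

    @property
    def filtered_codes(self) -> np.ndarray:
        if self._filtered is None:
            self._filtered = self.codes[self.counts >= self.cutoff]
        return self._filtered

    @property
    def members(self) -> set:
        if self._members is None:
            self._members = set(self.filtered_codes.tolist())
        return self._members

    def with_cutoff(self, cutoff: int) -> "KmerTable":
        return KmerTable(k=self.k, codes=self.codes, counts=self.counts, cutoff=cutoff)

    def __contains__(self, code: int) -> bool:
        return code in self.members

    def count_of(self, kmer: str) -> int:
        code = np.uint64(code_of(kmer, self.k))
        i = int(np.searchsorted(self.codes, code))
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return 0


def _trim_read(arr: np.ndarray, heads, tails, max_mm: int = 2) -> np.ndarray:
    """Strip a primer landing site from either end (exact or ≤2 mismatches)."""
    for p in heads:
        n = p.size
        if arr.size >= n and int(np.count_nonzero(arr[:n] != p)) <= max_mm:
            arr = arr[n:]
            break
    for p in tails:
        n = p.size
        if arr.size >= n and int(np.count_nonzero(arr[-n:] != p)) <= max_mm:
            arr = arr[:-n]
            break
    return arr


def count_kmers(
    reads: Iterable,
    k: int,
    layout: StrandLayout | None = None,
    trim_primers: bool = True,
) -> KmerTable:
    """Count every length-k window of each read and of its reverse complement.

    Reads may be strings or uint8 base arrays.  Reads shorter than k
    contribute nothing.  Orientations are kept separate (directed k-mers)
    because path search is directional; counting a read together with its
    reverse complement guarantees the forward strand path is represented
    whichever way the sequencer emitted the molecule.  Primer landing sites
    are trimmed when found intact (exact or ≤2 mismatches) at a read end.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 32:
        raise ValueError("k-mers are packed 2 bits/base into 64-bit codes (k <= 32)")
    layout = layout or StrandLayout()
    heads = tails = ()
    if trim_primers:
        from .dna import revcomp_arr as _rc

        p5 = seq_to_arr(layout.primer5)
        p3 = seq_to_arr(layout.primer3)
        heads = (p5, _rc(p3))
        tails = (p3, _rc(p5))

    arrs = []
    for r in reads:
        arr = seq_to_arr(r) if isinstance(r, str) else np.asarray(r, dtype=np.uint8)
        if trim_primers:
            arr = _trim_read(arr, heads, tails)
        if arr.size >= k:
            arrs.append(arr)
    if not arrs:
        return KmerTable(k=k, codes=np.empty(0, np.uint64), counts=np.empty(0, np.int64))

    concat = np.concatenate(arrs)
    ncodes = concat.size - k + 1
    mask = np.zeros(ncodes, dtype=bool)
    off = 0
    for a in arrs:
        mask[off : off + a.size - k + 1] = True
        off += a.size
    fwd = kmer_codes(concat, k)[mask]
    # reversing the complemented concatenation turns every within-read window
    # into the corresponding reverse-complement window; the validity mask
    # simply reverses with it
    rev = kmer_codes((3 - concat)[::-1], k)[mask[::-1]]
    codes, counts = np.unique(np.concatenate([fwd, rev]), return_counts=True)
    return KmerTable(k=k, codes=codes, counts=counts)


def apply_cutoff(table: KmerTable, cutoff, copies: int | None = None) -> KmerTable:
    """Exclude noise k-mers below a coverage cutoff.

    ``cutoff="auto"`` picks the deepest valley of the log-smoothed coverage
    histogram between the error mode (coverage ~1) and the copy-number mode,
    bounded to [2, copies/2] when the copy number is known.
    """
    if cutoff == "auto":
        cutoff = _auto_cutoff(table.counts, copies)
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    out = table.with_cutoff(int(cutoff))
    if len(out) == 0:
        raise DecodeAbort(f"k-mer table empty after coverage cutoff {cutoff}")
    return out


def _auto_cutoff(counts: np.ndarray, copies: int | None) -> int:
    hi_bound = max(2, copies // 2) if copies else None
    if counts.size == 0:
        return 2
    cap = int(counts.max())
    hist = np.bincount(counts.astype(np.int64), minlength=cap + 1)
    smooth = np.convolve(np.log1p(hist), np.ones(3) / 3.0, mode="same")
    peak = 2 + int(np.argmax(hist[2:])) if hist.size > 2 else 2
    upper = max(3, peak)
    valley = 2 + int(np.argmin(smooth[2:upper])) if upper > 2 else 2
    if hi_bound is not None:
        valley = min(valley, hi_bound)
    return max(2, valley)


# ---------------------------------------------------------------------------
# Stage 2: seeding, greedy path search, CRC selection

@dataclass
class PathCandidate:
    """A partial strand core; ``terminal`` is its last k bases."""

    sequence: str
    terminal: str
    dead_end: bool = False


def seed_kmers(m: int, table: KmerTable, layout: StrandLayout | None = None) -> list:
    """Initial k-mer codes for index ``m`` (empty ⇒ the strand is a dead-end).

    For k ≤ index length the seed is the first k index bases; for larger k
    every table k-mer whose leading index bases equal the encoded index seeds
    a path, found by a contiguous range scan of the sorted code array.
    """
    layout = layout or StrandLayout()
    k, il = table.k, layout.index_len
    idx = encode_index(m, il)
    if k <= il:
        code = code_of(idx[:k])
        return [code] if code in table else []
    prefix = code_of(idx)
    shift = 2 * (k - il)
    fc = table.filtered_codes
    lo = np.uint64(prefix) << np.uint64(shift)
    i0 = int(np.searchsorted(fc, lo, side="left"))
    if prefix + 1 < 4**il:
        hi = np.uint64(prefix + 1) << np.uint64(shift)
        i1 = int(np.searchsorted(fc, hi, side="left"))
    else:
        i1 = fc.size
    return [int(c) for c in fc[i0:i1]]


def greedy_path_search(
    seeds: Sequence[int],
    table: KmerTable,
    core_len: int,
    max_frontier: int = 100_000,
) -> list:
    """Breadth-first extension of every live path out to the core length.

    Each step extends every live path by each base whose k-mer (the path's
    terminal k−1 bases plus that base) survives the coverage filter; paths
    with no extension are dead-ends and are dropped; paths reaching
    ``core_len`` are emitted as candidate cores.  Raises
    :class:`FrontierOverflow` when the live set exceeds ``max_frontier``.
    """
    k = table.k
    if core_len < k:
        raise ValueError("core_len must be at least k")
    members = table.members
    mask = (1 << (2 * (k - 1))) - 1
    # a live path is (terminal_code, base_value_list)
    paths = [
        (s, [(s >> (2 * (k - 1 - i))) & 3 for i in range(k)]) for s in set(seeds)
    ]
    for _ in range(core_len - k):
        if len(paths) > max_frontier:
            raise FrontierOverflow(f"frontier exceeded {max_frontier}")
        nxt = []
        for code, vals in paths:
            stem = (code & mask) << 2
            hits = [b for b in range(4) if (stem | b) in members]
            if len(hits) == 1:
                vals.append(hits[0])
                nxt.append((stem | hits[0], vals))
            else:
                for b in hits:
                    nxt.append((stem | b, vals + [b]))
        paths = nxt
        if not paths:
            break
    return [arr_to_seq(np.asarray(vals, dtype=np.uint8)) for _, vals in paths]


def select_path(candidates: Sequence[str], layout: StrandLayout | None = None, m: int | None = None):
    """CRC-gated selection: exactly one passing candidate or a failure.

    Returns ``(status, payload)`` where payload is the 140-base payload region
    of the unique CRC-passing candidate.  With block checking enabled the
    parity bases are verified too.  Ties are never arbitrated — two passing
    candidates mean the strand is ambiguous.
    """
    layout = layout or StrandLayout()
    passing = []
    for core in candidates:
        ok, got_m, payload = check_strand(core, layout)
        if not ok:
            continue
        if m is not None and got_m != m:
            continue
        if layout.block_check_period is not None and not verify_block(
            payload, layout.block_check_period
        ):
            continue
        passing.append(payload)
    if not passing:
        return (STATUS_NO_CRC if candidates else STATUS_DEAD_END), None
    if len(set(passing)) > 1:
        return STATUS_AMBIGUOUS, None
    return STATUS_RECOVERED, passing[0]


# ---------------------------------------------------------------------------
# Whole-pool reconstruction

@dataclass
class DecodeReport:
    """Per-index outcomes of Stage 2 plus the overall recovery rate S_r."""

    k: int
    cutoff: int
    status: dict
    payloads: dict               # m -> payload bases (parity bases included)
    s_m: float | None = None

    @property
    def s_r(self) -> float:
        if not self.status:
            return 0.0
        return len(self.payloads) / len(self.status)

    @property
    def dropouts(self) -> list:
        return sorted(m for m, s in self.status.items() if s != STATUS_RECOVERED)

    def payload_bytes(self, layout: StrandLayout | None = None) -> list:
        """Recovered (m, data bytes) pairs, parity bases stripped."""
        layout = layout or StrandLayout()
        out = []
        for m, bases in sorted(self.payloads.items()):
            if layout.block_check_period is not None:
                bases = strip_block_checks(bases, layout.block_check_period)
                bases = bases[: 4 * (len(bases) // 4)]
            out.append((m, bases_to_bytes(bases)))
        return out


def reconstruct_all(
    reads: Iterable,
    indices: Sequence[int],
    k: int,
    layout: StrandLayout | None = None,
    cutoff="auto",
    copies: int | None = None,
    max_frontier: int = 100_000,
    trim_primers: bool = True,
    table: KmerTable | None = None,
) -> DecodeReport:
    """Stage 1 once, then independent Stage 2 reconstruction per index.

    Results do not depend on read order or on the order indices are
    processed.  On a frontier overflow the strand is retried once with the
    cutoff raised by one (more errors raise the necessary cutoff), then
    recorded as ambiguous.
    """
    layout = layout or StrandLayout()
    if table is None:
        table = count_kmers(reads, k, layout, trim_primers)
    ftab = apply_cutoff(table, cutoff, copies)
    esc: KmerTable | None = None
    status: dict = {}
    payloads: dict = {}
    for m in indices:
        seeds = seed_kmers(m, ftab, layout)
        if not seeds:
            status[m] = STATUS_DEAD_END
            continue
        try:
            cands = greedy_path_search(seeds, ftab, layout.core_len, max_frontier)
        except FrontierOverflow:
            if esc is None:
                esc = table.with_cutoff(ftab.cutoff + 1)
            try:
                s2 = seed_kmers(m, esc, layout)
                cands = greedy_path_search(s2, esc, layout.core_len, max_frontier)
            except FrontierOverflow:
                status[m] = STATUS_AMBIGUOUS
                continue
        st, payload = select_path(cands, layout, m=m)
        status[m] = st
        if payload is not None:
            payloads[m] = payload
    return DecodeReport(k=k, cutoff=ftab.cutoff, status=status, payloads=payloads)


# ---------------------------------------------------------------------------
# Theoretical ceiling: S_m

def estimate_sm(
    core_len: int = 164,
    copies: int = 10,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    break_rate: float = 0.0,
    reps: int = 200,
    cutoff: int = 2,
    k: int = K_MIN,
    seed: int | None = 0,
) -> float:
    """Monte Carlo estimate of the maximal strand reconstruction rate.

    A strand can be assembled only if its entire k-mer path survives the
    coverage filter, so per repetition one random core is corrupted into
    ``copies`` noisy copies, k-mers are counted (both orientations) and the
    fraction of repetitions in which every true k-mer keeps coverage ≥ cutoff
    is returned.  This ceiling is what the outer-code redundancy must budget
    for at a given operating point.  Uses common random numbers via ``seed``
    so that sweeps over rates or copies are smooth.
    """
    from .channel import apply_breaks, apply_point_errors

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if copies < cutoff:
        return 0.0
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(reps):
        core = rng.integers(0, 4, size=core_len, dtype=np.uint8)
        truth = np.unique(kmer_codes(core, k))
        pieces = []
        for _c in range(copies):
            frags = apply_breaks(core, break_rate, rng) if break_rate else [core]
            for f in frags:
                noisy = apply_point_errors(f, sub_rate, ins_rate, del_rate, rng)
                if noisy.size >= k:
                    pieces.append(kmer_codes(noisy, k))
                    pieces.append(kmer_codes((3 - noisy)[::-1], k))
        if not pieces:
            continue
        codes, counts = np.unique(np.concatenate(pieces), return_counts=True)
        pos = np.searchsorted(codes, truth)
        good = (
            (pos < codes.size)
            & (codes[np.minimum(pos, codes.size - 1)] == truth)
        )
        if good.all() and (counts[pos[good]] >= cutoff).all():
            ok += 1
    return ok / reps
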