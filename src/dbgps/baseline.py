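"""Clustering + multiple-alignment (CL-MA) baseline strand reconstruction.

The traditional trace-reconstruction route the de novo assembler is compared
against: orient each read by its primer landing site, trim the primers,
cluster by the exact 16-base index prefix, and call a per-column majority
consensus over a center-star alignment against the cluster medoid, accepting
the consensus only if its CRC passes.  No reassembly capability — that is
the point: a cluster of fragments or chimeras has no full-length,
CRC-passing consensus.

This is a minimal, faithful baseline, not a reproduction of any specific
published pipeline.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Sequence

import edlib

from .dna import revcomp
from .strand import StrandLayout, check_strand, decode_index, encode_index

_GAP = "-"


def _orient_and_trim(read: str, layout: StrandLayout, max_primer_edit: int = 5):
    """Return the trimmed core of a read, or None if it cannot be oriented.

    Orientation is chosen by whichever strand carries the better 5' primer
    hit; both primers are then located (edit distance ≤ ``max_primer_edit``)
    and stripped.
    """
    fwd = edlib.align(layout.primer5, read, mode="HW", task="locations", k=max_primer_edit)
    rc = revcomp(read)
    bwd = edlib.align(layout.primer5, rc, mode="HW", task="locations", k=max_primer_edit)
    df = fwd["editDistance"] if fwd["editDistance"] >= 0 else max_primer_edit + 1
    db = bwd["editDistance"] if bwd["editDistance"] >= 0 else max_primer_edit + 1
    if df > max_primer_edit and db > max_primer_edit:
        return None
    seq, hit = (read, fwd) if df <= db else (rc, bwd)
    start = hit["locations"][0][1] + 1
    rest = seq[start:]
    tail = edlib.align(layout.primer3, rest, mode="HW", task="locations", k=max_primer_edit)
    if tail["editDistance"] < 0:
        # no 3' landing site: a partial fragment, not a full-length molecule.
        # Standard read preprocessing keeps only full-length products.
        return None
    return rest[: tail["locations"][0][0]]


def _consensus(cluster: Sequence[str]) -> str:
    """Center-star majority consensus: column vote against the medoid."""
    if len(cluster) == 1:
        return cluster[0]
    # medoid = read minimising total edit distance to the others
    tot = [0] * len(cluster)
    for i in range(len(cluster)):
        for j in range(i + 1, len(cluster)):
            d = edlib.align(cluster[i], cluster[j], mode="NW", task="distance")["editDistance"]
            tot[i] += d
            tot[j] += d
    medoid = cluster[min(range(len(cluster)), key=lambda i: (tot[i], i))]
    T = len(medoid)
    col_votes = [Counter() for _ in range(T)]
    ins_votes = [Counter() for _ in range(T + 1)]  # insertions before column t
    n = 0
    for read in cluster:
        aln = edlib.align(read, medoid, mode="NW", task="path")
        cigar = aln["cigar"]
        q = t = 0
        num = ""
        pending: dict[int, str] = {}
        for ch in cigar:
            if ch.isdigit():
                num += ch
                continue
            ln = int(num)
            num = ""
            if ch in "=X":
                for _ in range(ln):
                    col_votes[t][read[q]] += 1
                    q += 1
                    t += 1
            elif ch == "D":          # base in medoid missing from read
                for _ in range(ln):
                    col_votes[t][_GAP] += 1
                    t += 1
            elif ch == "I":          # extra read bases between medoid columns
                pending[t] = pending.get(t, "") + read[q : q + ln]
                q += ln
        for t_ins, s in pending.items():
            ins_votes[t_ins][s] += 1
        n += 1

    out = []
    for t in range(T + 1):
        if ins_votes[t]:
            s, c = ins_votes[t].most_common(1)[0]
            if c * 2 > n:
                out.append(s)
        if t < T:
            votes = col_votes[t]
            if not votes:
                continue
            best = max(votes.values())
            # deterministic tie-break: prefer the medoid's own base, else A<C<G<T<gap
            tied = [b for b, c in votes.items() if c == best]
            if medoid[t] in tied:
                pick = medoid[t]
            else:
                pick = sorted(tied, key=lambda b: "ACGT-".index(b))[0]
            if pick != _GAP:
                out.append(pick)
    return "".join(out)


def ma_baseline(
    reads: Iterable[str],
    layout: StrandLayout | None = None,
    indices: Sequence[int] | None = None,
    min_cluster: int = 3,
    length_tolerance: float = 0.10,
) -> dict:
    """Recover payloads by clustering and majority-vote consensus.

    Returns ``{m: payload_bases}`` for every index whose cluster consensus
    passed the CRC.  Reads whose trimmed length deviates from the core length
    by more than ``length_tolerance`` are discarded, and clusters smaller
    than ``min_cluster`` are not voted on (a majority needs voters) — both
    standard guards in clustering pipelines, and precisely why this route
    collapses on fragmented or chimeric pools.
    """
    layout = layout or StrandLayout()
    core_len = layout.core_len
    want = set(indices) if indices is not None else None
    clusters: dict[int, list] = defaultdict(list)
    for read in reads:
        if not isinstance(read, str):
            from .dna import arr_to_seq

            read = arr_to_seq(read)
        core = _orient_and_trim(read, layout)
        if core is None or abs(len(core) - core_len) > length_tolerance * core_len:
            continue
        m = decode_index(core[: layout.index_len])
        if want is not None and m not in want:
            continue
        clusters[m].append(core)

    recovered: dict[int, str] = {}
    for m, cluster in clusters.items():
        if len(cluster) < min_cluster:
            continue
        cons = _consensus(cluster)
        if len(cons) != core_len:
            continue
        ok, got_m, payload = check_strand(cons, layout)
        if ok and got_m == m:
            recovered[m] = payload
    return recovered
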