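"""High-level file ↔ DNA pipeline glueing the outer code, the strand layout
and the de novo decoder together."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .decoder import DecodeReport, choose_k, reconstruct_all
from .fountain import (
    CHUNK_SIZE,
    Manifest,
    PoolDesign,
    assemble_file,
    chunk_file,
    decode_pool,
    generate_pool,
)
from .strand import StrandLayout

# Desk-scale outer redundancy default.  The outer code must budget for the
# strand-recovery ceiling S_m of the operating point: redundancy >
# (1+eps)/S_m - 1.  At ten copies and 3% mixed point errors S_m is ~0.92
# (see estimate_sm), hence 15% rather than the 7.8% a deeply sequenced pool
# (S_r >= 95%) gets away with.
DEFAULT_REDUNDANCY = 0.15


def encode_file(
    data: bytes,
    redundancy: float = DEFAULT_REDUNDANCY,
    k: int | None = None,
    layout: StrandLayout | None = None,
    chunk_size: int = CHUNK_SIZE,
    soliton_c: float = 0.025,
    soliton_delta: float = 0.001,
) -> tuple[PoolDesign, Manifest]:
    """Encode a byte string into an entanglement-free designed strand pool."""
    layout = layout or StrandLayout()
    chunks = chunk_file(data, chunk_size)
    if k is None:
        n_est = round(chunks.shape[0] * (1 + redundancy))
        k = choose_k(max(1, n_est), layout.core_len)
    design = generate_pool(chunks, redundancy, k, layout, soliton_c, soliton_delta)
    manifest = Manifest.from_pool(design, file_len=len(data))
    return design, manifest


def decode_reads(
    reads: Iterable,
    manifest: Manifest,
    cutoff="auto",
    k: int | None = None,
    copies: int | None = None,
    max_frontier: int = 100_000,
) -> tuple[bytes, DecodeReport]:
    """Reconstruct strands from raw reads and peel the fountain code.

    Returns the decoded file bytes together with the per-strand report.
    Raises :class:`dbgps.fountain.PartialDecodeError` when too few strands
    survive for the outer code.
    """
    report = reconstruct_all(
        reads,
        indices=manifest.seeds,
        k=k or manifest.k,
        layout=manifest.layout,
        cutoff=cutoff,
        copies=copies,
        max_frontier=max_frontier,
    )
    recovered = report.payload_bytes(manifest.layout)
    stream = decode_pool(
        recovered,
        n_chunks=manifest.n_chunks,
        chunk_size=manifest.chunk_size,
        soliton_c=manifest.soliton_c,
        soliton_delta=manifest.soliton_delta,
    )
    return assemble_file(stream, manifest.file_len), report
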