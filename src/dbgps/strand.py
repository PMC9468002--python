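"""Inner-code strand layout: index / payload / CRC fields and conversions.

A designed strand is a fixed-length oligo::

    primer5 (18 nt) | index (16 nt) | payload (140 nt) | CRC (8 nt) | primer3 (18 nt)

for a 164 nt core and a 200 nt total synthesis length.  The index is a
big-endian base-4 rendering of the strand number ``m`` (also the fountain
droplet seed), the payload carries 35 bytes of outer-code data at 2 bits per
base, and the CRC is CRC-16/CCITT-FALSE over the index+payload bytes, stored
as 8 bases.  The CRC is what lets the decoder pick the one correct path among
assembly candidates, so it is computed over bases exactly as they appear in
the core.

Bit conventions (fixed so outputs are bit-exact across platforms): each byte
maps to 4 bases most-significant bit pair first, with A=00, C=01, G=10, T=11.
"""

from __future__ import annotations

import binascii
from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, arr_to_seq, seq_to_arr

# Default sequencing-primer landing sites (18 nt each).  The field's designs
# keep these fixed per pool and trim them before decoding; any pair can be
# supplied through StrandLayout.
DEFAULT_PRIMER5 = "AGTCACGTACCGTTGCTA"
DEFAULT_PRIMER3 = "CTGAGTCGGAGACACGCA"


class LayoutError(ValueError):
    """A sequence does not fit the declared strand layout."""


@dataclass(frozen=True)
class StrandLayout:
    """Geometry of one designed strand.

    ``block_check_period`` (B) optionally devotes one payload base per B data
    bases to a mod-4 parity check; the payload region stays 140 nt and the
    core stays 164 nt regardless.
    """

    index_len: int = 16
    payload_len: int = 140
    crc_len: int = 8
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    block_check_period: int | None = None

    def __post_init__(self) -> None:
        if min(self.index_len, self.payload_len, self.crc_len) <= 0:
            raise LayoutError("all field lengths must be positive")
        if self.crc_len * 2 != 16:
            raise LayoutError("CRC field must hold 16 bits (8 bases)")
        if self.block_check_period is not None and not 3 <= self.block_check_period <= 10:
            raise ValueError("block_check_period must be in [3, 10]")

    @property
    def core_len(self) -> int:
        return self.index_len + self.payload_len + self.crc_len

    @property
    def total_len(self) -> int:
        return self.core_len + len(self.primer5) + len(self.primer3)

    @property
    def data_payload_len(self) -> int:
        """Payload bases that carry data (excludes block-check parity bases)."""
        if self.block_check_period is None:
            return self.payload_len
        b = self.block_check_period
        return self.payload_len - self.payload_len // (b + 1)

    def to_dict(self) -> dict:
        return {
            "index_len": self.index_len,
            "payload_len": self.payload_len,
            "crc_len": self.crc_len,
            "primer5": self.primer5,
            "primer3": self.primer3,
            "block_check_period": self.block_check_period,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrandLayout":
        return cls(**d)


@dataclass(frozen=True)
class StrandRecord:
    """One designed strand: index ``m``, payload and CRC bases, full sequence."""

    m: int
    payload: str
    crc: str
    sequence: str
    layout: StrandLayout = field(default_factory=StrandLayout, repr=False)

    @property
    def core(self) -> str:
        p5 = len(self.layout.primer5)
        return self.sequence[p5 : p5 + self.layout.core_len]


def bytes_to_bases(data: bytes) -> str:
    """Map bytes to bases, 4 per byte, MSB pair first (00→A … 11→T)."""
    raw = np.frombuffer(bytes(data), dtype=np.uint8)
    out = np.empty(4 * raw.size, dtype=np.uint8)
    out[0::4] = raw >> 6
    out[1::4] = (raw >> 4) & 3
    out[2::4] = (raw >> 2) & 3
    out[3::4] = raw & 3
    return arr_to_seq(out)


def bases_to_bytes(bases: str) -> bytes:
    """Inverse of :func:`bytes_to_bases`; length must be a multiple of 4."""
    arr = seq_to_arr(bases)
    if arr.size % 4:
        raise ValueError("base string length must be a multiple of 4")
    vals = (
        (arr[0::4].astype(np.uint8) << 6)
        | (arr[1::4] << 4)
        | (arr[2::4] << 2)
        | arr[3::4]
    )
    return vals.tobytes()


def encode_index(m: int, index_len: int = 16) -> str:
    """Render strand number ``m`` as ``index_len`` bases, big-endian base 4."""
    if not 0 <= m < 4**index_len:
        raise ValueError(f"index {m} out of range for {index_len} bases")
    return "".join(BASES[(m >> (2 * (index_len - 1 - i))) & 3] for i in range(index_len))


def decode_index(bases: str) -> int:
    m = 0
    for b in bases:
        m = (m << 2) | BASES.index(b)
    return m


def compute_crc(core: str, layout: StrandLayout | None = None) -> str:
    """CRC-16/CCITT-FALSE of the index+payload bases, emitted as 8 bases.

    The CRC runs over the byte image of the bases (39 bytes for the default
    156-base region), big-endian, poly 0x1021, init 0xFFFF, no reflection.
    """
    layout = layout or StrandLayout()
    expect = layout.index_len + layout.payload_len
    if len(core) != expect:
        raise LayoutError(f"CRC region must be {expect} bases, got {len(core)}")
    crc = binascii.crc_hqx(bases_to_bytes(core), 0xFFFF)
    return bytes_to_bases(crc.to_bytes(2, "big"))


def build_strand(m: int, payload: str, layout: StrandLayout | None = None) -> StrandRecord:
    """Assemble the full designed strand for index ``m``."""
    layout = layout or StrandLayout()
    if len(payload) != layout.payload_len:
        raise LayoutError(
            f"payload must be {layout.payload_len} bases, got {len(payload)}"
        )
    idx = encode_index(m, layout.index_len)
    crc = compute_crc(idx + payload, layout)
    seq = layout.primer5 + idx + payload + crc + layout.primer3
    return StrandRecord(m=m, payload=payload, crc=crc, sequence=seq, layout=layout)


def check_strand(core: str, layout: StrandLayout | None = None):
    """Validate a candidate core against its embedded CRC.

    Returns ``(ok, m, payload)``; ``m`` and ``payload`` are only meaningful
    when ``ok`` is True.  The length is checked strictly — a wrong-length
    candidate is a layout error, never silently truncated.
    """
    layout = layout or StrandLayout()
    if len(core) != layout.core_len:
        raise LayoutError(f"core must be {layout.core_len} bases, got {len(core)}")
    region = core[: layout.index_len + layout.payload_len]
    ok = compute_crc(region, layout) == core[layout.index_len + layout.payload_len :]
    m = decode_index(core[: layout.index_len])
    payload = core[layout.index_len : layout.index_len + layout.payload_len]
    return ok, m, payload


# ---------------------------------------------------------------------------
# Block-checking codes: one parity base after every B payload bases.  These
# give the path search a mid-strand pruning signal for very noisy channels
# (low-cost synthesis); off by default.

def _parity_base(block: str) -> str:
    return BASES[sum(BASES.index(b) for b in block) % 4]


def insert_block_checks(payload: str, B: int) -> str:
    """Interleave a mod-4 parity base after every complete block of B bases."""
    if not 3 <= B <= 10:
        raise ValueError("block period B must be in [3, 10]")
    out = []
    for i in range(0, len(payload), B):
        block = payload[i : i + B]
        out.append(block)
        if len(block) == B:
            out.append(_parity_base(block))
    return "".join(out)


def verify_block(prefix: str, B: int) -> bool:
    """Check every complete (B+1)-base block of a block-checked prefix."""
    if not 3 <= B <= 10:
        raise ValueError("block period B must be in [3, 10]")
    step = B + 1
    for i in range(0, len(prefix) - step + 1, step):
        chunk = prefix[i : i + step]
        if _parity_base(chunk[:B]) != chunk[B]:
            return False
    return True


def strip_block_checks(payload: str, B: int) -> str:
    """Remove the interleaved parity bases, returning the data bases."""
    step = B + 1
    return "".join(payload[i : min(i + B, len(payload))] for i in range(0, len(payload), step))
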