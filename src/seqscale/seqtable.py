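"""Per-position, per-strand k-mer index tables (the seqtable step).

Combines genome, mappability and mask into two integer vectors per contig
holding the k-mer index of every potential read alignment position, or the
sentinel where a position is unmappable, too close to a contig edge, or its
window contains an ambiguous base.

Coordinate convention: entry ``p`` on either strand refers to the nick
between bases ``p-1`` and ``p``. Minus-strand entries are pre-shifted by +1
(a minus read with 5' base at ``q`` is stored at ``q+1``), so the plus and
minus entries of one nick share a coordinate and the downstream tallying and
scaling steps are strand-agnostic.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, FileFormatError
from .mappability import MappabilityTrack
from .masks import SENTINEL, KmerMask, minus_kmer_indices, plus_kmer_indices
from .seqio import encode_sequence

_MAGIC = b"SQSTBL01"


@dataclass
class SeqTable:
    mask: KmerMask
    read_length: int
    contigs: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (plus, minus) uint32

    @property
    def n_kmers(self) -> int:
        return 4 ** self.mask.kmer_size

    def plus(self, contig: str) -> np.ndarray:
        return self.contigs[contig][0]

    def minus(self, contig: str) -> np.ndarray:
        return self.contigs[contig][1]


def build_seqtable(
    genome: dict[str, str], mappability: MappabilityTrack, mask: KmerMask
) -> SeqTable:
    """Compute the k-mer index of every potential read alignment position."""
    if set(genome) != set(mappability.contigs):
        raise ConfigError("mappability track contigs do not match genome")
    contigs = {}
    for name, seq in genome.items():
        plus_map, minus_map = mappability.contigs[name]
        if len(plus_map) != len(seq):
            raise ConfigError(
                f"mappability length mismatch for contig {name!r}"
            )
        codes = encode_sequence(seq)
        plus = plus_kmer_indices(codes, mask)
        plus[~plus_map] = SENTINEL
        minus = minus_kmer_indices(codes, mask)
        # minus entry at p corresponds to a 5' base at q = p-1
        shifted = np.zeros(len(seq), dtype=bool)
        shifted[1:] = minus_map[:-1]
        minus[~shifted] = SENTINEL
        contigs[name] = (plus, minus)
    return SeqTable(mask=mask, read_length=mappability.read_length, contigs=contigs)


# -- persistence ------------------------------------------------------------
#
# Layout (little-endian):
#   magic "SQSTBL01" | uint32 read_length | uint16 mask_len | mask ascii
#   | uint32 n_contigs
#   per contig: uint16 name_len | name utf-8 | uint64 contig_len
#               | contig_len * uint32 plus | contig_len * uint32 minus
# Sentinel entries are stored verbatim (0xFFFFFFFF).


def write_seqtable(table: SeqTable, path) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        mask_raw = table.mask.mask.encode("ascii")
        fh.write(struct.pack("<IH", table.read_length, len(mask_raw)))
        fh.write(mask_raw)
        fh.write(struct.pack("<I", len(table.contigs)))
        for name, (plus, minus) in table.contigs.items():
            raw = name.encode("utf-8")
            fh.write(struct.pack("<H", len(raw)))
            fh.write(raw)
            fh.write(struct.pack("<Q", len(plus)))
            fh.write(plus.astype("<u4").tobytes())
            fh.write(minus.astype("<u4").tobytes())


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FileFormatError("truncated seqtable file")
    return data


def read_seqtable(path, expect_mask: str | None = None,
                  expect_read_length: int | None = None) -> SeqTable:
    """Read a seqtable container, optionally validating its header."""
    with open(path, "rb") as fh:
        if _read_exact(fh, len(_MAGIC)) != _MAGIC:
            raise FileFormatError(f"{path} is not a seqtable container")
        read_length, mask_len = struct.unpack("<IH", _read_exact(fh, 6))
        mask_str = _read_exact(fh, mask_len).decode("ascii")
        if expect_mask is not None and mask_str != expect_mask:
            raise FileFormatError(
                f"seqtable mask {mask_str!r} != requested {expect_mask!r}"
            )
        if expect_read_length is not None and read_length != expect_read_length:
            raise FileFormatError(
                f"seqtable read length {read_length} != requested {expect_read_length}"
            )
        (n_contigs,) = struct.unpack("<I", _read_exact(fh, 4))
        contigs = {}
        for _ in range(n_contigs):
            (name_len,) = struct.unpack("<H", _read_exact(fh, 2))
            name = _read_exact(fh, name_len).decode("utf-8")
            (contig_len,) = struct.unpack("<Q", _read_exact(fh, 8))
            plus = np.frombuffer(_read_exact(fh, 4 * contig_len), dtype="<u4").copy()
            minus = np.frombuffer(_read_exact(fh, 4 * contig_len), dtype="<u4").copy()
            contigs[name] = (plus, minus)
    return SeqTable(mask=KmerMask(mask_str), read_length=read_length, contigs=contigs)
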