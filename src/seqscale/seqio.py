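"""Sequence and interval I/O helpers.

Genomes are held in memory as ``{contig_name: uppercase_string}`` maps; all
coordinates in the package are 0-based half-open. Conversion to/from 1-based
SAM coordinates happens only inside pysam at the BAM boundary.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path

import numpy as np
from Bio import SeqIO

# Base encoding used throughout: A=0, C=1, G=2, T=3; anything else (N,
# IUPAC codes, gaps) encodes to -1. Lowercase (soft-masked) bases are
# treated as their uppercase equivalents.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")

BASES = "ACGT"


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT characters pass through unchanged."""
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def kmer_to_string(index: int, k: int) -> str:
    """Decode a base-4 big-endian k-mer index back to its ACGT string."""
    out = []
    for _ in range(k):
        out.append(BASES[index & 3])
        index >>= 2
    return "".join(reversed(out))


def string_to_kmer(s: str) -> int:
    idx = 0
    for ch in s:
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"non-ACGT base in k-mer: {s!r}")
        idx = (idx << 2) | int(code)
    return idx


def _open_maybe_gzip(path):
    path = Path(path)
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def load_genome(path) -> dict[str, str]:
    """Read a FASTA file (plain or gzip) into a contig→sequence map.

    Sequences are uppercased; empty files raise ``ValueError``.
    """
    with _open_maybe_gzip(path) as handle:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def chrom_sizes(genome: dict[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


def read_bed(path) -> list[tuple]:
    """Parse a BED file into (contig, start, end[, name, score, strand]) tuples.

    Only the columns present are returned; coordinates are 0-based half-open.
    """
    rows = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            extra = tuple(parts[3:6])
            rows.append((contig, start, end) + extra)
    return rows


def write_bed(rows, path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
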