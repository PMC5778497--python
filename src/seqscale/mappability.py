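"""Exact single-read-length genome mappability.

A plus-strand position ``p`` is mappable iff the ``read_length`` substring
starting at ``p`` occurs exactly once among all ``read_length`` substrings of
all contigs on *both* strands — the behavior a real aligner exhibits, since a
read can align to either strand. A minus-strand coordinate ``q`` is mappable
iff the read whose 5'-most sequenced base is the complement of base ``q``
(i.e. the reverse complement of the window ``[q-read_length+1, q+1)``) is
unique in the same sense. Exact matching only, no mismatches; windows
containing non-ACGT characters are unmappable.

Both criteria reduce to uniqueness of the plus-strand window itself, because
occurrences(S) = plus_occurrences(S) + plus_occurrences(revcomp(S)) and this
quantity is invariant under reverse complementation of S. A palindromic
window pairs with itself and is therefore never unique.
"""

from __future__ import annotations

import struct
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FileFormatError
from .seqio import _COMPLEMENT

_MAGIC = b"SQSMAP01"
_ACGT = frozenset(b"ACGT")


@dataclass
class MappabilityTrack:
    """Per-contig, per-strand boolean mappability vectors for one read length."""

    read_length: int
    contigs: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (plus, minus)

    def plus(self, contig: str) -> np.ndarray:
        return self.contigs[contig][0]

    def minus(self, contig: str) -> np.ndarray:
        return self.contigs[contig][1]


def _window_uniqueness(genome: dict[str, str], read_length: int):
    """Per contig: boolean vector u where u[s] = window starting at s is
    ACGT-only and globally unique across both strands."""
    counts: Counter = Counter()
    enc = {name: seq.upper().encode("ascii") for name, seq in genome.items()}
    windows: dict[str, list] = {}
    for name, seq in enc.items():
        wins = []
        for s in range(len(seq) - read_length + 1):
            w = seq[s : s + read_length]
            if set(w) <= _ACGT:
                counts[w] += 1
                wins.append(w)
            else:
                wins.append(None)
        windows[name] = wins
    unique = {}
    for name, seq in enc.items():
        u = np.zeros(len(seq), dtype=bool)
        for s, w in enumerate(windows[name]):
            if w is None:
                continue
            rc = w.translate(_COMPLEMENT)[::-1]
            if counts[w] + counts[rc] == 1:
                u[s] = True
        unique[name] = u
    return unique


def compute_mappability(genome: dict[str, str], read_length: int) -> MappabilityTrack:
    """Compute exact unique mappability for every position of every contig."""
    if not genome:
        raise ValueError("empty genome")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if all(len(seq) < read_length for seq in genome.values()):
        warnings.warn(
            f"read_length {read_length} exceeds every contig length; "
            "all positions unmappable"
        )
    unique = _window_uniqueness(genome, read_length)
    contigs = {}
    for name, seq in genome.items():
        n = len(seq)
        u = unique[name]
        plus = u.copy()  # plus-strand read starts at the window start
        minus = np.zeros(n, dtype=bool)
        if n >= read_length:
            # minus read with 5' base at q covers window starting at q-L+1
            minus[read_length - 1 :] = u[: n - read_length + 1]
        contigs[name] = (plus, minus)
    return MappabilityTrack(read_length=read_length, contigs=contigs)


# -- persistence: run-length-encoded container ------------------------------
#
# Layout (little-endian):
#   magic "SQSMAP01" | uint32 read_length | uint32 n_contigs
#   per contig: uint16 name_len | name utf-8 | uint64 contig_len
#     per strand (plus then minus): uint8 first_value | uint64 n_runs
#                                   | n_runs * uint64 run lengths


def _rle_encode(v: np.ndarray):
    if len(v) == 0:
        return 0, np.zeros(0, dtype=np.uint64)
    change = np.flatnonzero(np.diff(v.astype(np.int8)))
    bounds = np.concatenate(([0], change + 1, [len(v)]))
    return int(v[0]), np.diff(bounds).astype(np.uint64)


def _rle_decode(first: int, runs: np.ndarray, n: int) -> np.ndarray:
    v = np.zeros(n, dtype=bool)
    pos = 0
    val = bool(first)
    for r in runs:
        if val:
            v[pos : pos + int(r)] = True
        pos += int(r)
        val = not val
    if pos != n:
        raise FileFormatError("run lengths do not sum to contig length")
    return v


def write_mappability(track: MappabilityTrack, path) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<II", track.read_length, len(track.contigs)))
        for name, (plus, minus) in track.contigs.items():
            raw = name.encode("utf-8")
            fh.write(struct.pack("<H", len(raw)))
            fh.write(raw)
            fh.write(struct.pack("<Q", len(plus)))
            for v in (plus, minus):
                first, runs = _rle_encode(v)
                fh.write(struct.pack("<BQ", first, len(runs)))
                fh.write(runs.astype("<u8").tobytes())


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FileFormatError("truncated mappability file")
    return data


def read_mappability(path) -> MappabilityTrack:
    with open(path, "rb") as fh:
        if _read_exact(fh, len(_MAGIC)) != _MAGIC:
            raise FileFormatError(f"{path} is not a mappability container")
        read_length, n_contigs = struct.unpack("<II", _read_exact(fh, 8))
        contigs = {}
        for _ in range(n_contigs):
            (name_len,) = struct.unpack("<H", _read_exact(fh, 2))
            name = _read_exact(fh, name_len).decode("utf-8")
            (contig_len,) = struct.unpack("<Q", _read_exact(fh, 8))
            strands = []
            for _s in range(2):
                first, n_runs = struct.unpack("<BQ", _read_exact(fh, 9))
                runs = np.frombuffer(_read_exact(fh, 8 * n_runs), dtype="<u8")
                strands.append(_rle_decode(first, runs, contig_len))
            contigs[name] = (strands[0], strands[1])
    return MappabilityTrack(read_length=read_length, contigs=contigs)


def unmappable_bed(track: MappabilityTrack):
    """Unmappable intervals (0-based half-open) per contig and strand."""
    rows = []
    for name, (plus, minus) in track.contigs.items():
        for strand_name, v in (("+", plus), ("-", minus)):
            first, runs = _rle_encode(~v)
            pos = 0
            val = bool(first)
            for r in runs:
                if val:
                    rows.append((name, pos, pos + int(r), "unmappable", 0, strand_name))
                pos += int(r)
                val = not val
    return rows


def mappability_path(fasta_path, read_length: int) -> Path:
    """Conventional sidecar filename used for intermediate-file reuse."""
    fasta_path = Path(fasta_path)
    return fasta_path.with_suffix(fasta_path.suffix + f".mer{read_length}.map")


def compute_or_load(fasta_path, genome: dict[str, str], read_length: int) -> MappabilityTrack:
    """Reuse an up-to-date sidecar container when present, else recompute."""
    cache = mappability_path(fasta_path, read_length)
    if cache.exists() and cache.stat().st_mtime >= Path(fasta_path).stat().st_mtime:
        track = read_mappability(cache)
        if track.read_length == read_length:
            return track
    track = compute_mappability(genome, read_length)
    write_mappability(track, cache)
    return track
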