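"""The N/X/C spaced k-mer mask grammar.

A mask is a string over ``{N, X, C}`` describing the sequence context around
an enzymatic cut site (nick): ``N`` positions index the bias table, ``X``
positions are ignored, and the single ``C`` marks the nick itself without
consuming a genomic base. ``NNNCNNN`` is a contiguous hexamer split 3/3
around the nick (kmer-size 6, plus-offset 3, minus-offset 3);
``NNXXNNXXCXXNNXXNN`` is a gapped 8-mer spanning 16 bp.

Conventions fixed here and used everywhere else:

* the genomic footprint (span) of a mask is ``len(mask) - 1`` because ``C``
  consumes no base;
* ``plus_offset`` (= number of spanned bases upstream of the nick) and
  ``minus_offset`` (downstream) are derived from the ``C`` position;
* k-mer indices encode the ``N``-position bases in base 4, first ``N`` most
  significant, with A=0, C=1, G=2, T=3; a window containing a non-ACGT base
  at any ``N`` position encodes to the sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MaskGrammarError
from .seqio import _CODE

#: Sentinel k-mer index (also used in seqtables for unmappable/edge positions).
SENTINEL = np.uint32(0xFFFFFFFF).item()

_MAX_KMER_SIZE = 15  # 4**15 < 2**32, keeps indices inside uint32


@dataclass(frozen=True)
class KmerMask:
    """A parsed spaced k-mer mask.

    Construction validates the character set and the single-``C`` rule but
    permits zero ``N`` positions (the all-``X`` mask is the natural starting
    point of the hill-climbing search and means "no sequence correction");
    :func:`parse_mask` applies the stricter user-facing grammar that
    additionally requires at least one ``N``.
    """

    mask: str

    def __post_init__(self):
        bad = set(self.mask) - set("NXC")
        if not self.mask:
            raise MaskGrammarError("empty mask string")
        if bad:
            raise MaskGrammarError(
                f"invalid mask character(s) {sorted(bad)} in {self.mask!r}"
            )
        if self.mask.count("C") != 1:
            raise MaskGrammarError(
                f"mask must contain exactly one C (cut marker): {self.mask!r}"
            )
        if self.kmer_size > _MAX_KMER_SIZE:
            raise MaskGrammarError(f"kmer size > {_MAX_KMER_SIZE} unsupported")

    # -- derived parameters -------------------------------------------------
    @property
    def kmer_size(self) -> int:
        return self.mask.count("N")

    @property
    def span(self) -> int:
        """Genomic footprint in bases (C consumes none)."""
        return len(self.mask) - 1

    @property
    def n_upstream(self) -> int:
        return self.mask.index("C")

    @property
    def n_downstream(self) -> int:
        return self.span - self.n_upstream

    @property
    def plus_offset(self) -> int:
        return self.n_upstream

    @property
    def minus_offset(self) -> int:
        return self.n_downstream

    @property
    def n_positions(self) -> np.ndarray:
        """Indices (within the span, C removed) of the N positions."""
        chars = self.mask.replace("C", "")
        return np.array([i for i, ch in enumerate(chars) if ch == "N"], dtype=np.int64)

    @property
    def n_offsets(self) -> np.ndarray:
        """Genomic offsets of the N positions relative to the cut coordinate."""
        return self.n_positions - self.n_upstream

    def reverse(self) -> "KmerMask":
        """The mask read on the opposite strand (character string reversed)."""
        return KmerMask(self.mask[::-1])

    def __str__(self) -> str:
        return self.mask


def parse_mask(text: str) -> KmerMask:
    """Parse a user-supplied mask string, enforcing the full grammar.

    Requires at least one ``N`` and exactly one ``C``; masks without an
    explicit cut marker must be built with :func:`mask_from_offsets` so the
    cut position is never ambiguous.
    """
    mask = KmerMask(text)
    if mask.kmer_size == 0:
        raise MaskGrammarError(f"mask has no informative (N) positions: {text!r}")
    return mask


def mask_from_offsets(kmer_size: int, plus_offset: int, minus_offset: int) -> KmerMask:
    """Build the contiguous (ungapped) mask from the parameter trio.

    ``plus_offset`` bases upstream and ``minus_offset`` bases downstream of
    the nick, all informative; they must sum to ``kmer_size``.
    """
    if kmer_size < 1:
        raise ValueError("kmer_size must be >= 1")
    if plus_offset < 0 or minus_offset < 0:
        raise ValueError("offsets must be non-negative")
    if plus_offset + minus_offset != kmer_size:
        raise ValueError(
            f"plus_offset + minus_offset must equal kmer_size "
            f"({plus_offset}+{minus_offset} != {kmer_size})"
        )
    return KmerMask("N" * plus_offset + "C" + "N" * minus_offset)


def reverse_mask(mask: KmerMask) -> KmerMask:
    return mask.reverse()


def kmer_index(window: str, mask: KmerMask) -> int:
    """Encode the N-position bases of a span-length window.

    Returns :data:`SENTINEL` when any N-position base is outside ACGT
    (case-insensitive).
    """
    if len(window) != mask.span:
        raise ValueError(
            f"window length {len(window)} != mask span {mask.span}"
        )
    idx = 0
    for pos in mask.n_positions:
        code = _CODE[ord(window[pos])]
        if code < 0:
            return SENTINEL
        idx = (idx << 2) | int(code)
    return idx


# -- vectorized per-contig index computation (shared by seqtable/synthetic) --

def plus_kmer_indices(codes: np.ndarray, mask: KmerMask) -> np.ndarray:
    """K-mer index for every plus-strand cut coordinate of one contig.

    ``codes`` is the int8 encoding of the contig. Entry ``p`` indexes the
    window ``[p - plus_offset, p + minus_offset)`` through the mask; edge
    positions and windows with ambiguous bases hold the sentinel.
    """
    n_contig = len(codes)
    out = np.full(n_contig, SENTINEL, dtype=np.uint32)
    lo = mask.n_upstream
    hi = min(n_contig - mask.n_downstream, n_contig - 1)
    if hi < lo:
        return out
    n = hi - lo + 1
    acc = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for off in mask.n_offsets:
        c = codes[lo + off : lo + off + n]
        ok &= c >= 0
        acc = (acc << 2) | np.where(c >= 0, c, 0)
    out[lo : hi + 1] = np.where(ok, acc, SENTINEL).astype(np.uint32)
    return out


def minus_kmer_indices(codes: np.ndarray, mask: KmerMask) -> np.ndarray:
    """K-mer index for minus-strand reads, stored at the plus-matched coordinate.

    A minus-strand read whose 5'-most sequenced base sits at coordinate ``q``
    detects the nick between ``q`` and ``q+1``; its entry is stored at
    ``p = q + 1`` so both strands of one nick share a coordinate. The window
    is the reverse complement of ``[p - minus_offset, p + plus_offset)``,
    indexed through the *same* mask.
    """
    n_contig = len(codes)
    out = np.full(n_contig, SENTINEL, dtype=np.uint32)
    lo = max(mask.n_downstream, 1)  # p=0 would need a 5' base at q=-1
    hi = min(n_contig - mask.n_upstream, n_contig - 1)
    if hi < lo:
        return out
    n = hi - lo + 1
    acc = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    # W[u] = complement(codes[p + n_upstream - 1 - u]) for span index u
    for pos in mask.n_positions:
        off = mask.n_upstream - 1 - int(pos)
        c = codes[lo + off : lo + off + n]
        ok &= c >= 0
        acc = (acc << 2) | np.where(c >= 0, 3 - c, 0)
    out[lo : hi + 1] = np.where(ok, acc, SENTINEL).astype(np.uint32)
    return out
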