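"""End-repair/ligation detection bias around nick sites.

A nick can be recovered by sequencing either the downstream fragment (a
plus-strand read starting at the nick) or the upstream fragment (a
minus-strand read whose 5' base is just upstream of it). For each nick the
upstream 3-mer ``u`` and downstream 3-mer ``v`` (both written in plus-strand
genome orientation) define one of 4096 cells; the ratio of plus- to
minus-detected reads in a cell measures which side of that sequence context
library preparation preferentially recovers. With no detection bias every
palindromic cell (v = revcomp(u)) is balanced, since both reads of such a
nick start with the same 3-mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .reads import ReadFilters, as_events
from .seqio import encode_sequence, kmer_to_string

_DEFAULT_MIN_COUNT = 10


@dataclass
class DetectionBiasTable:
    """64x64 plus/minus detection counts per (upstream, downstream) 3-mer."""

    plus_detected: np.ndarray   # (64, 64) int64; [u, v]
    minus_detected: np.ndarray
    flank: int = 3
    min_count: int = _DEFAULT_MIN_COUNT

    @property
    def defined(self) -> np.ndarray:
        """Cells with at least ``min_count`` reads on each side."""
        return (self.plus_detected >= self.min_count) & \
               (self.minus_detected >= self.min_count)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.plus_detected / self.minus_detected
        return np.where(self.defined, r, np.nan)

    @property
    def log2_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.ratio)

    def to_frame(self) -> pd.DataFrame:
        k = self.flank
        rows = []
        for u in range(4 ** k):
            for v in range(4 ** k):
                rows.append((
                    kmer_to_string(u, k), kmer_to_string(v, k),
                    int(self.plus_detected[u, v]), int(self.minus_detected[u, v]),
                    float(self.log2_ratio[u, v]),
                ))
        return pd.DataFrame(
            rows, columns=["upstream", "downstream", "plus_count",
                           "minus_count", "log2_ratio"],
        )


def detection_table(genome: dict[str, str], reads, flank: int = 3,
                    min_count: int = _DEFAULT_MIN_COUNT,
                    filters: ReadFilters | None = None) -> DetectionBiasTable:
    """Tally plus/minus detections per (upstream, downstream) flank pair.

    Each read's nick is located at the plus-matched coordinate ``p`` (the
    5' start for plus reads; 5' base + 1 for minus reads); the flanking
    3-mers are ``genome[p-3:p]`` and ``genome[p:p+3]`` in plus orientation.
    Nicks whose windows overrun the contig or contain ambiguous bases are
    skipped.
    """
    events = as_events(reads, filters=filters)
    n = 4 ** flank
    plus_counts = np.zeros((n, n), dtype=np.int64)
    minus_counts = np.zeros((n, n), dtype=np.int64)
    weights = (4 ** np.arange(flank - 1, -1, -1)).astype(np.int64)
    for name, (pos, is_minus) in events.contigs.items():
        if name not in genome:
            continue
        codes = encode_sequence(genome[name]).astype(np.int64)
        n_contig = len(codes)
        for minus_strand, out in ((False, plus_counts), (True, minus_counts)):
            p = pos[is_minus == minus_strand]
            if minus_strand:
                p = p + 1  # plus-matched nick coordinate
            ok = (p >= flank) & (p <= n_contig - flank)
            p = p[ok]
            if len(p) == 0:
                continue
            u = np.zeros(len(p), dtype=np.int64)
            v = np.zeros(len(p), dtype=np.int64)
            valid = np.ones(len(p), dtype=bool)
            for i in range(flank):
                cu = codes[p - flank + i]
                cv = codes[p + i]
                valid &= (cu >= 0) & (cv >= 0)
                u += np.where(cu >= 0, cu, 0) * weights[i]
                v += np.where(cv >= 0, cv, 0) * weights[i]
            np.add.at(out, (u[valid], v[valid]), 1)
    return DetectionBiasTable(
        plus_detected=plus_counts, minus_detected=minus_counts,
        flank=flank, min_count=min_count,
    )


def top_skew_motif(table: DetectionBiasTable, fraction: float = 0.05) -> np.ndarray:
    """Base-frequency matrix of the most skewed (u, v) 6-mers.

    Ranks defined cells by |log2 ratio|, keeps the top ``fraction`` and
    returns the unweighted per-position base-frequency matrix (2*flank, 4)
    of the concatenated upstream+downstream sequences.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    log2 = table.log2_ratio
    defined = table.defined
    if not defined.any():
        raise ValueError("no defined detection ratios")
    u_idx, v_idx = np.nonzero(defined)
    skew = np.abs(log2[u_idx, v_idx])
    n_top = max(1, int(np.ceil(fraction * len(skew))))
    order = np.argsort(-skew, kind="stable")[:n_top]
    k = table.flank
    freq = np.zeros((2 * k, 4))
    for u, v in zip(u_idx[order], v_idx[order]):
        seq = kmer_to_string(int(u), k) + kmer_to_string(int(v), k)
        for j, base in enumerate(seq):
            freq[j, "ACGT".index(base)] += 1
    return freq / n_top


def correlate_bias(a: DetectionBiasTable, b: DetectionBiasTable) -> float:
    """Pearson correlation of log2 ratios over cells defined in both tables."""
    shared = a.defined & b.defined
    if shared.sum() < 3:
        raise ValueError(
            f"only {int(shared.sum())} cell(s) defined in both tables (need >= 3)"
        )
    return float(pearsonr(a.log2_ratio[shared], b.log2_ratio[shared])[0])
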