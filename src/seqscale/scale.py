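"""Per-k-mer scale factors and corrected pileup tracks.

The scale factor of k-mer *j* on a strand is

    alpha(j) = (expected_j / M) / (observed_j / N)

the ratio of the k-mer's genomic frequency (among the M mappable positions
of that strand) to its frequency among the N observed reads of that strand.
Each read then contributes alpha(k-mer at its cut site) instead of 1 to the
pileup, so over-cut sequences are down-weighted and under-cut sequences
up-weighted; per-k-mer corrected mass is exactly proportional to genomic
frequency by construction.

K-mers never observed get alpha = 0: the value is never consulted, since no
read can look it up. K-mers observed but with zero expected count cannot
arise when both tallies come from the same seqtable; they get alpha = 1 with
a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .masks import SENTINEL, KmerMask
from .reads import ReadFilters, as_events
from .seqtable import SeqTable
from .tabulate import KmerCountTable


@dataclass
class ScaleFactors:
    mask: KmerMask
    alpha_plus: np.ndarray
    alpha_minus: np.ndarray
    M_plus: int
    M_minus: int
    n_observed_plus: int
    n_observed_minus: int
    undefined_plus: np.ndarray = None  # expected>0 but never observed
    undefined_minus: np.ndarray = None


def compute_scale_factors(counts: KmerCountTable) -> ScaleFactors:
    """Per-strand alpha(j) from a 6-column counts table."""
    if counts.observed_plus is None:
        raise ValueError("counts table lacks observed read counts")
    if counts.n_observed == 0:
        raise ValueError("no observed reads; scale factors undefined")
    alphas, undefined = [], []
    for exp, obs, M, N in (
        (counts.expected_plus, counts.observed_plus,
         counts.M_plus, counts.n_observed_plus),
        (counts.expected_minus, counts.observed_minus,
         counts.M_minus, counts.n_observed_minus),
    ):
        alpha = np.zeros(len(exp), dtype=np.float64)
        seen = obs > 0
        if N > 0 and M > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha[seen] = (exp[seen] / M) / (obs[seen] / N)
        impossible = seen & (exp == 0)
        if impossible.any():
            warnings.warn(
                f"{int(impossible.sum())} k-mer(s) observed but absent from the "
                "genomic tally; alpha set to 1 (counts likely from mismatched tables)"
            )
            alpha[impossible] = 1.0
        alphas.append(alpha)
        undefined.append((exp > 0) & ~seen)
    return ScaleFactors(
        mask=counts.mask,
        alpha_plus=alphas[0], alpha_minus=alphas[1],
        M_plus=counts.M_plus, M_minus=counts.M_minus,
        n_observed_plus=counts.n_observed_plus,
        n_observed_minus=counts.n_observed_minus,
        undefined_plus=undefined[0], undefined_minus=undefined[1],
    )


@dataclass
class ScaledPileup:
    """Per-contig, per-strand corrected read intensities (dense vectors)."""

    contigs: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (plus, minus)

    def merged(self, contig: str) -> np.ndarray:
        plus, minus = self.contigs[contig]
        return plus + minus

    def total_mass(self) -> float:
        return float(sum(p.sum() + m.sum() for p, m in self.contigs.values()))

    def nonzero(self, merged: bool = True):
        """Yield (contig, position, value[, strand]) for nonzero bases."""
        for name in self.contigs:
            if merged:
                v = self.merged(name)
                for pos in np.flatnonzero(v):
                    yield name, int(pos), float(v[pos])
            else:
                for strand, v in zip("+-", self.contigs[name]):
                    for pos in np.flatnonzero(v):
                        yield name, int(pos), float(v[pos]), strand


def scale_reads(table: SeqTable, reads, factors: ScaleFactors | None,
                shift_counts: bool = False, tail_edge: bool = False,
                no_scale: bool = False,
                filters: ReadFilters | None = None) -> ScaledPileup:
    """Accumulate the corrected (or raw) per-base pileup.

    Each passing read adds alpha(j) — or 1.0 under ``no_scale`` — at its cut
    coordinate on its strand. With ``shift_counts`` the minus-strand
    contribution is placed at the +1-shifted (plus-matched) coordinate so
    both sides of one nick pile up together; without it, at the unshifted
    5' (or tail-edge) coordinate. Reads hitting sentinel entries are dropped
    either way.
    """
    if not no_scale and factors is None:
        raise ValueError("factors required unless no_scale is set")
    if factors is not None and factors.mask.mask != table.mask.mask:
        raise ConfigError(
            f"scale factors mask {factors.mask.mask!r} != seqtable mask "
            f"{table.mask.mask!r}"
        )
    events = as_events(reads, filters=filters, tail_edge=tail_edge)
    contigs = {}
    for name, (plus_vec, minus_vec) in table.contigs.items():
        n_contig = len(plus_vec)
        plus_out = np.zeros(n_contig, dtype=np.float64)
        minus_out = np.zeros(n_contig, dtype=np.float64)
        if name not in events.contigs:
            contigs[name] = (plus_out, minus_out)
            continue
        pos, is_minus = events.contigs[name]
        for minus_strand, vec, out in (
            (False, plus_vec, plus_out), (True, minus_vec, minus_out)
        ):
            p = pos[is_minus == minus_strand]
            lookup = p + 1 if minus_strand else p
            ok = (lookup >= 0) & (lookup < n_contig)
            p, lookup = p[ok], lookup[ok]
            entries = vec[lookup]
            valid = entries != SENTINEL
            p, lookup, entries = p[valid], lookup[valid], entries[valid]
            if no_scale:
                weights = np.ones(len(entries))
            else:
                alpha = factors.alpha_minus if minus_strand else factors.alpha_plus
                weights = alpha[entries.astype(np.int64)]
            dest = lookup if (minus_strand and shift_counts) else p
            np.add.at(out, dest, weights)
        contigs[name] = (plus_out, minus_out)
    return ScaledPileup(contigs=contigs)


# -- track output -----------------------------------------------------------


def _format_value(x: float) -> str:
    return f"{x:.6g}"


def write_bedgraph(pileup: ScaledPileup, path, separate_strands: bool = False):
    """bedGraph with one line per nonzero base (strands merged by default)."""
    paths = []
    if separate_strands:
        base = str(path)
        for strand, suffix in (("+", ".plus"), ("-", ".minus")):
            spath = base + suffix if not base.endswith(".bedgraph") else \
                base[: -len(".bedgraph")] + suffix + ".bedgraph"
            with open(spath, "w") as fh:
                for name in pileup.contigs:
                    v = pileup.contigs[name][0 if strand == "+" else 1]
                    for pos in np.flatnonzero(v):
                        fh.write(f"{name}\t{pos}\t{pos + 1}\t{_format_value(v[pos])}\n")
            paths.append(spath)
        return paths
    with open(path, "w") as fh:
        for name, pos, value in pileup.nonzero(merged=True):
            fh.write(f"{name}\t{pos}\t{pos + 1}\t{_format_value(value)}\n")
    return [str(path)]


def write_bed(pileup: ScaledPileup, path, separate_strands: bool = False):
    """BED6 with one interval per nonzero base, score = intensity."""
    with open(path, "w") as fh:
        if separate_strands:
            for name, pos, value, strand in pileup.nonzero(merged=False):
                fh.write(f"{name}\t{pos}\t{pos + 1}\t.\t{_format_value(value)}\t{strand}\n")
        else:
            for name, pos, value in pileup.nonzero(merged=True):
                fh.write(f"{name}\t{pos}\t{pos + 1}\t.\t{_format_value(value)}\t.\n")


def write_bigwig(pileup: ScaledPileup, chrom_sizes: dict[str, int], path,
                 strand: str | None = None):
    """bigWig of the merged (or single-strand) pileup via pyBigWig."""
    import pyBigWig

    for name in pileup.contigs:
        if name not in chrom_sizes:
            raise ValueError(f"contig {name!r} absent from chrom sizes")
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(name, int(size)) for name, size in chrom_sizes.items()])
    for name in pileup.contigs:
        if strand == "+":
            v = pileup.contigs[name][0]
        elif strand == "-":
            v = pileup.contigs[name][1]
        else:
            v = pileup.merged(name)
        idx = np.flatnonzero(v)
        if len(idx) == 0:
            continue
        bw.addEntries(
            [name] * len(idx),
            [int(i) for i in idx],
            ends=[int(i) + 1 for i in idx],
            values=[float(v[i]) for i in idx],
        )
    bw.close()


def write_tracks(pileup: ScaledPileup, chrom_sizes: dict[str, int],
                 bed_path=None, bedgraph_path=None, bigwig_path=None,
                 separate_strands: bool = False):
    """Write any of BED / bedGraph / bigWig for one pileup."""
    if bed_path is not None:
        write_bed(pileup, bed_path, separate_strands=separate_strands)
    if bedgraph_path is not None:
        write_bedgraph(pileup, bedgraph_path, separate_strands=separate_strands)
    if bigwig_path is not None:
        if separate_strands:
            base = str(bigwig_path)
            stem = base[:-3] if base.endswith(".bw") else base
            write_bigwig(pileup, chrom_sizes, stem + ".plus.bw", strand="+")
            write_bigwig(pileup, chrom_sizes, stem + ".minus.bw", strand="-")
        else:
            write_bigwig(pileup, chrom_sizes, bigwig_path)


def merge_bedgraphs(paths, out_path):
    """Sum single-base bedGraph tracks (convenience for two-mask ATAC runs)."""
    acc: dict[tuple, float] = {}
    for path in paths:
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                contig, start, end, value = line.split("\t")
                key = (contig, int(start), int(end))
                acc[key] = acc.get(key, 0.0) + float(value)
    with open(out_path, "w") as fh:
        for (contig, start, end) in sorted(acc):
            fh.write(f"{contig}\t{start}\t{end}\t{_format_value(acc[(contig, start, end)])}\n")
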