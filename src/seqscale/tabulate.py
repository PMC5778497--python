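"""Tallying expected (genomic) and observed (aligned-read) k-mer counts.

The expected count of k-mer *j* on a strand is the number of mappable genome
positions whose seqtable entry is *j* — the frequency at which an unbiased
enzyme would generate reads carrying that k-mer. The observed count is the
number of filter-passing aligned reads whose cut coordinate holds entry *j*.
These two tallies are the numerator and denominator of the per-k-mer scale
factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FileFormatError
from .masks import SENTINEL, KmerMask
from .reads import ReadEvents, ReadFilters, as_events
from .seqtable import SeqTable
from .seqio import kmer_to_string


@dataclass
class KmerCountTable:
    """Expected and observed per-k-mer per-strand counts.

    ``n_observed`` is the total number of reads tallied (both strands);
    per-strand observed totals are available as ``n_observed_plus/minus``.
    """

    mask: KmerMask
    read_length: int
    expected_plus: np.ndarray
    expected_minus: np.ndarray
    observed_plus: np.ndarray | None = None
    observed_minus: np.ndarray | None = None
    n_skipped: int = 0  # reads hitting sentinel entries or missing contigs

    @property
    def n_kmers(self) -> int:
        return len(self.expected_plus)

    @property
    def M_plus(self) -> int:
        return int(self.expected_plus.sum())

    @property
    def M_minus(self) -> int:
        return int(self.expected_minus.sum())

    @property
    def n_observed_plus(self) -> int:
        return int(self.observed_plus.sum()) if self.observed_plus is not None else 0

    @property
    def n_observed_minus(self) -> int:
        return int(self.observed_minus.sum()) if self.observed_minus is not None else 0

    @property
    def n_observed(self) -> int:
        return self.n_observed_plus + self.n_observed_minus

    def kmer_strings(self) -> list[str]:
        k = self.mask.kmer_size
        return [kmer_to_string(j, k) for j in range(self.n_kmers)]


def _region_selectors(table: SeqTable, regions):
    """Per-contig boolean vectors from 0-based half-open intervals."""
    sel = {name: np.zeros(len(plus), dtype=bool)
           for name, (plus, _) in table.contigs.items()}
    for row in regions:
        contig, start, end = row[0], int(row[1]), int(row[2])
        if contig not in sel:
            warnings.warn(f"region contig {contig!r} absent from seqtable; skipped")
            continue
        sel[contig][max(start, 0): end] = True
    return sel


def count_expected(table: SeqTable, regions=None):
    """Tally non-sentinel seqtable entries per strand (optionally within regions)."""
    nk = table.n_kmers
    exp_plus = np.zeros(nk, dtype=np.int64)
    exp_minus = np.zeros(nk, dtype=np.int64)
    sel = _region_selectors(table, regions) if regions is not None else None
    for name, (plus, minus) in table.contigs.items():
        for vec, out in ((plus, exp_plus), (minus, exp_minus)):
            v = vec[sel[name]] if sel is not None else vec
            v = v[v != SENTINEL]
            if len(v):
                out += np.bincount(v.astype(np.int64), minlength=nk)
    return exp_plus, exp_minus


def count_observed(table: SeqTable, reads, filters: ReadFilters | None = None,
                   tail_edge: bool = False):
    """Tally the seqtable entries at the cut coordinates of aligned reads.

    ``reads`` may be a BAM/SAM path or pre-distilled :class:`ReadEvents`.
    Minus-strand reads use the +1-shifted entry (stored at the plus-matched
    nick coordinate). Returns (observed_plus, observed_minus, n_skipped)
    where skipped reads are those hitting sentinel entries, unknown contigs,
    or coordinates outside the contig.
    """
    events = as_events(reads, filters=filters, tail_edge=tail_edge)
    nk = table.n_kmers
    obs_plus = np.zeros(nk, dtype=np.int64)
    obs_minus = np.zeros(nk, dtype=np.int64)
    skipped = 0
    for name, (pos, is_minus) in events.contigs.items():
        if name not in table.contigs:
            warnings.warn(f"reads on contig {name!r} absent from seqtable; skipped")
            skipped += len(pos)
            continue
        plus_vec, minus_vec = table.contigs[name]
        n_contig = len(plus_vec)
        for minus_strand, vec in ((False, plus_vec), (True, minus_vec)):
            p = pos[is_minus == minus_strand]
            if minus_strand:
                p = p + 1  # +1 shift: entry stored at the nick coordinate
            ok = (p >= 0) & (p < n_contig)
            skipped += int((~ok).sum())
            entries = vec[p[ok]]
            valid = entries != SENTINEL
            skipped += int((~valid).sum())
            entries = entries[valid].astype(np.int64)
            if len(entries):
                target = obs_minus if minus_strand else obs_plus
                target += np.bincount(entries, minlength=nk)
    return obs_plus, obs_minus, skipped


def build_counts(table: SeqTable, reads=None, regions=None,
                 filters: ReadFilters | None = None,
                 tail_edge: bool = False,
                 restrict_observed: bool = False) -> KmerCountTable:
    """Assemble a :class:`KmerCountTable` from a seqtable and optional reads.

    Region restriction applies to the expected (genomic) tally only — its
    purpose is to exclude, e.g., inaccessible chromatin from the genomic
    k-mer census; set ``restrict_observed`` to also drop reads outside the
    regions for symmetry.
    """
    exp_plus, exp_minus = count_expected(table, regions=regions)
    counts = KmerCountTable(
        mask=table.mask, read_length=table.read_length,
        expected_plus=exp_plus, expected_minus=exp_minus,
    )
    if reads is not None:
        events = as_events(reads, filters=filters, tail_edge=tail_edge)
        if restrict_observed and regions is not None:
            sel = _region_selectors(table, regions)
            kept = {}
            for name, (pos, is_minus) in events.contigs.items():
                if name not in sel:
                    continue
                inside = (pos >= 0) & (pos < len(sel[name]))
                inside[inside] = sel[name][pos[inside]]
                kept[name] = (pos[inside], is_minus[inside])
            events = ReadEvents(contigs=kept)
        obs_plus, obs_minus, skipped = count_observed(table, events)
        counts.observed_plus = obs_plus
        counts.observed_minus = obs_minus
        counts.n_skipped = skipped
    return counts


# -- TSV serialization ------------------------------------------------------


def write_counts_table(counts: KmerCountTable, path,
                       with_observed: bool | None = None) -> None:
    """Write the tab-separated counts table.

    Four columns (k-mer index, k-mer string, plus count, minus count)
    without read data; six (two extra observed columns) with. A comment
    header records mask and read length so the table round-trips.
    """
    if with_observed is None:
        with_observed = counts.observed_plus is not None
    if with_observed and counts.observed_plus is None:
        raise ValueError("counts table has no observed counts")
    cols = {
        "index": np.arange(counts.n_kmers),
        "kmer": counts.kmer_strings(),
        "expected_plus": counts.expected_plus,
        "expected_minus": counts.expected_minus,
    }
    if with_observed:
        cols["observed_plus"] = counts.observed_plus
        cols["observed_minus"] = counts.observed_minus
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"#mask={counts.mask.mask}\tread_length={counts.read_length}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_counts_table(path) -> KmerCountTable:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#mask="):
            raise FileFormatError(f"{path}: missing counts-table header")
        fields = dict(part.split("=", 1) for part in header[1:].split("\t"))
        mask = KmerMask(fields["mask"])
        read_length = int(fields["read_length"])
        df = pd.read_csv(fh, sep="\t", header=None)
    if df.shape[1] not in (4, 6):
        raise FileFormatError(
            f"{path}: expected 4 or 6 columns, found {df.shape[1]}"
        )
    nk = 4 ** mask.kmer_size
    if len(df) != nk or not (df[0].values == np.arange(nk)).all():
        raise FileFormatError(f"{path}: k-mer index column inconsistent with mask")
    counts = KmerCountTable(
        mask=mask, read_length=read_length,
        expected_plus=df[2].to_numpy(np.int64),
        expected_minus=df[3].to_numpy(np.int64),
    )
    if df.shape[1] == 6:
        counts.observed_plus = df[4].to_numpy(np.int64)
        counts.observed_minus = df[5].to_numpy(np.int64)
    return counts
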