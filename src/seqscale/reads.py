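"""Distillation of aligned reads into cut events.

Every sequenced read reports a single enzymatic event at one genomic
coordinate: its 5' end by default, or its 3' end under the tail-edge
convention (used for run-on assays where the polymerase position is the 3'
end of the nascent RNA). For a minus-strand read the 5' end is the rightmost
aligned base and the 3' end (tail edge) the leftmost.

:class:`ReadEvents` is the canonical in-memory form — per-contig coordinate
and strand arrays — produced either from a BAM file (via pysam) or directly
by the simulators, so the tallying and scaling code never touches alignment
records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ReadFilters:
    """Read-level filters applied when distilling a BAM file.

    Defaults exclude unmapped, secondary, supplementary, duplicate-flagged
    and QC-fail records; no mapping-quality floor is applied by default.
    With ``first_mate_only`` each properly-paired fragment contributes only
    its first mate; by default each sequenced end reports its own cut event.
    """

    min_mapq: int = 0
    exclude_duplicates: bool = True
    exclude_qcfail: bool = True
    first_mate_only: bool = False

    def passes(self, read) -> bool:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if self.first_mate_only and read.is_paired and read.is_read2:
            return False
        return True


@dataclass
class AlignedReadEvent:
    """One distilled cut event (mostly for tests and tracing)."""

    contig: str
    cut: int
    strand: str  # '+' or '-'
    passes_filters: bool = True


@dataclass
class ReadEvents:
    """Per-contig arrays of cut coordinates and strand flags."""

    contigs: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    # name -> (pos int64, minus bool); pos is the 5' (or tail-edge) coordinate

    @property
    def n_total(self) -> int:
        return sum(len(pos) for pos, _ in self.contigs.values())

    @classmethod
    def from_events(cls, events) -> "ReadEvents":
        by_contig: dict[str, list] = {}
        for ev in events:
            if not ev.passes_filters:
                continue
            by_contig.setdefault(ev.contig, []).append((ev.cut, ev.strand == "-"))
        contigs = {}
        for name, rows in by_contig.items():
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            minus = np.array([r[1] for r in rows], dtype=bool)
            contigs[name] = (pos, minus)
        return cls(contigs=contigs)

    def subset(self, contig: str, mask: np.ndarray) -> "ReadEvents":
        pos, minus = self.contigs[contig]
        return ReadEvents({contig: (pos[mask], minus[mask])})


def read_events(bam_path, filters: ReadFilters | None = None,
                tail_edge: bool = False) -> ReadEvents:
    """Distill a sorted BAM/SAM file into :class:`ReadEvents`."""
    import pysam

    filters = filters or ReadFilters()
    by_contig: dict[str, tuple[list, list]] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if not filters.passes(read):
                continue
            if read.is_reverse:
                cut = read.reference_start if tail_edge else read.reference_end - 1
            else:
                cut = read.reference_end - 1 if tail_edge else read.reference_start
            lists = by_contig.setdefault(read.reference_name, ([], []))
            lists[0].append(cut)
            lists[1].append(read.is_reverse)
    contigs = {
        name: (np.array(pos, dtype=np.int64), np.array(minus, dtype=bool))
        for name, (pos, minus) in by_contig.items()
    }
    return ReadEvents(contigs=contigs)


def as_events(reads, filters: ReadFilters | None = None,
              tail_edge: bool = False) -> ReadEvents:
    """Accept a BAM/SAM path, a ReadEvents, or an AlignedReadEvent iterable."""
    if isinstance(reads, ReadEvents):
        if tail_edge:
            warnings.warn("tail_edge ignored: events already carry their coordinates")
        return reads
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        return read_events(reads, filters=filters, tail_edge=tail_edge)
    return ReadEvents.from_events(reads)
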