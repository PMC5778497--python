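"""Hill-climbing k-mer mask optimization driven by composite-profile flatness.

The alternative, assumption-light way to choose a mask: evaluate how flat a
candidate mask leaves the corrected composite profiles at sets of
transcription-factor binding sites. The composite profile of a TF is the
position-wise sum of scaled read counts across its (motif-oriented) sites;
the metric

    M_T(m) = sum_t sd( G_t(m) )

is the sum over TFs of the sample standard deviation (denominator N-1) of
the profile. Starting from a mask of all X (no correction), the search
greedily unmasks the single X whose conversion to N minimizes M_T, ties
broken toward the lowest position index, until no X remains; the full
trajectory is returned so the user can pick a complexity cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mappability import MappabilityTrack, compute_mappability
from .masks import KmerMask
from .reads import ReadFilters, as_events
from .scale import ScaledPileup, compute_scale_factors, scale_reads
from .seqtable import build_seqtable
from .tabulate import build_counts


@dataclass
class SiteSet:
    """Uniform-width motif-anchored binding sites for one TF."""

    label: str
    sites: list[tuple]  # (contig, start, end, strand)

    def __post_init__(self):
        widths = {end - start for _, start, end, _ in self.sites}
        if len(widths) > 1:
            raise ValueError(f"site set {self.label!r} has mixed widths: {widths}")
        strands = {s for *_, s in self.sites}
        if not strands <= {"+", "-"}:
            raise ValueError(f"invalid strand value(s) in {self.label!r}: {strands}")

    @property
    def width(self) -> int:
        return self.sites[0][2] - self.sites[0][1] if self.sites else 0

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "SiteSet":
        from .seqio import read_bed

        rows = read_bed(path)
        sites = []
        for row in rows:
            strand = row[5] if len(row) > 5 else "+"
            sites.append((row[0], int(row[1]), int(row[2]), strand))
        return cls(label=label or str(path), sites=sites)


@dataclass
class CompositeProfile:
    """Position-wise sum of scaled read counts across a site set."""

    label: str
    g: np.ndarray                      # length = site width
    per_site: np.ndarray | None = None  # optional (n_sites, width) matrix


def composite_profile(pileup: ScaledPileup, sites: SiteSet,
                      keep_matrix: bool = False) -> CompositeProfile:
    """Sum the merged-strand pileup over motif-oriented site windows.

    Minus-strand sites are read right-to-left so every row is in motif
    orientation; out-of-bounds sites are skipped with a warning.
    """
    width = sites.width
    g = np.zeros(width)
    rows = [] if keep_matrix else None
    merged = {name: pileup.merged(name) for name in pileup.contigs}
    for contig, start, end, strand in sites.sites:
        if contig not in merged or start < 0 or end > len(merged[contig]):
            warnings.warn(f"site {contig}:{start}-{end} out of bounds; skipped")
            continue
        window = merged[contig][start:end]
        if strand == "-":
            window = window[::-1]
        g += window
        if rows is not None:
            rows.append(window)
    return CompositeProfile(
        label=sites.label, g=g,
        per_site=np.array(rows) if rows is not None else None,
    )


def profile_metric(profiles) -> float:
    """Sum over TFs of the sample standard deviation of the composite profile."""
    total = 0.0
    for prof in profiles:
        g = prof.g if isinstance(prof, CompositeProfile) else np.asarray(prof)
        if len(g) < 2:
            raise ValueError("profile length must be >= 2 for a standard deviation")
        total += float(np.std(g, ddof=1))
    return total


@dataclass
class HillClimbStep:
    mask: str
    metric: float
    unmasked_position: int | None  # index in the mask string; None for the start


@dataclass
class HillClimbTrajectory:
    steps: list[HillClimbStep] = field(default_factory=list)

    @property
    def final_mask(self) -> str:
        return self.steps[-1].mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.mask, s.metric, s.unmasked_position) for s in self.steps],
            columns=["mask", "metric", "unmasked_position"],
        )


class MaskEvaluator:
    """Shared-state evaluator: one full tabulate+scale+profile pass per mask.

    Mappability and the distilled read events are computed once; per-mask
    results are cached by mask string, so re-examined neighbors are free.
    """

    def __init__(self, genome, reads, read_length, site_sets,
                 mappability: MappabilityTrack | None = None,
                 regions=None, shift_counts: bool = False,
                 filters: ReadFilters | None = None, tail_edge: bool = False):
        self.genome = genome
        self.events = as_events(reads, filters=filters, tail_edge=tail_edge)
        self.site_sets = list(site_sets)
        if not self.site_sets:
            raise ValueError("at least one site set required")
        self.mappability = mappability or compute_mappability(genome, read_length)
        self.regions = regions
        self.shift_counts = shift_counts
        self._cache: dict[str, float] = {}

    def pileup(self, mask: KmerMask) -> ScaledPileup:
        table = build_seqtable(self.genome, self.mappability, mask)
        counts = build_counts(table, self.events, regions=self.regions)
        factors = compute_scale_factors(counts)
        return scale_reads(table, self.events, factors,
                           shift_counts=self.shift_counts)

    def metric(self, mask_str: str) -> float:
        if mask_str not in self._cache:
            pileup = self.pileup(KmerMask(mask_str))
            profiles = [composite_profile(pileup, s) for s in self.site_sets]
            self._cache[mask_str] = profile_metric(profiles)
        return self._cache[mask_str]


def neighbors(mask_str: str) -> list[tuple[int, str]]:
    """All masks one X→N unmasking away, as (position, mask) pairs."""
    out = []
    for i, ch in enumerate(mask_str):
        if ch == "X":
            out.append((i, mask_str[:i] + "N" + mask_str[i + 1 :]))
    return out


def hill_climb(start_mask, site_sets, genome, reads, read_length,
               mappability: MappabilityTrack | None = None,
               regions=None, shift_counts: bool = False,
               filters: ReadFilters | None = None,
               tail_edge: bool = False,
               evaluator: MaskEvaluator | None = None) -> HillClimbTrajectory:
    """Greedy mask search: repeatedly unmask the X that minimizes M_T.

    ``start_mask`` may be all-X (plus the C cut marker) for a search over
    the full span. The trajectory records every accepted mask with its
    metric and the position unmasked; the final mask is all-N. Ties go to
    the lowest position index, making runs deterministic.
    """
    if isinstance(start_mask, KmerMask):
        start_mask = start_mask.mask
    KmerMask(start_mask)  # validates grammar (zero N allowed for the start)
    ev = evaluator or MaskEvaluator(
        genome, reads, read_length, site_sets, mappability=mappability,
        regions=regions, shift_counts=shift_counts, filters=filters,
        tail_edge=tail_edge,
    )
    current = start_mask
    steps = [HillClimbStep(current, ev.metric(current), None)]
    while "X" in current:
        scored = [(ev.metric(m), i, m) for i, m in neighbors(current)]
        best_metric, best_pos, best_mask = min(scored)  # ties -> lowest index
        current = best_mask
        steps.append(HillClimbStep(current, best_metric, best_pos))
    return HillClimbTrajectory(steps=steps)


def exhaustive_masks(span: int, cut_position: int) -> list[str]:
    """Every N/X mask over a span (2^span masks) with C at ``cut_position``."""
    out = []
    for bits in range(2 ** span):
        chars = ["N" if bits & (1 << (span - 1 - i)) else "X" for i in range(span)]
        chars.insert(cut_position, "C")
        out.append("".join(chars))
    return out
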