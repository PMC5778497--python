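"""Synthetic fixtures: random genomes, enzyme-biased cut simulations, motif sites.

The simulator inverts the correction model: nick positions are drawn with
probability proportional to a per-k-mer cut weight evaluated on the
plus-strand k-mer at the nick (so observed counts ~ genomic count x weight),
and the detected strand of each nick is drawn from a detection model
(constant 1/2, or logistic in a chosen base near the nick, emulating
end-repair/ligation bias). Reads are emitted as perfect, error-free
alignments, and a truth table records every nick's position, k-mer and
detected strand, so downstream estimates can be checked against known
ground truth. High-entropy random genomes keep mappability ~1, isolating
bias effects from mappability effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .masks import SENTINEL, KmerMask, plus_kmer_indices
from .reads import ReadEvents
from .seqio import encode_sequence, kmer_to_string

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(length: int, gc_fraction: float = 0.5,
                    seed=None) -> str:
    """I.i.d. random DNA with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p)
    return BASES[codes].tobytes().decode("ascii")


# -- detection models -------------------------------------------------------


@dataclass
class ConstantDetection:
    """Each nick is detected on the plus strand with fixed probability.

    ``p_plus = 1`` models single-sided assays where only the downstream
    fragment is ever sequenced.
    """

    p_plus: float = 0.5

    def __post_init__(self):
        if not 0 < self.p_plus <= 1:
            raise ValueError("p_plus must be in (0, 1]")

    def probabilities(self, codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        return np.full(len(positions), self.p_plus)


@dataclass
class LogisticDetection:
    """Plus-detection probability logistic in the presence of one base.

    ``offset`` is relative to the nick coordinate p (0 = first downstream
    base, -1 = last upstream base); the logit is ``intercept + coef`` when
    ``genome[p + offset] == base``, else ``intercept``.
    """

    offset: int = 0
    base: str = "A"
    coef: float = 1.0
    intercept: float = 0.0

    def probabilities(self, codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        target = "ACGT".index(self.base)
        hit = codes[positions + self.offset] == target
        return expit(self.intercept + self.coef * hit)

    def log_odds(self, has_base: bool) -> float:
        return self.intercept + (self.coef if has_base else 0.0)


@dataclass
class BiasModel:
    """Generative enzyme model: per-k-mer cut weights plus a detection model."""

    mask: KmerMask
    weights: np.ndarray  # length 4**kmer_size, positive
    detection: object = field(default_factory=ConstantDetection)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != 4 ** self.mask.kmer_size:
            raise ValueError("weights length must be 4**kmer_size")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")

    @classmethod
    def uniform(cls, mask: KmerMask, detection=None) -> "BiasModel":
        return cls(mask, np.ones(4 ** mask.kmer_size),
                   detection=detection or ConstantDetection())

    @classmethod
    def lognormal(cls, mask: KmerMask, sigma: float = 0.75, seed=None,
                  detection=None) -> "BiasModel":
        """Weights drawn log-normal(0, sigma) — a realistic spread of
        per-k-mer enzyme preference (~20-fold 95% range at sigma 0.75)."""
        rng = np.random.default_rng(seed)
        w = rng.lognormal(mean=0.0, sigma=sigma, size=4 ** mask.kmer_size)
        return cls(mask, w, detection=detection or ConstantDetection())

    @classmethod
    def from_pswm(cls, mask: KmerMask, theta: np.ndarray,
                  detection=None) -> "BiasModel":
        """Multiplicative weights from a PSWM over the mask's N positions."""
        theta = np.asarray(theta, dtype=np.float64)
        k = mask.kmer_size
        if theta.shape != (k, 4):
            raise ValueError(f"theta must be ({k}, 4)")
        w = np.ones(4 ** k)
        for j in range(k):
            digit = (np.arange(4 ** k) >> (2 * (k - 1 - j))) & 3
            w *= theta[j, digit] * 4.0  # x4: uniform theta -> uniform weights
        return cls(mask, w, detection=detection or ConstantDetection())


def simulate_cuts(genome: dict[str, str] | str, model: BiasModel, n_reads: int,
                  read_length: int, seed=None):
    """Draw biased nick events; returns (ReadEvents, truth DataFrame).

    Candidate nicks are restricted so both the plus and the minus read of
    the nick fit inside the contig (no edge effects). A plus detection
    yields a read starting at the nick coordinate p; a minus detection a
    read whose 5' base is at p - 1.
    """
    if isinstance(genome, str):
        genome = {"chr1": genome}
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    mask = model.mask
    candidates, cand_weights, cand_contig = [], [], []
    codes_by_contig = {}
    for name, seq in genome.items():
        codes = encode_sequence(seq)
        codes_by_contig[name] = codes
        idx = plus_kmer_indices(codes, mask)
        lo = max(read_length, mask.n_upstream, mask.n_downstream, 1)
        hi = len(seq) - max(read_length, mask.n_upstream, mask.n_downstream)
        if hi < lo:
            continue
        p = np.arange(lo, hi + 1)
        entry = idx[p]
        ok = entry != SENTINEL
        w = np.zeros(len(p))
        w[ok] = model.weights[entry[ok].astype(np.int64)]
        keep = w > 0
        candidates.append(p[keep])
        cand_weights.append(w[keep])
        cand_contig.extend([name] * int(keep.sum()))
    if not candidates:
        raise ValueError("genome too short for the requested read length/mask")
    pos_all = np.concatenate(candidates)
    w_all = np.concatenate(cand_weights)
    if w_all.sum() == 0:
        raise ValueError("all candidate cut weights are zero")
    contig_all = np.array(cand_contig)
    draw = rng.choice(len(pos_all), size=n_reads, p=w_all / w_all.sum())
    contigs_out: dict[str, tuple] = {}
    truth_frames = []
    for name in genome:
        sel = draw[contig_all[draw] == name]
        if len(sel) == 0:
            continue
        p = pos_all[sel]
        codes = codes_by_contig[name]
        p_plus = model.detection.probabilities(codes, p)
        minus = rng.random(len(p)) >= p_plus
        cut = np.where(minus, p - 1, p)  # 5'-base coordinate of the read
        order = np.argsort(cut, kind="stable")
        contigs_out[name] = (cut[order].astype(np.int64), minus[order])
        idx = plus_kmer_indices(codes, mask)
        truth_frames.append(pd.DataFrame({
            "contig": name,
            "nick": p[order],
            "kmer": [kmer_to_string(int(idx[x]), mask.kmer_size) for x in p[order]],
            "strand": np.where(minus[order], "-", "+"),
        }))
    events = ReadEvents(contigs=contigs_out)
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames \
        else pd.DataFrame(columns=["contig", "nick", "kmer", "strand"])
    return events, truth


def write_events_bam(events: ReadEvents, genome: dict[str, str],
                     read_length: int, bam_path) -> None:
    """Emit events as a sorted, indexed BAM of perfect alignments."""
    import pysam

    names = list(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(genome[n])} for n in names],
    }
    records = []
    for name, (pos, minus) in events.contigs.items():
        tid = names.index(name)
        for p, m in zip(pos, minus):
            start = int(p) - read_length + 1 if m else int(p)
            records.append((tid, start, bool(m)))
    records.sort()
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for i, (tid, start, is_minus) in enumerate(records):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"sim{i}"
            a.reference_id = tid
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.flag = 16 if is_minus else 0
            seq = genome[names[tid]][start : start + read_length]
            a.query_sequence = seq  # stored plus-strand, as SAM requires
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            bam.write(a)
    pysam.index(str(bam_path))


def simulate_biased_reads(genome: dict[str, str] | str, model: BiasModel,
                          n_reads: int, read_length: int, seed=None,
                          bam_path=None, truth_path=None):
    """Simulate biased cuts and optionally write BAM + truth TSV."""
    if isinstance(genome, str):
        genome = {"chr1": genome}
    events, truth = simulate_cuts(genome, model, n_reads, read_length, seed=seed)
    if bam_path is not None:
        write_events_bam(events, genome, read_length, bam_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return events, truth


def motif_sites(genome: dict[str, str] | str, motif: str,
                both_strands: bool = True):
    """All exact-match sites of a motif, as (contig, start, end, strand) rows.

    Reverse-complement matches are reported with strand '-'; a palindromic
    motif with ``both_strands`` is reported once per strand at each locus.
    """
    from .seqio import revcomp

    if isinstance(genome, str):
        genome = {"chr1": genome}
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT: {motif!r}")
    sites = []
    targets = [(motif, "+")]
    if both_strands:
        targets.append((revcomp(motif), "-"))
    for name, seq in genome.items():
        for target, strand in targets:
            start = seq.find(target)
            while start != -1:
                sites.append((name, start, start + len(motif), strand))
                start = seq.find(target, start + 1)
    sites.sort()
    return sites
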