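"""EM inference of the enzyme cut-site PSWM from k-mer counts.

The enzyme's cut bias is modelled as a position-specific weight matrix
(PSWM) theta = {p_{j,b}} of length K over the sequence surrounding the cut
site. Each observed k-mer x_i (with count n_i) is a cut site read in an
unknown orientation z_i: forward draws base x_{i,j} from column j, reverse
draws it from the complement of column K-j+1 — i.e. the reverse orientation
emits the reverse complement of x_i from theta. With per-k-mer orientation
priors gamma_i, the marginal likelihood of one k-mer is

    P(x_i) = gamma_i * prod_j p_{j, x_ij}  +  (1-gamma_i) * prod_j p_{j, rc(x_i)_j}

EM alternates the posterior of z_i (E-step) with closed-form updates of
gamma and theta (M-step); theta's sufficient statistics receive a
pseudo-count of 0.1 per cell. Because EM only finds local optima, the fit is
restarted from multiple random initializations and the best final
log-likelihood wins.

The fitted PSWM is turned into spaced k-mer masks by thresholding the
per-position information content, IC_j = 2 + sum_b p_{j,b} log2 p_{j,b}
(bits, uniform background): positions below threshold become X. Since read
orientation is unknown downstream, the forward mask is unioned with its own
reverse — a position stays N if it is N in either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import MaskGrammarError
from .masks import KmerMask
from .seqio import encode_sequence

_PSEUDO_COUNT = 0.1


@dataclass
class CutSitePSWM:
    """Result of one EM fit (best restart)."""

    theta: np.ndarray              # (K, 4) column-stochastic rows
    gamma: np.ndarray              # per input k-mer P(Z_i = fwd)
    log_likelihood: float
    ll_history: np.ndarray         # per-iteration marginal log-likelihood
    n_restarts: int
    n_iterations: int
    converged: bool
    seed: int | None = None
    kmers: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.theta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, columns=list("ACGT"),
                            index=np.arange(1, self.K + 1))


def _encode_kmers(kmers):
    seqs, counts = [], []
    for seq, n in kmers:
        if n < 1:
            raise ValueError(f"k-mer count must be >= 1 (got {n} for {seq!r})")
        seqs.append(seq)
        counts.append(float(n))
    if not seqs:
        raise ValueError("no k-mers supplied")
    K = len(seqs[0])
    if K == 0:
        raise ValueError("zero-length k-mers")
    X = np.empty((len(seqs), K), dtype=np.int64)
    for i, seq in enumerate(seqs):
        if len(seq) != K:
            raise ValueError(f"k-mer length mismatch: {seq!r} vs K={K}")
        codes = encode_sequence(seq)
        if (codes < 0).any():
            raise ValueError(f"ambiguous base in k-mer {seq!r}")
        X[i] = codes
    return seqs, X, np.asarray(counts)


def _row_loglik(logtheta: np.ndarray, X: np.ndarray) -> np.ndarray:
    K = X.shape[1]
    return logtheta[np.arange(K), X].sum(axis=1)


def _em_single(X, counts, theta0, max_iter, tol):
    """Run EM from one initialization; returns (theta, gamma, ll_history)."""
    K = X.shape[1]
    Xrc = 3 - X[:, ::-1]  # reverse complement of each k-mer, encoded
    theta = theta0
    gamma = np.full(len(X), 0.5)
    history = []
    with np.errstate(divide="ignore"):
        for _ in range(max_iter):
            logtheta = np.log(theta)
            lf = np.log(gamma) + _row_loglik(logtheta, X)
            lr = np.log1p(-gamma) + _row_loglik(logtheta, Xrc)
            ll = float((counts * np.logaddexp(lf, lr)).sum())
            if history and ll < history[-1] - 1e-9 * (1 + abs(history[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {history[-1]} -> {ll}"
                )
            converged = bool(
                history and abs(ll - history[-1]) <= tol * (1 + abs(history[-1]))
            )
            history.append(ll)
            if converged:
                break
            # E-step: posterior of forward orientation
            post = expit(lf - lr)
            # M-step
            gamma = post
            w_fwd = counts * post
            w_rev = counts * (1.0 - post)
            A = np.full((K, 4), _PSEUDO_COUNT)
            for j in range(K):
                A[j] += np.bincount(X[:, j], weights=w_fwd, minlength=4)
                A[j] += np.bincount(Xrc[:, j], weights=w_rev, minlength=4)
            theta = A / A.sum(axis=1, keepdims=True)
    return theta, gamma, np.array(history), converged


def em_fit(kmers, n_restarts: int = 10, max_iter: int = 500,
           tol: float = 1e-8, seed: int | None = None) -> CutSitePSWM:
    """Fit the cut-site PSWM by EM over unknown k-mer orientations.

    ``kmers`` is an iterable of ``(sequence, count)`` pairs, all the same
    length over ACGT — typically the observed read k-mer counts of a full
    (all-N) counts table. Restarts draw theta rows from Dirichlet(1,1,1,1)
    using per-restart streams spawned from ``seed``, so results are
    reproducible and independent of restart order; the restart with the
    highest final marginal log-likelihood is returned.
    """
    seqs, X, counts = _encode_kmers(kmers)
    K = X.shape[1]
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for stream in streams:
        rng = np.random.default_rng(stream)
        theta0 = rng.dirichlet(np.ones(4), size=K)
        theta, gamma, history, converged = _em_single(
            X, counts, theta0, max_iter, tol
        )
        if best is None or history[-1] > best[2][-1]:
            best = (theta, gamma, history, converged)
    theta, gamma, history, converged = best
    return CutSitePSWM(
        theta=theta, gamma=gamma, log_likelihood=float(history[-1]),
        ll_history=history, n_restarts=n_restarts,
        n_iterations=len(history), converged=converged, seed=seed, kmers=seqs,
    )


def information_content(pswm: CutSitePSWM | np.ndarray) -> np.ndarray:
    """Per-position information content in bits (uniform background).

    IC_j = 2 + sum_b p_{j,b} log2 p_{j,b}; 0 for a uniform column, 2 for a
    deterministic one. Zero probabilities contribute zero (they cannot occur
    after the pseudo-count, but the limit is handled anyway).
    """
    theta = pswm.theta if isinstance(pswm, CutSitePSWM) else np.asarray(pswm)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(theta > 0, theta * np.log2(theta), 0.0)
    return 2.0 + plogp.sum(axis=1)


def mask_from_ic(pswm: CutSitePSWM, threshold: float, cut_position: int) -> KmerMask:
    """Threshold per-position IC into an N/X mask, with the fwd/rev union rule.

    Position j is N iff IC_j >= threshold in the forward orientation OR in
    the reversed one (position K-1-j); the C cut marker is inserted after
    ``cut_position`` mask positions. Sweeping thresholds from high to low
    yields masks of increasing complexity.
    """
    if threshold < 0:
        raise ValueError("IC threshold must be non-negative")
    ic = information_content(pswm)
    K = len(ic)
    if not 0 <= cut_position <= K:
        raise ValueError(f"cut_position must be in 0..{K}")
    fwd = ic >= threshold
    unmasked = fwd | fwd[::-1]
    chars = ["N" if u else "X" for u in unmasked]
    chars.insert(cut_position, "C")
    mask = "".join(chars)
    if unmasked.sum() == 0:
        raise MaskGrammarError(
            f"IC threshold {threshold} leaves an empty mask (no N positions)"
        )
    return KmerMask(mask)


def masks_by_threshold(pswm: CutSitePSWM, thresholds, cut_position: int):
    """One (threshold, mask) pair per attainable threshold, skipping empties."""
    out = []
    for thr in thresholds:
        try:
            out.append((thr, mask_from_ic(pswm, thr, cut_position)))
        except MaskGrammarError:
            continue
    return out
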