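# Methods

## The correction model

Enzymatic accessibility assays report, for every genome position, how often
an enzyme cleaved (or a transposase inserted, or a polymerase stopped)
there. The observed per-base read count `O_{i,j}` at position *i* carrying
cut-site k-mer *j* is modelled as a k-mer-specific rescaling of the true
count: `R_{i,j} = alpha(j) * O_{i,j}`. Requiring that, aggregated over the
genome, true counts be proportional to the number of observable positions
per k-mer gives

```
alpha(j) ≈ [ Σ_m I(m,j) / M ] / [ Σ_i O_{i,j} / N ]
```

where `I(m,j)` indicates that mappable position *m* carries k-mer *j*, `M`
is the number of observable positions, and `N` the number of observed
reads. Both tallies are kept per strand, because mappability (and, for
enzymes like Tn5, the recognition sequence itself) differs between strands;
`alpha` is computed per strand with that strand's `M` and `N`, which makes
the unbiased case (`observed ∝ expected`) yield exactly `alpha = 1` even
when the two strands received different read totals.

Assumptions worth keeping in mind:

* the bias is a *per-read multiplicative* function of the local sequence
  through the chosen mask — no interaction with fragment length, GC-driven
  amplification, or chromatin state;
* reads are assigned to a single cut coordinate (5' end by default, 3' end
  with `tail_edge` for run-on assays);
* k-mers never observed in the library get `alpha = 0`; the value is never
  consulted because no read can look it up, but their genomic mass is
  unrecoverable, so the corrected total mass is `N · Σ_{j observed}
  expected_j / M ≤ N` (equality once every genomic k-mer has been seen).

## Coordinates, strands and the +1 shift

All internal coordinates are 0-based; entry *p* refers to the nick between
bases *p−1* and *p*. A minus-strand read whose 5' base sits at *q* detects
the nick between *q* and *q+1*; its seqtable entry is stored at *q+1*, so
the plus and minus entries of one nick share a coordinate and the tallying
and scaling steps are strand-agnostic. The `shift_counts` output option
then merely chooses whether minus-strand pileup mass is reported at the
shared nick coordinate or at the read's own 5' base. The minus-strand
window is the reverse complement of the plus-strand span, indexed through
the same mask — for a symmetric mask the two entries of one nick are
reverse-complement k-mers.

## Mappability

A position is observable only if a read of the experiment's length starting
there maps uniquely. Uniqueness is exact-match over both strands:
`occurrences(w) = plus_count(w) + plus_count(revcomp(w))`, so palindromic
windows pair with themselves and are never unique. No mismatches are
modelled (the behavior of exact k-mer counting); soft-masked lowercase is
uppercased; windows containing non-ACGT characters are unmappable. The
computation is a single hash tally of all read-length windows, exact at any
read length, and is cached in a run-length-encoded sidecar container that
is reused when up to date.

## Mask grammar

Masks are strings over `{N, X, C}`. `C` marks the nick and consumes no
genomic base (span = len − 1), at most one `C` is allowed and user-facing
parsing requires it, so the cut position is never ambiguous; the
`(kmer-size, plus-offset, minus-offset)` trio builds the equivalent
contiguous mask. K-mer indices are base-4 big-endian over the `N` positions
(A=0, C=1, G=2, T=3), an arbitrary but fixed encoding. The all-`X` mask
(k = 0) is accepted internally as the hill-climb start and means "no
sequence correction" (one k-mer, alpha = 1).

## EM cut-site model

The enzyme's preference is modelled as a PSWM `theta` of length K over the
sequence around the cut. Each observed k-mer `x_i` (count `n_i`) has an
unknown orientation: forward emits `x_{i,j}` from column *j*; reverse emits
the reverse complement of `x_i` from `theta`. With per-k-mer orientation
priors `gamma_i`, EM alternates the orientation posterior (E-step) with
closed-form updates (M-step): `gamma_i` becomes the posterior, and column
counts `A_j(b)` accumulate each k-mer with its forward weight plus its
reverse complement with the complementary weight, plus a pseudo-count of
0.1 per cell before normalization. The reverse-orientation count must be
attributed to the *mirrored* position (equivalently: add the
reverse-complemented k-mer), which is what the complete-data likelihood
dictates and what guarantees the marginal log-likelihood never decreases —
the implementation asserts monotonicity at every iteration.

Numerical choices: rows of `theta` initialized from Dirichlet(1,1,1,1),
`gamma_i = 0.5`; convergence at relative log-likelihood change < 1e-8 or
500 iterations; restarts (default 10) run from independent streams spawned
from one seed, so results are reproducible and restart-order independent;
the best final log-likelihood wins. Input weights are the raw observed
k-mer counts of a full (all-N) table by default; an option accepts
observed/expected ratios instead.

Per-position information content is the standard motif-logo definition
`IC_j = 2 + Σ_b p_{j,b} log2 p_{j,b}` (bits, uniform background). A
threshold turns the PSWM into a mask: position *j* is `N` iff `IC_j ≥ t` in
the forward *or* the reversed profile (the union rule — read orientation is
unknown downstream, so the mask must be usable in both).

**Limitations of the orientation model.** Because each k-mer carries its
own free orientation prior, the likelihood can always count a k-mer in its
more favorable orientation. Two consequences, both verified numerically and
reproduced faithfully here: (i) on *no-signal* (uniform) count tables the
optimum is not the uniform PSWM — the orientation freedom alone buys
likelihood — so IC values fitted from unbiased data are inflated and an IC
threshold should not be interpreted as a significance level; (ii) for
*weakly oriented* true motifs (dominant base per position ≲ 0.9) the global
optimum is a palindromized blend of the truth and its reverse complement
rather than the truth itself. For sharply oriented cut motifs the fit is
essentially exact (total variation per position ~5e-4 at 1e6 draws, sharp
planted motif), and recovery is always up to the inherent forward/reverse
ambiguity.

## Hill-climbing mask search

The flatness metric is `M_T(m) = Σ_t sd(G_t(m))`, the sum over TF site sets
of the sample standard deviation (denominator N−1) of the composite profile
(position-wise sum of merged-strand scaled counts over motif-oriented
sites; minus-strand sites are read right-to-left). Starting from all-`X`,
each step evaluates every single `X→N` unmasking with a complete
tabulate-and-scale pass and moves to the minimizer; ties break to the
lowest position index so runs are deterministic; the search stops when no
`X` remains and returns the full trajectory, leaving the complexity
cut-off to the user. Per-mask results are cached; mappability and the
distilled read events are shared across all evaluations.

## Detection bias

For every read the nick's upstream and downstream 3-mers (plus-strand
orientation) define one of 4096 cells; plus- and minus-detected reads are
tallied separately and the per-cell log2 plus/minus ratio measures which
side of the nick library preparation recovers. Ratios are defined only
where both sides have at least 10 reads (configurable — small-count ratios
are noise; the raw ratio is also emitted). Under unbiased detection every
palindromic cell (downstream = revcomp(upstream)) is balanced, since both
reads of such a nick begin with the same 3-mer. The top-skew composite
motif is the unweighted base-frequency matrix of the most skewed 6-mers;
cross-experiment agreement is the Pearson correlation of log2 ratios over
cells defined in both tables.

## Synthetic data

The generator inverts the correction model: i.i.d. random genomes (default
GC 0.5), nick positions drawn with probability proportional to a per-k-mer
weight evaluated on the plus-strand k-mer at the nick, detected strand
drawn from a detection model (constant 1/2; logistic in one flanking base
to emulate end-repair bias; constant 1 for single-sided assays). Reads are
emitted as perfect, error-free alignments (sorted, indexed BAM) together
with a truth table of every nick's position, k-mer and strand. Default
planted weights are log-normal with sigma 0.75 on the natural-log scale —
a ~20-fold 95% range, the order of spread reported for DNase hexamer
preference; the planted logistic detection coefficient is 1.5. High-entropy
random genomes keep mappability ≈ 1, isolating bias effects from
mappability effects; a separate fixture plants an exact repeat to exercise
the unmappable path.

What the simulations do *not* emulate: sequencing errors, fragment-size
distributions and two-ended fragments, PCR duplication, chromatin
structure, and real mappability landscapes. Passing tests therefore
demonstrate the correctness of the machinery — the tallies, the algebra of
the correction, the optimizers — under the stated generative model, not the
adequacy of a spaced k-mer model for any particular enzyme.

## Verification problem sizes

The from-scratch verification (`scripts/acceptance.py` and the end-to-end
test module) uses: 4 kb genomes for exact-oracle comparisons; a 200 kb
genome with 1e6 simulated cuts for weight recovery (the two strand views of
each hexamer are pooled into a single minimum-variance estimate before
correlating with the planted weights; corrected per-k-mer mass is exactly
proportional to genomic frequency by construction, which the script
measures rather than assumes); a 100 kb genome with 5e6 cuts and eight
random hexamer anchor sequences (±5 bp flanks) for profile flattening,
where the corrected profile's residual variation is pure sampling noise, so
the fold-reduction grows with depth and comfortably exceeds 5 at that
depth; 1e6 PSWM draws with dominant base 0.95 for EM recovery; a span-4
(16-mask) space with a 3-fold single-base preference and single-sided
detection for the greedy-vs-exhaustive comparison; and 1e5 unbiased cuts
for the detection-bias null, whose "within 3 standard errors" check is a
~3-sigma statement per cell and is expected to sit near its nominal level.

## Known limitations

* Whole contigs are held in memory (dense per-contig vectors); processing
  is chunked by contig only — appropriate for desk-scale genomes up to
  tens of megabases, not for streaming whole mammalian genomes on small
  machines.
* Exact-match mappability only; aligners tolerating mismatches will call a
  few more positions unique.
* Spliced alignments contribute their alignment-end coordinate under
  `tail_edge`; no transcript-aware 3'-end arithmetic.
* The binary mappability and seqtable containers are documented but not
  compatible with any other tool's formats.
* Library-size normalization, smoothing and footprint calling are out of
  scope; the corrected tracks are inputs to such tools.
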