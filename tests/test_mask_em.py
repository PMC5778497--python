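"""EM cut-site PSWM inference and information-content masks."""

import itertools

import numpy as np
import pytest

import seqscale as ss
from seqscale.errors import MaskGrammarError
from seqscale.mask_em import _PSEUDO_COUNT, CutSitePSWM, em_fit
from seqscale.seqio import kmer_to_string


def draw_kmer_counts(theta, n_draws, rng):
    """Sample k-mers from a PSWM with random orientation, aggregate counts."""
    K = theta.shape[0]
    draws = np.stack(
        [rng.choice(4, size=n_draws, p=theta[j]) for j in range(K)], axis=1
    )
    flip = rng.random(n_draws) < 0.5
    draws[flip] = 3 - draws[flip][:, ::-1]
    idx = (draws * (4 ** np.arange(K - 1, -1, -1))).sum(axis=1)
    counts = np.bincount(idx, minlength=4 ** K)
    return [(kmer_to_string(j, K), int(c)) for j, c in enumerate(counts) if c > 0]


class TestEmFit:
    def test_uniform_counts_no_signal_symmetry(self):
        """Symmetric no-signal data: the fitted model treats every k-mer
        identically (equal implied probability under its preferred
        orientation) and beats the uniform PSWM only via the orientation
        freedom, never by distinguishing k-mers."""
        K = 3
        kmers = [(kmer_to_string(j, K), 5) for j in range(4 ** K)]
        fit = em_fit(kmers, n_restarts=3, seed=1)
        logtheta = np.log(fit.theta)
        probs = []
        for seq, _ in kmers:
            codes = [("ACGT").index(c) for c in seq]
            fwd = sum(logtheta[j, c] for j, c in enumerate(codes))
            rev = sum(logtheta[K - 1 - j, 3 - c] for j, c in enumerate(codes))
            probs.append(max(fwd, rev))
        probs = np.array(probs)
        assert probs.std() < 1e-3  # no k-mer preferred over another
        # likelihood at least that of the uniform PSWM
        assert fit.log_likelihood >= 5 * (4 ** K) * K * np.log(0.25) - 1e-6

    def test_rows_sum_to_one_and_positive(self):
        rng = np.random.default_rng(2)
        theta = rng.dirichlet([1] * 4, size=4)
        kmers = draw_kmer_counts(theta, 5000, rng)
        fit = em_fit(kmers, n_restarts=3, seed=3)
        np.testing.assert_allclose(fit.theta.sum(axis=1), 1.0, atol=1e-9)
        assert (fit.theta > 0).all()
        assert ((fit.gamma >= 0) & (fit.gamma <= 1)).all()

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(4)
        theta = rng.dirichlet([0.3] * 4, size=5)
        kmers = draw_kmer_counts(theta, 20000, rng)
        fit = em_fit(kmers, n_restarts=2, seed=5)
        diffs = np.diff(fit.ll_history)
        assert (diffs >= -1e-6 * np.abs(fit.ll_history[:-1])).all()

    def test_planted_recovery_small(self):
        """Sharp planted PSWM recovered (or its reverse complement)."""
        rng = np.random.default_rng(6)
        K = 4
        theta_star = np.full((K, 4), 0.05 / 3 * 3)
        theta_star = np.full((K, 4), (1 - 0.95) / 3)
        for j in range(K):
            theta_star[j, rng.integers(4)] = 0.95
        kmers = draw_kmer_counts(theta_star, 200_000, rng)
        fit = em_fit(kmers, n_restarts=5, seed=7)
        tv_fwd = 0.5 * np.abs(fit.theta - theta_star).sum(axis=1).max()
        tv_rev = 0.5 * np.abs(fit.theta - theta_star[::-1, ::-1]).sum(axis=1).max()
        assert min(tv_fwd, tv_rev) < 0.02

    def test_orientation_symmetry(self):
        """Reverse-complemented input yields the position-reversed complement
        PSWM at the same log-likelihood."""
        rng = np.random.default_rng(8)
        theta = np.full((3, 4), 0.1)
        theta[np.arange(3), [0, 2, 1]] = 0.7
        kmers = draw_kmer_counts(theta, 30000, rng)
        from seqscale.seqio import revcomp

        kmers_rc = [(revcomp(s), n) for s, n in kmers]
        fit = em_fit(kmers, n_restarts=4, seed=9)
        fit_rc = em_fit(kmers_rc, n_restarts=4, seed=9)
        assert fit.log_likelihood == pytest.approx(fit_rc.log_likelihood, rel=1e-6)
        close_rev = np.allclose(fit_rc.theta, fit.theta[::-1, ::-1], atol=5e-3)
        close_same = np.allclose(fit_rc.theta, fit.theta, atol=5e-3)
        assert close_rev or close_same

    def test_reproducible_given_seed(self):
        kmers = [("ACGT", 7), ("TTAA", 3), ("GGCC", 2)]
        a = em_fit(kmers, n_restarts=4, seed=10)
        b = em_fit(kmers, n_restarts=4, seed=10)
        np.testing.assert_array_equal(a.theta, b.theta)

    @pytest.mark.parametrize(
        "bad", [[("ACG", 1), ("ACGT", 1)], [("ACNT", 1)], [("ACGT", 0)], []]
    )
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            em_fit(bad, n_restarts=1, seed=0)


class TestGridOracle:
    def test_two_kmer_toy_matches_grid_search(self):
        """{AA:5, TT:5}: EM's penalized objective matches an independent
        grid maximization of the same objective (orientation optimized
        out at its extremes), within grid resolution."""
        kmers = [("AA", 5), ("TT", 5)]
        fit = em_fit(kmers, n_restarts=10, seed=11)

        def objective(theta):
            # marginal likelihood with free per-k-mer orientation (sup at
            # 0/1) plus the Dirichlet smoothing implied by the pseudo-count
            total = 0.0
            for seq, n in kmers:
                codes = [("ACGT").index(c) for c in seq]
                fwd = np.prod([theta[j, c] for j, c in enumerate(codes)])
                rev = np.prod(
                    [theta[len(codes) - 1 - j, 3 - c] for j, c in enumerate(codes)]
                )
                total += n * np.log(max(fwd, rev))
            total += _PSEUDO_COUNT * np.log(theta).sum()
            return total

        grid = np.linspace(0.001, 0.999, 51)
        best = -np.inf
        for p1, p2 in itertools.product(grid, grid):
            # dominant mass on A, remainder split evenly (the family the
            # M-step's symmetric pseudo-count produces)
            q1, q2 = (1 - p1) / 3, (1 - p2) / 3
            theta = np.array([[p1, q1, q1, q1], [p2, q2, q2, q2]])
            best = max(best, objective(theta))
        em_objective = objective(fit.theta)
        assert em_objective >= best - 1e-9
        assert em_objective - best < 0.05


class TestInformationContent:
    def test_uniform_row_zero_bits(self):
        theta = np.array([[0.25, 0.25, 0.25, 0.25]])
        assert ss.information_content(theta)[0] == pytest.approx(0.0)

    def test_near_deterministic_row(self):
        theta = np.array([[0.997, 0.001, 0.001, 0.001]])
        ic = ss.information_content(theta)[0]
        assert ic == pytest.approx(1.97, abs=0.01)

    def test_half_half_row_one_bit(self):
        theta = np.array([[0.5, 0.5, 0.0, 0.0]])
        assert ss.information_content(theta)[0] == pytest.approx(1.0)


def _pswm_with_ic(ic_targets):
    """Build a PSWM whose per-position ICs approximate the targets."""
    from scipy.optimize import brentq

    rows = []
    for target in ic_targets:
        def f(p):
            q = (1 - p) / 3
            theta = np.array([p, q, q, q])
            return 2 + (theta * np.log2(theta)).sum() - target

        p = brentq(f, 0.2500001, 0.999999)
        q = (1 - p) / 3
        rows.append([p, q, q, q])
    theta = np.array(rows)
    return CutSitePSWM(
        theta=theta, gamma=np.array([]), log_likelihood=0.0,
        ll_history=np.array([0.0]), n_restarts=0, n_iterations=0,
        converged=True,
    )


class TestMaskFromIC:
    def test_threshold_zero_all_n(self):
        pswm = _pswm_with_ic([0.5, 0.5, 0.5, 0.5])
        mask = ss.mask_from_ic(pswm, 0.0, 2)
        assert mask.mask == "NNCNN"

    def test_threshold_above_two_empty_mask_error(self):
        pswm = _pswm_with_ic([0.5, 0.5])
        with pytest.raises(MaskGrammarError):
            ss.mask_from_ic(pswm, 2.5, 1)

    def test_union_rule_hand_enumeration(self):
        # IC = (1.5, 0.1, 0.1, 0.9), threshold 0.5, cut after position 2:
        # forward unmasked = (1,0,0,1); reversed = (1,0,0,1); union = same
        pswm = _pswm_with_ic([1.5, 0.1, 0.1, 0.9])
        mask = ss.mask_from_ic(pswm, 0.5, 2)
        assert mask.mask == "NXCXN"

    def test_union_rule_asymmetric(self):
        # IC = (1.5, 0.1, 0.1, 0.1): forward (1,0,0,0); reversed (0,0,0,1);
        # union unmasks both ends
        pswm = _pswm_with_ic([1.5, 0.1, 0.1, 0.1])
        mask = ss.mask_from_ic(pswm, 0.5, 2)
        assert mask.mask == "NXCXN"

    def test_negative_threshold_rejected(self):
        pswm = _pswm_with_ic([0.5])
        with pytest.raises(ValueError):
            ss.mask_from_ic(pswm, -0.1, 0)

    def test_masks_by_threshold_increasing_complexity(self):
        pswm = _pswm_with_ic([1.5, 0.3, 0.05, 0.9])
        pairs = ss.masks_by_threshold(pswm, [1.0, 0.5, 0.1, 0.0], 2)
        sizes = [m.kmer_size for _, m in pairs]
        assert sizes == sorted(sizes)
        assert sizes[-1] == 4
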