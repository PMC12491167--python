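"""MR estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest

from medmr.estimators import (
    InsufficientInstrumentsError,
    ivw,
    mode_estimate,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from tests.conftest import make_pair, pairs_from_ratios


class TestWaldRatio:
    def test_direct_ratio_and_delta_se(self):
        p = make_pair(beta_exp=0.1, beta_out=0.2, se_out=0.05)
        est = wald_ratio(p)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_pair(beta_out=0.0)).beta == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(make_pair(beta_exp=0.0))

    def test_first_vs_second_order_se_close_for_strong_instrument(self):
        # se_exp/|beta_exp| = 0.05 < 0.1: first-order within 1% of second-order
        p = make_pair(beta_exp=0.2, se_exp=0.01, beta_out=0.1, se_out=0.05)
        first = wald_ratio(p).se
        second = wald_ratio(p, second_order=True).se
        exact = np.sqrt(p.se_out**2 / p.beta_exp**2
                        + p.beta_out**2 * p.se_exp**2 / p.beta_exp**4)
        assert second == pytest.approx(exact)
        assert first == pytest.approx(second, rel=0.01)


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        p = make_pair(beta_exp=0.1, beta_out=0.2, se_out=0.05)
        assert ivw([p]).beta == pytest.approx(wald_ratio(p).beta)
        assert ivw([p], "fixed").se == pytest.approx(wald_ratio(p).se)

    def test_equal_ratios_recovered(self):
        pairs = pairs_from_ratios([0.7, 0.7, 0.7])
        assert ivw(pairs).beta == pytest.approx(0.7)

    def test_closed_form_oracle_three_snps(self):
        pairs = [make_pair("rs1", beta_exp=0.10, beta_out=0.05, se_out=0.010),
                 make_pair("rs2", beta_exp=0.20, beta_out=0.12, se_out=0.015),
                 make_pair("rs3", beta_exp=0.15, beta_out=0.04, se_out=0.020)]
        w = np.array([p.beta_exp**2 / p.se_out**2 for p in pairs])
        r = np.array([p.beta_out / p.beta_exp for p in pairs])
        assert ivw(pairs).beta == pytest.approx(float(np.sum(w * r) / np.sum(w)))

    def test_random_effects_never_deflates_se(self):
        pairs = pairs_from_ratios([0.5, 0.9, 1.5, 0.2])
        assert ivw(pairs).se >= ivw(pairs, "fixed").se
        homog = pairs_from_ratios([0.7, 0.7, 0.7])
        assert ivw(homog).se == pytest.approx(ivw(homog, "fixed").se)


class TestEgger:
    def test_noiseless_line_through_origin(self):
        pairs = [make_pair(f"rs{i}", beta_exp=0.05 * i, beta_out=0.05 * i * 0.7)
                 for i in (1, 2, 3, 4)]
        est = mr_egger(pairs)
        assert est.beta == pytest.approx(0.7, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_two_pairs_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger([make_pair("rs1"), make_pair("rs2")])

    def test_constant_pleiotropy_lands_in_intercept(self):
        c = 0.02
        pairs = [make_pair(f"rs{i}", beta_exp=0.05 * i, beta_out=0.05 * i * 0.7 + c)
                 for i in (1, 2, 3, 4, 5)]
        est = mr_egger(pairs)
        assert est.extra["intercept"] == pytest.approx(c, abs=1e-10)
        assert est.beta == pytest.approx(0.7, abs=1e-10)


class TestWeightedMedian:
    def test_equal_weight_middle_element(self):
        est = weighted_median(pairs_from_ratios([1.0, 2.0, 3.0]), n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_identical_ratios_and_vanishing_bootstrap_se(self):
        pairs = pairs_from_ratios([0.4] * 4, se_out=1e-6, se_exp=1e-6)
        est = weighted_median(pairs, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.4)
        # per-SNP noise ~1e-6 propagates to a bootstrap se of the same order
        assert est.se < 1e-3

    def test_interpolation_oracle_four_snps(self):
        pairs = [make_pair("rs1", beta_exp=0.10, beta_out=0.010, se_out=0.010),
                 make_pair("rs2", beta_exp=0.20, beta_out=0.060, se_out=0.020),
                 make_pair("rs3", beta_exp=0.10, beta_out=0.020, se_out=0.005),
                 make_pair("rs4", beta_exp=0.30, beta_out=0.120, se_out=0.030)]
        ratios = np.array([p.beta_out / p.beta_exp for p in pairs])
        weights = np.array([p.beta_exp**2 / p.se_out**2 for p in pairs])
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        cum = (np.cumsum(w) - 0.5 * w) / w.sum()
        below = np.searchsorted(cum, 0.5, side="right") - 1
        expected = r[below] + (r[below + 1] - r[below]) * (0.5 - cum[below]) / (cum[below + 1] - cum[below])
        est = weighted_median(pairs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(float(expected))

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(pairs_from_ratios([1.0, 2.0]), n_boot=10, seed=0)


class TestModeEstimate:
    def test_identical_ratios_returned_exactly(self):
        pairs = pairs_from_ratios([0.6] * 5)
        for weighted in (True, False):
            est = mode_estimate(pairs, weighted=weighted, n_boot=20, seed=0)
            assert est.beta == pytest.approx(0.6)

    def test_equal_weights_variants_coincide(self):
        pairs = pairs_from_ratios([0.2, 0.5, 0.9, 1.4])  # constant beta_exp/se_out
        simple = mode_estimate(pairs, weighted=False, n_boot=10, seed=3)
        weighted = mode_estimate(pairs, weighted=True, n_boot=10, seed=3)
        assert simple.beta == pytest.approx(weighted.beta)

    def test_bimodal_matches_grid_oracle(self):
        ratios = [1.00, 1.03, 0.97, 1.01, 0.99, 3.0, 3.05]
        pairs = pairs_from_ratios(ratios)
        est = mode_estimate(pairs, weighted=False, n_boot=10, seed=0)
        # independent dense-grid KDE oracle with the same bandwidth rule
        from scipy import stats as sps
        r = np.array(ratios)
        h = 0.9 * min(np.std(r, ddof=1), sps.median_abs_deviation(r, scale="normal")) \
            * len(r) ** (-0.2)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 20_001)
        dens = np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2).sum(axis=0)
        oracle = grid[np.argmax(dens)]
        assert abs(est.beta - oracle) < 0.02
        assert abs(est.beta - 1.0) < 0.1


class TestSharedInvariants:
    def _battery(self, pairs, seed=0):
        return [ivw(pairs), mr_egger(pairs),
                weighted_median(pairs, n_boot=30, seed=seed),
                mode_estimate(pairs, weighted=True, n_boot=30, seed=seed)]

    @staticmethod
    def _varied_pairs(ratios):
        return [make_pair(f"rs{i}", pos=i * 10_000, beta_exp=0.05 + 0.03 * i,
                          beta_out=(0.05 + 0.03 * i) * r, se_out=0.005 + 0.002 * i)
                for i, r in enumerate(ratios, 1)]

    def test_instrument_order_invariance(self, rng):
        pairs = self._varied_pairs([0.2, 0.7, 0.4, 1.1, 0.9])
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        for a, b in zip(self._battery(pairs), self._battery(shuffled)):
            assert a.beta == pytest.approx(b.beta, rel=1e-9)

    def test_sign_equivariance_under_reorientation(self):
        """Negating both effect columns (allele re-orientation after
        harmonization) leaves every estimate unchanged."""
        pairs = self._varied_pairs([0.2, 0.7, 0.4, 1.1])
        flipped = [make_pair(p.snp_id, beta_exp=-p.beta_exp, beta_out=-p.beta_out,
                             se_exp=p.se_exp, se_out=p.se_out, pos=p.pos)
                   for p in pairs]
        for a, b in zip(self._battery(pairs), self._battery(flipped)):
            assert a.beta == pytest.approx(b.beta, rel=1e-9)
            if a.method in ("ivw", "egger"):  # bootstrap SEs agree only stochastically
                assert a.se == pytest.approx(b.se, rel=1e-6)

    def test_noiseless_consistency_all_estimators(self):
        b = -0.35
        pairs = [make_pair(f"rs{i}", beta_exp=x, beta_out=b * x)
                 for i, x in enumerate([0.05, 0.1, 0.15, 0.2, 0.3], 1)]
        for est in self._battery(pairs):
            assert est.beta == pytest.approx(b, abs=1e-6), est.method

    def test_or_ci_construction(self):
        est = ivw(pairs_from_ratios([0.5, 0.8, 1.2]))
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.96 * est.se))
        assert est.ci_high == pytest.approx(np.exp(est.beta + 1.96 * est.se))
        assert est.ci_low < est.or_ < est.ci_high
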