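"""Two-site exchange model: closed forms vs brute-force propagator, joint fits."""

from dataclasses import replace

import numpy as np
import pytest

from rna2state.exchange import (
    DecayDataset,
    ExchangeParams,
    fit_exchange,
    monte_carlo_errors,
    populations_from_rates,
    propagator_oracle,
    rate_matrix,
    t1_curves,
    zz_auto_curves,
)
from rna2state.synthetic import MIXING_TIMES_MS, gen_exchange_dataset, scenario

from conftest import random_valid_params

TIMES = np.asarray(MIXING_TIMES_MS) / 1e3


class TestRateMatrix:
    def test_no_exchange_eigenvalues_are_minus_r1(self):
        rm = rate_matrix(ExchangeParams(0.0, 0.0, 2.0, 3.0))
        assert rm.lambda1 == pytest.approx(-2.0)
        assert rm.lambda2 == pytest.approx(-3.0)

    def test_symmetric_case_closed_form(self):
        # k_f = k_b = k, equal R1: lambda = -(R), -(R + 2k)
        rm = rate_matrix(ExchangeParams(5.0, 5.0, 2.0, 2.0))
        assert rm.lambda1 == pytest.approx(-2.0)
        assert rm.lambda2 == pytest.approx(-12.0)

    def test_against_generic_eigensolver(self):
        p = ExchangeParams(8.356, 12.534, 2.5, 2.5)
        rm = rate_matrix(p)
        ev = np.sort(np.linalg.eigvals(-rm.as_matrix()))[::-1]
        assert rm.lambda1 == pytest.approx(ev[0], abs=1e-12)
        assert rm.lambda2 == pytest.approx(ev[1], abs=1e-12)
        assert rm.lambda1 == pytest.approx(-2.5, abs=1e-12)
        assert rm.lambda2 == pytest.approx(-23.39, abs=1e-12)

    def test_elements_and_trace_determinant_identities(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_valid_params(rng)
            rm = rate_matrix(p)
            assert rm.a11 == p.k_f + p.r1_a
            assert rm.a22 == p.k_b + p.r1_b
            assert rm.a12 == -p.k_b and rm.a21 == -p.k_f
            assert rm.lambda1 + rm.lambda2 == pytest.approx(-(rm.a11 + rm.a22))
            assert rm.lambda1 * rm.lambda2 == pytest.approx(
                rm.a11 * rm.a22 - rm.a12 * rm.a21, rel=1e-10)
            assert rm.lambda2 <= rm.lambda1 <= 0

    def test_degenerate_flag(self):
        assert rate_matrix(ExchangeParams(0.0, 0.0, 2.0, 2.0)).degenerate
        assert not rate_matrix(ExchangeParams(1.0, 1.0, 2.0, 2.0)).degenerate

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ExchangeParams(-1.0, 0.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            ExchangeParams(1.0, 1.0, 0.0, 2.0)


class TestClosedFormCurves:
    def test_normalization_at_zero_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = random_valid_params(rng)
            for c in (*zz_auto_curves(p, [0.0]), *t1_curves(p, [0.0])):
                assert c[0] == 1.0

    def test_pure_relaxation_limit(self):
        p = ExchangeParams(0.0, 0.0, 2.0, 3.0)
        aa, bb = zz_auto_curves(p, TIMES)
        a, b = t1_curves(p, TIMES)
        np.testing.assert_allclose(aa, np.exp(-2.0 * TIMES), atol=1e-12)
        np.testing.assert_allclose(bb, np.exp(-3.0 * TIMES), atol=1e-12)
        np.testing.assert_allclose(a, np.exp(-2.0 * TIMES), atol=1e-12)
        np.testing.assert_allclose(b, np.exp(-3.0 * TIMES), atol=1e-12)

    def test_symmetric_exchange_invisible_to_t1(self):
        # starting from equilibrium, k_f = k_b and equal R1 gives pure e^{-Rt}
        p = ExchangeParams(7.0, 7.0, 2.0, 2.0)
        a, b = t1_curves(p, TIMES)
        np.testing.assert_allclose(a, np.exp(-2.0 * TIMES), atol=1e-12)
        np.testing.assert_allclose(b, np.exp(-2.0 * TIMES), atol=1e-12)

    def test_oracle_equivalence_random_grid(self):
        """Closed forms match exp(-At) propagation to 1e-9 over 1000 random sets."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = random_valid_params(rng)
            t = rng.uniform(0.0, 0.2)
            aa, bb = zz_auto_curves(p, [t])
            assert abs(aa[0] - propagator_oracle(p, t, [1.0, 0.0])[0]) < 1e-9
            assert abs(bb[0] - propagator_oracle(p, t, [0.0, 1.0])[1]) < 1e-9
            if p.k_ex > 0:
                m = propagator_oracle(p, t, [p.p_a, p.p_b])
                a, b = t1_curves(p, [t])
                assert abs(a[0] - m[0] / p.p_a) < 1e-9
                assert abs(b[0] - m[1] / p.p_b) < 1e-9

    def test_degenerate_eigenvalues_use_limiting_form(self):
        p = ExchangeParams(0.0, 0.0, 2.0, 2.0)
        aa, bb = zz_auto_curves(p, TIMES)
        np.testing.assert_allclose(aa, np.exp(-2.0 * TIMES), atol=1e-12)
        np.testing.assert_allclose(bb, np.exp(-2.0 * TIMES), atol=1e-12)

    def test_swap_symmetry(self, asymmetric_params):
        p = asymmetric_params
        q = ExchangeParams(p.k_b, p.k_f, p.r1_b, p.r1_a)
        aa_p, bb_p = zz_auto_curves(p, TIMES)
        aa_q, bb_q = zz_auto_curves(q, TIMES)
        np.testing.assert_allclose(aa_p, bb_q, atol=1e-12)
        np.testing.assert_allclose(bb_p, aa_q, atol=1e-12)
        a_p, b_p = t1_curves(p, TIMES)
        a_q, b_q = t1_curves(q, TIMES)
        np.testing.assert_allclose(a_p, b_q, atol=1e-12)
        np.testing.assert_allclose(b_p, a_q, atol=1e-12)

    def test_auto_peaks_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0.0, 0.2, 100)
        for _ in range(50):
            p = random_valid_params(rng)
            for c in zz_auto_curves(p, t):
                assert np.all(np.diff(c) <= 1e-12)
                assert np.all(c > 0) and np.all(c <= 1.0)

    def test_propagator_identity_at_zero(self, asymmetric_params):
        np.testing.assert_allclose(
            propagator_oracle(asymmetric_params, 0.0, [0.3, 0.7]), [0.3, 0.7])


class TestPopulationsFromRates:
    def test_equal_rates_give_half(self):
        fp = populations_from_rates(ExchangeParams(3.0, 3.0, 2.0, 2.0))
        assert fp.p_1B == 0.5 and fp.p_2B == 0.5

    def test_apo_like_split(self):
        fp = populations_from_rates(ExchangeParams(8.356, 12.534, 2.5, 2.5))
        assert fp.p_1B == pytest.approx(0.600, abs=1e-3)
        assert fp.p_2B == pytest.approx(0.400, abs=1e-3)
        assert fp.p_1B + fp.p_2B == 1.0

    def test_no_exchange_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            populations_from_rates(ExchangeParams(0.0, 0.0, 2.0, 2.0))


class TestFitExchange:
    def test_noiseless_self_consistency(self, asymmetric_params):
        p = asymmetric_params
        aa, bb = zz_auto_curves(p, TIMES)
        a, b = t1_curves(p, TIMES)
        ds = [DecayDataset("r", ch, TIMES, y)
              for ch, y in zip(("AA", "BB", "A", "B"), (aa, bb, a, b))]
        fit = fit_exchange(ds)
        np.testing.assert_allclose(fit.params.as_array(), p.as_array(), rtol=1e-6)
        assert fit.k_ex == pytest.approx(p.k_ex, rel=1e-6)

    def test_recovery_at_snr100(self, u24_datasets):
        fit = fit_exchange(u24_datasets)
        assert fit.k_ex == pytest.approx(20.89, rel=0.05)
        assert fit.params.p_a == pytest.approx(0.60, abs=0.05)

    def test_zz_only_fit_succeeds_with_wider_r1_uncertainty(self, u24_datasets):
        full = fit_exchange(u24_datasets)
        full = monte_carlo_errors(full, u24_datasets, n_runs=150, seed=3)
        zz = [d for d in u24_datasets if d.channel in ("AA", "BB")]
        part = fit_exchange(zz)
        part = monte_carlo_errors(part, zz, n_runs=150, seed=3)
        assert part.k_ex == pytest.approx(20.89, rel=0.15)
        assert part.param_errors["r1_a"] > full.param_errors["r1_a"]

    def test_missing_zz_channels_rejected(self, u24_datasets):
        t1_only = [d for d in u24_datasets if d.channel in ("A", "B")]
        with pytest.raises(ValueError, match="AA and BB"):
            fit_exchange(t1_only)

    def test_too_few_mixing_times_rejected(self, u24_params):
        t = TIMES[:3]
        aa, bb = zz_auto_curves(u24_params, t)
        ds = [DecayDataset("r", "AA", t, aa), DecayDataset("r", "BB", t, bb)]
        with pytest.raises(ValueError, match="distinct mixing times"):
            fit_exchange(ds)

    def test_mixed_residues_rejected(self, u24_datasets):
        bad = u24_datasets[:3] + [replace(u24_datasets[3], residue_id="other")]
        with pytest.raises(ValueError, match="multiple residues"):
            fit_exchange(bad)


class TestMonteCarloErrors:
    def test_vanishing_noise_gives_vanishing_errors(self, u24_params):
        aa, bb = zz_auto_curves(u24_params, TIMES)
        a, b = t1_curves(u24_params, TIMES)
        ds = [DecayDataset("r", ch, TIMES, y)
              for ch, y in zip(("AA", "BB", "A", "B"), (aa, bb, a, b))]
        fit = fit_exchange(ds)
        fit = monte_carlo_errors(fit, ds, n_runs=50, noise_sd=1e-8, seed=0)
        assert all(e < 1e-5 for e in fit.param_errors.values())

    def test_seed_stability(self, u24_datasets):
        fit = fit_exchange(u24_datasets)
        e1 = monte_carlo_errors(fit, u24_datasets, n_runs=300, seed=1)
        e2 = monte_carlo_errors(fit, u24_datasets, n_runs=300, seed=2)
        assert e1.param_errors["k_ex"] == pytest.approx(
            e2.param_errors["k_ex"], rel=0.10)

    def test_deterministic_given_seed(self, u24_datasets):
        fit = fit_exchange(u24_datasets)
        e1 = monte_carlo_errors(fit, u24_datasets, n_runs=40, seed=9)
        e2 = monte_carlo_errors(fit, u24_datasets, n_runs=40, seed=9)
        assert e1.param_errors == e2.param_errors

    def test_requires_at_least_two_runs(self, u24_datasets):
        fit = fit_exchange(u24_datasets)
        with pytest.raises(ValueError):
            monte_carlo_errors(fit, u24_datasets, n_runs=1, seed=0)


class TestDecayDataset:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError):
            DecayDataset("r", "AA", [0.01, 0.01, 0.02], [1, 1, 1])

    def test_rejects_zero_time(self):
        with pytest.raises(ValueError):
            DecayDataset("r", "AA", [0.0, 0.01], [1, 1])

    def test_rejects_unknown_channel(self):
        with pytest.raises(ValueError):
            DecayDataset("r", "AB", [0.01, 0.02], [1, 1])
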