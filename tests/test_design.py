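"""Filter-bank design: objective, constraints, factorization, verification."""

import json

import numpy as np
import pytest
import pywt

from owfb import (
    DesignSpec,
    InfeasibleDesignError,
    ProductFilter,
    design_product_filter,
    evaluate_product_spectrum,
    load_bank,
    objective_vector,
    save_bank,
    spectral_factorize,
    verify_filterbank,
)

from conftest import DESIGN_CASES

HAAR_MSSL = np.pi**2 / 3.0 - 2.0  # (1/pi) * int_0^pi f^2 (1 + cos f) df


def daubechies_mssl(N: int) -> float:
    """Spectral second moment of the same-length Daubechies filter."""
    taps = np.array(pywt.Wavelet(f"db{N // 2}").dec_lo)
    p = np.correlate(taps, taps, "full")[N - 1:]
    return float(objective_vector(N) @ p)


class TestObjectiveVector:
    def test_small_lengths_match_closed_form(self):
        np.testing.assert_allclose(objective_vector(2), [np.pi**2 / 3, -4.0])
        np.testing.assert_allclose(
            objective_vector(4), [np.pi**2 / 3, -4.0, 0.0, -4.0 / 9.0]
        )

    def test_haar_product_gives_analytic_second_moment(self):
        # sigma_f^2 of the Haar low-pass: (1/pi) int f^2 (1+cos f) df
        s = objective_vector(2)
        assert s @ np.array([1.0, 0.5]) == pytest.approx(HAAR_MSSL, abs=1e-12)

    @pytest.mark.parametrize("bad", [0, -2, 3, 7])
    def test_rejects_odd_or_nonpositive_length(self, bad):
        with pytest.raises(ValueError):
            objective_vector(bad)


class TestProductFilterDesign:
    def test_length_two_is_haar(self):
        pf, cert = design_product_filter(DesignSpec(2, 1))
        np.testing.assert_allclose(pf.p, [1.0, 0.5], atol=1e-12)
        assert cert.solver_status == "optimal"
        assert cert.objective_value == pytest.approx(HAAR_MSSL, abs=1e-9)

    def test_length_four_matches_hand_solved_d4(self):
        # with N=4, M=2 the constraints p1+p3=1/2, p1+9 p3=0 are a 2x2
        # system: p1 = 9/16, p3 = -1/16 (maximal-regularity product filter)
        pf, _ = design_product_filter(DesignSpec(4, 2))
        assert pf.p[1] == pytest.approx(9.0 / 16.0, abs=1e-10)
        assert pf.p[3] == pytest.approx(-1.0 / 16.0, abs=1e-10)
        np.testing.assert_allclose(pf.p[[0, 2]], [1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_half_band_imposed_exactly(self, N, M):
        pf, _ = design_product_filter(DesignSpec(N, M))
        assert pf.p[0] == 1.0
        assert np.all(pf.p[2::2] == 0.0)

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_regularity_constraints_hold(self, N, M):
        pf, _ = design_product_filter(DesignSpec(N, M))
        m = np.arange(N)
        # 2M zeros at z=-1: even pi-derivatives of the spectrum vanish
        assert abs(pf.p[0] + 2 * np.sum((-1.0) ** m[1:] * pf.p[1:])) < 1e-8
        for k in range(1, M):
            assert abs(np.sum((-1.0) ** m * m**(2 * k) * pf.p)) < 1e-6 * N ** (2 * k)

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_optimality_never_worse_than_daubechies(self, N, M):
        _, cert = design_product_filter(DesignSpec(N, M))
        assert cert.objective_value <= daubechies_mssl(N) + 1e-9

    def test_db3_feasible_point_bounds_n6_design(self):
        # the db3 product filter satisfies every (6, 2) constraint, so the
        # optimum cannot exceed its objective
        _, cert = design_product_filter(DesignSpec(6, 2))
        assert cert.objective_value <= daubechies_mssl(6) + 1e-9

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_certificate_is_psd_and_reproduces_p(self, N, M):
        pf, cert = design_product_filter(DesignSpec(N, M))
        assert cert.min_eigenvalue() >= -1e-8
        np.testing.assert_allclose(cert.trace_map(), pf.p, atol=1e-9)

    @pytest.mark.parametrize("N,M", [(4, 3), (2, 2), (16, 9)])
    def test_over_constrained_specs_rejected(self, N, M):
        with pytest.raises(InfeasibleDesignError, match="zero_moments"):
            DesignSpec(N, M)

    @pytest.mark.parametrize("N", [3, 0, -4])
    def test_bad_lengths_rejected(self, N):
        with pytest.raises(InfeasibleDesignError):
            DesignSpec(N, 1)


class TestSpectrumEvaluation:
    def test_haar_spectrum_endpoints(self):
        pf = ProductFilter(p=np.array([1.0, 0.5]))
        vals = evaluate_product_spectrum(pf, [0.0, np.pi])
        np.testing.assert_allclose(vals, [2.0, 0.0], atol=1e-14)

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_half_band_identity_on_fine_grid(self, N, M):
        pf, _ = design_product_filter(DesignSpec(N, M))
        f = np.linspace(0.0, np.pi, 2048)
        total = evaluate_product_spectrum(pf, f) + evaluate_product_spectrum(
            pf, np.pi - f
        )
        np.testing.assert_allclose(total, 2.0, atol=1e-8)

    def test_frequencies_outside_range_rejected(self):
        pf = ProductFilter(p=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            evaluate_product_spectrum(pf, [-0.1])
        with pytest.raises(ValueError):
            evaluate_product_spectrum(pf, [np.pi + 0.1])


class TestSpectralFactorization:
    def test_haar_factor(self):
        spec = DesignSpec(2, 1)
        pf, _ = design_product_filter(spec)
        fb = spectral_factorize(pf, spec)
        np.testing.assert_allclose(fb.a0, np.full(2, 1 / np.sqrt(2)), atol=1e-12)

    def test_d4_factor_matches_closed_form_db2(self):
        spec = DesignSpec(4, 2)
        pf, _ = design_product_filter(spec)
        fb = spectral_factorize(pf, spec)
        r3 = np.sqrt(3.0)
        db2 = np.array([1 + r3, 3 + r3, 3 - r3, 1 - r3]) / (4 * np.sqrt(2))
        err_fwd = np.abs(fb.a0 - db2).max()
        err_rev = np.abs(fb.a0 - db2[::-1]).max()
        assert min(err_fwd, err_rev) < 1e-10

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_autocorrelation_reproduces_product_filter(self, N, M, banks):
        fb = banks[(N, M)]
        pf, _ = design_product_filter(DesignSpec(N, M))
        q = np.correlate(fb.a0, fb.a0, "full")[N - 1:]
        np.testing.assert_allclose(q, pf.p, atol=1e-8)

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_squared_response_equals_product_spectrum(self, N, M, banks):
        fb = banks[(N, M)]
        pf, _ = design_product_filter(DesignSpec(N, M))
        f = np.linspace(0.0, np.pi, 512)
        n = np.arange(N)
        A = np.exp(-1j * np.outer(f, n)) @ fb.a0
        np.testing.assert_allclose(
            np.abs(A) ** 2, evaluate_product_spectrum(pf, f), atol=1e-8
        )

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_dc_gain_convention(self, N, M, banks):
        assert banks[(N, M)].a0.sum() == pytest.approx(np.sqrt(2.0), abs=1e-10)

    def test_quadrature_conjugation_relations(self, default_bank):
        fb = default_bank
        N = fb.N
        n = np.arange(N)
        np.testing.assert_allclose(fb.b0, fb.a0[::-1])
        np.testing.assert_allclose(fb.a1, (-1.0) ** n * fb.a0[::-1])
        np.testing.assert_allclose(fb.b1, (-1.0) ** (n + 1) * fb.a0)


class TestVerification:
    def test_haar_report(self, haar_bank):
        rep = verify_filterbank(haar_bank)
        assert rep.pr_residual < 1e-12
        assert rep.mssl_by_quadrature == pytest.approx(HAAR_MSSL, abs=1e-9)

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_quadrature_agrees_with_linear_functional(self, N, M, banks):
        # the closed-form s.p value and adaptive quadrature of the second
        # spectral moment are two routes to the same number
        fb = banks[(N, M)]
        rep = verify_filterbank(fb)
        assert abs(rep.mssl_by_quadrature - fb.achieved_mssl) < 1e-9

    @pytest.mark.parametrize("N,M", DESIGN_CASES)
    def test_residuals_within_tolerance(self, N, M, banks):
        rep = verify_filterbank(banks[(N, M)])
        assert rep.pr_residual < 1e-8
        assert rep.orthonormality_residual < 1e-8
        assert np.abs(rep.zm_residuals).max() < 1e-8

    def test_published_db2_taps_have_two_vanishing_moments(self):
        from owfb import WaveletFilterBank

        taps = np.array(pywt.Wavelet("db2").dec_lo)
        fb = WaveletFilterBank.from_lowpass(taps, DesignSpec(4, 2), 0.0)
        rep = verify_filterbank(fb)
        assert np.abs(rep.zm_residuals).max() < 1e-10


class TestSerialization:
    @pytest.mark.parametrize("suffix", [".json", ".txt"])
    def test_round_trip(self, default_bank, tmp_path, suffix):
        path = tmp_path / f"bank{suffix}"
        save_bank(default_bank, path)
        fb2 = load_bank(path)
        np.testing.assert_allclose(fb2.a0, default_bank.a0, atol=1e-15)
        assert fb2.achieved_mssl == pytest.approx(default_bank.achieved_mssl)
        assert fb2.spec.filter_length == default_bank.spec.filter_length
        assert fb2.spec.zero_moments == default_bank.spec.zero_moments

    def test_json_payload_is_plain_text(self, default_bank, tmp_path):
        path = tmp_path / "bank.json"
        save_bank(default_bank, path)
        payload = json.loads(path.read_text())
        assert len(payload["a0"]) == default_bank.N
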