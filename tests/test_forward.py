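"""Compartment signals, composite model, and relaxation weighting.

The quadrature-based oracles here integrate the per-orientation kernels
over the sphere directly, independent of the Legendre-convolution path
used by the implementation.
"""

import numpy as np
import pytest
from scipy import integrate

from cnoddi.forward import (
    DiffusivityConstants,
    RelaxationParams,
    TissueParams,
    apparent_fractions,
    signal_composite,
    signal_extra,
    signal_intra,
    signal_iso,
    signal_relaxation_weighted,
)
from cnoddi.scheme import AcquisitionScheme
from cnoddi.watson import KAPPA_MAX, WatsonParams, sphere_quadrature, watson_density

DC = DiffusivityConstants()
Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


def brute_intra(b, g, watson, d_par, order=64):
    nodes, w = sphere_quadrature(order)
    dens = watson_density(nodes, watson)
    return 4 * np.pi * np.sum(w * dens * np.exp(-b * d_par * (nodes @ g) ** 2))


def brute_extra(b, g, watson, d_par, ndi, order=64):
    nodes, w = sphere_quadrature(order)
    dens = watson_density(nodes, watson)
    mean_outer = 4 * np.pi * np.einsum("i,i,ij,ik->jk", w, dens, nodes, nodes)
    d_perp = d_par * (1 - ndi)
    tensor = d_perp * np.eye(3) + (d_par - d_perp) * mean_outer
    return np.exp(-b * g @ tensor @ g)


class TestIso:
    def test_b0(self):
        assert signal_iso(0.0, DC.d_iso) == 1.0

    def test_closed_form(self):
        assert signal_iso(2000, 3.0e-3) == pytest.approx(np.exp(-6), rel=1e-12)

    def test_strictly_decreasing_over_shells(self):
        vals = signal_iso(np.array([0.0, 700.0, 2000.0]), DC.d_iso)
        assert np.all(np.diff(vals) < 0)


class TestIntra:
    def test_parallel_stick_at_kappa_clamp(self):
        w = WatsonParams(Z, KAPPA_MAX)
        val = signal_intra(2000, Z, w, 1.7e-3)
        assert val == pytest.approx(np.exp(-3.4), abs=2e-3)

    def test_perpendicular_stick_at_kappa_clamp(self):
        w = WatsonParams(Z, KAPPA_MAX)
        assert signal_intra(2000, X, w, 1.7e-3) == pytest.approx(1.0, abs=0.02)

    def test_isotropic_dispersion_reduces_to_1d_integral(self):
        w = WatsonParams(Z, 0.0)
        oracle, _ = integrate.quad(lambda t: np.exp(-2000 * 1.7e-3 * t**2), 0, 1)
        assert signal_intra(2000, X, w, 1.7e-3) == pytest.approx(oracle, abs=1e-5)

    def test_bounded(self, scheme65):
        w = WatsonParams(Z, 5.0)
        vals = signal_intra(scheme65.b_values, scheme65.directions, w, DC.d_par)
        assert np.all((vals > 0) & (vals <= 1))


class TestExtra:
    def test_ndi_zero_closes_tortuosity(self):
        w = WatsonParams(Z, 3.0)
        for g in (Z, X):
            assert signal_extra(700, g, w, DC.d_par, 0.0) == pytest.approx(
                np.exp(-700 * DC.d_par), rel=1e-12
            )

    def test_b0_is_one(self):
        w = WatsonParams(Z, 3.0)
        assert signal_extra(0.0, X, w, DC.d_par, 0.6) == 1.0

    def test_oblique_matches_quadrature(self):
        w = WatsonParams(Z, 4.0)
        g = np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)])
        oracle = brute_extra(700, g, w, DC.d_par, 0.6)
        assert signal_extra(700, g, w, DC.d_par, 0.6) == pytest.approx(
            oracle, abs=1e-4
        )


class TestDispersedAgainstQuadrature:
    """Every dispersed signal agrees with brute-force spherical integration."""

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 4.0, 16.0, 64.0])
    @pytest.mark.parametrize("b", [700.0, 2000.0])
    def test_intra_and_extra(self, kappa, b):
        rng = np.random.default_rng(int(kappa * 10 + b))
        for _ in range(10):
            mu = rng.standard_normal(3)
            mu /= np.linalg.norm(mu)
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            w = WatsonParams(mu, kappa)
            assert signal_intra(b, g, w, DC.d_par) == pytest.approx(
                brute_intra(b, g, w, DC.d_par), abs=1e-4
            )
            assert signal_extra(b, g, w, DC.d_par, 0.55) == pytest.approx(
                brute_extra(b, g, w, DC.d_par, 0.55), abs=1e-4
            )


class TestComposite:
    def test_pure_csf(self, scheme65):
        p = TissueParams(0.0, 0.0, 1.0)
        np.testing.assert_allclose(
            signal_composite(p, scheme65),
            signal_iso(scheme65.b_values, DC.d_iso),
            rtol=1e-12,
        )

    def test_pure_extracellular(self, scheme65):
        w = WatsonParams(Z, 2.0)
        p = TissueParams(0.0, 1.0, 0.0, watson=w)
        expected = np.atleast_1d(
            signal_extra(scheme65.b_values, scheme65.directions, w, DC.d_par, 0.0)
        )
        expected[scheme65.b0_mask] = 1.0
        np.testing.assert_allclose(signal_composite(p, scheme65), expected,
                                   rtol=1e-12)

    def test_equals_weighted_sum_of_compartments(self, scheme65):
        w = WatsonParams(np.array([0.6, 0.0, 0.8]), 4.0)
        p = TissueParams(0.5, 0.3, 0.2, watson=w)
        b, g = scheme65.b_values, scheme65.directions
        s_in = np.atleast_1d(signal_intra(b, g, w, DC.d_par))
        s_ex = np.atleast_1d(signal_extra(b, g, w, DC.d_par, p.ndi))
        s_in[scheme65.b0_mask] = s_ex[scheme65.b0_mask] = 1.0
        by_hand = 0.5 * s_in + 0.3 * s_ex + 0.2 * signal_iso(b, DC.d_iso)
        np.testing.assert_allclose(signal_composite(p, scheme65), by_hand,
                                   atol=1e-12)

    def test_unity_at_b0_and_bounded(self, scheme65):
        p = TissueParams.from_ndi(0.6, 0.15, WatsonParams(Z, 3.0))
        a = signal_composite(p, scheme65)
        np.testing.assert_allclose(a[scheme65.b0_mask], 1.0, atol=1e-12)
        assert np.all((a > 0) & (a <= 1))

    def test_fraction_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            TissueParams(0.5, 0.4, 0.3)

    def test_joint_rotation_invariance(self, scheme65):
        from scipy.spatial.transform import Rotation

        mu = np.array([0.3, -0.5, np.sqrt(1 - 0.34)])
        p = TissueParams.from_ndi(0.6, 0.1, WatsonParams(mu, 6.0))
        base = signal_composite(p, scheme65)
        for seed in range(5):
            rot = Rotation.random(random_state=seed).as_matrix()
            rotated_scheme = AcquisitionScheme(
                scheme65.b_values,
                scheme65.directions @ rot.T,
                scheme65.echo_time,
                scheme65.repetition_time,
            )
            p_rot = TissueParams.from_ndi(
                0.6, 0.1, WatsonParams(rot @ mu, 6.0)
            )
            np.testing.assert_allclose(
                signal_composite(p_rot, rotated_scheme), base, atol=1e-10
            )


class TestRelaxationWeighted:
    def test_te_zero_long_tr_reduces_to_volume_weighted_sum(self, scheme65):
        p = TissueParams.from_ndi(0.6, 0.1, WatsonParams(Z, 4.0))
        relax = RelaxationParams()
        scheme = AcquisitionScheme(
            scheme65.b_values, scheme65.directions, 1e-9, 1e12
        )
        sig = signal_relaxation_weighted(p, relax, scheme, s0=2.0)
        np.testing.assert_allclose(
            sig, 2.0 * signal_composite(p, scheme), rtol=1e-9
        )

    def test_equal_t2_makes_normalized_signal_te_independent(self, scheme65):
        p = TissueParams.from_ndi(0.6, 0.1, WatsonParams(Z, 4.0))
        relax = RelaxationParams(t2_in_ex=80.0, t2_iso=80.0)
        normalized = []
        for te in (78.0, 120.0):
            scheme = AcquisitionScheme(
                scheme65.b_values, scheme65.directions, te, 1e12
            )
            sig = signal_relaxation_weighted(p, relax, scheme, s0=1.0)
            normalized.append(sig / sig[scheme65.b0_mask].mean())
        np.testing.assert_allclose(normalized[0], normalized[1], atol=1e-10)

    def test_apparent_fiso_closed_form_and_te_growth(self):
        p = TissueParams.from_ndi(0.6, 0.1, WatsonParams(Z, 4.0))
        relax = RelaxationParams(t2_in_ex=70.0, t2_iso=1500.0)
        previous = 0.0
        for te in (78.0, 90.0, 100.0, 120.0):
            fiso_app = apparent_fractions(p, relax, te, tr=np.inf)[2]
            r = np.exp(-te / relax.t2_iso + te / relax.t2_in_ex)
            closed = 0.1 * r / (0.9 + 0.1 * r)
            assert fiso_app == pytest.approx(closed, abs=1e-10)
            assert fiso_app > previous
            previous = fiso_app

    def test_nonpositive_relaxation_times_rejected(self):
        with pytest.raises(ValueError):
            RelaxationParams(t2_in_ex=-1.0)
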