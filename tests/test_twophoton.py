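"""Sum-over-states moments, rotational averaging and the GFSM expansion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fibrilight.errors import ResonanceError, UnknownStateError
from fibrilight.records import manifold_from_pairs
from fibrilight.twophoton import (
    SecondOrderMomentPair,
    delta_sos,
    gfsm_decomposition,
    gfsm_term,
    rotational_average_delta,
    second_order_moment_sos,
    two_state_decomposition,
)

from conftest import random_manifold


def _aligned_two_state(direction=(0.0, 0.0, 1.0), omega=0.1):
    d = np.asarray(direction, dtype=float)
    return manifold_from_pairs(
        energies={"0": 0.0, "S1": omega},
        state_dipoles={"0": 1.5 * d, "S1": 4.0 * d},
        right={("0", "S1"): 2.0 * d},
    )


class TestSecondOrderMoments:
    def test_zero_dipoles_give_zero_tensors(self):
        m = manifold_from_pairs(
            {"0": 0.0, "S1": 0.1},
            {"0": (0, 0, 0), "S1": (0, 0, 0)},
            {("0", "S1"): (0, 0, 0)},
        )
        pair = second_order_moment_sos(m, "S1", 0.05)
        assert np.all(pair.right == 0) and np.all(pair.left == 0)

    def test_degenerate_tensors_are_symmetric(self, rng):
        for _ in range(20):
            m = random_manifold(rng, n_states=3, hermitian=False)
            omega = m.energies["S1"]
            pair = second_order_moment_sos(m, "S1", omega / 2)
            for t in (pair.right, pair.left):
                np.testing.assert_allclose(t, t.T, rtol=1e-10, atol=1e-12)

    def test_two_state_tensor_matches_symbolic_two_term_sum(self):
        """Hand-chosen dipoles: each element must equal the K in {0, J}
        two-term sum evaluated independently with sympy rationals."""
        import sympy as sp

        omega = sp.Rational(1, 10)
        w = omega / 2
        mu01 = [sp.Rational(1, 2), sp.Rational(-1, 4), sp.Rational(3, 4)]
        mu00 = [sp.Rational(1, 5), sp.Rational(2, 5), sp.Rational(-1, 5)]
        mu11 = [sp.Rational(3, 2), sp.Rational(1, 2), sp.Rational(-1, 2)]
        # K = 0 term: mu(J,0) mu(0,0) / (0 - w); K = J term: mu(J,J) mu(J,0) / (omega - w)
        expected = sp.zeros(3, 3)
        for i in range(3):
            for j in range(3):
                k0 = (mu01[i] * mu00[j] + mu01[j] * mu00[i]) / (0 - w)
                kj = (mu11[i] * mu01[j] + mu11[j] * mu01[i]) / (omega - w)
                expected[i, j] = k0 + kj
        m = manifold_from_pairs(
            {"0": 0.0, "S1": float(omega)},
            {"0": [float(v) for v in mu00], "S1": [float(v) for v in mu11]},
            {("0", "S1"): [float(v) for v in mu01]},
        )
        pair = second_order_moment_sos(m, "S1", float(w))
        np.testing.assert_allclose(
            pair.right, np.array(expected, dtype=float), rtol=1e-12
        )
        np.testing.assert_allclose(pair.left, pair.right, rtol=0)  # Hermitian input

    def test_near_resonant_intermediate_raises_and_names_state(self):
        m = random_manifold(np.random.default_rng(0), n_states=3)
        omega_s1 = m.energies["S1"]
        with pytest.raises(ResonanceError, match="S1"):
            second_order_moment_sos(m, "S2", omega_s1 + 1e-9)

    def test_unknown_target_raises(self):
        m = random_manifold(np.random.default_rng(0))
        with pytest.raises(UnknownStateError):
            second_order_moment_sos(m, "S9", 0.01)


class TestRotationalAverage:
    def test_zero_tensors_give_zero_delta(self):
        z = np.zeros((3, 3))
        assert rotational_average_delta(SecondOrderMomentPair(z, z, 0.05)).delta == 0

    def test_invariance_under_proper_rotation(self, rng):
        for i in range(25):
            s = rng.normal(0, 1, (3, 3))
            s = s + s.T
            t = rng.normal(0, 1, (3, 3))
            t = t + t.T
            base = rotational_average_delta(SecondOrderMomentPair(s, t, 0.05)).delta
            r = Rotation.random(rng=rng).as_matrix()
            rot = rotational_average_delta(
                SecondOrderMomentPair(r @ s @ r.T, r @ t @ r.T, 0.05)
            ).delta
            assert rot == pytest.approx(base, rel=1e-10, abs=1e-12)

    def test_photon_energy_is_half_the_excitation_energy(self):
        z = np.zeros((3, 3))
        res = rotational_average_delta(SecondOrderMomentPair(z, z, 0.07))
        assert res.photon_energy == pytest.approx(res.excitation_energy / 2)


class TestDeltaSos:
    def test_hermitian_manifolds_are_non_negative(self, rng):
        deltas = [
            delta_sos(random_manifold(rng, n_states=n, hermitian=True), "S1").delta
            for n in (2, 3)
            for _ in range(100)
        ]
        assert min(deltas) >= 0.0

    def test_rotating_all_dipoles_leaves_delta_unchanged(self, rng):
        for _ in range(10):
            m = random_manifold(rng, n_states=3, hermitian=False)
            r = Rotation.random(rng=rng).as_matrix()

            def rot_pairs(table):
                return {k: r @ v.as_array() for k, v in table.items()}

            m_rot = manifold_from_pairs(
                dict(m.energies),
                {s: r @ v.as_array() for s, v in m.state_dipoles.items()},
                rot_pairs(m.transition_dipoles_right),
                rot_pairs(m.transition_dipoles_left),
            )
            assert delta_sos(m_rot, "S1").delta == pytest.approx(
                delta_sos(m, "S1").delta, rel=1e-10
            )

    def test_composition_equals_manual_pipeline(self, rng):
        m = random_manifold(rng, n_states=3, hermitian=False)
        omega = m.energies["S1"]
        manual = rotational_average_delta(
            second_order_moment_sos(m, "S1", omega / 2)
        )
        assert delta_sos(m, "S1").delta == manual.delta


class TestGfsm:
    def test_zero_chain_dipole_gives_exact_zero_term(self):
        m = manifold_from_pairs(
            {"0": 0.0, "S1": 0.1},
            {"0": (1, 0, 0), "S1": (0, 0, 0)},  # mu_11 = 0
            {("0", "S1"): (1, 1, 0)},
        )
        term = gfsm_term(m, "S1", "S1", "S1")
        assert term.value == 0.0
        assert term.magnitude_factor == 0.0
        assert term.angle_factor is None

    def test_parallel_dipoles_give_angle_factor_three(self):
        # every cosine = 1, so the printed bracket sums to 1*1 + 1*1 + 1*1
        m = _aligned_two_state()
        for k in ("0", "S1"):
            for l in ("0", "S1"):
                term = gfsm_term(m, "S1", k, l)
                assert term.angle_factor == pytest.approx(3.0, rel=1e-12)

    def test_term_scales_linearly_with_one_dipole_magnitude(self):
        base = _aligned_two_state()
        scaled = manifold_from_pairs(
            {"0": 0.0, "S1": 0.1},
            {"0": base.state_dipoles["0"].as_array(),
             "S1": 2.5 * base.state_dipoles["S1"].as_array()},
            {("0", "S1"): base.transition_dipoles_right[("0", "S1")].as_array()},
        )
        t0 = gfsm_term(base, "S1", "0", "S1")  # chain contains mu_11 once
        t1 = gfsm_term(scaled, "S1", "0", "S1")
        assert t1.value == pytest.approx(2.5 * t0.value, rel=1e-12)

    def test_0jjj_magnitude_factor_is_mu01_mu10_mu11_squared(self, rng):
        m = random_manifold(rng, n_states=2, hermitian=False)
        term = gfsm_term(m, "S1", "S1", "S1")
        pair = ("0", "S1")
        expected = (
            np.linalg.norm(m.transition_dipoles_left[pair].as_array())
            * np.linalg.norm(m.transition_dipoles_right[pair].as_array())
            * np.linalg.norm(m.state_dipoles["S1"].as_array()) ** 2
        )
        assert term.magnitude_factor == pytest.approx(expected, rel=1e-12)


class TestTwoStateDecomposition:
    def test_aligned_dipoles_sign_structure(self):
        # mixed terms carry denominators of opposite sign, so they are the
        # negative pair while the pure terms stay positive
        d = two_state_decomposition(_aligned_two_state(), "S1")
        assert d.terms[("0", "S1")].value < 0
        assert d.terms[("S1", "0")].value < 0
        assert d.terms[("0", "0")].value > 0
        assert d.terms[("S1", "S1")].value > 0

    def test_mixed_terms_identical(self, rng):
        for _ in range(20):
            m = random_manifold(rng, n_states=2, hermitian=False)
            d = two_state_decomposition(m, "S1")
            assert d.terms[("0", "S1")].value == d.terms[("S1", "0")].value

    def test_total_equals_delta_sos(self, rng):
        for _ in range(100):
            m = random_manifold(rng, n_states=2, hermitian=False)
            total = two_state_decomposition(m, "S1").total
            ref = delta_sos(m, "S1").delta
            assert total == pytest.approx(ref, rel=1e-10, abs=1e-12)

    def test_total_stored_terms_consistency(self, rng):
        d = two_state_decomposition(random_manifold(rng), "S1")
        assert d.total == pytest.approx(
            sum(t.value for t in d.terms.values()), rel=1e-12
        )

    def test_shifting_both_state_dipoles_preserves_total(self, rng):
        # the two-state total depends on the permanent dipoles only through
        # their difference
        shift = np.array([0.7, -1.3, 0.4])
        for _ in range(10):
            m = random_manifold(rng, n_states=2, hermitian=False)
            shifted = manifold_from_pairs(
                dict(m.energies),
                {
                    s: v.as_array() + shift
                    for s, v in m.state_dipoles.items()
                },
                {k: v.as_array() for k, v in m.transition_dipoles_right.items()},
                {k: v.as_array() for k, v in m.transition_dipoles_left.items()},
            )
            assert two_state_decomposition(shifted, "S1").total == pytest.approx(
                two_state_decomposition(m, "S1").total, rel=1e-9, abs=1e-10
            )

    def test_full_gfsm_matches_sos_for_three_states(self, rng):
        for _ in range(100):
            m = random_manifold(rng, n_states=3, hermitian=False)
            total = gfsm_decomposition(m, "S1").total
            ref = delta_sos(m, "S1").delta
            assert total == pytest.approx(ref, rel=1e-9, abs=1e-12)
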