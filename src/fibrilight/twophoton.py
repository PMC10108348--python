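"""Two-photon absorption strengths from sum-over-states second-order
moments, with the generalized few-state model (GFSM) decomposition.

The physics, in brief: a single beam of linearly polarized light drives the
|0> -> |J> two-photon transition through second-order transition-moment
tensors.  In non-Hermitian (coupled-cluster) response theory the right
(M_{J<-0}) and left (M_{0<-J}) tensors are built from different first-order
moments, and the rotationally averaged two-photon strength

    delta = (1/30) sum_{mu,nu} [ F M^L_mumu M^R_nunu
                               + G M^L_munu M^R_munu
                               + H M^L_munu M^R_numu ]

with the linear-polarization weights F = G = H = 2 can come out negative
for individual configurations; such values are reported as computed, never
clipped.  Expanding each tensor as a sum over intermediate states turns
delta into a sum of channel terms delta_{0JKL}, each a product of four
dipole magnitudes, a bracket of cosines between dipole directions, and two
energy denominators — the GFSM.  The two-state model keeps K, L in
{0, J}, giving the four terms delta_0J00, delta_0J0J = delta_0JJ0 and
delta_0JJJ.

Degenerate photons (each at omega_J / 2) are assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import F_LINEAR, G_LINEAR, GFSM_PREFACTOR, H_LINEAR
from .errors import ResonanceError, UnknownStateError
from .records import StateManifold

__all__ = [
    "SecondOrderMomentPair",
    "TwoPhotonResult",
    "GfsmTerm",
    "GfsmDecomposition",
    "second_order_moment_sos",
    "rotational_average_delta",
    "delta_sos",
    "gfsm_term",
    "gfsm_decomposition",
    "two_state_decomposition",
]

#: Energy denominators closer to zero than this (hartree) raise ResonanceError.
RESONANCE_GUARD = 1e-6


@dataclass(frozen=True)
class SecondOrderMomentPair:
    """Right (M_{J<-0}) and left (M_{0<-J}) second-order moment tensors, a.u."""

    right: np.ndarray
    left: np.ndarray
    photon_energy: float  # hartree


@dataclass(frozen=True)
class TwoPhotonResult:
    """Rotationally averaged two-photon strength for one excitation."""

    delta: float  # a.u.
    photon_energy: float  # hartree
    excitation_energy: float  # hartree

    @property
    def is_negative(self) -> bool:
        """Marks genuinely non-Hermitian configurations with delta < 0."""
        return self.delta < 0.0


@dataclass(frozen=True)
class GfsmTerm:
    """One (K, L) channel of the GFSM expansion.

    ``angle_factor`` is None when a dipole in the chain has zero length (the
    magnitude factor vanishes first and the whole term is exactly 0).
    """

    value: float
    magnitude_factor: float
    angle_factor: float | None


@dataclass(frozen=True)
class GfsmDecomposition:
    terms: Mapping[tuple[str, str], GfsmTerm]
    total: float


def _check_target(manifold: StateManifold, target: str) -> float:
    if target not in manifold.energies:
        raise UnknownStateError(f"unknown target state {target!r}")
    omega = manifold.energy(target)
    if omega <= 0.0:
        raise UnknownStateError(f"target {target!r} is not an excited state")
    return omega


def _denominator(manifold: StateManifold, state: str, photon_energy: float) -> float:
    d = manifold.energy(state) - photon_energy
    if abs(d) <= RESONANCE_GUARD:
        raise ResonanceError(state, d)
    return d


def second_order_moment_sos(
    manifold: StateManifold, target: str, photon_energy: float
) -> SecondOrderMomentPair:
    """Second-order transition moments by the complete sum over states.

    For each side the tensor is

        M_munu = sum_K [ mu_mu(J,K) mu_nu(K,0) + mu_nu(J,K) mu_mu(K,0) ]
                        / (omega_K - omega_photon)

    with K running over every manifold state, ground and target included
    (the permanent dipoles enter through the K = 0 and K = J terms).  The
    right tensor uses the right first-order moments, the left tensor the
    left ones.
    """
    _check_target(manifold, target)
    tensors = {}
    for side in ("right", "left"):
        m = np.zeros((3, 3))
        for k in manifold.state_labels:
            d = _denominator(manifold, k, photon_energy)
            a = manifold.dipole(target, k, side)
            b = manifold.dipole(k, "0", side)
            m += (np.outer(a, b) + np.outer(b, a)) / d
        tensors[side] = m
    return SecondOrderMomentPair(
        right=tensors["right"], left=tensors["left"], photon_energy=photon_energy
    )


def rotational_average_delta(moments: SecondOrderMomentPair) -> TwoPhotonResult:
    """Isotropically averaged two-photon strength for linear polarization.

    Equals the average over molecular orientations of the lab-frame
    two-photon probability (e . M^L . e)(e . M^R . e) for a fixed
    polarization vector e.  Negative values (possible for non-Hermitian
    tensor pairs) are returned as computed.
    """
    left, right = moments.left, moments.right
    if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
        raise ValueError("moment tensors must be finite")
    delta = (
        F_LINEAR * np.trace(left) * np.trace(right)
        + G_LINEAR * float(np.sum(left * right))
        + H_LINEAR * float(np.sum(left * right.T))
    ) / 30.0
    return TwoPhotonResult(
        delta=float(delta),
        photon_energy=moments.photon_energy,
        excitation_energy=2.0 * moments.photon_energy,
    )


def delta_sos(manifold: StateManifold, target: str) -> TwoPhotonResult:
    """delta for the |0> -> |target| transition at the degenerate photon
    energy omega_target / 2."""
    omega = _check_target(manifold, target)
    moments = second_order_moment_sos(manifold, target, omega / 2.0)
    return rotational_average_delta(moments)


def _sorted_product(values) -> float:
    out = 1.0
    for v in sorted(values):
        out *= v
    return out


def gfsm_term(
    manifold: StateManifold,
    target: str,
    k: str,
    l: str,
    photon_energy: float | None = None,
) -> GfsmTerm:
    """One GFSM channel term delta_{0JKL}.

    value = (4/15) * |mu^L_JK| |mu^L_K0| |mu^R_JL| |mu^R_L0|
            * [ cos(t^JK_K0) cos(t^JL_L0) + cos(t^JK_JL) cos(t^K0_L0)
              + cos(t^JK_L0) cos(t^JL_K0) ]
            / ( (omega_K - omega_J/2) (omega_L - omega_J/2) )

    Angles are handled as cosines from normalized inner products; a
    zero-length dipole anywhere in the chain short-circuits the term to
    exactly 0 with the angle factor undefined.  The cosine products and the
    magnitudes are reduced in sorted order so that the mirror terms
    delta_0J0J and delta_0JJ0 agree bitwise.
    """
    omega = _check_target(manifold, target)
    if photon_energy is None:
        photon_energy = omega / 2.0

    a_left = manifold.dipole(target, k, "left")
    b_left = manifold.dipole(k, "0", "left")
    a_right = manifold.dipole(target, l, "right")
    b_right = manifold.dipole(l, "0", "right")

    mags = [np.linalg.norm(v) for v in (a_left, b_left, a_right, b_right)]
    if min(mags) == 0.0:
        return GfsmTerm(value=0.0, magnitude_factor=0.0, angle_factor=None)

    d_k = _denominator(manifold, k, photon_energy)
    d_l = _denominator(manifold, l, photon_energy)

    ua, ub = a_left / mags[0], b_left / mags[1]
    va, vb = a_right / mags[2], b_right / mags[3]
    products = (
        float(ua @ ub) * float(va @ vb),
        float(ua @ va) * float(ub @ vb),
        float(ua @ vb) * float(va @ ub),
    )
    angle_factor = float(sum(sorted(products)))
    magnitude_factor = float(_sorted_product(mags))
    value = GFSM_PREFACTOR * magnitude_factor * angle_factor / (d_k * d_l)
    return GfsmTerm(value=value, magnitude_factor=magnitude_factor, angle_factor=angle_factor)


def gfsm_decomposition(
    manifold: StateManifold,
    target: str,
    intermediates: tuple[str, ...] | None = None,
) -> GfsmDecomposition:
    """GFSM expansion of delta over a set of intermediate states.

    With ``intermediates`` covering the whole manifold the total equals
    :func:`delta_sos` on the same manifold (the expansion is exact).
    """
    _check_target(manifold, target)
    if intermediates is None:
        intermediates = manifold.state_labels
    terms: dict[tuple[str, str], GfsmTerm] = {}
    for k in intermediates:
        for l in intermediates:
            terms[(k, l)] = gfsm_term(manifold, target, k, l)
    total = float(sum(t.value for t in terms.values()))
    return GfsmDecomposition(terms=terms, total=total)


def two_state_decomposition(manifold: StateManifold, target: str) -> GfsmDecomposition:
    """Two-state model: intermediates restricted to {0, target}, yielding the
    four terms delta_0J00, delta_0J0J, delta_0JJ0, delta_0JJJ.  The total
    equals delta_sos on the {0, target} sub-manifold."""
    return gfsm_decomposition(manifold, target, intermediates=("0", target))
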