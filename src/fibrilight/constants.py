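"""Physical constants and unit conversions.

Everything internal runs in Hartree atomic units (hartree for energies,
e*a0 for dipoles, a.u. for two-photon strengths); conversions happen only
at I/O and reporting boundaries.  All CODATA values come from
:mod:`scipy.constants` so they track the library's CODATA release.
"""

import math

from scipy import constants as _sc

#: Hartree energy in eV (CODATA).
HARTREE_EV: float = _sc.physical_constants["Hartree energy in eV"][0]

#: Photon wavelength/energy product, h*c/e in eV*nm: lambda(nm) = EV_NM / E(eV).
EV_NM: float = _sc.h * _sc.c / _sc.e * 1e9

#: Fine-structure constant alpha (dimensionless).
FINE_STRUCTURE: float = _sc.fine_structure

#: Bohr radius in cm.
BOHR_RADIUS_CM: float = _sc.physical_constants["Bohr radius"][0] * 100.0

#: Atomic unit of time in seconds.
ATOMIC_TIME_S: float = _sc.physical_constants["atomic unit of time"][0]

#: Atomic unit of the two-photon cross section, a0^4 * t0, in cm^4 s.
AU_2PA_CM4_S: float = BOHR_RADIUS_CM**4 * ATOMIC_TIME_S

#: One Goeppert-Mayer unit in cm^4 s photon^-1.
GM_CM4_S: float = 1e-50

#: Atomic unit of the 2PA cross section expressed in GM.
AU_2PA_GM: float = AU_2PA_CM4_S / GM_CM4_S

# Isotropic-averaging weights for a single beam of linearly polarized
# monochromatic light (two identical photons, parallel polarization).
F_LINEAR: int = 2
G_LINEAR: int = 2
H_LINEAR: int = 2

#: Prefactor of one GFSM channel term under the same polarization weights,
#: (F + G + H) * 2 / 30 for degenerate photons.
GFSM_PREFACTOR: float = 4.0 / 15.0

#: sigma = CROSS_SECTION_PREFACTOR_AU * omega^2 * g(2 omega) * delta, all in
#: a.u.; equals 4 pi^3 alpha a0^5 / c with c = 1/alpha and a0 = 1 in a.u.
CROSS_SECTION_PREFACTOR_AU: float = 4.0 * math.pi**3 * FINE_STRUCTURE**2

#: FWHM of a Gaussian divided by its standard deviation.
FWHM_PER_SD: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


def ev_to_hartree(energy_ev: float) -> float:
    return energy_ev / HARTREE_EV


def hartree_to_ev(energy_hartree: float) -> float:
    return energy_hartree * HARTREE_EV


def ev_to_nm(energy_ev: float) -> float:
    return EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    return EV_NM / wavelength_nm
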