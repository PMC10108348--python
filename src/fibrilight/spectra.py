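"""Ensemble spectral assembly.

From a site's collection of snapshots this module builds one-photon
statistics, Gaussian-broadened bands, the band-maximum location, the
average two-photon strength near the band maximum (the delta E_ave +- eps
window rule, eps = 0.05 eV by default), absolute two-photon cross sections
in GM, and the per-site suitability report against the 50 GM two-photon
brightness threshold.

Two-photon spectra are reported against the total two-photon excitation
wavelength, lambda_2PA = 2 * lambda_OPA for degenerate photons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    AU_2PA_GM,
    CROSS_SECTION_PREFACTOR_AU,
    EV_NM,
    FWHM_PER_SD,
    HARTREE_EV,
    ev_to_nm,
)
from .errors import DegenerateEnsembleError, EmptyWindowError
from .records import SnapshotRecord

__all__ = [
    "LineShape",
    "SpectrumGrid",
    "OnePhotonStats",
    "SiteReport",
    "gaussian_lineshape",
    "estimate_fwhm",
    "broadened_spectrum",
    "band_maximum",
    "average_delta_near_max",
    "cross_section",
    "two_photon_wavelength",
    "site_statistics",
    "brightness_check",
    "build_site_report",
    "site_reports_to_rows",
    "write_site_reports",
    "write_spectrum",
]

#: Averaging half-window around the band maximum, eV.
DEFAULT_EPSILON_EV = 0.05
#: Grid step for band-maximum location, eV.
DEFAULT_GRID_STEP_EV = 0.005
#: Two-photon brightness threshold for a useful imaging probe, GM.
BRIGHTNESS_THRESHOLD_GM = 50.0


@dataclass(frozen=True)
class LineShape:
    """Normalized line-shape profile; only Gaussian is supported."""

    kind: str = "gaussian"
    fwhm: float = 0.3  # eV

    def __post_init__(self):
        if self.kind != "gaussian":
            raise ValueError(f"unsupported line shape {self.kind!r}")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")

    def __call__(self, energy, center):
        return gaussian_lineshape(energy, center, self.fwhm)


@dataclass(frozen=True)
class SpectrumGrid:
    """A broadened spectrum on a regular energy grid (eV)."""

    energies: np.ndarray
    intensity: np.ndarray
    per_state: dict[str, np.ndarray] | None = None


def gaussian_lineshape(energy, center, fwhm: float):
    """Unit-area Gaussian over the energy axis, value in 1/eV.

    Peak value is (2/fwhm) sqrt(ln 2 / pi); half maximum at center +- fwhm/2.
    """
    if not fwhm > 0:
        raise ValueError("fwhm must be positive")
    peak = (2.0 / fwhm) * math.sqrt(math.log(2.0) / math.pi)
    arg = -4.0 * math.log(2.0) * ((np.asarray(energy) - center) / fwhm) ** 2
    out = peak * np.exp(arg)
    return float(out) if np.isscalar(energy) else out


def estimate_fwhm(excitation_energies: Sequence[float]) -> float:
    """Gaussian-equivalent FWHM, 2 sqrt(2 ln 2) times the sample standard
    deviation of per-snapshot excitation energies (eV in, eV out)."""
    values = np.asarray(list(excitation_energies), dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateEnsembleError(
            "need at least two distinct energies to estimate a width"
        )
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise DegenerateEnsembleError("zero variance ensemble")
    return FWHM_PER_SD * sd


def _split(snapshots: Iterable[tuple[float, float]]):
    pairs = list(snapshots)
    if not pairs:
        raise ValueError("empty snapshot list")
    e = np.array([p[0] for p in pairs], dtype=float)
    w = np.array([p[1] for p in pairs], dtype=float)
    return e, w


def broadened_spectrum(
    snapshots: Iterable[tuple[float, float]],
    fwhm: float,
    grid_step: float = DEFAULT_GRID_STEP_EV,
    pad_fwhm: float = 5.0,
) -> SpectrumGrid:
    """Sum of weight-scaled unit-area Gaussians on a regular grid."""
    energies, weights = _split(snapshots)
    lo = energies.min() - pad_fwhm * fwhm
    hi = energies.max() + pad_fwhm * fwhm
    grid = np.arange(lo, hi + grid_step, grid_step)
    intensity = np.zeros_like(grid)
    for e, w in zip(energies, weights):
        intensity += w * gaussian_lineshape(grid, e, fwhm)
    return SpectrumGrid(energies=grid, intensity=intensity)


def band_maximum(
    snapshots: Iterable[tuple[float, float]],
    fwhm: float,
    grid_step: float = DEFAULT_GRID_STEP_EV,
) -> float:
    """Energy (eV) of the maximum of the broadened ensemble band.

    ``snapshots`` are (excitation energy eV, weight >= 0) pairs; ties go to
    the lowest-energy grid point.
    """
    energies, weights = _split(snapshots)
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be >= 0 and not all zero")
    spectrum = broadened_spectrum(zip(energies, weights), fwhm, grid_step)
    return float(spectrum.energies[int(np.argmax(spectrum.intensity))])


def average_delta_near_max(
    snapshots: Iterable[tuple[float, float]],
    e_ave: float,
    epsilon: float = DEFAULT_EPSILON_EV,
) -> tuple[float, int]:
    """Mean delta over snapshots with excitation energy in
    [e_ave - eps, e_ave + eps], both endpoints inclusive.

    Returns (mean, count); an empty window raises EmptyWindowError rather
    than silently widening.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    energies, deltas = _split(snapshots)
    mask = (energies >= e_ave - epsilon) & (energies <= e_ave + epsilon)
    count = int(mask.sum())
    if count == 0:
        raise EmptyWindowError(
            f"no snapshot within {epsilon} eV of the band maximum at {e_ave} eV"
        )
    return float(deltas[mask].mean()), count


def cross_section(delta_au: float, photon_energy_ev: float, g_ev_inv: float) -> float:
    """Absolute two-photon cross section in GM.

    sigma = 4 pi^3 alpha a0^5 omega^2 g(2 omega) delta / c, evaluated in
    atomic units (where a0 = 1 and c = 1/alpha) and converted via
    1 GM = 1e-50 cm^4 s photon^-1.  Linear in delta and in g, quadratic in
    the photon energy.
    """
    if g_ev_inv < 0:
        raise ValueError("line-shape value must be >= 0")
    omega_au = photon_energy_ev / HARTREE_EV
    g_au = g_ev_inv * HARTREE_EV
    sigma_au = CROSS_SECTION_PREFACTOR_AU * omega_au**2 * g_au * delta_au
    return sigma_au * AU_2PA_GM


def two_photon_wavelength(lambda_opa_nm: float) -> float:
    """Total two-photon resonance wavelength for degenerate photons."""
    return 2.0 * lambda_opa_nm


@dataclass(frozen=True)
class OnePhotonStats:
    site_id: str
    n_snapshots: int
    mean_lambda_s1: float  # nm
    lambda_range_s1: float  # nm, max - min
    mean_lambda_s2: float | None  # nm; None when S2 absent
    s1_s2_separation: float | None  # nm, mean lambda(S1) - mean lambda(S2)


def site_statistics(ensemble: Sequence[SnapshotRecord]) -> OnePhotonStats:
    """One-photon summary of a single site's snapshot ensemble.

    Wavelengths come from energies via lambda(nm) = 1239.842 / E(eV).  A
    missing S2 state yields an absent (None) separation, never zero.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    sites = {rec.site_id for rec in ensemble}
    if len(sites) > 1:
        raise ValueError(f"ensemble mixes sites: {sorted(sites)}")

    lam1 = np.array(
        [ev_to_nm(rec.manifold.energies["S1"] * HARTREE_EV) for rec in ensemble]
    )
    has_s2 = all("S2" in rec.manifold.state_labels for rec in ensemble)
    if has_s2:
        lam2 = np.array(
            [ev_to_nm(rec.manifold.energies["S2"] * HARTREE_EV) for rec in ensemble]
        )
        mean2 = float(lam2.mean())
        separation = float(lam1.mean() - mean2)
    else:
        mean2 = None
        separation = None
    return OnePhotonStats(
        site_id=ensemble[0].site_id,
        n_snapshots=len(ensemble),
        mean_lambda_s1=float(lam1.mean()),
        lambda_range_s1=float(lam1.max() - lam1.min()),
        mean_lambda_s2=mean2,
        s1_s2_separation=separation,
    )


def brightness_check(sigma_gm: float, phi: float) -> tuple[float, bool]:
    """Two-photon brightness sigma * Phi and the strict > 50 GM pass flag."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("quantum yield must lie in [0, 1]")
    brightness = sigma_gm * phi
    return brightness, brightness > BRIGHTNESS_THRESHOLD_GM


@dataclass(frozen=True)
class SiteReport:
    """Spectral + brightness summary for one binding site."""

    site_id: str
    n_snapshots: int
    mean_lambda_s1: float  # nm
    mean_lambda_s2: float | None  # nm
    lambda_range_s1: float  # nm
    s1_s2_separation: float | None  # nm
    delta_mean_at_max: float  # a.u.
    delta_window_count: int
    sigma_max: float  # GM
    lambda_2pa_max: float  # nm
    band_max_ev: float  # eV
    fwhm: float  # eV
    negative_delta_fraction: float
    brightness: float  # GM
    brightness_pass: bool


def build_site_report(
    ensemble: Sequence[SnapshotRecord],
    deltas: Sequence[float],
    *,
    phi: float = 0.5,
    epsilon: float = DEFAULT_EPSILON_EV,
    grid_step: float = DEFAULT_GRID_STEP_EV,
    band_max_mode: str = "delta-weighted",
    include_negative: bool = True,
    fwhm: float | None = None,
) -> SiteReport:
    """Assemble the full per-site report from snapshots and their per-snapshot
    two-photon strengths (delta_sos output, same order as ``ensemble``).

    ``band_max_mode`` is either "delta-weighted" (argmax of the
    delta-weighted broadened band; negative deltas contribute zero weight)
    or "mean" (unweighted arithmetic mean of the excitation energies).
    ``include_negative`` controls whether negative-delta snapshots enter the
    window average; they are always counted in ``negative_delta_fraction``.
    """
    if len(deltas) != len(ensemble):
        raise ValueError("deltas and ensemble must have the same length")
    stats = site_statistics(ensemble)
    energies_ev = np.array(
        [rec.manifold.energies["S1"] * HARTREE_EV for rec in ensemble]
    )
    deltas = np.asarray(deltas, dtype=float)
    negative_fraction = float((deltas < 0).mean())

    if fwhm is None:
        fwhm = estimate_fwhm(energies_ev)

    if band_max_mode == "delta-weighted":
        weights = np.clip(deltas, 0.0, None)
        e_max = band_maximum(zip(energies_ev, weights), fwhm, grid_step)
    elif band_max_mode == "mean":
        e_max = float(energies_ev.mean())
    else:
        raise ValueError(f"unknown band_max_mode {band_max_mode!r}")

    if include_negative:
        window_pairs = zip(energies_ev, deltas)
    else:
        keep = deltas >= 0
        window_pairs = zip(energies_ev[keep], deltas[keep])
    delta_mean, count = average_delta_near_max(window_pairs, e_max, epsilon)

    g_peak = gaussian_lineshape(e_max, e_max, fwhm)
    sigma = cross_section(delta_mean, e_max / 2.0, g_peak)
    brightness, ok = brightness_check(sigma, phi)

    return SiteReport(
        site_id=stats.site_id,
        n_snapshots=stats.n_snapshots,
        mean_lambda_s1=stats.mean_lambda_s1,
        mean_lambda_s2=stats.mean_lambda_s2,
        lambda_range_s1=stats.lambda_range_s1,
        s1_s2_separation=stats.s1_s2_separation,
        delta_mean_at_max=delta_mean,
        delta_window_count=count,
        sigma_max=sigma,
        lambda_2pa_max=two_photon_wavelength(ev_to_nm(e_max)),
        band_max_ev=e_max,
        fwhm=fwhm,
        negative_delta_fraction=negative_fraction,
        brightness=brightness,
        brightness_pass=ok,
    )


_REPORT_FIELDS = [
    "site_id",
    "n_snapshots",
    "mean_lambda_s1",
    "mean_lambda_s2",
    "lambda_range_s1",
    "s1_s2_separation",
    "delta_mean_at_max",
    "delta_window_count",
    "sigma_max",
    "lambda_2pa_max",
    "band_max_ev",
    "fwhm",
    "negative_delta_fraction",
    "brightness",
    "brightness_pass",
]


def site_reports_to_rows(reports: Sequence[SiteReport]) -> list[dict]:
    rows = []
    for r in reports:
        rows.append({f: getattr(r, f) for f in _REPORT_FIELDS})
    return rows


def write_site_reports(reports: Sequence[SiteReport], path) -> None:
    """Flat tab-delimited site reports, one row per site, fixed formatting."""
    lines = ["\t".join(_REPORT_FIELDS)]
    for row in site_reports_to_rows(reports):
        cells = []
        for f in _REPORT_FIELDS:
            v = row[f]
            if v is None:
                cells.append("NA")
            elif isinstance(v, str):
                cells.append(v)
            elif isinstance(v, bool):
                cells.append(str(v).lower())
            elif isinstance(v, (int, np.integer)):
                cells.append(str(int(v)))
            else:
                cells.append("{:.10g}".format(v))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_spectrum(spectrum: SpectrumGrid, path) -> None:
    """Two-column (energy eV, intensity) text export for plotting."""
    lines = ["energy_ev\tintensity"]
    for e, i in zip(spectrum.energies, spectrum.intensity):
        lines.append("{:.10g}\t{:.10g}".format(e, i))
    Path(path).write_text("\n".join(lines) + "\n")
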