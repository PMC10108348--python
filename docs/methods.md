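# Methods

## Scope and model

`fibrilight` post-processes ensembles of electronic-structure snapshots for
a fluorescent probe bound to an amyloid fibril, one ensemble per binding
site, and combines them with per-frame MM-GBSA component tables into a
per-site suitability report for two-photon imaging. It deliberately starts
*after* the heavy engines: docking, classical and QM/MM dynamics and the
coupled-cluster response calculations are upstream producers of the
delimited tables this package reads; a seeded synthetic generator emulates
their statistical output so the whole analysis is testable end to end.

### Two-photon strengths

For a single beam of linearly polarized light driving the |0⟩→|J⟩
transition with two degenerate photons at ω_J/2, the rotationally averaged
two-photon strength is

    δ = (1/30) Σ_{μν} [ F M^L_{μμ} M^R_{νν} + G M^L_{μν} M^R_{μν}
                      + H M^L_{μν} M^R_{νμ} ],   F = G = H = 2,

where M^R (J←0) and M^L (0←J) are the right and left second-order
transition-moment tensors. With these weights δ equals the orientation
average of the lab-frame probability (e·M^L·e)(e·M^R·e) for a fixed
polarization vector e — a Monte-Carlo identity the test suite checks
explicitly. In non-Hermitian (coupled-cluster) response theory left and
right first-order moments differ, so δ of an individual snapshot can be
negative; such values are reported as computed, never clipped, and flagged
through `negative_delta_fraction` for downstream policy.

The tensors come from the complete sum over states,

    M_{μν} = Σ_K [ μ_μ(J,K) μ_ν(K,0) + μ_ν(J,K) μ_μ(K,0) ] / (ω_K − ω),

with K running over every manifold state including the ground and final
states, so the permanent dipoles enter through the K = 0 and K = J terms.
Denominators within 1e−6 hartree of zero raise a resonance error naming
the offending intermediate.

### Generalized few-state model

Substituting the SOS expansion into the contraction above factors δ into
channel terms indexed by intermediate states (K, L):

    δ_0JKL = (4/15) |μ^L_{JK}||μ^L_{K0}||μ^R_{JL}||μ^R_{L0}|
             × [ cosθ(JK,K0) cosθ(JL,L0) + cosθ(JK,JL) cosθ(K0,L0)
               + cosθ(JK,L0) cosθ(JL,K0) ]
             / ( (ω_K − ω_J/2)(ω_L − ω_J/2) ).

Angles are carried as cosines of normalized inner products (no arccos, no
branch issues); a zero-length dipole anywhere in a chain short-circuits
that term to exactly 0 with the angle factor marked undefined, since the
magnitude factor vanishes first. The two-state model restricts K, L to
{0, J}, giving δ_0J00, δ_0J0J ≡ δ_0JJ0 and δ_0JJJ; the mixed pair carries
denominators of opposite sign, which is why it is negative whenever the
dipoles are roughly aligned. The expansion is exact: summed over the full
intermediate set it reproduces the SOS value to ~1e−15 relative error,
which is how the transcription of the polarization weights and the bracket
structure is pinned down. The three bracket products and the four
magnitudes are reduced in sorted order so the mirror terms δ_0J0J and
δ_0JJ0 agree bitwise, not merely to rounding.

### Spectra and cross sections

Each site's band is a sum of unit-area Gaussians centered at the snapshot
excitation energies. The width is the Gaussian-equivalent FWHM,
2√(2 ln 2) × sample standard deviation of the per-snapshot S1 energies —
the simplest estimator consistent with a Gaussian profile; it is an
explicit argument everywhere so callers can substitute their own. The band
maximum is the argmax of the δ-weighted broadened band on a 0.005 eV grid
(negative δ contribute zero weight there); an unweighted-mean mode exists
because the weighting convention for locating the maximum is a genuine
open choice, and the mode in effect is logged with every run. δ values are
then averaged over snapshots within ±0.05 eV of the maximum (inclusive
endpoints, for determinism); an empty window is an error, never silently
widened. Negative-δ snapshots are included in the average by default and
counted in `negative_delta_fraction`; an exclusion switch exists.

The absolute cross section is

    σ = 4 π³ α a0⁵ ω² g(2ω) δ / c,

evaluated in atomic units (a0 = 1, c = 1/α) with CODATA constants from
`scipy.constants`, then converted via 1 GM = 10⁻⁵⁰ cm⁴ s photon⁻¹
(1 a.u. of σ ≈ 1.8968 GM). σ at the band maximum uses the peak line-shape
value g = (2/FWHM)√(ln 2/π) and photon energy E_max/2. Two-photon spectra
and band positions are reported against the total two-photon wavelength
λ_2PA = 2 λ_OPA (degenerate photons). Brightness is σ × Φ with the
fluorescence quantum yield Φ a user input (default 0.5); the imaging
threshold is a strict > 50 GM.

### MM-GBSA aggregation

Per-frame binding energy is ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA; site
summaries are component-wise means with the standard error of the mean of
per-frame totals (sample sd, ddof = 1). The "±" uncertainty of a binding
table is interpreted as this SEM; no entropy term is modeled. Ranking is
by most-negative mean total, ties broken lexicographically by site label.
Printed component means rounded to 0.1 kcal/mol can disagree with a
printed total by one rounding unit, so comparisons against display-rounded
tables use a 0.11 kcal/mol tolerance.

## Synthetic generator

The generator emulates, per site: S1/S2 excitation wavelengths as
truncated normals in wavelength space (statistics of such ensembles are
conventionally reported in nm, and truncation guards unphysical values);
transition-dipole directions scattered around a site-fixed axis within a
jitter cone; log-normal dipole magnitudes; a permanent S1 dipole roughly
collinear with the S0→S1 transition dipole (charge-transfer-like
geometry); left moments equal to right moments scaled by (1 + a·z),
z ~ N(0,1), with a the non-Hermitian asymmetry (a = 0 yields Hermitian
records); and independent normal MM-GBSA components. All draws flow
through `numpy.random.default_rng` (PCG64), so a seed fixes the ensemble
bit-for-bit.

The default calibration encodes the study conditions: 100 snapshots and
1000 GBSA frames per site; mean S1 wavelengths 594 nm (site 4) and 538 nm
(site 3) with sites 1–2 interpolated between the extremes (570/560 nm,
their means being unreported); S1–S2 separations 249/243/214/249 nm;
wavelength sds backed out from the target max–min ranges at n = 100
(144/140/85/85 nm) using a simulated expected-range factor (≈5.0 sd for
n = 100 — exact normal-range order statistics are awkward and the seeded
simulation is cheap); dipole magnitudes (|μ01| ≈ 2.3–3.2, |μ11| ≈ 6.5–8.6
a.u.) sized so the mean δ near the band maximum lands in the reported
10⁴–10⁵ a.u. band, with per-site scales following the reported ordering;
GBSA means set to the published component rows and per-component sds
(1.5/1.5/2.0/0.5 kcal/mol, doubled for the weakly bound surface site)
chosen so the SEM of the total over 1000 frames is ≈0.1 (≈0.2) kcal/mol.

What the generator does *not* emulate: time correlation along the
trajectory, conformational clustering, any coupling between binding
energetics and spectroscopy, and realistic correlations among GBSA
components. Passing tests therefore demonstrate the correctness of the
analysis pipeline on ensembles with the right marginal statistics — not
force-field or electronic-structure realism.

## Numerical choices

- Internal units: hartree, e·a0, a.u. for δ; conversions only at I/O and
  reporting boundaries (eV in files via the `_ev` header suffix;
  λ(nm) = 1239.842/E(eV)).
- Tolerances: 1e−10 relative for algebraic identities, 1e−6 hartree
  resonance guard, 1e−6 for line-shape quadrature.
- Band-maximum grid ties go to the lowest-energy grid point.
- Writers use fixed `%.12g` formatting so identical inputs are
  byte-identical and write∘read∘write is a fixed point.
- Problem sizes in the test and acceptance runs mirror the study ensemble
  (100 snapshots, 1000 GBSA frames per site); parameter-recovery checks
  use n = 5000 where convergence at 1/√n is the property under test.

## Known limitations

- Only degenerate single-beam 2PA; non-degenerate photon pairs are out of
  scope.
- The FWHM estimator and band-maximum rule are reasonable conventions, not
  unique; both are configurable and logged.
- Quantum yields are inputs, not predictions.
- The per-site δ and σ of a real probe/fibril system depend on unpublished
  per-snapshot response data; the synthetic calibration reproduces
  distributions and orders of magnitude, not exact published δ/σ values.
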