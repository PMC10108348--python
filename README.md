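# fibrilight

Ensemble two-photon absorption and binding-energy analysis for fluorescent
probes bound to amyloid fibrils.

Candidate probes for two-photon imaging of β-amyloid deposits must bind
fibrils tightly *and* absorb strongly in the near-infrared transparency
window in their bound conformation. Multiscale workflows assess this by
sampling probe–fibril configurations per binding site with (QM/MM)
molecular dynamics, computing excitation energies and left/right
transition dipoles per snapshot with non-Hermitian (coupled-cluster)
response theory, and estimating binding affinities with MM-GBSA.
`fibrilight` is the analysis layer of that workflow: it takes the
per-snapshot electronic records and per-frame MM-GBSA tables those engines
emit (as plain tab-delimited text) and turns them into per-site answers.

## What it computes

For the |0⟩→|J⟩ transition with two degenerate photons at ω_J/2:

- **second-order transition moments** by the complete sum over states,
  M_{μν} = Σ_K [μ_μ^{JK} μ_ν^{K0} + μ_ν^{JK} μ_μ^{K0}]/(ω_K − ω), kept
  separately for right (J←0) and left (0←J) first-order moments;
- **rotationally averaged two-photon strengths** for a single linearly
  polarized beam, δ = (1/30) Σ_{μν} [F M^L_{μμ}M^R_{νν} + G M^L_{μν}M^R_{μν}
  + H M^L_{μν}M^R_{νμ}] with F = G = H = 2, in atomic units — negative
  per-snapshot values from non-Hermitian input are reported, not clipped;
- the **generalized few-state model**: δ factored into (K, L) channel
  terms, each a product of four dipole magnitudes, a bracket of cosines
  between dipole directions, and two energy denominators, with the
  four-term two-state specialization δ_0J00, δ_0J0J ≡ δ_0JJ0, δ_0JJJ;
- **ensemble spectra**: Gaussian broadening with an FWHM of 2√(2 ln 2)
  times the snapshot-energy standard deviation, band-maximum location, the
  mean δ within ±0.05 eV of the band maximum, and absolute cross sections
  σ = 4π³ α a0⁵ ω² g(2ω) δ / c in GM (10⁻⁵⁰ cm⁴ s photon⁻¹);
- **MM-GBSA summaries**: per-frame totals ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA,
  site means with standard errors, and an affinity ranking;
- a **per-site report** combining mean S1/S2 wavelengths, wavelength
  ranges, δ and σ at the band maximum, the two-photon wavelength
  λ_2PA = 2λ_OPA, and the σ·Φ > 50 GM brightness check.

A seeded synthetic generator (`fibrilight.synthetic`) reproduces the
statistical structure of a four-site probe/fibril study — 100 snapshots
and 1000 GBSA frames per site — so the entire pipeline runs and is tested
without any external data.

## Worked example

```sh
fibrilight report --seed 1 --out out/
```

prints

```
site 1: lambda1 575 nm, delta 1.61e+05 a.u., sigma 532 GM, lambda_2PA 1148 nm, brightness 266 GM (pass)
site 2: lambda1 563 nm, delta 6.57e+04 a.u., sigma 122 GM, lambda_2PA 1147 nm, brightness 61 GM (pass)
site 3: lambda1 539 nm, delta 1.67e+05 a.u., sigma 321 GM, lambda_2PA 1091 nm, brightness 160 GM (pass)
site 4: lambda1 594 nm, delta 4.08e+04 a.u., sigma 135 GM, lambda_2PA 1197 nm, brightness 68 GM (pass)
strongest binder: site 1 (-43.4 kcal/mol)
```

Reading site 1: its snapshots average a 575 nm one-photon S0→S1
wavelength; the mean two-photon strength within ±0.05 eV of the band
maximum is 1.61×10⁵ a.u., giving a 532 GM cross section at a two-photon
resonance of 1148 nm — inside the biological transparency window — and a
brightness of 266 GM at an assumed quantum yield Φ = 0.5, comfortably past
the 50 GM imaging threshold. The core site binds strongest (−43.4
kcal/mol mean MM-GBSA total) *and* has the largest cross section, the
combination that makes a probe useful. `out/` receives the per-snapshot δ
and GFSM terms (`deltas.tsv`), site reports, per-site 2PA spectra,
full-precision and display-rounded GBSA tables, and a `run_manifest.json`
recording the configuration, seed and constants in effect.

The other subcommands expose the stages separately: `generate` writes
synthetic snapshot/GBSA tables, `twophoton` computes per-snapshot δ and
two-state GFSM terms from any snapshot table, `spectra` builds site
reports, and `gbsa` summarizes and ranks binding tables. All accept
`--config` (YAML), `--seed` and `--out`.

As a library:

```python
from fibrilight import delta_sos, two_state_decomposition, manifold_from_pairs

m = manifold_from_pairs(
    energies={"0": 0.0, "S1": 0.08},                      # hartree
    state_dipoles={"0": (0.5, 0, 0.2), "S1": (2.4, 0, 1.0)},  # e*a0
    right={("0", "S1"): (1.8, 0.3, 0.6)},                 # left=right: Hermitian
)
print(delta_sos(m, "S1").delta)            # 7683.75 a.u.
print(two_state_decomposition(m, "S1").terms[("S1", "S1")].value)  # 12226.2
```

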