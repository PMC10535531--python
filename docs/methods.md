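# Methods

This note documents the models behind `cyanospec`, the defaults and why,
what the synthetic data do and do not emulate, and the numerical choices a
maintainer would want to know.

## The scientific problem

Cyanobacteria discrimination from orbit hinges on a handful of narrow
spectral features: phycocyanin (PC) absorption near 620 nm, chlorophyll-a
(Chl-a) absorption near 675 nm, sun-induced Chl-a fluorescence near 685 nm
(weak in cyanobacteria, which hold most Chl-a in photosystem I), and the
particulate scattering/red-edge region past 700 nm. The package asks which
channels of an oversampled 500–780 nm imager carry that information, by
training neural-network retrievals on simulated spectra and scoring each
channel's permutation importance.

## Synthetic waters

Each water is drawn from one of seven optical water types with log-uniform
concentration priors (chlorophyll in µg/L, non-algal particles NAP in g/m³,
CDOM absorption at 440 nm in m⁻¹):

| type | chl | CAR | NAP | CDOM(440) |
|---|---|---|---|---|
| oligotrophic | 0.1–3 | U(0,1) | 0.05–2 | 0.02–0.5 |
| mixed_eutrophic | 3–30 | U(0,1) | 0.5–20 | 0.05–2 |
| sediment_dominated | 1–20 | U(0,1) | 20–200 | 0.05–2 |
| cdom_dominated | 1–20 | U(0,1) | 0.5–20 | 1–10 |
| eukaryote_bloom | 30–1000 | U(0,0.3) | 0.5–20 | 0.05–2 |
| cyano_bloom | 30–1000 | U(0.7,1) | 0.5–20 | 0.05–2 |
| scum | 1000–10000 | U(0.7,1) | 0.5–20 | 0.05–2 |

CAR — the cyanobacterial fraction of phytoplankton biomass — is defined as
a fraction in [0, 1] (an unbounded ratio would be an equally defensible
convention; the fraction makes the end-member mixing below linear and
bounded). Scum waters additionally carry `scum_fraction ~ U(0.3, 1)`.

**Phytoplankton absorption** mixes two Chl-a-specific end members,
`a_ph(λ) = chl · [(1−CAR)·a*_alg(λ) + CAR·a*_cy(λ)]`. Both bases are sums
of Gaussian bands (algae: 440, 490 carotenoid, 675 nm; cyanobacteria: 440,
650 weak, 675 nm plus a 620 nm PC band of FWHM 30 nm whose amplitude is
`0.0095 m²/mg × PC:Chl`), with a*_ph(675) on the ~0.016 m²/mg scale. The
basis shapes reproduce the diagnostic green-peak shift and 620 nm trough;
they are not measured pigment spectra.

**The PC label** is what a field algorithm would compute from the water's
own optics: `PC = [a_ph(620) − ε·a_ph(665)] / a*_pc(620)` with ε = 0.24 and
`a*_pc(620) = 0.0095·(0.5 + 0.5·CAR)` m²/mg (the specific coefficient
rises as cyanobacteria dominate). Both non-PC base curves are calibrated —
by adding a small 620 nm shoulder (chlorophyll-c-like) — so that
`a_base(620) = ε·a_base(665)` exactly. Consequently the chlorophyll
correction removes the non-PC pigments exactly, a purely algal water has
PC = 0, and the label round-trips through `build_iops` to machine
precision. The decomposition constants are config-exposed placeholders,
not literature-fitted values.

**Other constituents.** CDOM: `a_cdom(λ) = a(440)·exp(−S(λ−440))`, slope
`S ~ U(0.010, 0.020) nm⁻¹`. NAP: a*(440) = 0.03 m²/g, slope 0.011 nm⁻¹.
Particulate backscattering: `(0.0004·chl + 0.005·NAP)·(550/λ)^η` with
`η ~ U(0.3, 1.5)`, times a cyanobacteria-dependent NIR enhancement
`1 + CAR·sigmoid((λ−700)/15)` standing in for gas-vacuole scattering.
Pure water: a 10 nm laboratory-literature absorption table (NIR rise to
2.85 m⁻¹ at 750 nm) interpolated linearly; `bb_w = 0.0022·(400/λ)^4.32`.

**Reflectance closure.** `u = b_b/(a+b_b)`, sub-surface
`rrs = 0.0949·u + 0.0794·u²`, above-surface
`R_rs = 0.52·rrs/(1 − 1.7·rrs)` (sr⁻¹). Fluorescence adds two Gaussians at
685 nm (FWHM 25) and 730 nm (FWHM 50, amplitude ratio 0.2) scaled by
`0.001·chl·yield·(1 − 0.7·CAR)` with `yield ~ U(0, 0.02)` — linear in
biomass (no reabsorption saturation). Scum waters blend R_rs toward a
canonical vegetation red edge `ρ_veg = 0.05 + 0.45·sigmoid((λ−715)/10)`
weighted by `scum_fraction`, because closure models fail for floating mats.

**Atmosphere.** Per water, two atmospheres are sampled
(`τ_a(550) ~ U(0.02, 0.4)`, Ångström `α ~ U(0.5, 2)`, solar zenith
`U(20°, 60°)`, nadir view, adjacency weight `U(0, 0.3)`), giving
`TOAR = ρ_r + ρ_a + t·π·R_rs + t·w_adj·ρ_veg` with single-scattering path
reflectances (`ρ = τ·P/(4μ_sμ_v)`, Rayleigh phase `(3/4)(1+cos²Θ)`,
aerosol Henyey–Greenstein g = 0.7, ω = 0.95), the standard Rayleigh
optical-thickness polynomial, and two-way transmittances
`t = exp(−τ/2·(1/μ_s + 1/μ_v))` with `t = t_r·t_a`. The relative azimuth
is fixed at 90°, so cosΘ = −μ_sμ_v. BRR = (TOAR − ρ_r)/t_r removes the
molecular part only; with aerosols and adjacency off it inverts to π·R_rs
exactly, which the tests assert at 1e-9.

**What this does not emulate:** numerical radiative transfer (no
multiple scattering, no gaseous absorption lines), measured specific
optical properties, archived aerosol climatologies, sensor noise,
sun glint, or functional-clustering-derived water classes. Passing tests
therefore demonstrate the *methodology* — that the pipeline recovers the
information structure its generator encodes at realistic dynamic ranges —
not retrieval accuracy on real scenes.

## Instrument model

300 evenly spaced centers from 500 to 780 nm (spacing 280/299 ≈ 0.937 nm —
the imager's "approximately 1 nm" sampling; the 300-channel count is taken
as defining). Channel responses are Gaussians with
σ = FWHM/(2√(2 ln 2)), truncated at ±3σ and renormalized to unit sum, so a
flat spectrum is preserved exactly and resampling is linear. Decimation by
3 (100 channels, ~3 nm pitch) commutes with building the response matrix
on the decimated centers directly. Adjacent-channel binning is a plain
block mean (a trailing partial block is dropped with a warning).

## Retrieval

One network per product: input = log10(channel reflectance + 1e-6),
standardized per feature on training rows only; targets log10 for Chl-a
and PC (floored at 1e-6; PC can be exactly zero), raw for CAR. Five hidden
layers of 100 ReLU units, single linear output, Adam at 1e-3, batch 256,
MAE loss, ≤ 200 epochs with early stopping (patience 10) on a 10% inner
validation split and best-weight restoration. The validation MAE of an
MAE-trained network is noisy near convergence, so the trainer halves the
learning rate whenever validation stalls for patience/2 epochs
(ReduceLROnPlateau); without this, runs occasionally stop tens of epochs
early at visibly worse optima. The network is implemented on numpy because
the scikit-learn MLP offers only squared-error loss; training is
deterministic for a fixed seed.

Evaluation uses an outer seeded 80/20 record split; optionally 5-fold CV
over the 80% (fold mean ± sd reported) plus, always, a single model
trained on the full 80% whose held-out 20% metrics are the headline
numbers and whose test partition feeds attribution. R² is computed on the
model's native target scale (log10 for pigments), MAPE and RMSELE on
physical units; CAR MAPE is evaluated on observations > 0.01 and RMSELE
applies an additive floor of 1e-3 before log10 (values below −floor are
clipped to the floor; a free regression can produce slightly negative CAR
estimates). MAPE is reported in percent; log-scale error magnitudes and
percentage errors are not interchangeable and both are reported.

Full/P1/P2 models for one product share the training seed and data split,
so configuration comparisons are paired and reflect the band set, not
training luck.

## Attribution and band selection

Permutation importance uses L = 1 − R², so FI = e_perm − e_orig is
positive for informative channels; 5 within-column permutations are
averaged (the estimator's Monte-Carlo error at n = 10,000 is ≪ 0.05, which
the oracle test exploits: shuffling a perfect standard-normal predictor
has E[R²] = −1, hence FI = 2). Correlated adjacent channels share
importance — the known caveat of the method — which is why the analysis
runs on the decimated 100-channel grid.

Peak selection smooths the profile with a 3-channel moving average
(truncated at edges), collects strict local maxima (endpoints compete
against their single neighbor; plateaus yield no peak), and greedily
accepts peaks by descending attribution subject to a minimum separation —
9 nm for P1 (nine bands), 30 nm for P2 (three bands, one per broad
importance region). Ties break toward the lower wavelength for
determinism. The separations were chosen to be consistent with the
minimum gaps observed in the published selections; both are
config-exposed. Merging selections takes the union of centers (exact
duplicates collapse at tol_nm = 0; a positive tolerance collapses clusters
to their mean) and reports per-center duplicate counts, mirroring the
bold-marking of repeatedly selected bands in the published tables.

## Problem sizes and determinism

The test suite's emulated study uses 10,000 waters (R_rs only, 100
channels, nine trained networks, ~1.5 minutes on one CPU); the acceptance
script regenerates 4,000 waters and retrains everything from its `--seed`.
Every random draw in the package flows from an explicit seed:
`derive_seed(master, *tags)` hashes a stage tag with the master seed
(< 2³¹), the generator consumes one `numpy` Generator sequentially (so
label tables are byte-identical across reruns), and atmosphere draws occur
even for record types a configuration omits, keeping water labels
invariant to the requested data-type subset.

## Known limitations

- The emulator's spectra are smoother and better-behaved than EcoLight- or
  Modtran-class simulations; absolute retrieval metrics here should not be
  compared against field or full-physics studies.
- P1/P2 positions depend on the generator's feature placement; on real
  data the peaks shift (particularly toward the red at top-of-atmosphere,
  where aerosol attenuation suppresses blue-green information).
- The minimum-viable configuration is a union of per-product selections;
  its own retrieval performance is not evaluated.
- Spectral-index feature engineering (fluorescence line height, peak
  heights, band ratios) is deliberately out of scope.
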