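# cyanospec

**How many spectral bands — and which ones — does a satellite imager need to
detect cyanobacterial blooms?**

Cyanobacterial harmful algal blooms threaten drinking water, aquatic life and
recreation in inland waters. Their diagnostic pigment, phycocyanin (PC),
absorbs near 620 nm; chlorophyll-a (Chl-a) absorbs near 440/675 nm and
fluoresces near 685 nm; and dense blooms produce a strong red-edge
reflectance peak past 700 nm. A hyperspectral imager that oversamples
500–780 nm with ~300 overlapping 12 nm FWHM channels can, in principle,
capture all of this — but downlink budgets and signal-to-noise favor far
fewer bands.

`cyanospec` answers the question end to end, at desk scale, for researchers
in aquatic bio-optical remote sensing and instrument design:

1. **Simulate** labeled water-leaving reflectance spectra `R_rs(λ)` over
   seven optical water types (oligotrophic through hypereutrophic scum),
   with mixed cyanobacteria–algae populations controlled by the
   cyanobacteria:algae ratio (CAR ∈ [0, 1]), PC labels derived from
   phytoplankton absorption at 620 nm, explicit 685/730 nm Chl-a
   fluorescence with a reduced cyanobacterial yield, and — per water — two
   randomized atmospheres yielding top-of-atmosphere (TOAR) and
   Rayleigh-corrected (BRR) variants.
2. **Resample** spectra through a configurable imager model: Gaussian
   spectral response functions, FWHM variants, channel decimation
   (300 → 100 channels) and adjacent-channel binning.
3. **Retrieve** Chl-a, PC and CAR with a multilayer perceptron (five hidden
   layers × 100 ReLU units, Adam, MAE loss; log10 features and pigment
   targets), scored by R², MAPE and RMSELE on a held-out split.
4. **Attribute** importance to every channel by permutation: with error
   `L = 1 − R²`, the importance of channel *j* is
   `FI_j = mean(e_perm) − e_orig` over repeated within-column shuffles.
5. **Select** reduced configurations from the attribution peaks: **P1**
   (nine top peaks, near-Full accuracy) and **P2** (three primary peaks,
   the minimum viable configuration), and **merge** selections across
   products and data types into combined minimum-viable and optimal
   band sets.

The in-water forward model is the Gordon-style quadratic closure
`rrs = g0·u + g1·u²` with `u = b_b/(a + b_b)`, plus an analytic
single-scattering atmosphere — an emulator of the statistical structure of
large radiative-transfer training sets, not a radiometric replication.

## Worked example

```python
import dataclasses
import cyanospec as cs

grid = cs.default_grid()                       # 400-800 nm at 1 nm
gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
dataset = cs.generate_dataset(2000, seed=42, config=gen, grid=grid)

full = cs.decimate(cs.srf_matrix(cs.cyanosat_centers(), 12.0, grid,
                                 name="Full"), 3)   # 100 channels
res = cs.evaluate(dataset, "pc", full, cs.TrainConfig(), seed=0, run_cv=False)
print(res.report.r2, res.report.mape_percent)

profile = cs.permutation_importance(res.model, res.X_test, res.y_test,
                                    full.centers, n_repeats=5, seed=1)
print(profile.sorted_view()[:3])
```

Output (printed by `examples/04_retrieve_and_attribute.py`):

```
PC retrieval (held-out n=400): R2=0.907 MAPE=187% RMSELE=0.429
top 5 channels by permutation importance (1-R2 increase):
   575.9 nm  FI=0.314
   589.9 nm  FI=0.297
   750.0 nm  FI=0.268
   615.2 nm  FI=0.244
   702.3 nm  FI=0.234
```

R² = 0.907 means the network explains 91% of the held-out log-PC variance;
the high MAPE reflects the enormous dynamic range (PC spans zero to
thousands of µg/L). The attribution ranks the green-peak region (~575–590
nm), the PC absorption region (~615 nm) and the red/NIR scattering region
(~700–750 nm) as most informative — exactly the physics the generator
encodes. `cs.select_p1(profile)` and `cs.select_p2(profile)` turn such
profiles into nine- and three-band configurations, and `cs.merge_configs`
combines them; merging the published per-product three-band selections
yields 7 (R_rs), 8 (TOAR) and 8 (BRR) minimum-viable bands
(`examples/05_band_selection_and_merging.py`).

Each script in `examples/` is a short narrative of one capability:
simulation, atmospheric propagation, instrument resampling, retrieval +
attribution, band selection + merging. A thin CLI mirrors the pipeline
(`cyanospec run --seed 1 --out runs/demo`).

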