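# preedge

Mn K-edge HERFD pre-edge analysis for discriminating ammonia-binding
modes of the oxygen-evolving complex (OEC) of photosystem II.

## The problem

The OEC — the Mn₄CaO₅ cluster that oxidizes water — binds ammonia, a
water analogue, in its S₂ state, but the binding site (substitution of
the O5 μ-oxo bridge, of a terminal water W1/W2 on Mn4, or addition of a
sixth ligand on Mn4 or Mn1) cannot be read off a single measurement.
High-energy-resolution fluorescence-detected (HERFD) X-ray absorption
sharpens the weak Mn 1s→3d pre-edge region (~6538–6545 eV) enough that
the small intensity changes induced by ammonia binding become usable
evidence: each candidate structural model predicts, via quantum-chemical
transition calculations, a distinct change of the pre-edge, and the model
whose predicted change best matches the measured change is the best
structural assignment.

`preedge` implements the full analysis as a reusable, tested pipeline:

1. **Preprocessing of measured spectra** — area normalization, 5-point
   binning, removal of the residual S₁ population (~10%) from 1-flash
   spectra, smoothing-spline subtraction of the rising-edge background,
   and deconvolution of the pre-edge into three Voigt components whose
   noise-free reconstruction is differenced;
2. **Postprocessing of computed stick spectra** — Gaussian (or
   Lorentzian / pseudo-Voigt) broadening of per-site transition tables,
   summation over the four Mn sites, and a single global energy
   shift / intensity scale fitted once against the untreated S₂
   reference (values near 35.3 eV / 0.018) and frozen for all models;
3. **Model discrimination** — treated-minus-native difference spectra
   for experiment and for every candidate model, scored by

   RMSD = √( (1/N) Σᵢ (yᵢ,calc − yᵢ,exp)² )

   on a common grid of N = 240 energies over 6538–6544.5 eV, with an
   exclusion screen for models whose absolute pre-edge intensity over
   6540–6543 eV significantly exceeds the native spectrum;
4. **Synthetic data with known ground truth** — a generator that
   emulates the statistical structure of the measurements (four-site
   stick spectra, logistic rising edge, Gaussian noise at SNR ≈ 20,
   0.1 eV grid, S₁ cross-contamination), so every stage and the
   end-to-end ranking are testable without any external download.

## Worked example

Run the full pipeline on a synthetic experiment in which the "treated"
sample was generated from candidate model C2 (ammonia replacing the
terminal W2 water on Mn4):

```bash
preedge pipeline --config demo.yaml
```

with `demo.yaml`:

```yaml
mode: synthetic
seed: 5
out_dir: demo
```

The log shows each stage and its parameters:

```
INFO preedge: stage simulate: seed=5 snr=20.0 f=0.100
INFO preedge: stage rank: 14 candidate models, region (6538.0, 6544.5), 240 points, fwhm 1.00 eV
INFO preedge: stage calibrate: shift 35.300 eV, scale 0.0012708
INFO preedge: best model: C2 (RMSD 0.001563)
```

and `demo/ranking.csv` begins:

```
model_id,binding_mode_class,rmsd,rank,excluded,exclusion_reason,calibration_shift_eV,calibration_scale,kernel_fwhm_eV
C2,W2-substitution,1.562627e-03,1,False,,35.3000,0.00127079,1.000
A5,O5-substitution,2.506758e-03,2,False,,35.3000,0.00127079,1.000
E2,Mn1-addition,2.943445e-03,3,False,,35.3000,0.00127079,1.000
```

The planted model C2 ranks first: its calculated difference spectrum is
closest (RMSD 1.56 × 10⁻³ in normalized intensity units) to the
experimental difference reconstructed from the Voigt fits.  The three
"nitrido" variants A2–A4 appear at the bottom of the file with
`excluded=True`: their pre-edge intensity over 6540–6543 eV exceeds the
native spectrum by far more than the 25% screening threshold, so they carry
a score but no rank.  Every row records the calibration and broadening
it was produced with.  (The calibration scale differs from the planted
0.018 only because measured spectra are area-normalized before
analysis; the energy shift is recovered at 35.300 eV.)

The same pipeline runs from files (`mode: files`) given four measured
scans (two-column XY text) and a stick table
(`model_id,site,energy_eV,intensity` CSV/TSV), which is the route for
analyzing externally deposited experimental data and transition tables.

## Library use

```python
import preedge as p

cfg = p.SynthConfig(seed=5)
native = p.generate_native_model(cfg)
models = p.generate_binding_mode_variants(native, cfg)
planted = next(m for m in models if m.model_id == "C2")
native_pair, treated_pair, truth = p.simulate_experiment(planted, native, cfg)
results = p.analyze_experiment(native_pair, treated_pair, models, native)
```

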