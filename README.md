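# guvphase

Quantitative analysis of protein–lipid phase-coupling assays on model
membranes — the experiments used to study how biomolecular condensates
(for example, annexin A11 condensing through its low-complexity domain)
change the phase state and mechanics of the giant unilamellar vesicle
(GUV) or lysosomal membranes they sit on.

The package is for membrane biophysicists and cell biologists who run
these assays and want a scriptable, tested replacement for ad-hoc
ImageJ/Origin workflows. It covers every quantitative stage of the
pipeline, plus a seeded synthetic-data generator that produces each input
modality with known ground truth, so the whole pipeline is testable
without any microscope data:

| stage | readout |
| --- | --- |
| GUV segmentation + recruitment | mean protein intensity over the Gaussian-blurred, thresholded membrane mask |
| Ratiometric lipid order | φ = Σ I_blue-green / Σ I_red over the mask (solvatochromic dye; higher φ = more ordered lipids); a live-cell variant with per-channel background subtraction |
| Condensate detection + phase diagram | 8-connected components; a field is *condensed* iff mean area > 0.4 µm² and > 20 condensates per 90 µm²; SVM (linear / poly-2) phase boundary |
| Granulosity index | G = sd/mean of the Fourier high-pass-filtered image (0 for a uniform field) |
| FRAP | F(t) = M(1 − e^(−t/τ)) on normalised post-bleach frames; % recovery at fixed times |
| Dose–response | 4-parameter logistic in log₁₀(dose) with a saturation call |
| IR spectroscopy | Savitzky–Golay second-derivative localization of the lipid C=O band (liquid ≈ 1730 cm⁻¹; a gel transition shifts it up ~8 cm⁻¹), amide-I secondary-structure fractions, protein:lipid (1655/1730 cm⁻¹) ratio maps |
| Membrane mechanics | OLS strain-vs-pressure over 100–1000 Pa; relative elastic modulus E_rel = slope_ref/slope_sample |
| Diffusional sizing | 1-D advection–diffusion forward model; R_H from a 0.1–50 nm grid fit via D = k_BT/(6πηR_H) |

## Worked example

```python
from guvphase import imaging, kinetics, spectra, synth
from guvphase.synth import SynthConfig

# ratiometric lipid order on a synthetic dye-labelled GUV
cfg = SynthConfig(seed=7)
blue, red, marker, truth = synth.make_pk_image(cfg, true_phi=1.4)
mask = imaging.segment_guv(marker)
result = imaging.compute_phi(blue, red, mask)
print(f"relative lipid order phi = {result.phi:.3f}")

# second-derivative C=O peak of a gel-phase lipid spectrum
spec, _ = synth.make_spectrum(SynthConfig(seed=0, noise_sd=0.0), phase="gel")
deriv = spectra.second_derivative(spectra.preprocess(spec, "afmir"), "afmir")
peak = spectra.locate_co_peak(deriv)
print(f"gel-phase C=O band: {peak.position_cm1:.1f} cm^-1")

# FRAP recovery fit
trace, _ = synth.make_frap_trace(SynthConfig(seed=3), mobile_fraction=0.8,
                                 tau_s=3.0, noise_sd=0.02)
fit = kinetics.fit_recovery(kinetics.normalize_trace(trace))
print(f"FRAP: M = {fit.mobile_fraction:.3f}, tau = {fit.tau_s:.2f} s, "
      f"recovery at 5 s = {kinetics.percent_recovery_at(fit, 5.0):.1f}%")
```

prints

```
relative lipid order phi = 1.398
gel-phase C=O band: 1738.0 cm^-1
FRAP: M = 0.807, tau = 3.01 s, recovery at 5 s = 65.4%
```

φ recovers the configured lipid order of the synthetic membrane to
within noise; the gel-phase carbonyl band sits 8 cm⁻¹ above the
1730 cm⁻¹ liquid position, the signature of a liquid-to-gel lipid
transition; and the FRAP fit returns the mobile fraction and time
constant the trace was generated with.

Every stage is also reachable from the command line (`guvphase --help`):
`synth`, `segment`, `recruit`, `phi`, `condense`, `phasemap`,
`granulosity`, `frap`, `dose`, `spectrum`, `mechanics`, `size`. Each
command writes its results plus a JSON run manifest (package version,
config hash, seeds), and identical seeds give byte-identical outputs.

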