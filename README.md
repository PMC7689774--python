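# f19lung

Toolkit for comparing inhaled fluorinated gases as ¹⁹F lung-MRI contrast
agents — specifically octafluorocyclobutane (OFCB, C₄F₈, one spectral peak
from 8 equivalent ¹⁹F nuclei) against perfluoropropane (PFP, C₃F₈, a 6:2
CF₃/CF₂ doublet). It is aimed at preclinical MR physicists who want to
predict, simulate and statistically test the SNR gain of one gas over
another at fixed scan time.

## The model

The steady-state spoiled gradient-echo signal is

```
S = S₀ · (1 − E₁) · e^(−TE/T2*) · sin α / (1 − cos α · E₁),   E₁ = e^(−TR/T₁)
```

with S₀ ∝ the number of equivalent ¹⁹F nuclei of the imaged peak. Averaging
NSA repetitions multiplies SNR by √NSA while scan time grows as NSA, so two
gases acquired in the same scan window are compared on SNR/NSA
("NSA-normalized SNR"). The package evaluates this model, derives Ernst
angles `α_E = arccos(E₁)` and scan-time-constrained NSA/TR, estimates the
relaxation constants that parameterize it (inversion-recovery T₁ fits of
`M(TI) = M₀(1 − 2β e^(−TI/T₁))`, T2* = 1/(π·FWHM) from Lorentzian line
fits), measures image SNR with ROI conventions, and grades paired SNR
differences with a t test and a Jeffreys–Zellner–Siow Bayes factor on the
Kass–Raftery scale. A synthetic-data module generates ground-truthed
spectra, inversion-recovery series, and k-space-simulated 2-D GRE magnitude
images for the whole chain.

## Worked example

```python
from f19lung import presets, predicted_advantage, reproduce_theory

res = predicted_advantage(
    presets.gas("ofcb-invivo"), presets.gas("pfp-invivo"),
    presets.protocol("breath-hold-ofcb"), presets.protocol("breath-hold-pfp"),
)
print(f"{res.advantage_pct:.1f}%")       # 86.2%
print(reproduce_theory().to_string(index=False))
```

prints

```
86.2%
     scenario  signal_a  signal_b  snr_theory_a  snr_theory_b  normalized_a  normalized_b  advantage_pct
  breath-hold  4.879837  3.209813     19.519347     15.724810      1.219959      0.655200      86.196338
continuous-70  4.326013  2.672278     51.912158     39.726271      3.244510      1.655261      96.011947
full-recovery  6.028062  3.867581     32.462108     24.764600      1.119383      0.604015      85.323832
         mean       NaN       NaN           NaN           NaN           NaN           NaN      89.177372
```

Reading: with in vivo relaxation constants (OFCB T₁ = 17.77 ms, T2* = 3.4 ms;
PFP T₁ = 12.8 ms, T2* = 2.2 ms), OFCB's normalized SNR is predicted ~86%
higher during an 11-s breath-hold (NSA 16 vs 24), ~96% higher during
continuous breathing at the 70° Ernst angle (NSA 144 vs 221, normalized by
the breath-hold NSAs), and ~85% higher in the full-recovery 90° regime
(NSA 29 vs 41) — roughly a 90% average advantage at equal scan time.

A full simulated study — lung-phantom images for both gases, ROI SNR,
normalization, paired t test and Bayes factor — runs from the shell:

```
f19lung end-to-end --seed 1 --animals 5 --outdir out/
f19lung reproduce-theory
f19lung simulate spectrum --gas pfp-pure --seed 3 --out spec.csv
f19lung fit-t2star spec.csv --peaks 2
```

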