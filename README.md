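# muscleqmri

Multimodal, non-invasive assessment of skeletal-muscle fibrosis from
quantitative NMR and ultrasound shear-wave elastography (SWE), built as a
tested analysis pipeline with a calibrated synthetic cohort generator
standing in for the paired injured/control mouse cohort.

## The problem

Muscle fibrosis — collagen accumulation in the extracellular matrix — is
usually quantified by histology of biopsies. Several in-vivo measurements
are sensitive to it, each through a different physical mechanism:

- **ECV** (extracellular volume fraction), from gadolinium-induced
  relaxation-rate changes in muscle vs plasma:
  `ECV = (ΔR1)_muscle / (ΔR1)_plasma`, with `R1 = 1/T1` measured pre/post
  contrast by saturation-recovery T1 mapping
  (`S(TR) = M0·(1 − eff·e^{−TR/T1})`).
- **T2 maps** from a 32-echo MSME acquisition (5.15 ms spacing), estimated
  by matching each voxel decay to a dictionary of extended-phase-graph
  (EPG) echo trains over a (T2, B1) grid — necessary because a surface
  coil's variable refocusing angle creates stimulated echoes that bias a
  mono-exponential fit.
- **CPMG T2 spectra** (200 echoes, 1 ms spacing): discrete 1/2/3-component
  exponential fits `S = Σ_k M0k·e^{−TE/T2k}`, compared by F-tests.
- **UTE T2\***: 16-echo ultra-short-TE decays fitted with
  `S = |A_short·e^{(−1/T2*_s + 2πi·970 Hz)·TE} + A_long·e^{−TE/T2*_l}|`,
  i.e. a bi-exponential whose short component is chemically shifted 970 Hz
  off water.
- **ASL perfusion** over a rest → cuff-ischemia → reperfusion paradigm:
  `f = (λ/T1m)·r/(e^{−tT/T1a} − r)` with `r = (M − M⁺)/M`, summarized by
  the rest baseline, the peak reperfusion flow, and the total repaid
  volume (baseline-subtracted integral over reperfusion).
- **SWE viscoelastic index** `SMi = (SM80 − SM0)/SM0` from shear moduli at
  0° and 80° ankle plantar flexion.
- **Histogram texture** (skewness, Pearson kurtosis, energy `Σ p_i²`) over
  ROI intensities of high-resolution T1-weighted images.

The statistics layer ties these to histological collagen fraction: paired
Wilcoxon tests, Spearman and partial Spearman correlations (rank
residualization on ordinal histology scores and perfusion covariates), a
14%-collagen fibrosis classification, ROC AUC with DeLong confidence
intervals, and an equal-weight signed composite index that combines
robust-standardized metrics.

Because no cohort data are deposited, `muscleqmri.synth` generates every
signal type with known ground truth, calibrated so that group medians and
metric–collagen rank correlations match the reference values. The tests
and the acceptance script demonstrate that the full fitting pipeline
recovers these calibrated truths.

## Worked example

```python
from muscleqmri import (gen_t1_series, fit_t1, compute_ecv, get_preset,
                        build_t2_dictionary, epg_cpmg_forward, match_t2)

preset = get_preset("pooled_injured")

# T1 fitting at the 13-TR saturation-recovery protocol
fit = fit_t1(gen_t1_series(1649.9))
print(round(fit.t1_ms, 1))          # 1649.9

# ECV from muscle/plasma T1 pre/post contrast
ecv = compute_ecv(1650, 1200, 2200, 400)
print(round(ecv.ecv, 4))            # 0.1111

# EPG-dictionary T2 mapping at B1 = 0.9
d = build_t2_dictionary()           # T2 5-80 ms x B1 0.4-1.2, ~31k atoms
sig = epg_cpmg_forward(preset.t2_msme_ms.median, 1650.0, 0.9, 5.15, 32)
t2, b1, score = match_t2(sig, d)
print(t2, b1)                       # 21.4 0.9
```

The numbered scripts under `analysis/` run the narrative end to end —
`01_simulate_cohort.py` (paired 18-animal cohort), `02_parameter_recovery.py`
(noiseless truth-vs-recovered table; max relative error ~1e-15),
`03_cohort_statistics.py` (paired tests and collagen correlations),
`04_roc_composite.py` (univariate ROC and the composite-index AUC
trajectory) — writing their tables under `results/`.

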