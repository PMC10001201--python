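# pdxsynergy

Analysis toolkit for discovering and validating **two-drug synergy** in
breast-cancer cell lines and patient-derived xenografts (PDXs): plate-reader
viability normalization, coefficient-of-drug-interaction (CDI) anchor
screening, Chou–Talalay median-effect combination-index analysis, in-vivo
tumor-growth synergy scoring, and the companion expression arm
(gene-signature scoring/clustering, single-cell QC, signature-restricted
PCA, antibody-array normalization). A seed-reproducible synthetic-data
generator provides ground-truth inputs for every stage.

It is written for preclinical pharmacology and translational genomics
groups who run anchor-drug combination screens (e.g. a drug library on top
of a PI3K inhibitor) and follow up hits in fixed-ratio dose-escalation
designs and mouse trials.

## The statistics at the core

**CDI (coefficient of drug interaction).** On viability fractions,

```
CDI = v_AB / (v_A · v_B)
```

CDI = 1 is Bliss independence, CDI < 1 synergy, CDI < 0.7 *significant*
synergism, CDI > 1 antagonism. The same ratio applied to vehicle-normalized
mean final tumor sizes scores in-vivo synergy.

**Median-effect / combination index.** Each agent (and each fixed-ratio
mixture, on total dose) is fitted to the median-effect equation

```
fa / fu = (D / Dm)^m,          fu = 1 − fa
```

by least squares on the log-linearized form. At an effect level fa, with
Dx_i(fa) the single-agent dose reaching fa and d_i the component doses
inside the combination reaching the same fa,

```
CI(fa)  = d_A / Dx_A(fa) + d_B / Dx_B(fa)       (CI < 1 ⇒ synergy)
DRI_i   = Dx_i(fa) / d_i                        (DRI > 1 ⇒ dose saving)
```

The range of interest for cytotoxic combinations is high fractional kill,
fa ≥ 0.75.

## Worked example

Simulate two inhibitors and a synergy-built-in 1:1 mixture (interaction
factor 0.5), normalize to vehicle, fit, and profile CI/DRI:

```python
import numpy as np
from pdxsynergy import assay_io, median_effect as me, synthgen as sg

spec = sg.SimulationSpec(seed=11, noise_cv=0.05, replicates=3)
plate_a = sg.sim_dose_response(spec, m=1.8, dm=2.0,
                               doses=sg.effect_range_doses(1.8, 2.0), compound="BYL719")
plate_b = sg.sim_dose_response(spec, m=1.8, dm=6.0,
                               doses=sg.effect_range_doses(1.8, 6.0), compound="afatinib")
dm_mix = 1 / (0.5 / 2.0 + 0.5 / 6.0)
doses_c = dm_mix * (49 ** (1 / 1.8)) ** np.linspace(-1, 1, 9)
plate_c = sg.sim_combination_surface(spec, (1.8, 2.0), (1.8, 6.0), (1, 1),
                                     doses_c.tolist(), model="interaction", kappa=0.5)

def fit(plate):
    norm = assay_io.normalize_viability(plate)
    sub = norm[norm["compound"] != "vehicle"]
    fa = 1 - assay_io.pct_to_fraction(sub["viability_pct"])
    return me.fit_median_effect(sub["dose_uM"].to_numpy(), fa)

fit_a, fit_b, fit_c = fit(plate_a), fit(plate_b), fit(plate_c)
profile = me.ci_dri_profile(fit_a, fit_b, fit_c, me.ComboDesign(ratio=(1, 1)))
```

Output:

```
BYL719           m = 1.91   Dm = 2.09 uM   r = 0.9995
afatinib         m = 1.87   Dm = 6.26 uM   r = 0.9959
1:1 mix          m = 1.90   Dm = 1.67 uM   r = 0.9974
CI at fa=0.75: 0.53   min DRI in ROI: 2.48
synergistic in ROI: True
```

The fitted slopes and median-effect doses recover the simulated truth to a
few percent at 5% assay noise; the combination index ≈ 0.5 across the
high-kill range reproduces the planted interaction strength, and both
drugs could be dosed ~2.5× lower in combination for the same effect.

The same analyses are exposed on the command line (`synergy normalize`,
`synergy mutations --gene PIK3CA`, `synergy screen`, `synergy venn`,
`synergy compusyn`, `synergy invivo`, `synergy signatures`, `synergy scqc`,
`synergy sigpca`, `synergy simulate`).

## Layout

- `src/pdxsynergy/assay_io.py` — viability tables, vehicle normalization, mutation panel
- `src/pdxsynergy/median_effect.py` — median-effect fits, CI/DRI profiles
- `src/pdxsynergy/cdi_synergy.py` — CDI, anchor screens, hit intersections, screen correlation
- `src/pdxsynergy/invivo.py` — tumor trials, final-size ANOVA/Tukey, in-vivo CDI
- `src/pdxsynergy/signatures.py` — signature scoring, clustering, cell QC, signature PCA, antibody arrays
- `src/pdxsynergy/synthgen.py` — ground-truth synthetic data generators
- `src/pdxsynergy/calibration.py` — end-to-end recovery benchmarks
- `docs/methods.md` — models, assumptions, parameter choices, limitations
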