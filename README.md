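# segquant

Propagation of brain-tissue segmentation variability into
water-referenced MRS metabolite concentration estimates.

## The problem

"Absolute" metabolite concentrations from single-voxel in vivo magnetic
resonance spectroscopy (MRS) are obtained by referencing the metabolite
signal to the unsuppressed water signal and correcting for the tissue
composition of the acquisition voxel.  That correction depends on the
gray-matter (GM), white-matter (WM) and CSF fractions inside the
cm-scale MRS voxel, which are estimated by segmenting an anatomical
image — and different segmentation tools (ANTs, FSL, SPM) disagree
systematically about those fractions.  This package quantifies how that
disagreement propagates into the final concentration estimates for a
test-retest study design: it extracts voxel tissue fractions from
probability maps, applies the tissue-and-relaxation correction, and
runs the repeated-measures inference battery that separates
method-driven differences from session-to-session noise.

## The model

The molar concentration of metabolite M is

```
[M] = (S_M / S_H2O) * (f_GM d_GM R_GM + f_WM d_WM R_WM + f_CSF d_CSF R_CSF)
      / ((1 - f_CSF) R_M) * [H2O]
```

with `f_x` the fractional volumes of GM/WM/CSF in the voxel, `d_x` the
compartment water densities (0.78 / 0.65 / 0.97), `R_x = exp(-TE/T2) *
(1 - exp(-TR/T1))` the compartment-specific water relaxation
attenuation, `R_M` the metabolite relaxation attenuation, `[H2O]` =
55.51 mol/L, and the `(1 - f_CSF)` denominator excluding CSF from the
metabolite-bearing volume.  At fixed signals the estimate is
proportional to the water-side correction factor, so between-method
fraction differences translate directly into concentration differences.

The statistics follow the study's design: Method x Session
repeated-measures models with a participant random intercept (fit as
the exactly equivalent balanced ANOVA), estimated marginal means,
Tukey-HSD pairwise contrasts, within-/between-method percent
differences, Pearson age associations with the normalized GM fraction
`f_GM / (f_GM + f_WM)`, and Steiger's Z for comparing the dependent
correlations across methods.  A synthetic-study generator emulates the
full test-retest design (13 participants x 2 sessions x 3 methods) with
known true concentrations, so every pipeline stage is checked against
ground truth.

## Worked example

```python
import segquant as sq

cfg = sq.default_quant_config()          # TE/TR = 35/2000 ms, 3 T relaxation
att, _, k = sq.attenuation_from_config(cfg)

# Mean voxel compositions reported by two segmentation methods
fsl = sq.TissueFractions(0.43, 0.30, 0.26)
spm = sq.TissueFractions(0.56, 0.27, 0.17)
cf_fsl = sq.correction_factor(fsl, att, k)   # 0.5323
cf_spm = sq.correction_factor(spm, att, k)   # 0.4925
print(sq.group_percent_difference(cf_fsl, cf_spm).value_pct)  # 7.78
```

The printed 7.78 is the percent difference in estimated concentration
(same spectra, same modeling) attributable purely to the segmentation
disagreement between the FSL-like and SPM-like mean compositions.

The full synthetic study is driven by the numbered scripts:

```
python analysis/01_simulate_study.py     # study table, seed 42
python analysis/02_phantom_fractions.py  # voxel-mask extraction vs geometry
python analysis/03_quantify.py           # per-method tCr concentrations
python analysis/04_propagation_stats.py  # ANOVA, Tukey, percent differences
python analysis/05_csf_sensitivity.py    # d[M]/df_CSF across CSF fractions
```

`04_propagation_stats.py` prints, for the default run:

```
tCr Method effect: F(2,60) = 116.32, p = 2.26e-21
Tukey contrasts (tCr, mM):
  ANTS - FSL: -0.40 (SE 0.04, t = -9.33, p = 8.46e-13)
  ANTS - SPM: +0.25 (SE 0.04, t = 5.79, p = 8.23e-07)
  FSL - SPM: +0.66 (SE 0.04, t = 15.12, p = 7.99e-15)
Between-method percent differences (session-averaged):
  ANTS vs FSL: 5.5%   ANTS vs SPM: 3.6%   FSL vs SPM: 9.1%
```

i.e. a strong segmentation-method effect on the quantified tCr (largest
between FSL and SPM, ~9%) even though every method saw the same
signals, while sessions do not differ.  A `segquant` command-line
interface exposes the same stages (`simulate`, `fractions`, `quantify`,
`compare`, `report`).

## Layout

- `src/segquant/` — library: `voxel_anatomy` (mask + fraction
  extraction), `quantification` (correction model and its inverse),
  `comparison` (percent differences, CSF sensitivity), `study_stats`
  (ANOVA/Tukey/correlations/Steiger), `synthetic` (study generator and
  phantoms), `pipeline`, `report`, `cli`.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — modeling assumptions, defaults and limitations.
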