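# comboscreen

Analysis pipeline for fixed-ratio drug-combination viability screens, of the
kind used to find combinatorial regimens against treatment-resistant tumors
(e.g. melanoma progressing on immune checkpoint blockade), plus the in vivo
growth-curve statistics used to validate hits. It is aimed at lab
bioinformaticians and screening groups who have long-format plate readouts
and want a reproducible, scriptable alternative to spreadsheet + commercial
point-and-click analysis.

## What it computes

**Viability normalization.** Percent viability of a well is
`Treatment_A / Control_A × 100%`, where `A` is absorbance and the control
value is the mean over a model line's vehicle wells. Values above 100% are
retained and flagged, never clamped.

**Median-effect curve fitting.** Each 6-point concentration–response curve
(serial dilution anchored at the drug's clinical peak plasma concentration
C_max) is summarized with the median-effect model

```
fa / fu = (D / Dm)^m,     fa = 1 − viability/100,  fu = 1 − fa
```

fit as an ordinary least-squares line of `log10(fa/fu)` on `log10(D)`.
`Dm` is the dose for a 50% effect, `m` the sigmoidicity.

**Fixed-ratio combinations and the combination index.** Two drugs are mixed
at the constant molar ratio of their C_max values and screened at two levels,
C_max and 10% C_max. For a combination delivering doses `(D1, D2)` at
measured fraction affected `fa`, the Chou–Talalay combination index
(mutually exclusive form) is

```
CI = D1 / Dx1(fa) + D2 / Dx2(fa),      Dx_i = Dm_i · (fa/(1−fa))^(1/m_i)
```

CI < 1 indicates synergism, CI = 1 additivity, CI > 1 antagonism.

**Cross-model ranking.** Treatments × model-lines matrices of % viability
(or trapezoid AUC, `Σ ΔX·(Y1+Y2)/2`, over log10 dose) are ranked by
cross-model mean — lower means more effective — with bootstrap confidence
limits for AUCs.

**In vivo statistics.** Tumor volume is `length × width² / 2`; treatment
arms are compared by a two-sided randomization (permutation) test on a
per-animal growth summary (volume-vs-day AUC by default), exact when the
relabeling count permits and Monte Carlo otherwise, with Bonferroni
correction across comparisons.

**Synthetic data with known truth.** Generators produce every input the
pipeline consumes: single-agent plates from known `(Dm, m)`, fixed-ratio
combination plates whose fraction affected solves the Loewe additivity
equation with a potency-boost interaction ψ (so the true CI is exactly 1/ψ),
multi-model screens with a planted dominating combination, and stochastic
exponential tumor-growth studies. These power the test suite end to end.

## Worked example

Simulate one drug pair with a two-fold potency-boost synergy (true CI = 0.5),
fit the single agents, and profile the combination:

```python
from comboscreen import *

ta = DrugTruth("cobimetinib", dm=0.25, m=1.5, cmax=0.5)
tb = DrugTruth("regorafenib", dm=6.0, m=2.0, cmax=8.1)
design = CombinationDesign("cobimetinib", "regorafenib", 0.5, 8.1)
records = (
    simulate_single_agent_plate(ta, noise_sd=0.02, seed=1, model_id="MM-337")
    + simulate_single_agent_plate(tb, noise_sd=0.02, seed=2, model_id="MM-337")
    + simulate_combination_plate(
        ta, tb, InteractionTruth("cobimetinib", "regorafenib", psi=2.0),
        design=design, noise_sd=0.02, seed=3, model_id="MM-337",
        include_controls=False)
)
curves = {c.treatment_id: c for c in normalize_viability(records)}
fit_a = fit_median_effect(curves["cobimetinib"])
fit_b = fit_median_effect(curves["regorafenib"])
print(f"cobimetinib:  Dm = {fit_a.dm:.3f} uM, m = {fit_a.m:.2f}, r2 = {fit_a.r2:.3f}")
print(f"regorafenib:  Dm = {fit_b.dm:.3f} uM, m = {fit_b.m:.2f}, r2 = {fit_b.r2:.3f}")
for p in ci_profile(curves["cobimetinib+regorafenib"], fit_a, fit_b, design).points:
    print(f"fa = {p.fa:.3f}  total dose = {p.total_dose:7.3f} uM  "
          f"CI = {p.ci:.3f}  ({p.label})")
```

prints

```
cobimetinib:  Dm = 0.322 uM, m = 0.98, r2 = 0.926
regorafenib:  Dm = 6.753 uM, m = 1.58, r2 = 0.963
fa = 0.005  total dose =   0.027 uM  CI = 1.087  (antagonism)
fa = 0.028  total dose =   0.086 uM  CI = 0.694  (synergism)
fa = 0.055  total dose =   0.272 uM  CI = 1.119  (antagonism)
fa = 0.355  total dose =   0.860 uM  CI = 0.460  (synergism)
fa = 0.782  total dose =   2.720 uM  CI = 0.303  (synergism)
fa = 0.962  total dose =   8.600 uM  CI = 0.212  (synergism)
```

The single-agent fits recover the simulated potencies to within plate noise.
At mid-to-high effect levels the CI sits well below 1, flagging the planted
synergy; the scatter at `fa < 0.1` is expected — there the fraction affected
is the small difference between a noisy well and its control, and CI
estimates at extreme effect levels should be read with caution (the
conventional reporting window is roughly ED50–ED90).

The same stages are available from the shell:

```
comboscreen simulate --out-dir data --seed 5
comboscreen rank --plates data/plates.csv --level cmax10 \
    --out-matrix out/matrix.csv --out-ranking out/ranking.json
comboscreen growthtest --measurements data/measurements.csv \
    --group-a vehicle:treated --out out/growth.json
comboscreen run --config config.yaml --plates data/plates.csv --out-dir out
```

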