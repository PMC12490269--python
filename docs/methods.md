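# Methods

This note documents the statistical models, defaults, and numerical choices
behind `comboscreen`, and what the synthetic-data validation does and does
not establish about real screening data.

## Viability normalization

Raw absorbances are normalized per model line: the control level is the mean
absorbance of all vehicle (`is_control`) wells of that model, and each
treated well maps to `absorbance / control_mean × 100` percent viability.
Consequences of this choice:

* control wells average exactly 100% by construction;
* viability above 100% (wells outgrowing the control) is biologically
  meaningful noise and is retained, flagged per replicate, and never
  clamped — downstream stages decide how to treat it;
* a model with no control wells, or a nonpositive control mean, is a hard
  error naming the model. Zero-concentration wells must be flagged as
  controls; a treated record at zero dose is rejected rather than fitted.

## Median-effect model

Each curve is summarized by the median-effect equation
`fa/fu = (D/Dm)^m`, which is linear in log–log coordinates:
`log10(fa/fu) = m·log10(D) − m·log10(Dm)`. The fit is unweighted ordinary
least squares on this line (the classical median-effect plot), with:

* **Replicate handling.** Replicates are averaged to one `fa` per dose
  before regression; per-dose SD is kept on the curve object for reporting.
* **Clipping.** The linearization is undefined at `fa ∈ {0, 1}`. Mean `fa`
  outside `(clip_eps, 1 − clip_eps)` — default `clip_eps = 0.005` — is
  excluded from the regression (and counted in `n_clipped`); optionally such
  points can instead be clipped to the band and included. At least two
  interior doses are required.
* **Validity.** A nonpositive fitted slope (no dose response, or an
  inverted one) is an error, not a silent bad fit; `r²` of the line is
  reported as the goodness diagnostic.

The forward equation is evaluated as `fa = 1/(1 + (Dm/D)^m)`, which is
stable for doses far above `Dm` where `(D/Dm)^m` would overflow.

## Dose ladders

Ladders are serial dilutions from a top dose anchored at the drug's clinical
C_max. The dilution factor of the screening design is not fixed by the assay
definition; the default is half-log (√10 ≈ 3.162), so a 6-point ladder spans
2.5 orders of magnitude and — usefully for the fixed-ratio design — contains
both the top dose and exactly 10% of it (two half-log steps). A factor of 10
also contains the 10% level; arbitrary factors are accepted for single-agent
work.

## Fixed-ratio combinations and the combination index

At scale level `s` a pair delivers `(s·cmax_a, s·cmax_b)`: the molar ratio
`cmax_a : cmax_b` is constant while the total dose varies, and the screen's
two levels are `s = 1` (C_max) and `s = 0.1`. A combination plate's
"concentration" column carries the total dose of the mixture; the design
splits it with weights `w_a = cmax_a/(cmax_a + cmax_b)`, `w_b = 1 − w_a`.

The combination index at a point is the mutually exclusive Chou–Talalay
form, `CI = D1/Dx1(fa) + D2/Dx2(fa)`, with no third cross-term; the
non-exclusive (conservative) variant is deliberately not implemented. Two
asymmetries are intentional and mirror screening practice:

* `fa` at each combination dose comes from the **measured** combination
  viability (replicate mean, clipped like the single-agent fit);
* the iso-effective doses `Dx_i` come from the **fitted** single-agent
  median-effect models of the same model line.

Points whose combination `fa` falls outside the clip band are excluded and
counted; a profile with no interior point is an error. Because a strict
CI = 1 is unattainable with noise, labels use a band: |CI − 1| ≤ 0.05 is
reported "additive", below that synergism, above antagonism.

CI estimates at extreme effect levels are intrinsically ill-conditioned:
near `fa → 0` (or 1) the measured fraction affected is the small difference
between a noisy well and its control, and a 1% absorbance error is a large
relative error in `fa` (or `fu`). The validation suite therefore reads
per-seed CI bands on the mid-effect window (roughly ED50–ED90) and uses
medians when pooling across the full profile.

## AUC and ranking

The screen's cross-model effectiveness summary is the trapezoid area under
the viability curve, `Σ ΔX·(Y1 + Y2)/2` over adjacent dose pairs. The dose
axis is `log10`(µM) by default — the standard choice for sigmoidal screening
curves, giving each dilution step equal weight — with a linear axis
available. AUC confidence limits are nonparametric bootstrap percentiles
(resampling replicates within dose; 1000 resamples, seeded).

Screen matrices (treatments × models) hold either % viability at one
fixed-ratio level or per-curve AUC. A missing (treatment, model) cell is a
hard completeness error — never an implicit zero, which would silently
promote the treatment in the ranking. Ranking sorts treatments by ascending
cross-model mean (lower viability/AUC = more effective), breaking exact ties
lexicographically and reporting them. Ranking is invariant to rescaling all
cells by a common positive factor. Heatmap rendering follows the screening
convention: 0% viability darkest red, 100% white; cells above 100% are drawn
white and remain flagged in the matrix.

## Growth-curve statistics

Tumor volume from caliper length and width is `L·W²/2` (mm³); measurements
with width > length are swapped and flagged rather than rejected. The
default per-animal summary is the trapezoid AUC of volume over days (the
whole-trajectory burden); endpoint volume is available as an alternative.
The original screening studies do not pin down the permuted statistic, so
the default is documented, not claimed to match.

The randomization test permutes arm labels over animals and computes the
two-sided p-value of the absolute difference in group means. With at most
20,000 distinct relabelings the null distribution is enumerated exactly
(the identity relabeling counts, so p ≥ 1/N and p = 1 for identical groups);
otherwise `n_perm` Monte Carlo draws are used with the add-one correction
`p = (b+1)/(n_perm+1)`. Relabelings exactly as extreme as the observed one
must count as hits, so the comparison carries a slack of 1e−9 relative to
the magnitude of the summaries — with an absolute epsilon, float round-off
on summaries of order 10³ silently dropped the observed statistic's own
ties and biased Monte Carlo p-values low. Note the granularity limit of
exact enumeration: at 4+4 animals each relabeling pairs with its mirror, so
attainable two-sided levels are k/35 and the best achievable size at
α = 0.05 is 1/35 ≈ 0.029; calibration studies should use ≥ 6 animals per
arm. Bonferroni correction multiplies each p by the family size, capped
at 1.

## Synthetic-data generators

The generators define the validation conditions with known ground truth:

* **Single-agent plates.** Control absorbance has mean 1.0; a treated
  well's expectation is `(1 − fa(D))` times control. Noise is multiplicative
  Gaussian (relative sd, default 2% — typical of replicate CVs in
  luminescence/absorbance viability assays), truncated at zero because
  plate-reader noise scales with signal. Three replicate wells per dose.
* **Combination plates.** The combined fraction affected at component doses
  `(d_a, d_b)` solves the Loewe additivity equation with a potency boost ψ:
  `ψ·d_a/Dx_a(fa) + ψ·d_b/Dx_b(fa) = 1`, found by bracketed root-finding
  (Brent, tolerance near machine precision) on `fa ∈ (0, 1)`, where the
  left side is strictly decreasing. ψ = 1 is exact Loewe additivity; ψ > 1
  behaves as if both doses were multiplied by ψ. This one-parameter
  interaction was chosen because it yields a closed-form expected CI of
  exactly 1/ψ, making the whole generator → normalize → fit → CI pipeline
  self-checking; fa-dependent interaction surfaces are out of scope. A zero
  dose on either side reduces exactly to the other drug's single-agent
  response.
* **Screens.** Five combinations × seven model lines by default. Drug
  potencies are drawn narrowly around `Dm = 2×C_max` (0.15 log10-sd,
  slope m ~ U(1, 2)) so single agents are modest at their C_max, as in
  practice; a shared per-model sensitivity factor (0.1 log10-sd) shifts
  whole columns without reordering treatments. The first combination gets
  ψ = 3, the rest ψ = 1. Dominance of the planted winner is part of the
  generator's contract, not left to chance: a competitor whose expected
  noiseless cross-model viability at the ranking level (10% C_max) comes
  within 3 percentage points of the planted combination's is redrawn.
* **Growth studies.** Per-animal volumes follow
  `V(t) = V0·exp(rate·effect·t)` with lognormal measurement noise
  (sd 0.15 on the log scale). Defaults: V0 = 70 mm³ (a typical enrollment
  threshold), rate 0.25/day (doubling ≈ 2.8 days, in the range of
  aggressive syngeneic melanoma models), measurements every 3 days through
  day 21, 8 animals per arm. Volumes convert to caliper pairs with
  `L = W = (2V)^(1/3)` so the volume formula round-trips exactly.

All generators are bit-reproducible under a fixed seed.

**What passing tests show — and don't.** The synthetic plates have
independent, homoscedastic-relative noise, no spatial plate effects, no
edge artifacts, and single-agent behavior that follows the median-effect
model exactly; the growth model is exponential with independent lognormal
errors. Validation against them demonstrates that the *analysis* is correct
and calibrated under its own model assumptions (CI recovers 1/ψ, the
permutation test holds its size, the ranking recovers a truly dominant
combination). It does not establish robustness to model misspecification in
real data — non-sigmoidal curves, plate gradients, correlated replicates,
or growth plateaus.

## Validation problem sizes

The shipped suites use sizes chosen to make the statistical assertions
sharp while keeping the full run in the order of seconds: 50 seeds for the
noisy Loewe-null CI calibration, 200 seeds for noisy parameter recovery,
100 replicate screens for planted-winner recovery, and 1000 null studies
for permutation-test size (at 8/arm, where exact enumeration has fine
granularity).

## Pipeline and reproducibility

`run_pipeline` wires the stages together: normalize → single-agent fits →
CI profiles for configured pairs → matrices at each fixed-ratio level →
ranking (at 10% C_max by default) → optional growth comparisons with
Bonferroni correction. CSV readers are strict — one malformed row fails the
whole file, with all problems listed by line number — because silently
dropping rows corrupts ranking matrices. All randomness (bootstrap,
Monte Carlo permutations) flows from the single configured seed via seed
sequences, and the result bundle, including every written file, is
deterministic given inputs + config.

## Known limitations

* No 4PL/5PL logistic fitting or profile-likelihood IC50 intervals, and no
  plate spatial-effect correction.
* Only the mutually exclusive CI variant; no dose-reduction index,
  isobolograms, or Bliss/HSA/ZIP scores.
* The randomization test assumes exchangeable animals under the null; no
  mixed-effects or repeated-measures modeling of growth curves.
* The additive label band (|CI − 1| ≤ 0.05) is a reporting convention, not
  a significance test; CI uncertainty is not propagated from fit errors.
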