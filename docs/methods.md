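# Methods

## Scope and model

`matepref` simulates and analyses fully factorial no-choice mating
assays among isogenic lines. The scientific objects are:

1. **Preference functions.** A chooser's relative response to a mate
   with trait value *t* > 0 is either open-ended,
   *r(t) = e^(y·ln t) = t^y* (one parameter, the steepness *y*; the
   trait enters on the natural-log scale), or unimodal,
   *r(t) = exp(−(t − y)²/(2ν²))* (peak preference *y* in trait units,
   width ν > 0). A population of choosers is a sample of parameter
   values; its response matrix over a male trait grid is normalised
   per chooser (rows sum to 1 by default, max = 1 optionally — the
   choice rescales rows and cannot change any ranking). Population-level
   preference is the column mean; attractiveness ranks are average ranks
   of that vector, larger = more attractive.

2. **Trial generation.** Each (male line × female line) cell accrues
   trials until a mating quota is met (default ≥ 10 matings, hard cap
   per cell), mirroring the replicate-until-enough-matings field
   protocol. All three response channels are log-normal:
   ln(courtship latency) = baseline + male propensity + female
   attractiveness-to-males + noise; ln(copulation latency) = baseline −
   stimulus·scale + female responsiveness + noise, censored at the
   recording limit (default 3600 s, unmated pairs recorded at exactly
   that value); ln(copulation duration) similarly, defined only for
   mated pairs. The *stimulus* is the female line's preference response
   to the male line's trait, normalised per female to max 1, optionally
   multiplied by a per-female-line discrimination strength. Ages are
   uniform integers on 3–6 days, independent of line. Array and chamber
   identifiers are pure labels.

   The empirical studies this mimics analyse but do not model their
   data; the log-normal link with a linear stimulus → log-latency map
   (higher preference → shorter latency) is an explicit artifact
   assumption of this package, chosen because latency distributions are
   right-skewed and the analysis stage fits log-scale linear models.

3. **Preference components.** From per-cell means of a channel:
   responsiveness (unweighted mean over partner lines), choosiness
   (sample SD among cell means, n−1 denominator; alternatives CV, CV²,
   (max − mean)/total trial SD, (max − mean)/trial SD within the max
   cell), global attractiveness (unweighted mean over chooser lines)
   and its inverse. Copulation latency is female-controlled (chooser =
   female line); courtship latency and copulation duration are
   male-controlled. Components are computed on raw seconds by default
   with a log-scale option; copulation-latency cells use mated trials
   only by default, with a censor-capped option (both exposed because
   the field convention is ambiguous and the choice is a genuine
   sensitivity axis).

4. **Inference.** Log-scale OLS with Type-III tests (sum-to-zero
   coding) for the male-controlled channels; Cox proportional hazards
   (Efron ties) for the censored female channel, with per-effect
   likelihood-ratio χ² from drop-one nested refits; Levene's test
   (classic mean-centred; median option = Brown–Forsythe) for variance
   heterogeneity among chooser lines; Benjamini–Hochberg FDR within a
   channel's effect family; OLS regression of female-line choosiness on
   male-line inverse attractiveness for the line-level genetic
   correlation; Kendall's W (tie-corrected) with an independent-
   permutation null for rank concordance.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| open-ended steepness y | N(2, 0.3) | — | canonical population used throughout the simulations |
| unimodal peak y | N(10.5, 2) | trait units | canonical variable-peak population |
| unimodal width ν | 15 fixed, or N(15, 7) | trait units | wide preferences relative to the trait grid |
| trait grid | 10 points, 4.5–16.5 | trait units | peak mean ± 3 SD; endpoints are not biologically pinned, only the spread matters |
| censor time | 3600 | s | one-hour recording limit |
| mating quota / cap | 10 / 40 per cell | trials | field protocol; cap bounds worst-case effort |
| noise_sd | 0.8 | log-seconds | realistic trial-to-trial scatter; validation studies use 0.2 ("low noise") where stated |
| stimulus_scale | 1.5 | log-seconds | most- vs least-preferred male line differ ~4.5× in median latency |
| baselines | ln-copulation 6.8, ln-courtship 4.0, ln-duration 7.0 | log-seconds | ≈ 900 s, 55 s, 1100 s medians, fly-realistic |

`paper_like_design()` raises the copulation baseline (7.6) and noise
(0.9) so the weakest cells sit near the censor limit and per-cell mating
proportions span roughly 0.4–1.0, like published factorial data.

Sampled ν ≤ 0 under N(15, 7) is rejection-sampled until positive:
truncation preserves ν > 0 at a small, quantifiable cost to the nominal
mean/SD, and no published truncation point exists to copy.

## Design choices in the discrimination rule

`discriminate_models` labels a trial table by combining Kendall's W
across female lines' male-line rankings with the genotype × genotype
interaction in the Cox model:

- **open_ended_or_shared_peak**: W ≥ 0.9 *and* the concordance
  permutation test significant;
- **variable_peak_unimodal**: W < 0.9 *and* the interaction LR test
  significant;
- **inconclusive** otherwise.

Two deliberate choices here. First, "W significantly below 1" admits no
exact test when cell means carry sampling noise (observed W is < 1
almost surely), so a high-W threshold (default 0.9) plus the permutation
test against the no-shared-ranking null stands in for it. Second, the
interaction test is *not* required to be non-significant for the
open-ended label: variation in open-ended steepness produces a genuine
magnitude-only G×G interaction (different females spread their responses
differently across the same ranking), which the LR test detects at low
noise even though every female ranks males identically. Concordance,
not interaction, is the quantity that separates the classes; the
interaction requirement is kept only where it adds evidence (the
variable-peak side, where discordant rankings must also be statistically
supported).

## Validation studies (matepref.studies)

All studies are seeded and recomputed from scratch by
`scripts/acceptance.py`; sizes are scaled to run on one CPU in minutes.

- **Closed forms.** Both response functions agree with their analytic
  expressions to machine precision on a 100-point grid.
- **Ranking invariants.** Open-ended populations and shared-peak
  unimodal populations give W = 1 exactly (the shared peak is placed
  off-centre of the grid so no two males are exactly equidistant from
  it; a symmetric peak creates genuine ties, which average ranks handle
  but floating-point rounding can split); variable-peak populations
  (y ~ N(10.5, 2), ν ~ N(15, 7), 10 females × 10 males) give W < 1 in
  ≥ 95% of 200 replicates.
- **Statistic oracles.** Every component statistic and Kendall's W
  match independent from-definition recomputations on random small
  fixtures (tests), and W matches the Friedman statistic identity
  χ² = m(n−1)W including tie corrections.
- **Null calibration.** Levene stage: 10 lines × 100 trials of
  equal-variance log-normal latencies, applied on the log scale (where
  the mean-centred statistic is calibrated; on raw skewed seconds
  classic Levene is intrinsically liberal — that is a property of the
  statistic, not of the implementation), 4000 replicates. OLS stages:
  4×4 lines × 3 trials/cell with all effects null, censoring disabled,
  2500–4000 replicates; the F tests are exact under the log-normal
  generator. Cox stage: 3×3 lines × 30 trials/cell, ~23% censoring,
  constant assay age, male-genotype drop-one LR, 2000–3000 replicates.
  The age factors are held out of the Cox calibration deliberately:
  with the full 16-parameter model at ~205 events the drop-one LR's
  true size is ≈ 0.062 (measured at 4000+ replicates against an
  independent proportional-hazards implementation, which agrees with
  this one to four decimals on identical data), a finite-sample
  parameter-load effect of likelihood-ratio tests generally, not of
  this implementation; in the constant-age (10-parameter) regime the
  measured size is ≈ 0.053. Users fitting many nuisance parameters per
  event should expect mildly liberal LR effect tests — see Known
  limitations.
- **Closed-loop discrimination.** 6×6 lines, quota 15 matings/cell,
  noise 0.2; 50 replicates per arm (open-ended vs variable-peak
  generators); accuracy ≥ 90% required for both. The design is scaled
  down from 10×10 because the drop-one Cox refits dominate runtime; the
  discrimination signal (W near 1 vs far below 1) is, if anything,
  harder at 6×6. Residual variable-peak misses are replicates whose
  sampled widths are so large that preferences are nearly flat — the
  interaction is then genuinely near-undetectable, which is the correct
  behaviour, not a power defect.
- **Genetic-correlation recovery.** 10 shared-genotype lines with
  latent trait–discrimination correlation 0.8 (log-normal male trait,
  log-normal female stimulus multiplier), 30 matings/cell, noise 0.2,
  stimulus scale 0.4 — a regime where the seconds-scale choosiness and
  inverse-attractiveness functionals remain near-linear in the latents,
  so the measured line-level correlation approaches the built-in 0.8.
  With strong nonlinearity (large stimulus scale) the measured Pearson
  correlation is attenuated well below the latent value; that
  attenuation is a property of the seconds-scale functionals, documented
  here so users interpret raw-scale genetic correlations accordingly.

## What the synthetic data do and do not show

The generator reproduces the design structure (factorial lines, mating
quotas, censoring, log-scale additivity, line-level effects) but not:
multivariate male phenotypes (attractiveness here is one-dimensional by
construction), condition dependence, environmental covariates (array,
day, humidity are labels only), non-log-normal latency shapes, or
male × female interaction in the male-controlled channels (off by
default, switchable via effects construction). Passing validation
therefore shows the *procedures* are correct and well calibrated under
the stated model, not that real fly data satisfy that model.

## Numerical choices and degenerate inputs

- Rank ties: average ranks everywhere.
- Sample SDs use the n−1 denominator; singleton cells have undefined SD.
- A Cox partial likelihood that is monotone in some coefficient (a
  factor level perfectly ordering events, common at very low noise)
  halts Newton iteration; the fitter escalates a ridge penalizer through
  (1e−6, 1e−4, 1e−2), applying the same value to full and reduced fits
  so LR comparisons stay valid, and records it in the result metadata.
- Age factors with a single level are dropped from model formulas with
  a log message; factors with fewer than two levels or designs with
  empty cells raise errors naming the offending cells.
- Permutation p-values use the add-one estimator (never exactly zero);
  concordance default is 2000 permutations.
- Readers validate rather than coerce: any invariant violation (latency
  beyond the censor time, a mated pair without a duration, an unmated
  pair not at the censor time) rejects the file with CSV line numbers.

## Known limitations

- Type-III tests emulate the common commercial-stats convention via
  sum-to-zero coding; exact numerical agreement with other software's
  effect tables depends on their coding and tie-handling conventions.
- The Cox drop-one LR retains the interaction when testing a main
  effect (the Type-III analogue); the tested hypothesis is
  coding-dependent in nonlinear models, as it is everywhere this
  convention is used.
- Cox LR effect tests are mildly liberal when the model carries many
  parameters relative to events (measured ≈ 0.062 at nominal 0.05 with
  16 parameters and ~205 events; ≈ 0.053 with 10); a full 10×10 design
  with its 81-df interaction and ≥ 1000 events sits well inside the
  comfortable regime, but small pilot datasets do not.
- Under near-monotone partial likelihoods the ridge fallback biases LR
  statistics toward zero; results carry the penalizer used in their
  metadata so affected fits are identifiable.
- Choosiness measured as an SD of means conflates preference-function
  spread with residual cell-mean noise; the validation studies quantify
  (rather than remove) this at their stated sizes.
- Peak-preference *locations* are not estimable from these designs
  (attractiveness is measured, the underlying trait space is not); the
  package deliberately offers no such estimator.
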