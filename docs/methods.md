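# Methods

This note documents the statistical procedures, the synthetic-data design and
the numerical conventions of `riskreclass`, in the order the pipeline uses
them.

## Cohort and register model

The unit of analysis is a worker with baseline predictors — age (years),
self-rated health (SRH, ordinal 1 = poor … 4 = excellent), prior sickness
absence accumulated over the 2 years before baseline (days and episodes), and
the CIS fatigue sum score (integer 20–140, higher = more fatigued) — and
1-year follow-up SA aggregates. Outcomes are binary: *high SA days* (≥30
cumulated days) and *high SA episodes* (≥3 episodes).

Register conventions:

- an episode runs from the first SA day to return to work, inclusive of both
  endpoints (days 1–10 count 10 days);
- episodes of one worker separated by *fewer than* 28 calendar days are one
  episode (a gap of exactly 28 keeps them separate). The insurance rule
  speaks of *worked* days between episodes; a calendar register cannot
  distinguish worked from non-worked gap days, so the gap is measured in
  calendar days and the 28 is configurable;
- the day total of a merged episode is the sum of its constituents' inclusive
  day counts — the gap days were worked and never count as SA days.
  Consequently day totals are invariant under merging; only episode counts
  change;
- episodes straddling the observation window are clipped to it before
  counting;
- missing data are handled by complete-case filtering only, as in the study
  the package emulates; no imputation.

## Risk models

Both outcomes get an *established* logistic model (age/10, SRH as a single
ordinal term, prior SA — days/10 for the days outcome, episodes untransformed
for the episodes outcome) and an *extended* model adding fatigue/10. SRH as
one linear term (rather than dummies) matches the single per-category odds
ratio the field reports for it; prior SA days enter continuously on the
per-10-days scale anchored by the reported OR scaling. Fitting is Newton
maximum likelihood (statsmodels) with log-likelihood tolerance 1e-8 and at
most 100 iterations. Perfect separation is reported as a flagged,
non-converged model (predictions refuse to run), never as silent estimates;
a constant predictor is a validation error naming the column. Inference is
Wald throughout — symmetric CIs on the log-odds scale — matching the
conventional reporting of such models.

Risks are evaluated **in-sample** (models fit and applied to the same
cohort), as reclassification studies conventionally do; this leaves a small
optimism in the IDI that a held-out evaluation would remove.

## Hosmer–Lemeshow

Subjects are ranked by predicted risk and cut into 10 near-equal groups; a
run of tied risks at a boundary stays intact in the lower group (so groups
can be unequal, and with ≤ groups distinct risk values some groups vanish —
df follows the realised group count minus 2, floored at 1). The statistic is
χ² = Σ (O_g − E_g)² / (n_g π̄_g (1 − π̄_g)) with E_g the sum of predicted
risks, so expected-event totals equal Σ risks exactly. Groups with π̄ = 0 or
1 contribute nothing (warned). Adequate calibration is read as p ≥ 0.05. The
type-I behaviour of this recipe is verified by simulation (500 correctly
specified cohorts of n = 2,000; rejection rate required in [0.03, 0.08]).

## Reclassification metrics

- Category boundary: *low* means risk ≤ threshold, matching table headers of
  the form "≤10 % / >10 %"; boundary ties are low. The 10 % and 20 %
  thresholds are analysed as two independent binary stratifications, because
  the published tables are 2×2 per threshold, not one 3-category scheme.
- NRI component variance: (p_up + p_down − (p_up − p_down)²)/n, the standard
  binomial-difference form. The original software's CI endpoints differ from
  this formula in the second decimal (implied SE 5.62 % vs 5.58 % for the
  days/10 % events component), so recomputed CIs are compared with published
  ones at ±0.15 percentage points rather than exactly, and recomputed
  p-values within one unit of the last printed digit.
- *n.a.* semantics: when no subject in a stratum changes category the point
  estimate is mathematically 0, but the result is flagged `not_available`
  with no SE/CI/p, mirroring how such cells are published; the 0 is retained
  internally so sums remain defined.
- The overall NRI is the component sum with independent-strata SE; the
  category-free variant counts any directional risk change as a move (exact
  ties stay) and always carries a caveat note, reflecting its documented
  false-positive problem.
- IDI = slope(new) − slope(old) = mean(Δrisk | events) − mean(Δrisk |
  nonevents); its SE combines the two within-stratum standard errors of the
  mean per-subject risk difference. The algebraic identity between the three
  formulations is asserted at 1e-12.
- The bootstrap alternative resamples cases and non-cases separately
  (percentile CI, default 2,000 replicates, seeded); if the metric is
  unavailable in more than half the replicates the bootstrap result is
  flagged unavailable too.

## Synthetic cohort generator

The generator exists so that every pipeline stage has realistic, fully
specified inputs. Its defaults reproduce the emulated study's conditions:

- n = 579; age ~ Normal(44.4, 9.3); 62 % men; working hours
  ~ Normal(34.5, 8) clipped to [1, 80].
- Fatigue is a truncated normal on [20, 140] whose *parent* mean/SD are
  solved by 2-D moment matching so the truncated distribution itself has mean
  51.2 and SD 21.0 (using 51.2/21.0 as parent moments would bias the sample
  mean up and the SD down). Scores are rounded to integers.
- SRH is categorical with probabilities 143/330/103/3 over
  excellent/good/fair/poor (the observed cohort proportions).
- Fatigue and SRH are drawn jointly through a Gaussian copula. The reported
  fatigue–SRH correlation is |r| = 0.44 without a stated sign convention;
  since higher fatigue accompanies worse health, the generator targets
  r = −0.44 on the 1–4 coding. The latent correlation is solved exactly:
  with SRH a step function of the second latent normal, the covariance
  decomposes threshold-wise into smooth 1-D Gaussian expectations evaluated
  by Gauss–Hermite quadrature, and the monotone equation is solved by
  bisection (sample check at n = 50,000: r = −0.441).
- Prior SA days and episodes are drawn from the observed 6-bin marginals with
  uniform placement within bins (open-ended bins capped at 180 days / 8
  episodes, plausible 2-year accumulations). One shared latent uniform feeds
  both quantile maps (comonotone coupling), so zero days coincide with zero
  episodes; the rank-perfect dependence this induces is stronger than real
  data but harmless to the models, which use one prior term each.
- Outcomes are Bernoulli draws from joint logistic models whose coefficients
  are the published *univariate* odds ratios (fatigue 1.16/1.14 per 10
  points, SRH 0.59/0.56, prior days 1.02 per 10, prior episodes 1.60, age
  0.99/0.92 per 10 years) used as generating log-odds. Univariate ORs used
  jointly shift the implied marginal associations slightly, so recovery tests
  compare joint refits against the generating coefficients — like with like.
  Intercepts are not published; they are solved by 1-D root finding so the
  simulated prevalences hit 59/579 and 65/579 (calibrated on a fixed internal
  100,000-draw covariate sample, independent of the user seed).
- Follow-up *counts* are drawn conditional on the binary outcomes: 3–5
  episodes (probabilities 0.5/0.3/0.2) for high-episode workers, 30–120 days
  for high-day workers, sub-threshold values otherwise, with days ≥ episodes
  and days > 0 iff episodes > 0 always; every combination fits a 365-day
  window with 28-day separations.
- Missingness is planted as exactly round(rate × n) records with one blanked
  analysis field each, so the 633 → 579 participant flow is reproducible.
- All randomness flows from one `numpy` Generator seeded explicitly; equal
  seeds give byte-identical cohorts.

The register generator inverts the aggregation: it partitions each worker's
day total over their merged episodes, places them with ≥28-day separations
plus multinomially distributed slack, and records a configurable fraction of
multi-day episodes as two raw episodes separated by a 1–27-day gap —
aggregation recovers every worker's (days, episodes) exactly.

What the generator does **not** emulate: real covariate-outcome confounding
structure beyond the stated logistic models, seasonality of absence,
employment turnover, clustering within departments, or any association
between prior SA and the other covariates except the days/episodes coupling.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated model, not external validity on real registers.

## Verification against the published tables

The four published count tables are embedded as fixtures, and a first-class
verification mode recomputes every statistic they determine. Agreement rules:
counts exactly; NRI point estimates to the printed precision (±0.01 on the
percentage scale — one published entry, 5.09 %, is the double rounding of
3/59 = 5.0847 % → 5.085 → 5.09, and is matched at that precision); CI bounds
within ±0.15 percentage points and p-values within one printed unit (see the
variance note above). One published p-value (0.91 for the days/10 % events
component) equals the z statistic of its own counts, whose two-sided p is
0.36; it is treated as a transcription slip and excluded from comparison.

## Problem sizes and determinism

Calibration and recovery checks use one shared 50,000-worker cohort (fixed
seed); the H–L type-I simulation uses 500 replicates of n = 2,000; oracle
equivalence uses 1,000 random instances of n ≤ 50 against per-subject Python
enumeration. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the whole suite inside a couple of minutes.
All seeds are fixed constants or derived from an explicit `--seed`.

## Known limitations

- Asymptotic NRI inference is unreliable with very few movers (the n.a. and
  bootstrap machinery exist for exactly that reason).
- The H–L test's power and null distribution degrade with heavy ties or tiny
  groups; the df convention then follows the realised grouping.
- In-sample evaluation overstates the IDI slightly; a held-out split is
  possible via the library API but is not the default, for fidelity to
  standard practice.
- The generator's univariate-ORs-as-joint-coefficients choice means its
  *marginal* associations only approximate the published univariate ORs; the
  acceptance output reports the joint refits, which is the exact comparison.
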