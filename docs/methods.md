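# Methods

## Dimer population model

KEAP1 acts as an obligate homodimer. For a genotype expressing a WT monomer
fraction w (and 1−w of a sensor-dead mutant), random pairing with equal
allelic dosage gives dimer-pool fractions w² (WT/WT), 2w(1−w) (WT/mut) and
(1−w)² (mut/mut) — the same combinatorics as Hardy–Weinberg genotype
frequencies. The default w = 0.5 models a balanced heterozygote; unequal
allelic expression is supported by passing a different w. The model assumes
monomers pair independently of their sensor status and that dimer exchange
has equilibrated; no kinetics are modelled.

## Activity under stress: two hypotheses, two arithmetic modes

The stress strength is a single dimer-level parameter f ∈ [0, 1]: the
fraction of the WT-homodimer pool inactivated, inferred as 1 − a from the
residual activity a measured in an all-WT animal under the same stress. This
makes the WT-homodimer term w²(1−f) empirical and hypothesis-independent.
Mutant homodimers are treated as fully active under oxidative stress (the
sensor-dead protein still represses NRF2 basally); no partial-activity
parameter is exposed.

Only the heterodimer term differs:

- **dimer inactivation**: both members must be modified; the mutant member
  cannot be, so the heterodimer inactivated fraction is 0 and the term is
  2w(1−w).
- **monomer inactivation**: one modified member suffices. Two arithmetic
  modes are provided:
  - `paper_linear` (default): the heterodimer inactivated fraction is f/2 —
    a linearisation treating the heterodimer as carrying half the modifiable
    material of a WT homodimer. This is the bit-faithful reproduction of the
    printed arithmetic (f = 0.74 → 37% of heterodimers inactivated, totals
    63% vs 81.5%).
  - `binomial`: the exact per-monomer form; the modification probability p
    solves 1 − (1−p)² = f for the WT homodimer, giving p = 1 − √(1−f) for
    the heterodimer's single WT member (f = 0.74 → 49.0%, total 57.0%).

  Whether the halving rule was meant as an approximation of a binomial
  process or as a distinct mechanistic assumption is not decidable from the
  source analysis; both are implemented and neither is asserted as true.
  Since 1 − √(1−f) ≥ f/2 on [0, 1], the binomial mode always predicts at
  most the linear mode's activity, with equality only at f = 0.

A hypothesis is *supported* when its predicted total activity lies inside the
confidence interval of the measured activity estimate; the verdict records
`monomer`, `dimer`, `both` or `neither` literally — no tie-break is applied
when the interval covers both predictions, because the data then genuinely
fail to discriminate.

## Calibration curve and inversion

The curve relating KEAP1 protein level L (percent of WT) to target-gene
fold-induction m is modelled as a power law, log m = β₀ + β₁(log L − log 100),
fitted by ordinary least squares in log-log space (scipy's linregress). The
form is a modelling choice: repression strength behaves multiplicatively,
the two-parameter monotone law passes through the known anchor behaviour
(100% → 1.0-fold; 26% → 4.0-fold implies slope ≈ −1.03), and it is
analytically invertible: L = 100·exp((log m − β₀)/β₁). A monotone spline was
considered and deliberately excluded — four dosage levels cannot support more
than two parameters. Fits require ≥ 3 distinct levels and a strictly negative
slope (the model presumes repression; a positive trend is an error, not a
warning). Fold-change 1.0 is anchored to the WT group's geometric mean, and
replicate observations are aggregated by geometric mean throughout, because
the noise model is multiplicative.

Inverted activities above 100% (observations below the fitted baseline) are
clipped to 100% with a warning: activity is defined as a fraction of the WT
pool. Activities are held as fractions in [0, 1] internally; percentages
appear only at I/O boundaries.

### Bootstrap confidence intervals

Uncertainty is quantified by a nonparametric percentile bootstrap (default
2000 resamples, seeded, deterministic): each resample redraws the calibration
points with replacement *stratified by level* (so every dosage level stays
represented — the degenerate single-level resample is impossible by
construction, though a defensive guard remains) and the observed replicates,
refits the line (vectorised closed-form OLS, identical to the full-data
estimator), and inverts the resampled geometric-mean observation. Resamples
whose refitted slope is non-negative cannot be inverted and are redrawn; the
2.5th and 97.5th percentiles form the interval, widened if necessary to
contain the full-data point estimate. The interval is reported as a
percentile-bootstrap 95% CI; no claim is made that it matches the method
behind any externally reported interval. Percentile intervals at n = 5
replicates are known to run slightly narrow; the measured coverage at the
default study conditions is 94/100 (see the acceptance suite).

## Sensor residue maps and fail-safe combinatorics

The oxidative sensor comprises Cys226, Cys613 and Cys622/624, organised as
three redundant parts P1 = {226}, P2 = {613}, P3 = {622, 624}; any two intact
parts can form the functional disulfide, so the sensor is functional iff at
least two parts retain a thiol. P3 is a single redundant part: either of
622/624 suffices. The electrophile sensor set is {151, 273, 288}, disjoint
from the oxidative set, with inducer classes mapped as: Class I requires
Cys151, Class II requires Cys288, Class III reacts with any of the three,
Class IV (reactive oxygen species) acts through the oxidative fail-safe.
The neighbor map carries exactly the two basic residues adjacent to sensor
cysteines with an established role in thiol reactivity (His225, Arg614); no
neighbor set is invented for the electrophile sensors. The map is a plain
config object so species numbering offsets or extended windows can be
supplied without code change.

Variant classification is by position lookup with chemistry flags
(`destroys_thiol` for Cys → non-Cys, `destroys_basicity` for His/Arg/Lys →
non-basic). A variant whose reference amino acid disagrees with the map is
classified non-sensor with a warning rather than an error, tolerating
annotation drift across transcript versions. Allele frequencies are carried
through as annotations only; no population-genetic statistics are computed.

## Synthetic data generator

The generator emulates the statistical structure of the study design, not its
biology: a calibration series at levels {100, 40, 19, 5}% with n = 5
replicates per group, lognormal multiplicative noise (log-scale SD default
0.25 — a tuning stand-in chosen so synthetic CI widths resemble the
±13-percentage-point intervals the real measurements support, not a measured
value), and a stress cohort whose expected fold-changes are the ground-truth
model's own predictions pushed through the ground-truth curve (slope default
−1). One root seed feeds per-table child streams (numpy SeedSequence spawn
keys), so generating one table never shifts another's draws. The generator
does not simulate RNA-seq counts, between-animal biological variance
distinct from measurement noise, normalisation-gene error, or qPCR
efficiency — so passing recovery tests demonstrate the inference chain is
correct under its own assumptions, not that real cohorts of this size would
always be decisive.

On that point: at the default conditions (noise 0.25, n = 5), the
heterozygote activity estimate has a sampling SD near 10 percentage points,
while the two predictions sit 18.5 points apart. The estimate therefore lands
in the window where the CI covers both predictions in roughly 40% of
cohorts, and exclusive selection of the generating hypothesis succeeds in
only ~47-50% of seeded cohorts (the remainder being mostly honest `both`
verdicts, not wrong selections). A single decisive cohort is thus partly
fortunate; the acceptance suite runs this experiment at the stated conditions
and records the outcome rather than tuning the noise down to force
decisiveness. Decisive selection at ≥ 90% of cohorts would require an
estimate SD ≤ ~4 points (log-noise ≤ ~0.14 at n = 5).

## Numerical choices

- Fractions validated to [0, 1]; dimer-class fractions must sum to 1 within
  1e-12; a float round-off of the activity sum marginally above 1 (≤ 1e-9) is
  clamped back into the heterodimer term.
- Bootstrap seeds: one integer seed per estimate; condition i in the pipeline
  uses seed + i so conditions are independent but the run is reproducible.
  JSON reports use sorted keys and embed the config hash and seed, making
  re-runs byte-identical.
- Degenerate inputs: < 3 distinct calibration levels, non-positive levels or
  fold-changes, out-of-range fractions and inverted CIs raise typed errors;
  the CLI maps configuration errors to exit 2 and data errors to exit 3.

## Known limitations

- The power-law form is an assumption; with only four dosage levels it cannot
  be tested against richer monotone forms.
- The halving rule and the binomial mode bracket plausible heterodimer
  arithmetic but neither is mechanistically validated.
- The fail-safe model is purely combinatorial — it ignores disulfide
  geometry, partial reactivity and expression effects of variants.
- The bootstrap treats calibration and observation noise as exchangeable
  within groups; systematic (e.g. batch) errors are outside the model.
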