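# Methods

## Task and cohort model

The synthetic generator (`synthio`) emulates a gap-paradigm
prosaccade/antisaccade battery in a single-dose crossover design: 19
patients tested on drug and on placebo (visit order block-randomized,
10 vs 9), 25 controls tested once.  Each task block has 24 trials, four at
each signed eccentricity ±3°, ±5°, ±7°, with a central fixation of
800–1200 ms followed by a 200 ms gap; recordings are simulated at 500 Hz.
These task constants are fixed properties of the design being emulated;
everything else is a population parameter with a documented default.

Per subject, latent parameters are drawn once:

| parameter | default population | units / meaning |
|---|---|---|
| `V_true` | N(130, 13); patients +10 in the untreated state | deg·s⁻¹·deg⁻¹ᐟ²; main-sequence coefficient |
| `gain` | N(0.9, 0.05) | amplitude / eccentricity; <1 models hypometria |
| latency `mu_log` | N(4.70, 0.15) | log-ms of the shifted lognormal |
| `error_propensity` | N(−1.5, 0.5) | logit of the baseline antisaccade error rate (~18%) |
| `pupil_baseline` | N(1500, 150) | arbitrary recorder units |

Defaults are order-of-magnitude-plausible values for older adults and
mild–moderate parkinsonism (saccadic latencies with a 90 ms physiological
floor and a ~200 ms median; peak velocities of 220–350 deg/s over 3–7°);
they are deliberately round and are not fitted to any dataset.  The drug
effect is a set of additive offsets applied on the active session:
latency −15 ms, V −10 (cancelling the patients' untreated elevation, i.e.
the drug *normalizes* the main sequence), antisaccade error logit +0.6,
pupil +100 units.

Trial generation: amplitude = gain·|eccentricity|·(1+ε_A) with
ε_A ~ N(0, 0.05); peak velocity = V·√amplitude·(1+ε_V) with
ε_V ~ N(0, 0.10); latency = 90 ms + LogNormal(mu, 0.35).  Antisaccade
errors are Bernoulli with logit = propensity − coupling·z, where z is the
trial latency standardized on the subject's own log scale and coupling
defaults to 1: fast, reflexive responses are the ones that err toward the
target, which induces both the within-subject latency difference between
incorrect and correct antisaccades and the across-subject correlation
between mean prosaccade latency and error rate.  This logistic coupling
is the simplest mechanism that reproduces those two signatures; it is not
an accumulator race model and makes no claim about process dynamics.

Velocity traces are raised-cosine: v(t) = v_peak·½(1−cos 2πt/T).  Because
∫v = v_peak·T/2 must equal the amplitude while the peak equals the drawn
peak velocity, the duration follows as T = 2·amplitude/v_peak (27–41 ms
over the task range, consistent with the classic linear duration–amplitude
rule to within a few ms).  We chose this self-consistent closure over an
independent linear duration rule, which cannot satisfy both constraints
under a fixed profile shape.

Determinism: a single integer seed; per-subject substreams are derived by
CRC-32 hashing of the subject id, so identical (config, seed) yields
byte-identical output files and adding subjects does not perturb existing
ones.

What the generator does **not** emulate: sample-level gaze position,
fixational eye movements and microsaccades, square-wave jerks, corrective
saccades, vertical components, head movement, and any latency–amplitude
dependence.  Passing tests therefore demonstrate that the estimators
recover parameters under the stated generative model, not that the
pipeline is robust to every artefact of real recordings.

## Pupil preprocessing

Order of operations: window QC on the **raw** validity mask (15 s windows,
dropped strictly above 15% missing, trailing partial window discarded),
then blink padding (±100 ms around each invalid run, detected on the
original mask so padding is applied exactly once), linear interpolation
(constant extension at the boundaries), Hann smoothing (200 ms window,
forced odd length, unit-sum kernel, reflected edges — output range can
never exceed the input range), then z-scoring, ±3 SD clipping and
averaging restricted to the kept windows.  Counting missingness before
padding means QC measures recording quality, not the padding parameter.

The clip is applied to the smoothed, z-scored signal; the Hann length is
a free parameter (the smoothing literature for pupillometry does not fix
one) and is exposed in the configuration.

**Z-scoring scope.** Statistics (mean, SD) are pooled over all of a
subject's sessions, then applied per session.  A per-session scope would
force every session mean to ~0 and erase between-condition differences —
the quantity of interest in a drug study; the subject scope keeps
conditions comparable within a subject while still removing between-
subject differences in recorder units.  Controls have one session, for
which the two scopes coincide.

## Saccade parsing

Gates are strict inequalities (amplitude in (1.5, 10) deg, latency in
(90, 2500) ms); boundary values are excluded.  Prosaccade trials whose
first valid saccade is directed away from the target are discarded by
default (`prosaccade_wrong_way="discard"`); an alternative mode searches
the remainder of the trial for the first valid toward-target saccade.
Zero horizontal displacement is an ambiguous direction and invalidates
the trial.

The ±2.5 SD participant filter is a single pass: means and sample SDs
(ddof = 1) are computed once on the post-gate trial set and not updated
after removals.  Prosaccades are screened jointly on latency, peak
velocity, amplitude and a *within-participant* velocity residual; the
analysis-grade residuals are recomputed afterwards by `kinemetrics` on
the filtered, pooled set — the double computation is intentional, since
filtering must precede the pooled fit.  Cells with fewer than 3 valid
trials cannot support an SD estimate and are flagged, not filtered.

## Kinematics

Velocity residuals come from OLS of peak velocity on amplitude.  The
default scope pools all primary prosaccades of a comparison set: a
constant velocity offset between conditions then moves only the
intercept, so condition contrasts on residuals are translation-invariant.
A per-participant scope exists for the outlier filter.  Whether the
regression should be pooled or per-participant is genuinely open; pooled
is the default because cross-condition comparability is the purpose of
the residual.

Time-normalized profiles map saccade time to [0, 1] and average velocity
and cumulative distance (trapezoidal integral over real time) in 10
half-open bins [(k−1)/10, k/10), the last bin closed.  Traces with fewer
than 10 samples are linearly resampled to 100 points first.

## Main sequence

`V = Σ y√x / Σ x` is the exact least-squares solution for y = V√x (a
through-origin regression on √x).  The bootstrap case-resamples saccades
(1000 replicates; optionally stratified within subjects, preserving per-
subject counts); the reported V is the replicate median and the interval
the 2.5/97.5 percentiles.  Degenerate resamples (a single repeated point)
remain solvable by the closed form.  Δ peak velocity evaluates the frozen
reference curve continuously at each observed amplitude — no amplitude
binning or matching tolerance is involved.  The one-sample test on deltas
treats trials as independent observations (the unit of analysis is the
saccade); with n = 1 or zero-variance deltas the test statistics are
reported as NaN rather than raised.

## Bayes factors

The JZS Bayes factor places a Cauchy(0, r) prior (r = √2/2) on the
standardized effect under H₁.  Using the inverse-gamma(½, r²/2) scale-
mixture representation, BF₁₀ = ∫₀^∞ (1+Ng)^(−1/2) ·
[1 + t²/((1+Ng)ν)]^(−(ν+1)/2) · π(g) dg ÷ (1+t²/ν)^(−(ν+1)/2), with
N the effective sample size (n, or n₁n₂/(n₁+n₂)) and ν the degrees of
freedom.  The integral is evaluated by adaptive quadrature after the
substitution g = eᵘ, entirely in log space, with the null marginal
factored out of the integrand so that large Bayes factors never overflow;
the quadrature's relative error estimate is carried in the result (< 1e−4
in practice).  Tests verify the quadrature against a dense trapezoid
oracle and an independent implementation.

Summary-statistic Bayes factors use the pooled-variance t (the convention
of default Bayes-factor t-tests, which assume equal variances), while
frequentist p-values from the same summaries are better matched by the
Welch variant; both are exposed and the pooled/Welch discrepancy is
visible in the CLI output.

## Problem sizes and numerical choices

Validation simulations use sizes at which the checked properties are
informative yet quick: 200 replicate cohorts of 300 saccades for
parameter recovery and interval coverage, 2000 null replicates for type-I
calibration of the Welch test, ≈210 simulated sessions for the
latency–error coupling, 5400 trials for the latency asymmetry of
antisaccade errors.  The end-to-end driver on the default 63-session
cohort (3 min pupil traces at 500 Hz) completes in well under two minutes
on a single core.

Tolerances: oracle equivalences are asserted at 1e−3 relative (Bayes
factors), 1e−10 absolute (convolution), machine-level for OLS normal
equations.  Degenerate inputs fail loudly with typed errors (rank-
deficient regressions, zero-variance z-scores, empty traces, QC failure)
rather than returning silent NaNs, except where a NaN is the documented
result of an undefined test.

## Known limitations

- The generator's population defaults are plausible, not fitted; absolute
  simulated effect sizes should not be read as predictions.
- Latencies are independent of amplitude and of the main sequence;
  real saccades show weak dependencies.
- Mixed-effects modelling (for repeated-measures group contrasts) is out
  of scope by design: the pipeline exports tidy trial-wise tables
  (`primary_saccades.tsv`, `task_summary.tsv`, `pupil_summary.tsv`)
  suitable for such fits in external tools.
- Contingency-table and mixed-model Bayes factors are not implemented.
- Native eye-tracker binary formats (EDF/ASC) are not parsed; the
  expected event-table schema is documented in `synthio.EVENT_COLUMNS`.
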