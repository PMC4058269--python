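# Methods

## The task and its arithmetic

The probabilistic-delivery task (PDT) is a two-choice free-operant protocol.
One hole yields a small certain reward (SS, 1–2 pellets); the other a large
probabilistic one (LLL, 5–6 pellets) delivered with the session's set
probability *p*. Testing rarefies *p* over seven levels — 100%, 50%, 33%,
25%, 20%, 17%, 14% — one session per level for rats (25-min sessions, 15-s
post-choice timeout) and three consecutive sessions per level for marmosets
(5-min sessions, 6-s timeout; 21 testing sessions in total). The 33% and 17%
levels are treated as exactly 0.33 and 0.17: they are experimenter-chosen
session parameters printed to two digits, not approximations of 1/3 and 1/6.

Odds against delivery are `odds = 1/p − 1`, the mean number of omitted
deliveries before a successful one. The indifferent point for a reward ratio
*r* is `p = 1/r` (expected payoffs equal when `r·p = 1`). The default
`RewardSpec` carries *declared* nominal fold-ratios (3, 5), which place the
indifference zone at *p* = 20–33%; the extreme ratios implied by the actual
pellet ranges (2.5 and 6) are available behind a flag
(`indifference_zone(..., nominal=False)`). Probabilities are stored as
fractions in (0, 1] throughout; only user-facing text prints percentages.

## Synthetic cohorts

No trial-level dataset for this task is public, so validation rests on a
generative model that matches the analysis model exactly:

- **Choice.** Each trial is an LLL choice with probability
  `clamp(a + b·log10(set_odds + 1), 0, 100)/100`. The generator uses *set*
  odds while the analysis fits *experienced* odds — mirroring reality, where
  the animal faces the programmed schedule but the analyst observes realized
  deliveries. The gap shrinks with trial count and is itself tested
  (experienced odds at *p* = 0.20 with ~10⁴ LLL trials land within 4 ± 0.5).
- **Delivery.** Bernoulli(*p_set*) independently per LLL trial; SS always
  delivers. Pellets are uniform integers on the configured range; omitted
  trials contribute exactly zero.
- **Throughput.** Trial counts are Poisson with rate
  `λ·(1 + c·log10(odds + 1))` per minute. Poisson (rather than fixed) counts
  emulate free-operant responding; `c > 0` reproduces the rate compensation
  with which some subjects offset reward rarefaction. Zero-trial sessions are
  legal and propagate as missing metrics.
- **Inadequate pokes.** Poisson counts per trial in the post-choice timeout
  window: `persistence_rho` toward LLL and `restlessness_rho` toward SS on
  omission trials, `background_rho` toward each hole otherwise. No within-
  timeout temporal structure is modeled because the analysis uses only
  counts per trial.

Defaults: base rates of 2.4 trials/min (rat) and 8 trials/min (marmoset)
give roughly 60 and 40 trials per session — chosen once for statistical
power, since no published trial counts exist for either species; the demo
temperaments use intercept 95%, slopes −15 (gambler-like) vs −90
(non-gambler-like) % per log₁₀-unit, omission poke bursts of 1.5 pokes/trial
on the phenotype-typical hole, 0.3 on the other, background 0.2, and rate
compensation c = 1.2 for non-gambler marmosets only (the only group that
showed it in vivo). Per-subject, per-session random substreams derive from
the master seed via `SeedSequence([seed, subject_index, session_index])`, so
logs are byte-identical across reruns and stable under cohort reordering.

What the generator does **not** emulate: within-session learning or
satiation, intertrial timing (per-minute rates divide by the nominal session
length), near-miss or cue-conditioned effects, and any mechanistic
(reinforcement-learning) account of choice. Passing tests therefore show the
*pipeline* is correct under the assumed statistical structure, not that real
animals follow it.

## Session metrics

Per subject × session: `pref_LLL = 100·#LLL/n`, `trials_per_min = n/T`,
`pellets_per_min = Σpellets/T` (T the nominal session length — sessions had
fixed durations), `persistence = Σ inadequate_LLL / n` and
`restlessness = Σ inadequate_SS / n`. The persistence/restlessness
denominator is *all* completed trials, and timeout pokes from rewarded trials
are included: the source protocol defines them as per-trial averages per
session and gives no rule for excluding rewarded-trial timeouts (they are
merely noted to occur mainly after omissions). Experienced probability is
`100·successful LLL/total LLL`; sessions with no LLL choice, or with LLL
chosen but never rewarded, have undefined experienced odds and are reported
missing with a warning — no continuity correction is applied, avoiding
invented infinite or capped odds. Such sessions drop out of the slope fit.

## Phenotyping

1. **Inclusion**: mean %LLL preference over all sessions at the pre-
   indifference levels (*p* = 1.0 and 0.5) must be *strictly* greater than
   60%. For marmosets all replicate sessions enter the mean (the protocol is
   silent on whether one or all replicates were used; averaging uses all the
   information and is the least arbitrary reading).
2. **Slope**: ordinary least squares of %LLL preference on
   log₁₀(experienced odds + 1), one point per testing session (up to 7 for
   rats, 21 for marmosets; the *p* = 1.0 sessions contribute x = 0). Base 10
   matches the spreadsheet convention under which the original slopes were
   computed; the labels are provably invariant to the base, since a change of
   base rescales every slope by the same positive constant (property-tested).
   The estimator is cross-checked against an independent normal-equations
   oracle to 1e-9. At least two usable points with distinct x are required.
3. **Median split**, computed within species on included subjects only
   (recomputing after exclusions; a pooled variant is available): slopes
   strictly below the median → non-gambler (steeper decline), strictly above
   → gambler. A subject exactly at the median joins the provisional group
   whose slopes its value is closest to — by default the nearer group mean
   (excluding the median subject), with exact equidistance resolved to
   non-gambler; `tie_rule="nearest-neighbor"` substitutes the nearest
   individual slope. If one provisional group is empty its distance is
   treated as infinite, so tied subjects join the non-empty group. All
   slopes equal is an error: there are no separable subpopulations.

The within-species split is the default because the two species' slopes are
on the same scale but their cohorts were analyzed as separate groups; the
`pooled=True` option covers the other reading.

## Group summaries and pipeline

`group_summary` averages replicate sessions within subject first (so each
subject contributes one value per probability level), then reports
across-subject mean and SEM (sample SD/√n; missing for n < 2) per
species × strategy × level. `run_pipeline` chains simulate/load → metrics →
classify → summarize and writes a manifest (seed, SHA-256 of the canonical
config, package version, stage timings, warnings). Plotting
(`plot_preference_curves`) is an optional convenience; the numeric tables
are the contract.

## Numerical choices and verification scale

- Probability levels are matched with an absolute tolerance of 1e-9 when
  locating schedule levels or inclusion sessions.
- The OLS slope uses `numpy.polyfit` (degree 1); tests compare it against a
  hand-written normal-equations oracle on 1,000 random small designs.
- Parameter recovery runs 100 seeded replicates of a 6 + 6 cohort
  (generative slopes −10 vs −90, intercept 100, rat schedule, ~60 trials per
  session): all 1,200 subject labels must be ≥95% correct and the mean
  absolute slope error ≤15 % per log-unit (measured ≈11.6). These problem
  sizes keep the whole suite under a minute while leaving the statistical
  assertions comfortably powered.

## Known limitations

- The published group-level animal results (figures and table values) cannot
  be reproduced without the undeposited raw data; the summary *layout*, not
  its values, is the deliverable, and the simulator is only required to
  reproduce their qualitative directions (tested for the throughput and
  persistence contrasts).
- The generator is descriptive, not mechanistic; recovered slopes estimate
  the generative preference line, and mild attenuation from experienced-odds
  noise is expected at low trial counts (the error is tested to shrink as
  trials per session grow).
- Training-phase sessions are not simulated; if an event log contains them,
  they are excluded from the fit by the `min_session_index` convention.
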