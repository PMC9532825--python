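# Methods

## Data-generating model

One simulated trial consists of `N` patients:

* **Accrual.** Enrollment calendar times are `T · Beta(a, b)` with accrual
  duration `T` and shape defaults `a = 1.5`, `b = 1`, so the cumulative
  accrual is `(t/T)^1.5` — 35% of patients by half the window. Units are
  months throughout; calendar time is counted from accrual start and
  patient time from randomization.
* **Events.** Latent PFS times are exponential: control hazard
  `log 2 / m_c` (default median `m_c = 12`), experimental hazard multiplied
  by the true hazard ratio (proportional hazards). A single latent event
  time per patient stands in for progression or death; there is no separate
  death process, no dropout and no cure fraction.
* **Assessment grid.** Tumor status is assessed every `Δ` months from
  randomization (default 2) until progression is documented, so the
  documented event time is the first grid point at or after the latent
  time; the documentation delay is uniform on `(0, Δ)` in distribution and
  averages `Δ/2`.
* **Event-driven trigger.** The analysis dataset is frozen at the calendar
  time of the `D`-th qualifying documented event. `D` comes from
  Schoenfeld's approximation; the two built-in designs are 500 patients /
  HR 0.70 / 331 events and 220 patients / HR 0.60 / 162 events, both with
  a 12-month control median, two-sided 5% alpha and 90% nominal power.

## Shutdown mechanics

A shutdown is a half-open calendar window `[S, S + d)` (default length 6
months) during which no enrollment and no tumor assessments happen:

* Enrollment times at or after `S` are shifted by `+d` (accrual is
  suspended and resumes where it left off, not re-drawn).
* Grid scans with calendar time inside the window are not performed. An
  event whose *detection scan* falls inside the window is documented at the
  reopening evaluation at `S + d` and flagged `via_reopening`; an event
  whose detection scan falls after the window is documented at that regular
  scan. The reopening evaluation enters a patient's assessment history only
  when it documents their progression — progression-free patients simply
  resume their regular grid, so censoring falls on regular scans. Besides
  matching how sites triage a backlog (pending progressions are read first,
  routine surveillance resumes per protocol), this keeps every censoring
  interval consistent with the latent time: a patient whose progression
  arose between a suppressed scan and reopening, but whose next regular
  scan documents it, has no contradictory negative assessment at reopening.
* The flag definition matters quantitatively: flagging on the suppressed
  detection scan (the default) censors slightly more events than flagging
  on the latent time lying in the window (`censor_on="true"`, available as
  a switch), because it also catches events arising just before the window
  whose scan was missed.

## Estimand strategies

Given one trial and a cutoff:

* **exact_times** — benchmark on the latent times, censored at the cutoff.
* **treatment_policy** — events at their documented times; everyone else
  censored at their last performed assessment on or before the cutoff
  (patients with none are censored at 0; patients enrolled after the
  cutoff are excluded).
* **hypothetical** — treatment-policy rows, but flagged events are censored
  at the patient's last assessment strictly before the window start
  (0 when there was none).
* **hypothetical_delayed** — same censoring, but the cutoff is determined
  by counting only unflagged events, restoring the event count at the cost
  of a later analysis. If fewer patients than the target can ever produce
  unflagged events the trial is flagged target-unreached and analyzed at
  the follow-up horizon (default 240 months, long enough for the smaller
  design's delayed analyses, whose upper range runs past 170 months).
* **interval** — each documented event contributes the censoring interval
  `(last negative assessment, documenting assessment]`; undocumented
  patients contribute `(last assessment by cutoff, ∞)`. Shutdown-spanning
  intervals are naturally wide; no imputation is involved.

**Event-count cap.** Deferred documentation creates a calendar atom at the
reopening time. When the target-th event falls inside that atom (typical
when the trigger lands just after reopening, e.g. a shutdown at month 24 in
the larger design), "all events documented by the cutoff" would exceed the
design target; the datasets therefore demote tied events documented exactly
at the cutoff beyond the target to censored rows, with an arm-neutral
deterministic tie-break (latest enrollment demoted first). This mirrors an
analysis frozen at the prespecified event count and is the regime in which
the treatment-policy strategy visibly dilutes the hazard ratio (toward
~0.72 for the built-in HR 0.70 design) and loses a few points of power,
because the deferred events all carry the same arm-uninformative
documentation time. Passing `target_events=None` disables the cap.

## Right-censored analysis

* **Logrank.** Standard unweighted two-sample logrank, vectorized
  in-package (it runs millions of times across experiments); cross-checked
  against lifelines in the test suite.
* **Cox HR.** lifelines' partial-likelihood fit with Efron tie handling —
  ties are pervasive on the grid, and Breslow would bias the HR toward 1.
  Monotone-likelihood or non-converged fits return NaN and are excluded
  (with counts) from aggregation.
* **KM median.** First time the curve falls below 0.5; when it lands on 0.5
  exactly, the midpoint of the flat stretch to the next drop (or to the
  last follow-up time). This midpoint convention — the one used by
  mainstream survival software — is essential on a grid: the control
  latent median (12) sits exactly on a scan time, so per-trial medians are
  12, 13 (midpoint) or 14 in nearly equal measure and the across-replicate
  median is 13.0, a one-month inflation of the true 12. Not-reached
  medians propagate as `+inf` and are counted separately.

## Interval-censored analysis (first principles)

* **Turnbull construction.** Innermost intervals `(q, p]` are maximal
  intersections of the observation intervals; exact observations
  (`L == R`) are widened by a data-scaled epsilon. The NPMLE places mass
  only there and is indeterminate inside them.
* **Self-consistency EM.** Uniform start;
  `m_j ← (1/n) Σ_i w_i α_ij m_j / Σ_k α_ik m_k` on deduplicated rows until
  the largest mass change is below `tol` (default 1e-8, max 10,000
  iterations). The log-likelihood is non-decreasing (asserted in tests).
  Masses whose true value is 0 decay only geometrically, so boundary cases
  can exhaust the iteration budget with a small residual mass; the estimate
  is then returned flagged non-converged. On grid-heavy simulated data the
  unique-endpoint deduplication makes each iteration trivially cheap.
* **Median bounds.** Because the NPMLE is indeterminate inside innermost
  intervals, the median is reported as a bracket: the median of the
  survival curve with all mass at left endpoints (Low) and at right
  endpoints (High), each with the same midpoint convention as above. On
  the no-shutdown grid this yields the Low/High inflation pattern
  11.0/13.0 around the true control median 12. These are indeterminacy
  brackets, not confidence intervals: per replicate they contain the true
  median only when the estimated crossing cell is the right one (~93% for
  a median on the grid, much less for one interior to a grid cell), but
  the across-replicate aggregated brackets contain the true medians of
  both arms, which is the meaningful calibration statement.
* **Two-sample test.** Score-type logrank built on the pooled NPMLE with
  `s log s` (Sun/Finkelstein) scores and the permutation-moment variance;
  the p-value uses the chi-square reference by default and Monte-Carlo
  label permutation below 50 subjects (`method` switch).
* **Proportional hazards.** Joint maximization of
  `Π_i [S0(L_i)^{exp(xβ)} − S0(R_i)^{exp(xβ)}]` over the log-HR and log
  baseline-hazard increments on the innermost right endpoints, by L-BFGS-B
  with analytic gradients, initialized from the pooled NPMLE. A joint
  quasi-Newton step was chosen over alternating baseline/β updates for
  robustness at the small support sizes the grid induces. Boundary fits
  (|log HR| > 30) are flagged. Single-dataset checks can bound the log-HR
  error only to a few standard errors (~2/√n); the asymptotic bias is
  below what a desk-scale test can resolve.

## Replication engine

Replicate `r` of cell `c` uses `SeedSequence([master_seed, c, r])`, so
results are bit-identical regardless of execution order and any replicate
is reproducible in isolation. Across-replicate summaries report the median
and the 2.5th–97.5th percentile range (type-7 linear interpolation; an
order statistic landing on `+inf` is reported as not reached), power as
the fraction of two-sided p-values below alpha, and counts of not-reached
medians, target-unreached trials and failed replicates (expected zero).
Default experiment sizes: 2,000 replicates for right-censored analyses
(Monte-Carlo SE on power ≈ 0.7 points), 500 for the interval-censored
path; the acceptance script uses 2,000 per cell. A full 10,000-replicate
reproduction is a configuration change.

## Known limitations

* One latent event per patient: deaths are not modeled separately, and all
  shutdown-window events are treated as progressions documented at
  reopening — in a real trial death dates would be known exactly.
* Exponential baselines and proportional hazards only; delayed separation,
  crossing hazards and cure fractions are out of scope, as are dropout,
  FDA-style censoring after repeated missed visits, and staggered
  multi-site shutdowns.
* The reopening evaluation is a single common make-up assessment at
  `S + d`; an alternative reading (each patient's first regular scan after
  reopening) spreads documentation over one scan interval and changes
  grid-valued summaries.
* Whether accrual suspension re-draws enrollment times is unknowable from
  the design alone; the rigid shift adopted here follows the "delayed by
  the shutdown length" reading.
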