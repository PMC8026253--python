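# Methods

## The foraging agent

One trial presents `n_objects = 15` identical objects, one of which is the
(invisible) reward target, drawn uniformly.  The agent inspects objects
sequentially until it hits the target (*found*) or reaches the saccade cap
(*censored*; default 25, matching the 25-bin summary support).  Its state
is an ordered working-memory store of previously inspected objects, oldest
first.  Three parameters govern behavior:

| parameter | range | meaning |
|---|---|---|
| capacity *C* | 1–15 (integer) | maximal number of stored items |
| decay *D* | 1–*C* (integer) | eviction is uniform over the *D* oldest entries (*D* = 1: strictly oldest; *D* = *C*: any item) |
| utility *U* | [0, 1] | probability that a choice consults memory |

Choice rule: with probability *U* the agent *exploits* — a uniform draw
among objects neither stored nor currently fixated; otherwise (or when
every non-current object is stored, so the exploit set is empty) it
*explores* — a uniform draw among all non-current objects.  The first
choice of a trial has no current object (gaze starts on the fixation
point), so all 15 objects are candidates.  Memory update follows each
non-terminal choice: a stored item is refreshed to most-recent (the
alternative, leaving its age unchanged, is available as
`on_revisit="ignore"`); a new item triggers eviction first if the store is
at capacity.  The terminating choice triggers no update.  Found trials and
censored trials both contribute to all summaries.

Two closed forms anchor the implementation: at (*C* = 15, *D* = 1,
*U* = 1) search is sampling without replacement — saccade count uniform on
1–15, mean 8, zero revisits; at *U* = 0 search is memoryless with hit
probability 1/15 on the first choice and 1/14 thereafter — expected
uncensored count 1/15 + (14/15)(1 + 14) = 211/15 ≈ 14.07.  Both are
verified by simulation in the test suite, together with an exact
brute-force enumeration oracle for a 3-object, 4-saccade configuration.

Two simulation engines implement identical rules: a per-trial loop (the
readable reference) and a vectorized batch engine used for the Monte-Carlo
grid (memory as a membership mask plus per-object registration times;
eviction ranks members by registration time).  They consume different
random streams, so they agree in distribution (total-variation test) but
not trial by trial.

## Behavioral summaries

For a trial set, three 25-bin vectors are computed and individually
normalized to unit sum:

1. **revisit by position** — fraction of choices at saccade ordinal
   *k* = 1…25 that return to an already-inspected object.  The denominator
   is trials surviving to ordinal *k* (the alternative, all trials, is
   available; attrition otherwise deflates late bins).
2. **revisit by distance** — histogram of index lags between a revisit and
   the most recent prior inspection of the same object.  Lag is the
   saccade-index difference (A-B-A → 2); lag 1 is impossible because the
   current object is never a candidate.  Lags beyond 25 are clipped into
   bin 25 so no mass is dropped.
3. **saccade count** — histogram of per-trial choice counts, clipped the
   same way.

A component with no mass (e.g. no revisits under perfect memory) stays
all-zero and is flagged rather than normalized; its 25 zero bins remain in
place so the concatenated vector (position ‖ distance ‖ count, in that
fixed order) always has 75 bins.  Each trial's contribution to all three
vectors is precomputed as a feature row, so a reweighted trial set (a
bootstrap resample) is summarized by a weighted column sum instead of a
rescan.

## Fitting

The parameter grid is every (*C*, *D*, *U*) with *C* 1–15, *D* 1–*C*, and
*U* ∈ {0.00, 0.02, …, 1.00} — 120 × 51 = 6,120 sets, enumerated in fixed
(capacity, decay, utility) order.  Each set is simulated once and
summarized; the goodness of fit of grid vector S_i to observed vector M is

    CD_i = 1 − Σ_b (M_b − S_ib)² / Σ_b (M_b − mean(S_i))²,

with mean(S_i) the grand mean of the *simulated* vector over its 75 bins.
CD is 1 iff M = S_i and may be negative.  Centering the denominator on the
simulated rather than the observed mean is deliberate and is the default;
a conventional-R² mode (`center="obs"`) is provided but not used by any
other component.  A constant reference vector makes the denominator vanish
and raises a degenerate-reference error.  The arg-max over the grid is the
fit; ties break toward the earliest grid entry (lowest capacity, then
decay, then utility).  A best CD below 0.7 flags the fit unreliable.

Grid summaries depend only on (number of simulated trials, seed) — never
on the data — so they are computed once and cached (in memory and
optionally on disk as `.npz`), with one independent child stream per grid
point spawned from the cache seed.  Simulation noise in S_i is therefore
frozen per cache; refitting against the same cache is deterministic.
Downstream, a bootstrap resample or time window refits at the cost of one
75-bin weighted summary plus a vectorized CD sweep (milliseconds), which
is what makes 1,000-fold bootstraps and sliding-window scans desk-scale.

**Bootstrap.**  Trials are resampled with replacement, each resample refit,
and the per-parameter 2.5th–97.5th percentiles of the refits form the
middle-95% band; the point estimate is the unresampled fit and need not lie
inside.  A post-injection estimate outside the preinjection band is called
a significant departure.

**Sliding windows.**  Trials pooled across sessions (pooling precedes
fitting; per-session fits are not averaged) in windows of 10 min advanced
by 5 min, each window refit; empty windows and CD < 0.7 windows are
flagged, not interpreted.

**Parameter distance.**  Σ over the three parameters of ((p₁ − p₂)/scale)²,
with the default scale the per-parameter standard deviation over the
comparison set; used to compare within-subject to across-subject session
dispersion.

## Task geometry and the synthetic generator

Stimulus sites live on a 7 × 11 grid with 4° spacing (77 sites spanning
24° × 40°, centered).  The grid site nearest the fixation point is
excluded — fixation may be off-grid, and excluding the nearest site keeps
the candidate count at 76 in every case — and each trial draws 15 sites
uniformly without replacement; adjacent sites are exactly 4° apart, so the
">4° apart" placement constraint is read as ≥ 4°, which the grid
guarantees.  The chance reference for saccade amplitudes — five random
object pairs per iteration, 100 iterations per session, averaged — draws
pairs within single trials' arrays by default (`mode="across"` pools the
session); the exhaustive mean over all 76-candidate pairs is 19.27°.

`generate_session` drives the agent through full task timing: 500–1000 ms
uniform fixation, a 6,000-ms search limit, 200-ms reward delay, 800-ms
intertrial interval.  Per-saccade time cost is a gamma-distributed
intersaccadic interval (shape 4, mean 220 ms — fixation durations in the
200–250 ms range typical of active search) plus a nominal 40-ms saccade
duration; searching is censored when the next saccade would exceed the
limit, with the first saccade always granted.  At these defaults a
~10-saccade trial spends ~2.6 s searching and sessions of 1,100 trials
span ~95 min, matching the scale of hour-long recording sessions.

Drug effects are phenomenological, not pharmacokinetic: an effect level
rising linearly to its maximum at `onset_minutes` (default 15) and decaying
exponentially afterwards (`recovery_halflife_minutes`, default 30)
interpolates each model parameter toward `baseline × scale`, with capacity
and decay rounded and clipped back to their integer ranges and utility
clipped to [0, 1]; peak-velocity suppression, postsaccadic drift and ISI
inflation follow the same time course for the kinematic side.

Synthetic eye traces render a trial's choice sequence at 1 kHz: each
saccade travels a straight line with a raised-cosine (sin²) velocity
profile whose peak equals the main-sequence value Ėmax[1 − exp(τ·Amp)]
(duration 2·Amp/Ė), fixation dwells are Gaussian (mean 220 ms, floor
120 ms), and optional ingredients add exponential postsaccadic creep
(30-ms time constant, parameterized by its 100-ms integral displacement to
match the drift-measurement window), white position noise, and
out-of-window excursions.

What the generator does *not* emulate — and hence what passing tests do
not establish about recorded data: spatial choice biases (real subjects
prefer neighboring objects; the agent treats objects as exchangeable, so
its chance-level saccade amplitudes are a feature, not a bug), reaction
times correlated with decision difficulty, measurement artifacts (blinks,
coil slippage, calibration drift), curved or multi-component saccade
trajectories, and any genuine pharmacology beyond the imposed parameter
time courses.

## Oculomotor analysis: numerical choices

Velocity and acceleration are Savitzky–Golay derivatives of the position
channels (21-ms window, polynomial order 3).  Order 2 was rejected after
measurement: a quadratic local fit attenuates the velocity peak of short
saccades several percent more than that of long ones, which tilts the
fitted main sequence (τ biased ~9% on noiseless traces); order 3 tracks
the peak to <1%.  Detection keeps contiguous epochs above 70°/s, merges
epochs separated by <20 ms (so corrective movements within the 4°
inter-object spacing do not fragment a saccade), then extends each epoch's
edges outward while speed exceeds a 5°/s secondary threshold and is still
falling.  Without this relaxation, onsets sit 9–21 ms late (the 70°/s
crossing is well inside the movement) and offsets clip the decelerating
tail into the drift window, inflating drift estimates by ~0.3°.  The
acceleration (>1000°/s² peak) and displacement (>2°) criteria are applied
per refined epoch.

Choice registration scans between-saccade fixation intervals for the
longest contiguous run of samples within 2° of a single object and
registers runs longer than 100 ms, merging consecutive registrations of
the same object.  Postsaccadic drift is the straight-line displacement
over the 100 ms after offset, returned as NaN when the window is truncated
by trace end or the next saccade.  The main-sequence fit is bounded
nonlinear least squares (Ėmax > 0, τ < 0) initialized at the maximal
observed velocity and τ = −2/median amplitude; it requires ≥ 5 saccades
spanning > 5° of amplitude.  The virtual window for trial exclusion is
48° × 33° (stimulus field plus a 4° margin per side), and a trial is
excluded if any search-epoch sample leaves it.

## Problem sizes

The shipped tests and the acceptance script run everything at sizes chosen
to keep a full check on one CPU comfortable while leaving Monte-Carlo
error well inside the asserted tolerances: grid caches use 500 simulated
trials per grid point (the fitting layer defaults to 5,000 per point for
analysis use), observed synthetic data sets use 1,000–5,000 trials,
bootstraps use 200 resamples (default 1,000), closed-form checks use
50,000 trials, and the enumeration oracle is checked against 100,000
simulated trials.  Parameter recovery at these sizes is capacity ±1 and
utility ±0.04 with best CD > 0.95 at the reference parameter set
(10, 2, 0.90), across 20 independent data seeds.

## Known limitations

* Decay is weakly identified from behavior: of the three summaries only
  the revisit-lag histogram moves with it appreciably, so single-session
  decay estimates scatter widely and bootstrap bands for decay are wide.
  This mirrors the behavior of the statistic itself, not an implementation
  defect.
* CD compares a noisy observed vector to noisy simulated vectors; with
  small windows (≲100 trials) the arg-max is dominated by simulation and
  sampling noise, which is exactly what the CD < 0.7 reliability rule is
  for.
* The utility grid step (0.02) bounds the precision of any utility
  estimate; reported ±0.04 recovery is two grid steps.
* The session CSV dialect stores floats via `repr` for lossless round
  trips; files written by other tools are validated but precision is
  theirs.
* The trace generator's saccades are straight with symmetric velocity
  profiles; detectors tuned on it may need re-validation on real traces
  with curved or overshooting movements.
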