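# Methods

## The generative model

`stageflow` models the progression of a chronic disease (the bundled
configuration targets type 2 diabetes) as three stacked stochastic layers
over a patient's timeline, observed only through the ICD-10 codes recorded
at encounters.

**Stages.** A continuous-time Markov jump process over `K` ordered disease
stages with intensity matrix `Q` (units: events per year). `Q` is
constrained forward-only: strictly lower-triangular entries are zero and
the last stage is absorbing, so a trajectory's stage index never decreases.
Between two encounters separated by `dt` years the stage transition
probability is `expm(Q dt)`, computed by uniformization (Poisson-weighted
powers of `I + Q/lambda`, truncated at 1e-12 tail mass; the interval is
halved recursively when `lambda dt > 30`). Uniformization keeps the
lower-triangle zeros exact, so the forward-only structure survives
numerically.

**Complication onsets.** Each of `W` complication categories is an
irreversible binary state. At a patient's first encounter, while in stage
`k`, complication `w` is already present with probability `pi_onset[k, w]`.
Over a later interval of `dt` years an inactive complication activates with
probability `1 - (1 - h_onset[k, w])^dt`, a per-year hazard evaluated at
the stage of the interval's *destination* encounter (stages are only
sampled at encounters, and the attribution of a mid-interval onset to a
stage has to be a convention; the destination encounter is the one whose
record reveals the onset).

**Findings.** A bipartite noisy-or network maps complications to the `N`
binary findings of one encounter:
`p_n = 1 - (1 - leak_n) * prod_{w active, allowed} (1 - A[w, n])`.
The leak is an always-on cause explaining findings with no active
complication parent.

**Anchors.** Expert-asserted (complication -> code) links prune the
observation layer: an anchored code keeps only the link from its anchor
complication, removing `W - 1` activation parameters per anchored code.
The unpruned parameter count is `K*K + 2*K*W + N*W` (stage transitions,
two onset parameters per stage/complication pair, activations); leaks are
maintained but reported separately from that count, and
`count_free_parameters` additionally reports the forward-only `Q` count
`K(K-1)/2`. Anchored links keep their topology fixed but their weights
remain learnable (initialized at `anchor_init`, default 0.8); a
`freeze_anchors` option pins them for the stricter reading in which anchors
are set once and never re-estimated. The bundled anchor file carries the
12 diabetes complication categories with their 28 anchored ICD-10 codes.

## Preprocessing

Raw events (patient, ISO-8601 date, code) are filtered to codes with at
least `min_count` (default 30) total occurrences, counted per event row
across all patients before any patient-level exclusion. Each patient's
events are binned into windows of `granularity_years` (default 1) anchored
at their first retained event (progression depends on intervals, not
calendar time); duplicate codes within a window collapse to one binary
observation, and patients with fewer than two slices are excluded. A year
with no events leaves no slice; the temporal layers consume the integer
year gap between adjacent slices. Unparseable dates are dropped with a
warning, never a crash.

## Learning

Parameters are estimated by Monte Carlo EM with blocked Gibbs sampling,
chosen because every full conditional is closed-form and therefore
testable against exact enumeration on small instances:

* **Stages** are drawn by forward filtering / backward sampling over the
  `K`-state chain with interval matrices `expm(Q dt)`. The emission at a
  slice is the onset-chain term of the current complication sample; the
  noisy-or observation terms do not involve the stage and cancel.
* **Onset times** are drawn per complication by enumerating the `T + 1`
  monotone onset configurations (onset at slice `0..T-1`, or never) with
  the exact conditional given the stages and the other complications'
  current states (systematic-scan Gibbs; the likelihood couples
  complications through shared findings).
* **Observation-layer statistics** use the firing-indicator augmentation
  of the noisy-or: given a positive finding, each active allowed cause
  fired with posterior probability `A[w, n] / p_n` (and the leak with
  `leak_n / p_n`); given a negative finding, no cause fired. These
  expectations are accumulated directly (Rao-Blackwellized) rather than
  sampled. A single "which cause did it" draw weighted by activation
  probability — which `sample_attributions` provides for annotating
  trajectories — is biased as an estimator whenever causes co-occur, and
  is deliberately not used in the M-step.
* **Stage-layer statistics** (expected holding times and jump counts of
  the jump process between observed slice endpoints) come from Van Loan
  augmented matrix exponentials, cached per interval length within an EM
  iteration.
* **Onset-year augmentation**: when an onset happens across a multi-year
  gap, the year within the gap is drawn from the truncated geometric
  conditional so hazard updates stay conjugate.

The M-step is posterior-mean smoothing: Beta(1, 1) pseudo-counts on every
probability parameter and Gamma(1, 1) pseudo-counts on intensity rates
(configurable). Sweep statistics are averaged over retained sweeps so the
prior weight does not depend on the sweep count. Convergence is declared
when the relative change of the smoothed complete-data log-likelihood
stays below `convergence_tol` (default 1e-4) over 5 consecutive
iterations; defaults are 200 iterations of 20 sweeps with 5 burn-in,
reducible for desk-scale experiments. A single seeded generator drives all
sampling and patients are processed in sorted-id order, so runs are
bit-reproducible.

Supervised verification: with latents fixed to simulated ground truth, one
pass of the statistics plus the M-step reproduces every fixture parameter
to about one percent, isolating the estimator from Monte Carlo E-step
behavior.

**Initialization.** The likelihood surface couples stage-boundary
placement with hazard levels: a fit can park stage boundaries in the wrong
place and compensate with distorted hazards, a local optimum that a flat
initialization readily falls into (we observed such a mode with markedly
lower observed-data likelihood than the generating parameters, checked by
an exact forward sum over the product chain). Initialization therefore
encodes two weak, domain-motivated expectations: onset parameters start on
a ramp increasing with stage (complication pressure grows as the disease
advances), with 10% lognormal jitter to break complication symmetry, and
the adjacent-stage intensities start at `(K − 1) / mean observed span`, so
a typical trajectory initially traverses all stages over its observation
window instead of stalling in the first stage. Activation and leak
probabilities start from `init_beta` draws (default Beta(1, 3), mean 0.25,
reflecting sparse coded data); anchored activations start at
`anchor_init`.

**Initial stage prior.** For observational data, patients enter the
registry mid-course, so inference and learning default to a uniform prior
over the stage at the first encounter. When fitting cohorts generated from
year 0 in stage I (recovery experiments), `initial_stage="first"` matches
the generative process; recovery under a knowingly wrong initial-stage
prior would measure the mismatch, not the estimator.

## Inference

`map_trajectory` computes the *joint* MAP over stages and complication
onsets (the narrative use case reads off one coherent trajectory), by
dynamic programming over the product chain of (stage, active-set) states.
Both coordinates are monotone and the onset transition cost is additive
per complication, so the subset maximization over predecessors reduces to
`W` coordinate-wise relaxations of a `2^W` array per slice (`W <= 20`
guard). `brute_force_map` enumerates all monotone assignments as the
oracle, breaking exact ties by the lexicographically smallest (stage
sequence, then onset-time vector); the DP's per-slice greedy preference
agrees except on exactly tied objectives.

`forecast` extends a trajectory deterministically: the predicted stage at
a future year is the largest stage whose cumulative reaching probability
exceeds a threshold (default 0.5 — the operationalization of "may show up
after t years"), and an inactive complication's predicted onset year is
the first year its cumulative onset probability along that stage path
crosses the same threshold. `posterior_complication_probs` gives Monte
Carlo activation marginals from Gibbs sweeps at fixed parameters.

## Synthetic patients

Generation follows the model exactly: every patient starts at time 0 in
stage I; holding times are exponential with rate `|Q_kk|` and the next
stage is chosen proportional to `Q_kj`; encounters happen yearly, onsets
use the hazard of the stage at the encounter, and findings are drawn from
the noisy-or. Observation ends one residence year (default 1) after entry
to the last stage, or at the horizon (default 60 years, far beyond typical
paths so truncation is negligible).

The default stopping rule ends observation when the *latent* path reaches
the last stage — informative censoring that the three-layer likelihood
does not model. Empirically this matters: EM initialized at the true
parameters drifts on such cohorts (late-stage hazards and intensities
biased low) even though the supervised estimator is exact. Recovery
experiments therefore generate with `observation_years=10`, a fixed
follow-up window independent of progression, the way a registry with a
fixed study window observes patients. What the recovery tests show is that
the estimator recovers the truth when the data match the model's censoring
assumptions; they do not certify behavior under outcome-dependent
follow-up, which real registries may exhibit.

The fixture model (`K=3, W=2, N=6`) emulates the shape of sparse coded
data: one anchored code per complication, leaks of 0.04, moderate
unanchored activations giving one to three positive codes per encounter,
multi-year stage holding times (rates 0.35 and 0.30 per year), and onset
hazards increasing with stage (0.08-0.45 per year).

## Cohort analytics

`stage_summary` reports mean stage-entry years, mean holding times (over
patients observed to leave a stage) and per-stage complication prevalence,
where "has complication w at stage s" means active at some time during the
occupancy of s. The retrospective tables condition on the last stage:
among patients with a complication (or a full co-occurrence pattern)
active while in stage V, the percentage already positive while in each
earlier stage, rounded half-up to one decimal to match printed table
precision. Patients truncated before the last stage are excluded from the
base group but kept in the cohort denominator. Irreversibility makes the
columns monotone (V->IV >= ... >= V->I) and makes any sub-pattern's
percentage dominate its super-pattern's; both are asserted as properties
on every simulated cohort.

## Known limitations

* The synthetic-data generator shares the model's assumptions (conditional
  independence of complications given the stage, binary noisy-or
  observations, time-homogeneous hazards); passing recovery tests
  demonstrates internal consistency, not robustness to real-data features
  such as coding drift, visit-frequency dependence on disease severity, or
  left-censored entry (an entry-delay option exists but is off by default).
* The joint MAP is exact but exponential in `W` per slice (fine at the
  bundled `W=12`; a guard rejects `W > 20`).
* `pi_onset` rows for stages never occupied at a first encounter are
  informed only by the prior (they shrink to 0.5 under Beta(1, 1)); the
  same applies to intensities of transitions never visited.
* Stage labels are identified by time ordering (forward-only chain), not
  by any clinical calibration; `K` and `W` are fixed by configuration, not
  learned.
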