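# Methods

## Model

The analysis treats a subject's fixation sequence on an `n_r × n_c` cell
matrix as the output of a first-order Markov chain on the cell lattice.
Three modeling assumptions are made explicit:

1. **Fixations are the signal.** Only fixation events enter the analysis;
   saccades and blinks are parsed and carried but never used. A fixation
   is reduced to its start/end time and average gaze position, binned to a
   cell with half-open pixel bins (`col = ⌊(x − x₀)/w⌋`, likewise rows).
2. **Time is discretized at the fixation scale.** The trajectory is
   resampled at step `dt` (default 0.1 s ≈ one average fixation), each
   fixation contributing `max(1, ⌊duration/dt⌋)` consecutive samples of
   its cell. This puts within-cell (self) transitions and between-cell
   transitions on equal footing: a dwell twice the average produces one
   self-transition. Saccade gaps are elided — consecutive fixations are
   adjacent in the chain — but trial boundaries break it, since each trial
   presents a different screen and a cross-trial "transition" would be an
   artifact. (Counting across trials is available via
   `sample_trajectory(..., break_on_trial=False)` for comparison.)
3. **Recognition leaks through out-transition diversity.** A concealed
   target is betrayed by cells that the gaze repeatedly *leaves in varying
   directions* (approach-and-flee), i.e. by high Shannon entropy of the
   estimated outgoing transition distribution, concentrated on a spatially
   narrow spot.

Per source cell, transition probabilities are maximum-likelihood row
normalizations of the counts, and the out-entropy is
`H = −Σ p ln p` in nats with the `0 · ln 0 = 0` convention. Unvisited and
terminal cells (zero row total) get `H = 0` and can never seed a peak:
a zero row carries no evidence.

## Selection rule

High entropy alone is not sufficient — broad ridges of moderate entropy
arise from ordinary scanning. The rule therefore trades height against
width:

* up to `n_peaks = 3` dominant local maxima (8-connected neighborhoods,
  `H > 0`) seed clusters in descending order of height;
* each cluster is the 8-connected flood-fill of cells with
  `H ≥ rel_threshold · H(peak)`, `rel_threshold = 0.25` — relative to the
  *seeding peak*, so a weak secondary peak keeps a proportionally weak
  skirt. Earlier peaks keep contested cells; later flood-fills do not pass
  through claimed cells (deterministic, dominance-consistent);
* all unclaimed cells pool into one background cluster;
* every cell is scored `S = H · exp(−α · C)` with `C` the size of its
  cluster and `α = 0.1`; the argmax of `S` (row-major on ties) is the
  prediction, and the full descending ranking is kept for search-cost
  accounting.

`α = 0.1` keeps a 3-cell peak at 74 % of its raw entropy while a ~200-cell
background cluster is suppressed by e⁻²⁰; the two cues — "high" and
"narrow" — are thus both active at the default. `α = 0` degenerates to
pure entropy ranking, which the 2 × 2 illustration uses.

## Fallback heuristic

When the entropy prediction misses, the first `k = 3` in-grid fixations of
the *first* trial are searched serially: fixation cell, its 8 neighbors in
row-major order, next fixation, and so on, deduplicated. The premise is
that the very first orienting movements on the first screen are drawn
toward the concealed cell before deliberate control sets in. The cost of a
rescue is the 1-based plan position of the target (reported for exact and
for Chebyshev-1-tolerant matching; rescues in cohort reports use the
tolerant criterion, matching the hit criterion).

## Evaluation

A prediction is a tolerant hit if it lies within Chebyshev distance 1 of
the truth (the 8-neighborhood, consistent with 8-connectivity everywhere
else). Chance baselines on the default grid: exact 1/225 ≈ 0.004; tolerant
9/225 = 0.04 for an interior target (the default comparison); the
edge-corrected average 1849/50625 ≈ 0.0365 is reported alongside. Cohort
hit counts are tested with the exact one-sided upper binomial tail — the
claim is directional.

## Synthetic sessions

No public recordings of this paradigm exist, so `gazeloc.simulate` stands
in for human data. Per trial it scripts:

* a random horizontal/vertical **segmenting line** and a reading-order
  scan of 6 line-adjacent cells (the overt yes/no task), dwell
  log-normal with mean 90 ms, sd 25 ms;
* with probability 0.25 a **stray glance** at a uniform cell (brief,
  mean 70 ms), placed before the scan as a re-orientation;
* for avoider and decoy strategies, with probability `slip_rate` an
  **approach-and-flee excursion** at screen onset: one brief fixation on a
  ring cell (Chebyshev 1 of the target) followed by a flight to a uniform
  cell at Chebyshev ≥ 4. The approach is habitual — 70 % of slips land on
  a subject-specific preferred ring cell — so that cell accumulates many
  distinct flee exits: a high, narrow out-entropy peak. A uniform choice
  over all 8 ring cells instead spreads the evidence into a broad
  elevated blob that the size penalty then wrongly suppresses;
* for `decoy_fixator`, two long (mean 400 ms) dwells on a deliberately
  chosen decoy cell, inserted mid-scan;
* `random_scanner` performs the task only (null model).

Fixation positions are cell centers plus isotropic Gaussian jitter
(σ = 10 px); trials are truncated at the exposure cap when one is set
(1.5 s in the speeded condition; self-paced otherwise). Cohorts draw
uniform targets and per-subject seeds from a `SeedSequence`, apportion
strategy mixes by largest remainder, and are byte-reproducible from the
base seed.

Dwell means matter more than they look: at `dt = 0.1 s` a ~90 ms fixation
contributes exactly one sample at every `dt` in {0.05, 0.1, 0.2}, which is
why predictions are stable under resampling; fixations several times
longer than `dt` would give every singly-visited cell a spurious
`ln 2` of self-transition entropy and fuse the map into one cluster.

**What the simulator does not emulate:** oculomotor kinematics (saccade
main sequence, velocity profiles), pupil dynamics, calibration drift,
center-of-screen bias, memory effects across trials, or subjects whose
avoidance produces *no* ring traffic at all. Passing tests therefore show
that the pipeline recovers targets when the assumed approach-and-flee
statistics are present at the simulated strength — not that human subjects
exhibit those statistics at that strength.

## Numerical choices

* Natural logarithm throughout (the illustration's values ln 3 ≈ 1.1,
  ln 2 ≈ 0.69 force it).
* Sparse dict-of-pairs transition storage; the dense 225² matrix is
  materialized only on request (`to_dense`).
* Tiny negative entropy round-off on deterministic rows is clipped to 0.
* All ties (peak order, argmax) break row-major: deterministic and
  platform-independent. Exact score ties do occur on short trajectories
  (small-integer count ratios), where tie-breaking legitimately breaks
  symmetry equivariance; the equivariance tests assert a unique argmax as
  a precondition.
* Degenerate inputs fail loudly: logs with no in-grid fixation, trajectories
  with no countable transition, zero-entropy peaks, empty cohorts.

## Problem sizes in the test suite

Unit and property tests run on 2×2 to 8×8 grids; the exhaustive oracle
check enumerates all 87 376 trajectories of length ≤ 8 on the 2×2 grid.
Cohort-level tests use 4–20 subjects × 28 trials (≈ 200 fixations per
subject), and the slip-rate monotonicity check averages 20 cohort seeds
per slip level. These sizes keep the full suite in the tens of seconds
while leaving every statistical conclusion comfortably clear of its
threshold.

## Known limitations

* The Markov/entropy estimator ignores visit counts beyond row
  normalization: a cell left twice in two directions has the same
  out-entropy as one left twenty times in two directions. A count-aware
  prior (e.g. Krichevsky–Trofimov smoothing) is a natural extension.
* `α` and `rel_threshold` are fixed heuristics, not fitted; per-session
  calibration is out of scope.
* The fallback plan's usefulness depends entirely on first-fixation
  behavior and is reported, never claimed significant on its own.
* Process-level entropy production (stationary-weighted) is not computed;
  the decision rule uses per-cell out-entropy only.
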