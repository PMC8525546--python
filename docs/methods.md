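# Methods

This note records the model as implemented, the parameters that matter and why
their defaults are what they are, what the synthetic stimuli do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Stimuli (the generative process)

A stimulus is a 30×30 binary pigment grid (locations indexed row-major from 0)
carrying up to four motif families, cumulative across complexity levels:

| level | adds                               | default rows (band row 14) |
|------:|------------------------------------|----------------------------|
| 0     | horizontal 5-cell segments         | 14                         |
| 1     | oblique 5-cell segments below      | 15–19                      |
| 2     | oblique 5-cell segments above      | 9–13                       |
| 3     | vertical 5-cell segments below     | 21–25                      |

Segments tile every 7 columns; obliques alternate +45°/−45° across tiles but
form one motif family per side of the band. Exact stencil geometry is a
package design choice — only the qualitative description (a line; verticality
added below, then above, then vertical lines) is externally fixed. Each level
adds 20 pigment cells, so the four families are balanced. The layout is
deterministic; complexity 3 needs at least 22 rows. Background cells carry the
sentinel motif label −1 and never enter A².

What a green test on these stimuli does **not** establish: anything about
curved vessel geometry, photographic appearance, or natural scenes; the
stimuli are minimal binary abstractions whose only controlled property is the
amount and orientation of decorative structure.

## Perception

Likelihood remapping keeps knowledge local: after every saccade the level-1
likelihood is re-read from the 3×3 patch at the new location; off-grid slots
observe deterministic no-pigment, so all nine local states exist everywhere
(whether the original scheme clamps or forbids edges is unknown; this is the
simplest contract preserving the state space). Level-1 inference is exact
Bayes over the nine local states with a uniform prior per fixation — beliefs
about local states do not persist across remaps because remapping redefines
the local state space.

Level-2 (motif) inference runs once per four level-1 steps: the cycle's four
(location, outcome) pairs enter as a product of per-cell Bernoulli factors,
`P(pigment | motif m, loc) = 1−ε` on m's cells and `ε` elsewhere
(ε = 10⁻³, the likelihood floor; it prevents zero-evidence dead ends under the
otherwise deterministic likelihoods), times the temporal prior `B² q₂(t−1)`.
How the four level-1 outcomes aggregate into the level-2 update is not fixed
externally; the 4-factor product is this package's choice.

## Action

Candidates are all 900 grid locations (a Chebyshev saccade-length limit is
configurable but off by default). Each candidate is scored by single-step
expected free energy; the prediction term uses the propagated belief about the
*current* motif, `B² q₂(t−1)`, while the novelty term weights the Dirichlet
information gain `1/α_ij − 1/α₀j` by the *previous posterior* `q₂(t−1)` — the
update the move will feed is `outer(q₂(t), q₂(t−1))`, so the column learned
about is indexed by where the agent believes it came from. Weighting novelty
by the propagated belief instead lets novelty reinforce the already-dominant
transition and the trajectory locks into a two-cycle; this is a qualitative
failure mode, not a tuning nuance. Background candidates carry zero novelty:
landing there evidences no motif transition.

Action selection is a hard argmin with exact ties broken uniformly by the
run's seeded generator. Within one 4-step cycle the G landscape is constant,
so the four fixations fall on the (tied) cells of the currently most
attractive motif — spatial spread within a motif comes entirely from
tie-breaking.

## Learning

Only B² is learned. Counts start uniform at `dirichlet_seed / 4` per entry
(seed = prior mass *per column*, default 1.0 — the convention under which 50
repeated observations of one transition from a unit seed give the closed-form
entry (50+¼)/(50+1)); each cycle adds `rate · outer(q₂(t), q₂(t−1))`
(rate 1.0), so a 100-timestep episode adds exactly 25 units of count mass.
Learning rate, seed and preference magnitudes are externally unstated; all are
exposed in config.

## Parameter defaults and the exploration regime

| parameter        | default | meaning                                      |
|------------------|---------|----------------------------------------------|
| timesteps        | 100     | saccades per episode (25 level-2 cycles)     |
| C (preferences)  | ±4      | log-preference pigment vs background (nats)  |
| w_risk, w_amb    | 1, 1    | weights of the pragmatic G terms             |
| w_novelty        | 24      | weight of the Dirichlet information gain     |
| ε                | 10⁻³    | likelihood floor                             |
| dirichlet seed   | 1.0     | prior count mass per B² column               |
| dirichlet rate   | 1.0     | count mass added per cycle                   |

The one calibrated quantity is the **novelty-to-preference ratio** `w_n/|C|`.
Two scale constraints govern the dynamics: (i) preference risk must dominate
the pigment/background contrast (gap ≈ `|C_pig − C_bg|·(p_pred − ε)` ≈ 2–3
nats), or the agent wanders off the decoration; (ii) novelty must dominate the
*residual* risk differences among pigment-bearing candidates across the whole
episode — those residual gaps saturate near `|C_pig − C_bg|` nats as a column
concentrates, while the Dirichlet gain decays like 1/count, so too small a
ratio lets the trajectory absorb into a single reinforced transition chain.
Absorption collapses transition learning onto one entry at every complexity
level, which inverts the complexity–entropy relation the model exists to
exhibit. A coarse scan of ratios {2, 3, 4, 6, 8} on pilot sweeps shows
sustained exploration with balanced (not dwell-dominated) transition counts
from ratio 6, and saturation above it (ratios 6 and 8 give identical
trajectories); the default is the smallest sufficient ratio, `w_n = 24` with
`C = ±4`. Background visits remain at zero for every ratio scanned, so
constraint (i) is never in tension with (ii) in this range.

## Metrics

- `Vi = (h·n_vert − w·n_horiz)/(h·n_vert + w·n_horiz)` with (h, w) the
  bounding box of the *visited* region (a fixed display size would make h, w
  constants and decouple the index from behaviour). A saccade is vertical if
  |Δrow| > |Δcol|, horizontal if |Δcol| > |Δrow|; exact diagonals and
  zero-moves count as neither (configurable counting is deliberately not
  offered; the exclusion rule avoids double counting). The widely circulated
  denominator form that repeats the vertical count is treated as a typo: the
  symmetric denominator is what bounds the index in [−1, 1].
- C-PAST entropy: Shannon entropy in nats (0·log 0 = 0), summed over columns.
  Natural log throughout, consistent with the EFE computations.
- Hit rate: fraction of categorisation hits.

## The transfer task

Shapes are 5×5 masks: the four motif shapes plus a "+" distractor. A cut-out
is the restriction of a shape to a viewing window (four half-planes, two
mid-lines, nine single-cell glimpses); its compatibility set is computed from
geometry — every shape whose restriction to that window is identical. Sensing
is non-noisy: the trial likelihood is the exact compatibility indicator. The
transferred 4×4 matrix is embedded into the 5-shape space with the "+"
row/column at the ε floor and columns renormalised, which keeps every prior
strictly positive; the matrix is frozen (bit-identical before and after a
run). Each trial: one blank-display propagation step through B², the cut-out
observation, then a decision drawn from the posterior reweighted by `e^{−8}`
on "+" (the aversion that guarantees a committed choice). Belief carries
forward across trials — with a per-trial reset the transferred transitions
would be inert.

The predetermined series alternates a diagnostic view with the fully ambiguous
centre glimpse, and never repeats a shape on consecutive trials. These two
protocol choices are load-bearing and were made from exact expected-hit
analysis (the decision draw does not feed back into the belief, so the
expected hit rate is computable in closed form given a series): alternation
re-collapses the belief onto the true shape before every ambiguous trial, so
ambiguous-trial accuracy is exactly `(1 − B²[prev | restricted])/3` — a direct
readout of learned column dispersal; without alternation, consecutive
ambiguous trials route the prior through B² *row means*, whose incidental
asymmetries reward confidently wrong matrices. Sampling the decision (rather
than hard argmax, which is also available as `decision_rule: argmax`) keeps
accuracy continuous in the prior; under argmax an exactly uniform untouched
column outscores a genuinely learned but imperfect one, which breaks the
graded relation between training complexity and performance.

## Numerical choices

- All posteriors normalised exactly; level-2 inference in log space.
- G ties: candidates within 10⁻¹² of the minimum, chosen uniformly by the
  run's generator; all randomness in a sweep descends from one master seed
  via SeedSequence spawn keys, so results are order-independent and runs are
  byte-reproducible.
- Degenerate inputs raise typed errors (`ConfigurationError`,
  `DegenerateInputError`, `UndefinedMetricError`) rather than silently
  renormalising: an all-zero matrix column, an empty candidate set, and a
  zero-denominator vertical index are caller errors.

## Known limitations

- The agent is not fitted to human eye-tracking data; scanpaths are heuristics
  of the modelled mechanism, and none of the green tests establish
  correspondence with human gaze statistics.
- The 4:1 cycle ratio, single-step lookahead, and learning restricted to B²
  are structural assumptions, not discoveries of the simulation.
- The stimulus geometry is one concrete realisation of the verbal level
  descriptions; metric *values* (though not the qualitative orderings, which
  are robust across master seeds) depend on it.
- The transfer-task protocol is the minimal design under which a transferred
  prior can matter at all given non-noisy cut-out sensing; richer accounts of
  cut-out perception would need a noisy likelihood model the source material
  does not specify.
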