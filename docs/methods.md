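# Methods

This note documents the modelling choices behind `typerhythm`: the
decomposition and its solver, the sleep and phase extractors, the synthetic
data generator and what it does and does not emulate, numerical details, and
known limitations.

## Data model and aggregation

Sessions are binned by the UTC hour of their start time. Inter-key delays
are pooled across an hour's sessions before the median is taken; delays
above 5 s are treated as pauses rather than typing and discarded, a standard
keystroke-dynamics convention. Four modalities are computed per observed
cell — median inter-key delay, summed key count, upright rate, movement
rate — and an hour with no sessions is missing in *all* modalities. This
asymmetric treatment of zero is deliberate: the framework's premise is that
absent data may mean sleep, so absence must be imputed by the temporal
structure, never asserted as an observed zero.

Matrices live on a UTC grid; per-day local UTC offsets are carried as
metadata only. A fixed reference clock makes travel visible as genuine phase
shifts instead of being absorbed by local clock changes. Partial first/last
days are retained with their missing hours masked.

Standardisation z-scores each modality over its observed cells (population
denominator) and negates the inter-key delay, so every modality points the
same way ("larger = more active"). A `standardised` flag on the tensor makes
the operation idempotent — re-standardising does not flip the delay sign a
second time.

## Temporal graph

Nodes are (day, hour) cells; edges link consecutive hours (including the
midnight wrap into the next listed day) and the same hour on adjacent
calendar days, all with unit weight (differential hour/day weights are
exposed but default to 1). Days absent from the grid contribute no edges, so
a data gap splits the graph into components and prevents any information
flow across it; days present in the grid but with no observations keep their
nodes and are imputed. There is no wrap from the last day back to the first.

## Graph-regularised SVD

Component `k` minimises, over the running residual `R`,

    F(u, w) = Σ_{(m,t)∈Ω} (R_mt − u_m w_t)² + λ wᵀLw,   ‖u‖₂ = 1.

Choices that were genuinely open, and how they were settled:

* **One shared time factor.** The four day-by-hour matrices are vectorised
  and stacked into a single 4×(24·D) matrix with the graph acting on the
  time dimension. This is the smallest model in which one score matrix
  summarises all modalities.
* **Penalty on the scaled factor.** The roughness penalty applies to
  `w = σv`, not to the unit-norm `v`. Penalising `v` makes the objective
  scale-degenerate (any penalty can be dodged by moving norm between the
  factors), whereas penalising `w` yields a well-posed problem whose λ → 0
  limit is the plain SVD and whose λ → ∞ limit drives the *score* variance
  to zero. Only the time factor is regularised, not the loadings.
* **Masked alternating least squares.** Only observed cells enter the fit
  term; no pre-imputation. Because the observation mask is shared across
  modalities, both updates are exact coordinate minimisers with closed
  forms: `u ← c/‖c‖` with `c = R_Ω w`, and `w` from the SPD system
  `(diag(mask) + λL) w = mask ⊙ (uᵀR)`. The system matrix is constant over
  iterations and factorised once (sparse LU). The objective trace is
  therefore exactly non-increasing.
* **Initialisation** is deterministic: `w` starts from the per-bin mean of
  observed standardised values, `u` from its masked projection. A seed
  matters only for optional random restarts (off by default).
* **Convergence**: relative objective change below `tol` (default 1e-8)
  *and* relative change of the time factor below `sqrt(tol)/10`, or 500
  iterations. The second condition exists because the objective is flat near
  the optimum — objective-only stopping can leave the factors an order of
  magnitude less converged than the objective suggests.
* **Deflation** for `k > 1`: the fitted rank-one term is subtracted from the
  observed residual entries. Downstream analyses use only component 1, so
  simplicity beats joint orthogonal fitting.
* **Sign convention**: each component is flipped, if necessary, so the key
  count loading is non-negative.
* **λ = 0 with fully empty time bins** makes the `w` system singular; this
  is rejected with an instruction to use λ > 0 or drop the bins.

λ is the one hyperparameter that matters. The default heuristic re-masks 20%
of observed bins, refits on the remainder over a log grid (10⁻²…10²),
averages the held-out imputation RMSE over 3 folds, and returns the smallest
λ within tolerance of the grid minimum; a manual value can always be passed
instead. Typical selected values on the simulator's default data are
0.3–1.

With a globally shared loading vector, a perturbation in one graph component
can still reach another component *through* `u`; the graph strictly
separates the time-factor solve only. The disconnection guarantee is
therefore exact for perturbations that preserve the loading direction (e.g.
rescaling one component's block of a rank-one matrix) and approximate
otherwise.

## Sleep extraction

Cells with score strictly below a threshold are sleep; ties are wakeful.
Daily sleep duration is the per-day count of sleep cells — non-contiguous
sleep and naps count, and no assumption is made about when sleep occurs.
Days are UTC days, matching the matrix grid. Each day also reports its
number of observed hours; the pipeline drops days with fewer than 4 by
default, since extreme estimates concentrate on data-poor days.

Threshold methods: `manual` (pass-through), `otsu` (between-class variance
on the histogram), `valley` (minimum of a Gaussian-KDE between its two
largest modes, with a prominence guard — the dip must fall below 0.95× the
smaller mode, otherwise the density is declared effectively unimodal and an
error is raised), and `auto` (valley, falling back to Otsu when unimodal).
`auto` is the pipeline default: the valley matches the bimodal
sleep/wake picture when it exists, Otsu covers degenerate shapes.

## Phase and transitions

Hour `h` maps to angle `2π(h+0.5)/24` — an hourly aggregate represents the
whole hour, and the half-hour offset avoids a systematic early bias. Scores
are clipped at zero to serve as vector lengths (`shift-min` and `softplus`
transforms are exposed as alternatives). The day's phase is the angle of the
weighted mean vector; the resultant length (mean-vector norm over total
weight) flags days with no coherent rhythm, and a day with zero or fully
cancelling weights is marked undefined rather than raising.

Transitions are UTC-offset change-points that persist for at least 7
consecutive days (counting the transition day); a change whose persistence
window contains a further change is discarded, and a minimum-magnitude
filter (e.g. ≥ 2 h) is available. Phases from 3 days before to 7 days after
are centred on the unweighted circular mean of the pre-transition days and
mapped to (−12, +12] hours, so wrap-around through midnight is handled.
East/west groups are compared per offset day with Welch's unequal-variance
t-test (Welch–Satterthwaite df), flagged not-computable below two
observations per group.

The day-crosslink smoothing deliberately resists day-to-day phase change, so
the estimated phase lags an abrupt shift for the first day or two (a
refractory period) and the immediate post-transition deflection is somewhat
attenuated at larger λ. This is a property of the method, not a bug in the
test data.

## Synthetic data generator

The generator emulates the assumptions the framework rests on, with defaults
chosen to represent a regular, phone-engaged adult:

* a stable chronotype (mid-sleep 04:00 local) with nightly duration drawn
  N(8 h, 0.75 h), re-entraining after each scheduled offset change at a
  finite rate (default 1.0 h/day eastward vs 1.5 h/day westward — eastward
  travel re-entrains more slowly, consistent with the jet-lag literature;
  the asymmetry is a free parameter with no canonical value);
* session counts per awake hour ~ Poisson with a plateau-shaped rate
  (3/h, dropping by half only near the sleep boundary via a `1 − 0.5|x|⁴`
  edge profile): phone use is sustained across the waking day rather than
  sinusoidal;
* lognormal inter-key delays whose median follows a mild diurnal
  performance curve (250 ms base, 10% slower at the sleep boundary) under a
  dominant between-session context factor (lognormal σ = 0.3) — what is
  being typed moves tempo far more than time of day does;
* wake-hour missingness 20%, whole days missing 2%;
* brief nocturnal phone checks with probability 0.15 per sleep hour (one
  short, slow, flat-in-bed session). These anchor the night region of the
  score matrix at genuinely low values, as real night-time checks do;
  without any night observations, graph imputation can only interpolate
  between the flanking wake hours;
* Bernoulli orientation/movement flags (upright 0.8 day / 0.5 night-check;
  moving 0.3 / 0.1);
* ground truth: integer sleep hours per UTC day on the hour grid, nap
  hours, and the true activity phase (wake midpoint, UTC).

Reference emulators: a wearable-style nightly sleep measure (truth plus
Gaussian noise, naps excluded by default as ring devices typically miss
daytime naps) and an hourly self-report scale top-coded at "10+ hours" with
optional reporting noise and attrition. Cohorts are composed from per-user
random effects on chronotype and mean sleep.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: autocorrect/backspace behaviour, weekday
structure and social schedules, irregular or fragmented sleep, technical
outages distinct from behavioural absence, device sharing, and covariates
such as mood or menstrual cycle. A population with long screen-free
wind-down before bed will have its sleep overestimated by any
rest-activity method, this one included.

`lowrank_diurnal_matrix` is a second, deliberately minimal generator — a
rank-one matrix whose diurnal time factor drifts in phase and amplitude
across days — used to probe the imputation machinery in the regime the graph
penalty targets (smooth along the graph, not identical across days). On
perfectly day-stable data the per-hour-of-day mean is a near-oracle
imputer; the graph method's advantage appears exactly when the rhythm
drifts.

## Problem sizes and determinism

Tests and the acceptance script run single-user problems of 20–90 days
(480–2160 time bins), where a full pipeline takes well under a second; the
transition analysis simulates 20 independent travellers. All randomness
flows from explicit seeds (`numpy.random.default_rng`), pipeline reruns with
the same config and seed are byte-identical, and the simulator is
reproducible bit for bit.

## Known limitations

* Sleep estimates are integer hours on a UTC-day grid; they measure the
  rest period of *device* activity, which systematically includes
  screen-free wakeful time adjacent to sleep.
* Component 1 must be an activity factor for the downstream steps to be
  meaningful; data whose dominant variation is not activity-like (checked
  via the loading signs) would need manual component selection.
* The valley threshold requires genuine bimodality; sparse users may need a
  manual threshold, mirroring the hand-set threshold the method was designed
  around.
* Phase is only defined for days with net positive activity scores; heavy
  smoothing (large λ) attenuates and delays phase responses to abrupt
  shifts.
* Group-level joint decompositions and non-negativity constraints are out
  of scope; multi-user analyses pool per-user fits.
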