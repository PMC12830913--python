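# typerhythm

Diurnal rhythm inference from smartphone typing dynamics.

Most people carry a stable ~24-hour sleep–wake rhythm, and it leaves a
footprint in how they type on their phone: when, how much, how fast, and in
what posture. `typerhythm` turns event-level typing-session records into a
quantitative, time-resolved measure of device activity and reads two rhythm
features off it — **daily sleep duration** and the **daily phase of peak
activity** — without ever assuming when the person is supposed to be awake.
It is aimed at digital-phenotyping and circadian researchers who have
keyboard/session telemetry but no wearable, and at anyone studying how
rhythms respond to disruptions such as time-zone travel.

## The model

Four hourly modalities are aggregated per UTC (day, hour) cell: median
alphanumeric inter-key delay (an inverse measure of typing speed), total key
presses, upright-orientation rate, and movement rate. After per-modality
z-scoring (and a sign flip for the inter-key delay so that larger always
means more active), the day-by-hour matrices are stacked into one matrix
`X ∈ R^{4×24D}` with a shared observation mask `Ω` — an hour with no
sessions is *missing*, not zero, because absent typing may simply be sleep.

Hours are linked by a temporal graph: each hour to its predecessor and
successor (23:00 → next day's 00:00 included) and to the same hour on the
neighbouring days — a spiral with crosslinks. Its Laplacian `L` feeds a
masked, graph-regularised SVD. Component `k` is fitted to the running
residual `R` by minimising

```
F(u, w) = Σ_{(m,t)∈Ω} (R_mt − u_m w_t)²  +  λ wᵀ L w ,   ‖u‖₂ = 1,
```

over modality loadings `u` and a scaled time factor `w = σv`, by alternating
exact updates (each is a closed-form coordinate minimiser, so the objective
never increases). Only observed cells enter the fit; the Laplacian term
propagates information into unobserved hours from adjacent hours and the
same hour on adjacent days — *selective imputation*. Days absent from the
grid disconnect the graph, so nothing flows across a data gap. The first
component's score matrix (σ₁v₁ reshaped day-by-24) is a general measure of
typing activity, defined at every cell.

Downstream:

* **Sleep** — the score histogram is split by a threshold (manual, Otsu, or
  the valley between the two dominant KDE modes); cells strictly below it
  count as sleep, per day, with no contiguity requirement (naps and split
  nights count, chronotype unrestricted).
* **Phase** — each day's row is read in polar coordinates (hour → angle,
  clipped score → vector length); the weighted circular mean's angle is the
  day's activity phase in UTC. Persistent UTC-offset changes are detected,
  phases are centred on each transition's pre-transition circular-mean
  baseline, and east- vs westward travel is compared per offset day with
  Welch's t-tests. Westward travel appears as a phase increase in UTC,
  eastward as a decrease.

Because no public session-level dataset exists, the package ships a
first-class simulator (`typerhythm.simulate`) that generates session streams
with known ground truth — chronotype, nightly sleep, wake-hour missingness,
nocturnal phone checks, travel schedules with finite re-entrainment — plus
wearable-style and top-coded self-report reference emulators.

## Worked example

```python
import typerhythm as tr

scenario = tr.UserScenario(n_days=60, seed=2)       # 8 h mean sleep, chronotype 04:00
sim = tr.simulate_user(scenario)                    # 1969 sessions

tensor = tr.standardise_modalities(tr.aggregate_sessions(sim.records))
model = tr.GRSVD.from_tensor(tensor, lam=1.0)
res = model.fit()
print(res.summary())
```

```
Graph-regularised SVD results
================================================================
bins: 1440  observed: 719  lambda: 1  rank: 1
converged: True  iterations: 13
----------------------------------------------------------------
modality                 u_1
median_ikd            0.4315
key_count             0.6860
upright_rate          0.4713
movement_rate         0.3481
----------------------------------------------------------------
sigma                26.3784
penalty wLw         165.9647
```

All four loadings are positive (inter-key delay was sign-flipped), so
component 1 is a common activity factor, dominated by key count. Sleep and
phase hang off the results object:

```python
sleep = res.sleep_series(method="auto", min_observed_hours=4)
print(sleep.head(4).to_string(index=False))
```

```
      date  sleep_hours  n_observed_hours  threshold_used
2024-01-06            7                11       -0.594913
2024-01-07            7                13       -0.594913
2024-01-08            7                16       -0.594913
2024-01-09            8                10       -0.594913
```

Against the simulator's ground truth these daily counts have a median
absolute error of 1.0 h. `res.phase_series()` gives per-day phase, e.g.
14.48 h UTC with resultant length 0.71 on the first day — mid-afternoon peak
activity, as expected for a 04:00-midsleep chronotype.

The same pipeline is scriptable from the shell:

```
typerhythm simulate --n-days 60 --seed 2 --out sessions.csv
typerhythm run --sessions sessions.csv --seed 2 --out-dir run_output
```

which writes the tensor, graph edge list, scores, sleep/phase series,
transition tests and a `summary.json`.

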