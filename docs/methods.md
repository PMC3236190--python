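# Methods

## Signal and contamination model

The object of study is a finite series of positive event intervals (ISIs)
generated by cyclic repetition of a pattern of `p` intervals.  Two
contaminations are modelled, chosen to mimic how a regularity-generating
neural circuit couples to a noise source:

* **Jitter**: every emitted pattern interval `t` is replaced by `t + δ`.
  The scale of `δ` is a fraction of the *smallest* pattern interval, so a
  "10% jitter" means the same thing regardless of the pattern's units.  The
  default law is uniform on `±(fraction × min interval)`; an unsigned
  uniform, a Gaussian (scale = standard deviation), and a truncated
  long-tailed (Cauchy) variant are available — in the regime of interest
  the differences are negligible, so these are convenience options.  Draws
  are independent per event; a non-positive result is resampled rather than
  clipped, which preserves the shape of the jitter law near zero.
* **Insertion noise**: a nominal fraction `f` of all events is drawn from a
  noise-interval law instead of the pattern.  Two paradigms:
  * *event-wise* — each event is independently noise with probability `f`;
    the pattern phase pointer advances only when a pattern event is emitted;
  * *pattern-wise* (default) — repeated Bernoulli draws either append one
    whole jittered pattern (`p` events, probability `q̃`) or a single noise
    event.  For the realized per-event noise fraction to equal the nominal
    `f`, the insertion probability must be rescaled:
    `q̃ = (1 − f) / (1 − f + f·p)`, the solution of
    `(1 − q̃) / ((1 − q̃) + q̃·p) = f`.  This is verified both by a direct
    Monte-Carlo count of insertion draws and by labelling every generated
    event.

  The noise-interval law defaults to uniform on `(0, 1.5 × max pattern
  interval]`: it spans and exceeds the pattern's own scale without
  introducing a new free scale parameter.  This is the single most
  influential unmodelled choice — a wider or narrower noise law moves the
  noise background of the correlation curve relative to the pattern's steps,
  and with it the exact noise percentages at which the criteria degrade.

Generation stops at the first draw reaching the requested event count, so a
pattern-wise series may carry up to `p − 1` trailing excess events; callers
that need an exact embedded point count truncate.  All generation is
deterministic given the seed.

**Surrogates** are uniformly random permutations of the interval sequence:
they preserve the value distribution (and hence every property of the `m=1`
embedding) exactly while destroying sequential structure.

## Correlation curves

Series are delay-embedded with delay 1 (consecutive ISIs) at dimension `m`.
The correlation integral `C(ε)` is the average, over `n_ref` reference
points drawn without replacement, of the fraction of the *other* points
within closed max-norm distance `ε` (the reference point itself is excluded,
which removes a constant offset at small radii; with `n_ref` at least the
point count the estimate equals the full pairwise computation).  Defaults
follow the recommendation of ~250 reference points for 10⁴ embedded points.
The max norm is what makes the steps sharp: the distance between two
embedded pattern windows is decided by a single componentwise comparison.

**Radius grid.**  Two modes:

* `linear` (default): `n_eps = 140` equal ε-increments up to the largest
  sampled distance.  Because the increment scales with the data, log-log
  curves remain covariant under time-unit rescaling.  The linear grid
  compresses the small-radius region — where pair counts are tiny and
  difference-quotient slopes are shot-noise dominated — into a few wide
  log-bins, while finely resolving the pattern-scale steps.  This matters:
  with a log grid reaching down to the smallest sampled distance, spurious
  shot-noise peaks in the derivative defeat the exactly-`k`-peaks criteria
  ~30% of the time *even on noiseless data* at the default sampling depth.
* `log`: log₁₀(ε) stepped by `log_eps_step` (default 0.05) from the smallest
  positive sampled distance, with one extra step prepended so the first rise
  is itself visible as a step.  Useful for inspecting scaling regions.

In both modes, leading curve samples with `C < c_floor` (default 4·10⁻⁴,
i.e. ~10³ counted pairs at the default 2.5·10⁶ sampled pairs) are dropped:
below that support the slope standard error exceeds ~0.4 slope units and the
samples carry no usable shape information.  `c_floor = 0` disables the
guard.  Ties at bin edges are counted inside the ball (closed-ball
convention), which makes the degenerate two-cluster configuration exact:
two coincident-point clusters of `k` points each give `C = (k−1)/(2k−1)`
below the cluster distance and 1 at it.

## Step and plateau criteria

The derivative of the log-log curve is approximated by difference quotients
between consecutive samples.  A *step* at height level `h` is a maximal
contiguous run of derivative samples strictly above `h`; a *plateau* sample
is one below a (lower) level.  Three height levels with quality weights
grade each criterion; all are configurable and recorded in output metadata.

* **Peak levels** (criteria (a), (b)): slopes (0.5, 1.0, 2.0) with weights
  (1, 2, 3) — sharper steps earn more.  In the ideal case every step's slope
  exceeds all three levels.
* **Plateau below-levels** (criterion (c)): slopes (0.25, 0.5, 1.0) with
  weights (3, 2, 1) — flatter plateaus earn more.  The levels sit well below
  typical step slopes (≥ 2 at moderate jitter) but at the scale of the
  smooth noise background; with much smaller below-levels essentially no bin
  of a contaminated curve counts as plateau and the criterion degenerates to
  counting the saturation tail.

**Criterion (a)** — single-step visibility at `m = p` (for odd `p` all
inter-cluster max-norm distances coincide, so exactly one step should
remain).  Each level showing exactly one peak contributes its weight.
Noise can make vanished steps reappear; when two or three peaks are observed
at a level, the series is compared against the surrogate ensemble member in
which repeated steps emerge most pronouncedly (largest weighted excess-peak
count).  The surrogate's excess-peak pronouncedness minus the series' —
excess peaks clipped to [0, 2] and scaled to at most one weight unit per
level — is added, so a series whose spurious steps are weaker than the
fully randomized case retains credit.  A series as steppy as its surrogate
scores zero.

**Criterion (b)** — exactly-`p`-peaks visibility, evaluated by default at
`m = 1`, where the `p(p−1)/2` pairwise cluster distances generically reduce
to `p` distinct values for `p = 3`.  Note that at `m = 1` a permutation
surrogate has the identical correlation curve (the integral depends only on
the value multiset), so (b) has no surrogate baseline; its noise robustness
is judged against its own noiseless score.

**Criterion (c)** — plateau-flatness difference between `m = p` and
`m = p − 1`, the dimension pair being configurable.  The weighted average
(over below-levels) of plateau-sample counts at the lower dimension is
subtracted from the count at the higher one, both restricted to the common
log-radius span.  On clean data the difference is positive (one long plateau
versus two step-interrupted ones).  On heavily contaminated data the raw
value turns negative — the noise background steepens with embedding
dimension — and the pattern shows in the *margin over the matched
surrogate*, which in the validation sweeps stays positive up to and beyond
90% noise events at low jitter.  This margin, not the raw sign, is the
operative indicator at high noise.

Across a parameter grid, each criterion's replicate-averaged matrix is
normalized by its grid maximum; visibility regions are I (≥ 0.66),
II (≥ 0.33) and III below, with criterion (a) merging II into III.
Thresholds are configurable and recorded.

## Ideal-case step-count bounds

Grouping the unordered cyclic position pairs of a pattern by shift `k`
decomposes the componentwise distance graph into subgraphs: for `k < p/2` a
`p`-cycle of distance values, and for even `p` one extra shift-`p/2`
subgraph with `p/2` edges whose values repeat with period `p/2`.  The
max-norm distance between clusters `k` apart is a sliding-window maximum of
width `m` over the corresponding cyclic value sequence.  For a cyclic
sequence of `L` generically distinct values the number of distinct window
maxima lies between `⌈L/m⌉` (largest values spread regularly) and
`L − m + 1` (monotone ordering), collapsing to 1 for `m ≥ L`.  Summing over
subgraphs — cross-subgraph coincidences are non-generic — gives

```
odd p:   N_min = (p−1)/2 · ⌈p/m'⌉            N_max = (p−1)/2 · (p − m' + 1)
even p:  N_min = (p−2)/2 · ⌈p/m'⌉ + ⌈p/2m⌉   N_max = (p−2)/2 · (p − m' + 1) + max(p/2 − m + 1, 1)
```

with `m' = min(m, p)` — windows longer than one period add no new
comparisons, so values for `m > p` clamp to `m = p`.  Consequences:
`N_min = N_max = p(p−1)/2` at `m = 1`, and `N_min = N_max = ⌊p/2⌋` for
`m ≥ p` (shift symmetry `d(k) = d(p−k)`).

The closed forms are verified numerically: a brute-force oracle builds the
`p` cluster centres explicitly, counts distinct pairwise max-norm distances
(merged within a relative tolerance of 10⁻⁹ of the largest distance, safe
for generic double-precision patterns), and is checked to fall inside
`[N_min, N_max]` for 500 random patterns per `(p, m)` with `p ∈ 2..7`,
`m ∈ 1..p+2`, and to be non-increasing in `m` per pattern.  Generic patterns
are sampled i.i.d. uniform on [0.5, 2.0] with near-coincident values
resampled.

## Validation sweeps and problem sizes

The phase-diagram and acceptance computations use the length-3 pattern
(1, 3, 4), pattern-wise noise, 10⁴ embedded points, 250 reference points and
20 seeded replicates per jitter-noise cell; per-cell seeds derive from
`SeedSequence((base_seed, jitter_index, noise_index, replicate, stream))` so
any cell is independently re-runnable.  The test suite exercises the same
pipeline at 1 500–4 000 points and 100–150 reference points, which leaves
the qualitative structure intact while keeping the default run fast; the
guideline and CLI examples run at a few hundred to ~1 200 events.

## What the synthetic generator does and does not capture

It reproduces the stationarity, jitter scale and insertion statistics that
the method's validation is framed in.  It does not model refractory
dynamics, rate drift, correlated or state-dependent noise, non-stationary
patterns, or continuous-time spike trains — so passing tests demonstrate
the detector's behaviour under the stated contamination model, not
performance on arbitrary recorded data.

## Known limitations

* Neighbouring steps merge under strong jitter (or for patterns with two
  nearly equal distinct distances); a pattern is then still indicated, but
  possibly of the wrong length.  This is the method's natural limit.
* The exact noise percentage at which each criterion degrades depends on the
  noise-interval law relative to the pattern's scale (see above) and on the
  level/weight vectors; the defaults are documented choices, not universal
  constants.
* Criterion scores are discrete sums of weights, so replicate medians move
  in jumps; grid normalization is by the observed maximum and is flagged
  (not silently patched) when no cell scores positively.
* The correlation integral is computed by direct distance evaluation
  (vectorized, no neighbour-search acceleration); cost is
  `O(n_ref × n_points × m)` per curve.
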