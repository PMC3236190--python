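# loglogstep

Detection of short periodic patterns in noisy event-interval series — spike
trains in particular — via **steps in the log-log plot of the correlation
integral**.

## The problem and the method

An interspike-interval (ISI) series that repeats a short pattern of `p`
intervals, embedded in `m`-dimensional space by the coordinate-delay
construction

```
x_i = (s_i, s_{i+1}, …, s_{i+m-1}),
```

collapses onto `p` point clusters, one per cyclic shift of the pattern.  The
correlation integral

```
C(ε) = ⟨ fraction of points within max-norm distance ε of a reference point ⟩
```

then rises in sharp steps at the distinct inter-cluster distances, so its
log-log plot is a staircase rather than the straight line of a fractal
signal.  Where Fourier analysis and template matching break down — strong
timing jitter, a large fraction of noise events — the staircase survives.

The package provides:

* **Simulator** — patterned ISI series contaminated by jitter (a fraction of
  the smallest pattern interval) and insertion noise under two paradigms
  (single noise events competing with whole-pattern insertions, with the
  insertion probability rescaled so the nominal per-event noise fraction is
  comparable), plus permutation surrogates.
* **Correlation curves** — delay embedding and the correlation integral over
  a radius grid (linear increments by default, log-spaced optional), max
  norm, random reference points.
* **Step/plateau criteria** — three weighted quality measures on the
  difference-quotient derivative of the curve: (a) exactly one step at
  `m = p` with a surrogate comparison, (b) exactly `p` steps at `m = 1`,
  (c) the plateau-flatness difference between `m = p` and `m = p − 1`.
* **Analytical bounds** — closed forms for the minimal and maximal number of
  steps observable in the ideal noiseless case as a function of `p` and `m`,

  ```
  odd p:   N_min = (p−1)/2 · ⌈p/m⌉          N_max = (p−1)/2 · (p − m + 1)
  even p:  N_min = (p−2)/2 · ⌈p/m⌉ + ⌈p/2m⌉  N_max = (p−2)/2 · (p − m + 1) + max(p/2 − m + 1, 1)
  ```

  (with `m` clamped to `p`), verified against a brute-force oracle that
  enumerates distinct inter-cluster max-norm distances.
* **Phase diagrams** — jitter × noise sweeps of the normalized criteria with
  visibility regions I (excellent), II (fair), III (ambiguous).
* **Guideline report** — a practical screen of an unknown series for its
  pattern length.

## Worked example

```python
import loglogstep as ls

pattern = ls.Pattern((1, 3, 4))
series = ls.generate_series(
    pattern,
    ls.JitterSpec(fraction=0.05),                          # ±5% of the smallest ISI
    ls.NoiseSpec(fraction=0.30, paradigm="pattern_wise"),  # 30% noise events
    n_events=10_002,
    seed=7,
)

def curve(data, m, seed):
    pts = ls.embed(data, ls.EmbeddingConfig(m=m))
    return ls.correlation_integral(pts, ls.CorrelationConfig(n_ref=250, seed=seed))

curves = {m: curve(series, m, seed=m) for m in (1, 2, 3)}
surrogate = ls.make_surrogate(series, seed=99)
surr_curves = [curve(ls.make_surrogate(series, seed=100 + k), 3, seed=200 + k)
               for k in range(5)]

print("q_b =", ls.criterion_b(curves[1], p=3))
print("q_a =", ls.criterion_a(curves[3], surr_curves))
print("q_c (series)    =", round(ls.criterion_c(curves[3], curves[2]), 2))
print("q_c (surrogate) =", round(ls.criterion_c(curve(surrogate, 3, 301),
                                                curve(surrogate, 2, 302)), 2))
print("bounds at (p=3, m=3):", ls.bounds(3, 3))
```

prints

```
q_b = 5.0
q_a = 1.5
q_c (series)    = -11.67
q_c (surrogate) = -13.33
bounds at (p=3, m=3): BoundsResult(n_min=1, n_max=1, p=3, m=3)
```

`q_b = 5.0` (of a maximum 6): the three steps of the length-3 pattern are
still cleanly visible at `m = 1` under this contamination — the two sharpest
height levels see exactly three derivative peaks each.  `q_a = 1.5`: noise
makes a second step reappear at `m = 3`, but the repeated steps are less
pronounced than in the steppiest member of the surrogate ensemble, so part
of the weight is retained.  The raw plateau-count difference `q_c` is
negative on noisy data (the noise background steepens with dimension); the
pattern shows in its margin over the matched surrogate (−11.67 vs −13.33).
The ideal noiseless case would show exactly one step at `m = 3`
(`N_min = N_max = 1`).

The same pipeline is scriptable from the shell:

```
loglogstep simulate --pattern 1,3,4 --jitter 0.1 --noise 0.3 -n 10000 --seed 7 -o series.txt
loglogstep curve -i series.txt -m 3 --nref 250 -o curve.tsv
loglogstep criteria -i series.txt --pattern-length 3 -o scores.json
loglogstep bounds --p 2..7 --m 1..7 -o bounds.tsv
loglogstep guideline -i series.txt --p-max 6
```

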