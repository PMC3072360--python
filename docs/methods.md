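# Methods note

This note records the model, the numerical conventions, the default
parameters (with units and the reasons for their values), and the design
decisions behind `pmnshape`. Problem sizes quoted here (900 frames at 2 s,
10 cells per group, and so on) are package defaults chosen to represent a
typical 30-minute single-cell recording campaign; every one of them is a
plain parameter.

## 1. The order parameter R(t)

Each frame is a binary silhouette on a pixel grid (row-major, origin at
the top-left, pixel centers at integer coordinates). Cleanup
(`extract_mask`) keeps the largest 8-connected foreground component
(ties broken by first row-major pixel), fills interior holes using
4-connected background (the standard Jordan pair of connectivities), and
rejects masks touching the image border, whose counts would be truncated.
Grayscale input is thresholded by Otsu's method or a numeric cut.

Two pixel counts are taken per frame:

* area `A` — number of foreground pixels;
* perimeter `p` — number of foreground pixels with at least one
  4-neighbour background pixel (off-grid counts as background).

The roundness is `R = r1 / r2` with `r1 = p / 2π`, `r2 = √(A/π)`.
For continuous-circle inputs (`p = 2πr`, `A = πr²`) the operation returns
`R = 1.0` exactly — this is the anchor the acceptance script recomputes.
For *rasterized* circles the literal pixel-count perimeter is biased low
relative to the geometric arc length (diagonal runs are undercounted), so
rasterized `R` sits near, not at, 1; the bias is a property of the
counting definition, shared by all frames, and cancels from within-series
dynamics. A chain-weighted perimeter estimate is available behind
`method="weighted"` but all defaults use the literal count.

One movie yields exactly one `R` value per frame: a 900-frame recording
gives a series of 900 values at `dt = 2 s`.

## 2. Synthetic silhouette generator

### Shape model

Star-convex radial model about a center:

```
r(θ, t) = r0 · (1 + Σ_k a_k(t) cos(kθ + φ_k))
```

evaluated on 1024 boundary vertices and rasterized by including every
pixel whose center radius is at most the interpolated boundary radius at
its angle. Mode `k = 1` is excluded (to first order it translates the
shape rather than deforming it); net motion enters only through the
explicit centroid drift of the translocating state. Frames whose total
amplitude `Σ|a_k|` exceeds 0.88 are rescaled (only the fluctuating modes;
the static texture is a fixed property of the cell) so the boundary stays
safely star-convex (`min r > 0.1 r0`); the clipped-frame count is
reported as ground truth.

### Amplitude dynamics

Four ingredients add on the mode amplitudes:

1. **Dynamic modes** `k = 2..8`: stationary Ornstein–Uhlenbeck processes,
   exact discretization
   `x_{t+1} = x_t e^{−dt/θ} + σ √(1 − e^{−2dt/θ}) ξ_t`, relaxation time
   `θ` (s) and stationary amplitude `σ` per mode.
2. **Burst process** (treadmilling): a two-state telegraph switch gates
   modes 2–4 — multiplicative gain 2 on their OU amplitudes plus an
   additive protrusion amplitude 0.10 while "on". The on/off rates
   (1/30 s⁻¹ and 1/25 s⁻¹) are fully modulated in antiphase at the
   treadmilling protrusion-cycle period (252.1 s), so bursts ignite near
   the modulation peaks and recur rhythmically with stochastic jitter.
   The additive term gives bursts a reproducible size: a purely
   multiplicative gain inherits the χ²-like height variation of the OU
   amplitudes, which smears the burst line and leaks power into the
   lowest periodogram bins.
3. **Microvillus texture**: (a) a *static* per-cell corrugation on high
   modes 17–24 (per-cell total `Σ|a| ~ U(0.08, 0.30)`, random signs and
   phases) — this dominates the time-averaged `R`, differs between cells
   but not between states, and is why the group *mean* of `R` does not
   separate idling from treadmilling; (b) a fast *flicker* (OU with
   θ = 0.8 s, σ = 0.008 on modes 9–16, both states) that sets the
   near-white high-frequency floor of `R(t)`.
4. **Standing wave**: a slow deterministic oscillation of the mode-2
   amplitude, period 507.4 s (≈ 8.46 min) for idling. In treadmilling
   the slow rhythm is carried by the burst gating at 252.1 s (≈ 4.20 min)
   instead. These periods are the states' characteristic slowest border
   modes and are what the slowest-Fourier-mode detector recovers.

### State presets (defaults)

| parameter | idling | treadmilling | translocating | unit / note |
|---|---|---|---|---|
| frames n / dt | 900 / 2 | 900 / 2 | 900 / 2 | frames / s |
| r0 / grid | 60 / 256 | 60 / 256 | 30 / 256 | px (smaller cell so the track fits) |
| θ modes 2–8 | 10 | 10,10,10,12,12,12,12 | 20 | s |
| σ modes 2–8 | 0.015 | 0.02,0.02,0.02,0.03,0.03,0.03,0.03 | 0.01 | fraction of r0 |
| burst modes / gain / boost | — | 2–4 / 2.0 / 0.10 | — | |
| burst on/off rates | — | 1/30, 1/25 | — | s⁻¹ |
| burst modulation | — | depth 1.0, period 252.1 s | — | |
| osc mode-2 mean / amp / period | 0.08 / 0.05 / 507.4 s | 0.08 / 0 / — | 0.30 / 0 / — | fixed a₂ = 0.3 polarizes the translocating ellipse |
| drift velocity | 0 | 0 | 0.08 | px/s |

The transition preset runs the idling parameters before the switch index
(`t_switch = 283` by default) and the treadmilling parameters after, with
the OU paths continuous at the switch, deterministic amplitude offsets
ramped over 15 samples, and the burst process starting "on" at the switch
(the observed state change *is* the protrusion onset).

Calibration: the preset defaults were tuned in a single calibration pass
so that the expected group contrasts emerge at the default study size,
then frozen. At 10 + 10 cells (fixed seeds): SD p ≈ 2·10⁻⁵ and skew
p ≈ 3·10⁻⁴ (both higher in treadmilling), Λ1 p ≈ 0.04 and α ≈ 2.7·10⁻³
(both lower), mean p ≈ 0.14 (not significant); median slowest-mode period
10 min (idling) vs 5.5 min (treadmilling).

### Reproducibility

One root seed; every stochastic ingredient draws from its own child
stream (`numpy.random.SeedSequence` spawn keys), so adding an ingredient
never perturbs the others, and identical `(params, seed)` give
bit-identical frame stacks.

### What the generator is and is not

It emulates the *statistics* of the shape fluctuations (amplitude scale,
relaxation times, intermittency, rhythms, between-cell texture
heterogeneity), not cell mechanics: there is no cytoskeleton, adhesion or
force balance, and translocation is a rigid drift rather than emergent
polarity. It is a test harness and null model, not a biophysical model.

## 3. Measure battery

All measures run on `R(t)`; per-measure failures (short or degenerate
series) are captured with reasons rather than aborting, and group
statistics use the available subsets with adjusted df.

* **S1, S2** — mean and sample SD (`ddof = 1`).
* **S3, S4** — skewness `m3 / var^{3/2}` and excess kurtosis
  `m4 / var² − 3` with 1/n central moments (the conventional g1/g2).
* **Λ1 (Wolf)** — leading Lyapunov exponent by neighbour tracking in a
  3-dimensional delay embedding (delay 1): evolve fiducial and neighbour
  3 samples, accumulate `log(d1/d0)`, replace with a fresh nearest
  neighbour subject to a Theiler window of 10 samples and scale bounds
  (≥ 10⁻⁴ of the data range, ≤ 0.1 of the attractor extent); result in
  natural-log units per sample step. Oracle: the fully chaotic logistic
  map `x → 4x(1−x)` gives Λ1 = ln 2 within ±0.1.
* **Periodogram** — one-sided, mean removed, no taper by default,
  normalized so `Σ power = (1/n)·Σ(x−x̄)²` (discrete Parseval; verified
  to 10⁻¹⁰ in tests).
* **α** — OLS slope of `log10 power` on `log10 f` over the middle third
  of the **log-frequency axis**. Band choice: the discrete random-walk
  spectrum is `1/sin²(πf/fs)`, which follows `f⁻²` only at low relative
  frequency; the middle third *by bin index* sits at `f/fs ∈ [1/6, 1/3]`
  where the true slope is ≈ −1.6, so the white-noise/random-walk oracles
  (0 and −2) select the log-axis band (20-replicate means 0.03 ± 0.08 and
  −2.00 ± 0.07). The index band remains available
  (`band="middle_third_index"`).
* **Slowest Fourier mode** — the lowest-frequency qualifying peak of the
  periodogram smoothed by an edge-normalized 3-bin moving average. A peak
  must be an interior local maximum (exact plateaus from a smeared
  single-bin line are resolved to the raw-power argmax within the
  plateau) and exceed both the median smoothed power and 25 % of the
  smoothed maximum. Rationale: on a raw periodogram the lowest-frequency
  "local maximum" is almost surely a noise bump, reporting ≈ 30 min for
  any red-tinted spectrum; the median rule alone excludes nothing on a
  red spectrum (its median lies far below the low-frequency floor), hence
  the prominence floor; and plain zero-padded smoothing fabricates a
  maximum at the lowest bin of steep spectra, hence the edge
  normalization. A global-argmax variant is available (`mode="argmax"`).

## 4. Embeddings and recurrence plots

**Broomhead–King.** Window length `M = 8` (about one correlation decay
of `R(t)` at 2 s sampling). The trajectory matrix `X` of mean-removed
lagged windows gives `C_M = XᵀX/(n−M+1)`; eigenvalues are returned in
descending order, eigenvectors sign-fixed (largest-magnitude entry
positive), and the eigenfunctions are `Ψ_i = X v_i`. Identities tested:
`Σ eigenvalues = trace C_M` (to 10⁻¹⁰) and `⟨Ψ_i²⟩ = λ_i`. The occupied
phase volume (bounding box of `Ψ1..Ψ3`) is an order of magnitude larger
for treadmilling than idling cells.

**Recurrence plots.** `RP[i,j] = Θ(ε − ‖x_i − x_j‖)` on the
3-dimensional delay embedding (τ = 1), Euclidean norm, absolute `ε = 1`
by default; a quantile mode (`ε` = q-th percentile of off-diagonal
distances, default q = 10) makes cross-state comparisons scale-fair.
The per-diagonal recurrence profile summarizes return-time structure;
its coefficient of variation is higher for treadmilling cells (clustered
returns) in 10/10 seed-matched pairs.

## 5. Wavelet transition analysis

Complex Morlet mother wavelet, center frequency `ω0 = 6` (implemented as
PyWavelets `cmor` with bandwidth 2.0 and center frequency `ω0/2π`; the
equivalent Fourier period is `scale · 4π/(ω0 + √(2+ω0²)) ≈ 1.03 · scale`).
Scales: 64 log-spaced values in `[2, n/4]` samples. The series mean is
removed before the transform — the finite convolution's edge response to
the DC offset of `R(t)` would otherwise swamp the slow scales. A cone of
influence flags points closer than `scale·√2` samples to either edge.

**Change point.** The slow-band modulus (largest third of the scale
grid) rises after an idling→treadmilling switch, but it localizes poorly:
a wavelet atom of scale `a` spreads post-switch energy ≈ `a` samples
backwards, and late protrusion bursts can dominate a local-derivative
statistic. The change point is therefore the maximizer of the sum of two
normalized least-squares step-fit statistics
(`√(t(n−t)/n)·|mean after − mean before|`), one on the fast-band
(< 20-sample scales; narrow atoms localize the fluctuation-amplitude
jump sharply) and one on the all-scale mean-modulus curve. On the
default transition ensemble this lands within ±60 samples of the true
switch in 10/10 runs (maximum error 27 samples), and the slow-band
modulus is higher post-switch in 10/10.

## 6. Group statistics

Pooled-variance two-sample t per measure, `t = (x̄_b − x̄_a)/se`,
`df = n_a + n_b − 2` (10 vs 10 → 18), with subsets and adjusted df when
a measure is missing for some cells (flagged in the output). Default
p-value: one-tailed in the direction of the observed difference,
`p = sf(|t|, df)` (t = 0 → p = 0.5), which is invariant under swapping
the group labels; `greater`, `less` and `two-sided` tails are available.
No multiple-testing correction is applied across the six measures.

The single-cell before/after comparison splits a transition series at
the known switch index (both segments ≥ 100 samples), reports signed
per-measure deltas, and checks them against the expected directions
(SD up, skew up, Λ1 down, α down).

## 7. Limitations

* The perimeter is a literal pixel count; absolute `R` values depend on
  resolution and should only be compared within a fixed pixel size.
* Wolf's Λ1 on short noisy series is a *relative* dynamics index, not a
  certified chaos detector; its scale bounds and evolution interval are
  heuristics inherited from the original algorithm.
* The generator's states are phenomenological; parameter values were
  calibrated once against the intended group contrasts and are not fits
  to any individual cell.
* The change-point statistic assumes a single switch per recording.
* `df = n1 + n2 − 2` assumes equal group variances; no Welch correction
  is applied, matching the study convention.
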