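# pmnshape

Shape-dynamics analysis of single-cell silhouette movies.

`pmnshape` turns a time-lapse of binary cell silhouettes (for example, a
polymorphonuclear leukocyte imaged every 2 s for 30 min) into a single
order-parameter time series and a battery of nonlinear dynamics measures
that distinguish the cell's behavioural states — *idling* (near-circular,
small fast border fluctuations), *treadmilling* (intermittent large
protrusion cycles without net motion) and *translocating* (polarized,
moving) — and that localize the spontaneous transitions between them.

## The science in brief

**Order parameter.** Each silhouette frame is reduced to two pixel counts:
the area `A` (foreground pixels) and the perimeter `p` (foreground pixels
with at least one 4-neighbour background pixel). These define two
circle-equivalent radii, `r1 = p / 2π` (perimeter-derived) and
`r2 = √(A/π)` (area-derived), whose ratio

```
R = r1 / r2
```

is the *relative radial roundness*. A perfect continuous circle gives
`R = 1` exactly; the more convoluted the outline at fixed area, the larger
`R`. One movie therefore becomes one series `R(t)`, and everything
downstream — moments, chaos measures, spectra, embeddings, wavelets — runs
on that series.

**Measure battery.** Per cell the package reports the mean and SD of
`R(t)`, its skewness and excess kurtosis (1/n central moments, `g1`/`g2`
conventions), the leading Lyapunov exponent `Λ1` by Wolf's
neighbour-tracking algorithm in a 3-dimensional delay embedding, the
log-log spectral slope `α` of the periodogram (fit over the middle third
of the log-frequency axis), and the period of the slowest qualifying
Fourier mode. The discriminating pattern between idling and treadmilling
cells is *dynamical*, not morphological: the mean of `R(t)` does not
separate the states (it is dominated by each cell's static border
texture), while SD and skewness rise and `Λ1` and `α` fall when a cell
treadmills.

**Phase-space views.** Broomhead–King (singular-spectrum) embeddings with
window `M = 8` give denoised eigenfunction trajectories `Ψ1..Ψ3`;
recurrence plots (dimension 3, delay 1) show whether return times are
homogeneous (idling) or clustered into bands (treadmilling).

**Transitions.** A complex Morlet wavelet scalogram (`ω0 = 6`) resolves
when a cell switches state: the modulus rises at slow scales after an
idling→treadmilling switch, and a least-squares step fit to the fast-band
and all-scale modulus curves localizes the change point to within a few
tens of frames.

**Group statistics.** Two groups of cells are compared measure-by-measure
with a pooled-variance two-sample t statistic, `df = n1 + n2 − 2` (10 vs
10 cells → `df = 18`), one-tailed in the direction of the observed
difference by default.

**Synthetic cells.** Because real movies are scarce, the package ships a
seeded generator of silhouette movies: a star-convex radial shape model
`r(θ,t) = r0 (1 + Σ a_k(t) cos(kθ + φ_k))` whose mode amplitudes combine
Ornstein–Uhlenbeck dynamics, rhythmically gated protrusion bursts, a
static per-cell border texture and a slow standing wave, rasterized to
binary frames. Identical parameters and seed give bit-identical movies.
Defaults are calibrated so the group contrasts above emerge at the
default study size (10 cells per state, 900 frames at 2 s).

## Worked example

Ten lines from silhouettes to a measure battery:

```python
import pmnshape as ps

params = ps.SyntheticParams.treadmilling(seed=2000)   # 900 frames, 2 s/frame
series, info = ps.simulate_roundness(params)          # rasterize + reduce to R(t)
print(f"n = {series.n} frames, duration = {series.duration / 60:.0f} min")

ms = ps.measure_battery(series)
print(f"mean R = {ms.mean:.3f}   SD = {ms.sd:.4f}   skew = {ms.skew:.2f}")
print(f"Lambda1 = {ms.lambda1:.3f} /step   alpha = {ms.alpha:.2f}   "
      f"slowest mode = {ms.slowest_period_min:.1f} min")
```

prints

```
n = 900 frames, duration = 30 min
mean R = 1.178   SD = 0.0217   skew = 0.70
Lambda1 = 0.715 /step   alpha = -0.66   slowest mode = 4.3 min
```

A small two-group comparison (3 idling vs 3 treadmilling cells; the full
study uses 10 vs 10):

```python
from pmnshape.measures import measure_battery

idle = [measure_battery(ps.simulate_roundness(ps.SyntheticParams.idling(seed=s))[0])
        for s in (1000, 1001, 1002)]
tread = [measure_battery(ps.simulate_roundness(ps.SyntheticParams.treadmilling(seed=s))[0])
         for s in (2000, 2001, 2002)]
cmp = ps.compare_groups(idle, tread)
print(cmp.to_frame()[["measure", "mean_a", "mean_b", "t", "df", "p"]]
      .round(4).to_string(index=False))
```

prints

```
 measure  mean_a  mean_b       t  df      p
    mean  1.4137  1.3605 -0.2835   4 0.3954
      sd  0.0094  0.0230  3.0762   4 0.0185
    skew  0.3407  0.7368  3.3422   4 0.0144
kurtosis  0.6304  0.8001  0.3452   4 0.3737
 lambda1  0.7459  0.7139 -5.7750   4 0.0022
   alpha -0.1174 -0.5759 -2.5905   4 0.0303
```

Already at 3 + 3 cells the dynamical measures (SD, skew, Λ1, α) separate
the states while the mean roundness does not.

The same analysis from the command line, on a movie file:

```
$ pmnshape simulate --state transition --seed 3000 --out cell.tif --truth truth.json
wrote 900 frames to cell.tif (clipped 5 frames)
$ pmnshape roundness --in cell.tif --out r.csv
wrote 900 R values to r.csv
$ pmnshape measures --in r.csv
{
  "mean": 1.3632813282026826,
  "sd": 0.028396062704355293,
  "skew": 0.9060667302752298,
  "kurtosis": 0.40037704591483214,
  "lambda1": 0.7258578905045291,
  "alpha": -0.8632456702839211,
  "slowest_period_min": 3.75,
  "failures": {}
}
$ pmnshape cwt --in r.csv --out scalogram.png
```

`pmnshape roundness` accepts any multi-page TIFF (or directory of PNG
frames) of binary or grayscale silhouettes — real microscopy masks work
exactly like synthetic ones. Other verbs: `embed` (Broomhead–King), `rp`
(recurrence plot), `compare` (two groups of R(t) CSVs), `run` (full
pipeline from a JSON config; see `pmnshape.RunConfig`).

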