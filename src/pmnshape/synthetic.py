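"""Seeded synthetic silhouette movies for the three PMN behavioural states.

The generator is a star-convex radial shape model

    r(theta, t) = r0 * (1 + sum_k a_k(t) * cos(k*theta + phi_k))

rasterized on a pixel grid, one frame per ``dt`` seconds.  The mode
amplitudes a_k(t) combine four ingredients, chosen to emulate the
shape-fluctuation statistics of living neutrophils rather than their
mechanics:

* **dynamic modes** (k = 2..8): Ornstein-Uhlenbeck processes with relaxation
  time ``theta_k`` and stationary amplitude ``sigma_k``.  Idling cells have
  fast, small modes; treadmilling cells slow, large ones.
* **burst process** (treadmilling): a two-state telegraph switch gates the
  low modes (multiplicative gain plus an additive protrusion amplitude),
  producing the intermittent, multi-mode protrusions seen in treadmilling
  cells.  The switching rates are modulated in antiphase at the state's
  characteristic protrusion-cycle period, so bursts recur rhythmically and
  the slowest spectral mode of R(t) sits at that period.
* **microvillus texture**: a per-cell *static* high-order roughness (the
  cell's resting border corrugation, which dominates the time-averaged R and
  differs between cells but not between the idling/treadmilling states) plus
  a fast, fine *flicker* (short-relaxation OU on high modes, common to both
  states) that sets the near-white high-frequency floor of R(t).
* **standing wave**: a slow deterministic amplitude oscillation of one low
  mode, with default periods matching the characteristic slowest border
  oscillations of each state (idling ~8.46 min, treadmilling ~4.20 min).

Mode 1 is excluded (it is a pure translation surrogate); net motion enters
only through the explicit centroid drift of the translocating state.

Reproducibility: a single root seed; every stochastic ingredient draws from
its own deterministically derived child stream, so adding modes never
perturbs existing ones and identical (params, seed) give bit-identical
frame stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import GridError, StarConvexityError
from .mask import BinaryMask, centroid, feret_diameter, mask_metrics, \
    TRANSLOCATION_THRESHOLD
from .series import RSeries

_CROSS = ndimage.generate_binary_structure(2, 1)
_SQUARE = ndimage.generate_binary_structure(2, 2)

#: total |a_k| budget; amplitude vectors are rescaled to this bound so the
#: outline stays safely star-convex (min r > 0.1 r0)
AMP_CLIP = 0.88


@dataclass
class SyntheticParams:
    """Configuration of one synthetic recording.

    Defaults (set by the state classmethods) define the study conditions:
    900 frames at 2 s (a 30 min recording), base radius 60 px on a 256 px
    grid.  All amplitudes are dimensionless fractions of r0.
    """

    state: str = "idling"
    n: int = 900
    dt: float = 2.0
    r0: float = 60.0
    grid: int = 256
    seed: int = 0
    # dynamic OU modes; theta/sigma may be scalars or per-mode tuples
    modes: tuple = (2, 3, 4, 5, 6, 7, 8)
    theta: float | tuple = 10.0  # OU relaxation time, seconds
    sigma: float | tuple = 0.015  # OU stationary amplitude
    # fast microvillus flicker (state-independent)
    flicker_modes: tuple = (9, 10, 11, 12, 13, 14, 15, 16)
    flicker_theta: float = 0.8
    flicker_sigma: float = 0.008
    # static per-cell roughness (state-independent distribution)
    static_modes: tuple = (17, 18, 19, 20, 21, 22, 23, 24)
    static_scale: tuple = (0.08, 0.30)   # uniform range of per-cell sum |a_k|
    # telegraph burst process (treadmilling); the on-rate may be modulated
    # rhythmically at the state's characteristic protrusion-cycle period
    burst_modes: tuple = ()
    burst_gain: float = 1.0
    burst_on_rate: float = 0.0   # per second, off->on
    burst_off_rate: float = 0.0  # per second, on->off
    burst_mod_depth: float = 0.0   # 0 = free telegraph, ~1 = rhythmic gating
    burst_mod_period: float = 252.1  # seconds
    burst_boost: float = 0.0     # additive amplitude of burst protrusions
    # slow standing-wave border mode
    osc_mode: int = 2
    osc_mean: float = 0.0
    osc_amp: float = 0.0
    osc_period: float = 507.4    # seconds
    # translocation
    drift_velocity: float = 0.0  # px/s along +x
    # transition
    t_switch: int | None = None

    def __post_init__(self):
        if self.r0 < 20:
            raise ValueError("r0 must be at least 20 px")
        if self.n < 2 or self.dt <= 0:
            raise ValueError("need n >= 2 frames and dt > 0")
        budget = self._sigma_budget()
        if budget >= 0.9:
            raise ValueError(
                f"amplitude budget {budget:.3f} >= 0.9 breaks star-convexity")

    def _per_mode(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, float), (len(self.modes),))
        return arr.copy()

    def _sigma_budget(self) -> float:
        sig = self._per_mode(self.sigma)
        gains = np.array([self.burst_gain if k in self.burst_modes else 1.0
                          for k in self.modes])
        return float((sig * gains).sum())

    # ------------------------------------------------------------------
    # state presets

    @classmethod
    def idling(cls, seed: int = 0, **over) -> "SyntheticParams":
        """Near-circular cell: fast, small border fluctuations; faint slow
        standing wave at the idling characteristic period (8.457 min)."""
        kw = dict(state="idling", theta=10.0, sigma=0.015,
                  osc_mode=2, osc_mean=0.08, osc_amp=0.05,
                  osc_period=507.4, seed=seed)
        kw.update(over)
        return cls(**kw)

    @classmethod
    def treadmilling(cls, seed: int = 0, **over) -> "SyntheticParams":
        """Intermittent large protrusions: telegraph-gated bursts on the low
        modes 2-4 (gain 2 plus an additive protrusion amplitude 0.10), with
        the on/off rates fully modulated at the treadmilling characteristic
        period (4.201 min) so bursts recur rhythmically, plus faster large
        mid modes (pseudopod flutter)."""
        kw = dict(state="treadmilling",
                  theta=(10.0, 10.0, 10.0, 12.0, 12.0, 12.0, 12.0),
                  sigma=(0.02, 0.02, 0.02, 0.03, 0.03, 0.03, 0.03),
                  burst_modes=(2, 3, 4), burst_gain=2.0, burst_boost=0.10,
                  burst_on_rate=1.0 / 30.0, burst_off_rate=1.0 / 25.0,
                  burst_mod_depth=1.0, burst_mod_period=252.1,
                  osc_mode=2, osc_mean=0.08, osc_amp=0.0,
                  osc_period=252.1, seed=seed)
        kw.update(over)
        return cls(**kw)

    @classmethod
    def translocating(cls, seed: int = 0, **over) -> "SyntheticParams":
        """Polarized smooth ellipse (fixed mode-2 amplitude 0.3) with net
        centroid drift; smaller cell so the track fits the grid."""
        kw = dict(state="translocating", r0=30.0, theta=20.0, sigma=0.01,
                  static_scale=(0.05, 0.15), osc_mode=2, osc_mean=0.30,
                  osc_amp=0.0, drift_velocity=0.08, seed=seed)
        kw.update(over)
        return cls(**kw)

    @classmethod
    def transition(cls, seed: int = 0, t_switch: int = 283, **over) -> "SyntheticParams":
        """Idling regime before ``t_switch``, treadmilling after, amplitudes
        continuous at the switch (deterministic offsets ramp over 15
        samples; the burst process starts 'on' at the switch, since the
        observed state change is defined by protrusion onset)."""
        kw = dict(state="transition", t_switch=t_switch,
                  burst_modes=(2, 3, 4), burst_gain=2.0, burst_boost=0.10,
                  burst_on_rate=1.0 / 30.0, burst_off_rate=1.0 / 25.0,
                  burst_mod_depth=1.0, burst_mod_period=252.1,
                  seed=seed)
        kw.update(over)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticRecording:
    """Frames plus the ground truth that generated them."""

    frames: list
    params: SyntheticParams
    amplitudes: np.ndarray       # (n, K) effective a_k(t) after clipping
    mode_numbers: np.ndarray     # (K,) angular mode k per column
    phases: np.ndarray           # (K,) fixed phase phi_k per column
    burst: np.ndarray            # (n,) telegraph state (0/1)
    centers: np.ndarray          # (n, 2) shape center (x, y) per frame
    clipped: int                 # frames whose amplitude vector was rescaled
    t_switch: int | None = None

    @property
    def n(self) -> int:
        return len(self.frames) if self.frames else self.amplitudes.shape[0]

    def truth_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "mode_numbers": self.mode_numbers.tolist(),
            "phases": self.phases.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "burst": self.burst.tolist(),
            "centers": self.centers.tolist(),
            "clipped": self.clipped,
            "t_switch": self.t_switch,
        }


# ---------------------------------------------------------------------------
# shape model primitives

def radial_boundary(amplitudes: Sequence[float], phases: Sequence[float],
                    r0: float, mode_numbers: Sequence[int],
                    n_vertices: int = 1024):
    """Closed polygon of the radial shape model.

    Returns (vertices, theta, r): ``vertices`` is an (n_vertices, 2) array of
    (x, y) points ordered counterclockwise about the origin, sampled on a
    uniform theta grid; ``r`` is the radial function at those angles.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = _radial_profile(theta, np.asarray(amplitudes, float),
                        np.asarray(phases, float),
                        np.asarray(mode_numbers, int), r0)
    if r.min() <= 0.1 * r0:
        raise StarConvexityError(
            f"min r(theta) = {r.min():.2f} <= 0.1 r0 = {0.1 * r0:.2f}")
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return verts, theta, r


def _radial_profile(theta, a, phi, ks, r0):
    mod = np.ones_like(theta)
    for k, ak, pk in zip(ks, a, phi):
        if ak != 0.0:
            mod = mod + ak * np.cos(k * theta + pk)
    return r0 * mod


def rasterize(polygon: np.ndarray, grid: int, center=None,
              cleanup: bool = True) -> BinaryMask:
    """Rasterize a closed star-convex polygon on a ``grid x grid`` lattice.

    A pixel is included iff its center's radius (about the shape center) is
    at most r(theta of that center), with r linearly interpolated between
    polygon vertices.  ``center`` defaults to the vertex centroid of the
    polygon (which must already be expressed in grid coordinates).
    """
    poly = np.asarray(polygon, float)
    if center is None:
        center = poly.mean(axis=0)
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx <= grid - 1 and 0 <= cy <= grid - 1):
        raise GridError(f"shape center ({cx:.1f}, {cy:.1f}) is off the grid")
    dx = poly[:, 0] - cx
    dy = poly[:, 1] - cy
    th = np.arctan2(dy, dx)
    rr = np.hypot(dx, dy)
    order = np.argsort(th)
    th, rr = th[order], rr[order]
    rmax = rr.max()
    if cx - rmax < -0.5 or cx + rmax > grid - 0.5 \
            or cy - rmax < -0.5 or cy + rmax > grid - 0.5:
        raise GridError("polygon extends outside the raster grid")
    yy, xx = np.mgrid[0:grid, 0:grid]
    pth = np.arctan2(yy - cy, xx - cx)
    pr = np.hypot(xx - cx, yy - cy)
    rb = np.interp(pth, th, rr, period=2.0 * math.pi)
    g = pr <= rb
    if cleanup:
        g = _cleanup(g)
    return BinaryMask(g)


def _cleanup(g: np.ndarray) -> np.ndarray:
    labels, nlab = ndimage.label(g, structure=_SQUARE)
    if nlab > 1:
        sizes = ndimage.sum_labels(g, labels, index=np.arange(1, nlab + 1))
        g = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(g, structure=_CROSS)


# ---------------------------------------------------------------------------
# stochastic ingredients

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=key))


def ou_path(n: int, dt: float, theta: float, sigma: float,
            rng: np.random.Generator, x0: float | None = None,
            theta2: float | None = None, sigma2: float | None = None,
            t_switch: int | None = None) -> np.ndarray:
    """Exact-discretization Ornstein-Uhlenbeck path.

    x_{t+1} = x_t e^{-dt/theta} + sigma sqrt(1 - e^{-2 dt/theta}) xi_t, with
    stationary initial condition (unless ``x0`` is given).  If ``t_switch``
    is set, (theta2, sigma2) take over from that index on, the path staying
    continuous at the switch.
    """
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal() if x0 is None else x0
    xi = rng.standard_normal(n - 1)
    for t in range(1, n):
        th = theta if (t_switch is None or t < t_switch) else theta2
        sg = sigma if (t_switch is None or t < t_switch) else sigma2
        rho = math.exp(-dt / th)
        x[t] = x[t - 1] * rho + sg * math.sqrt(1.0 - rho * rho) * xi[t - 1]
    return x


def telegraph_path(n: int, dt: float, on_rate: float, off_rate: float,
                   rng: np.random.Generator, start: int | None = None,
                   mod_depth: float = 0.0, mod_period: float = 252.1,
                   mod_phase: float = 0.0) -> np.ndarray:
    """Two-state (0/1) continuous-time Markov switch sampled every dt.

    With ``mod_depth = 0`` this is the free telegraph process with exact
    two-state transition probabilities and stationary start
    (P(on) = on_rate / (on_rate + off_rate)) unless ``start`` is given.
    A nonzero ``mod_depth`` modulates the instantaneous rates in
    antiphase: ``on_rate * (1 + mod_depth * cos(2 pi t / mod_period +
    mod_phase))`` and ``off_rate * (1 - mod_depth * cos(...))``.  Near
    depth 1 bursts ignite almost only around the modulation peaks and are
    extinguished soon after the peak passes, producing rhythmic protrusion
    cycles at ``mod_period`` with stochastic jitter in onset and duration.
    """
    if on_rate <= 0 or off_rate <= 0:
        return np.zeros(n, dtype=int)
    b = np.empty(n, dtype=int)
    if start is None:
        p_on = on_rate / (on_rate + off_rate)
        b[0] = int(rng.random() < p_on)
    else:
        b[0] = int(start)
    u = rng.random(n - 1)
    if mod_depth == 0.0:
        lam = on_rate + off_rate
        p_on = on_rate / lam
        decay = math.exp(-lam * dt)
        p_on_given_on = p_on + (1 - p_on) * decay
        p_on_given_off = p_on * (1 - decay)
        for t in range(1, n):
            p = p_on_given_on if b[t - 1] else p_on_given_off
            b[t] = int(u[t - 1] < p)
        return b
    tt = np.arange(n) * dt
    mod = mod_depth * np.cos(2.0 * math.pi * tt / mod_period + mod_phase)
    kon = np.clip(on_rate * (1.0 + mod), 0.0, None)
    koff = np.clip(off_rate * (1.0 - mod), 0.0, None)
    p_on_given_off = 1.0 - np.exp(-kon * dt)
    p_off_given_on = 1.0 - np.exp(-koff * dt)
    for t in range(1, n):
        if b[t - 1]:
            b[t] = int(u[t - 1] >= p_off_given_on[t - 1])
        else:
            b[t] = int(u[t - 1] < p_on_given_off[t - 1])
    return b


def _static_roughness(params: SyntheticParams):
    """Per-cell static high-order corrugation: amplitudes and phases."""
    rng = _rng(params.seed, 0)
    ks = np.asarray(params.static_modes, int)
    if ks.size == 0:
        return ks, np.zeros(0), np.zeros(0)
    lo, hi = params.static_scale
    total = rng.uniform(lo, hi)
    raw = np.abs(rng.standard_normal(ks.size)) + 1e-12
    amps = raw / raw.sum() * total * rng.choice([-1.0, 1.0], size=ks.size)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=ks.size)
    return ks, amps, phases


# ---------------------------------------------------------------------------
# simulation

def _amplitude_trajectories(params: SyntheticParams):
    """Assemble effective per-frame amplitudes for all modes.

    Returns (ks, phases, a_eff (n, K), burst (n,), clipped_count).
    """
    p = params
    n, dt, ts = p.n, p.dt, p.t_switch
    transition = p.state == "transition"
    if transition:
        pre, post = SyntheticParams.idling(), SyntheticParams.treadmilling()
    # dynamic modes
    dyn_ks = np.asarray(p.modes, int)
    dyn_phases = _rng(p.seed, 1).uniform(0.0, 2.0 * math.pi, size=dyn_ks.size)
    dyn = np.empty((n, dyn_ks.size))
    if transition:
        th_pre, sg_pre = pre._per_mode(pre.theta), pre._per_mode(pre.sigma)
        th_post, sg_post = post._per_mode(post.theta), post._per_mode(post.sigma)
    else:
        th, sg = p._per_mode(p.theta), p._per_mode(p.sigma)
    for j, k in enumerate(dyn_ks):
        rng = _rng(p.seed, 10, int(k))
        if transition:
            dyn[:, j] = ou_path(n, dt, th_pre[j], sg_pre[j], rng,
                                theta2=th_post[j], sigma2=sg_post[j],
                                t_switch=ts)
        else:
            dyn[:, j] = ou_path(n, dt, th[j], sg[j], rng)
    # telegraph burst gain on selected modes
    if transition:
        burst = np.zeros(n, dtype=int)
        if ts is not None and ts < n:
            # rhythmic gating phased so a modulation peak sits at the switch
            burst[ts:] = telegraph_path(
                n - ts, dt, p.burst_on_rate, p.burst_off_rate,
                _rng(p.seed, 3), start=1, mod_depth=p.burst_mod_depth,
                mod_period=p.burst_mod_period, mod_phase=0.0)
    else:
        mod_phase = float(_rng(p.seed, 3, 1).uniform(0.0, 2.0 * math.pi))
        burst = telegraph_path(n, dt, p.burst_on_rate, p.burst_off_rate,
                               _rng(p.seed, 3), mod_depth=p.burst_mod_depth,
                               mod_period=p.burst_mod_period,
                               mod_phase=mod_phase)
    gain = 1.0 + (p.burst_gain - 1.0) * burst.astype(float)
    for j, k in enumerate(dyn_ks):
        if k in p.burst_modes:
            dyn[:, j] = dyn[:, j] * gain + p.burst_boost * burst
    # standing wave on one low mode (added to that mode's amplitude)
    t = np.arange(n) * dt
    osc_phase0 = _rng(p.seed, 2).uniform(0.0, 2.0 * math.pi)
    if transition:
        ramp = np.clip((np.arange(n) - (ts or 0)) / 15.0, 0.0, 1.0)
        mean = pre.osc_mean + (post.osc_mean - pre.osc_mean) * ramp
        amp = pre.osc_amp + (post.osc_amp - pre.osc_amp) * ramp
        freq = np.where(np.arange(n) < (ts or 0),
                        1.0 / pre.osc_period, 1.0 / post.osc_period)
        phase = osc_phase0 + 2.0 * math.pi * np.cumsum(freq) * dt
        osc_mode = pre.osc_mode
    else:
        mean, amp = p.osc_mean, p.osc_amp
        phase = osc_phase0 + 2.0 * math.pi * t / p.osc_period
        osc_mode = p.osc_mode
    osc = mean + amp * np.cos(phase)
    j_osc = int(np.flatnonzero(dyn_ks == osc_mode)[0]) if osc_mode in dyn_ks else None
    if j_osc is not None:
        dyn[:, j_osc] = dyn[:, j_osc] + osc
    # flicker modes
    fl_ks = np.asarray(p.flicker_modes, int)
    fl_phases = _rng(p.seed, 1, 1).uniform(0.0, 2.0 * math.pi, size=fl_ks.size)
    fl = np.empty((n, fl_ks.size))
    for j, k in enumerate(fl_ks):
        fl[:, j] = ou_path(n, dt, p.flicker_theta, p.flicker_sigma,
                           _rng(p.seed, 11, int(k)))
    # static roughness
    st_ks, st_amps, st_phases = _static_roughness(p)
    st = np.broadcast_to(st_amps, (n, st_ks.size)).copy()

    ks = np.concatenate([dyn_ks, fl_ks, st_ks])
    phases = np.concatenate([dyn_phases, fl_phases, st_phases])
    a = np.concatenate([dyn, fl, st], axis=1)
    # star-convexity guard: rescale the *dynamic* part of frames whose total
    # |a| exceeds the clip (the static corrugation is a fixed property of the
    # cell, so only the fluctuating modes are compressed)
    n_dyn = dyn.shape[1] + fl.shape[1]
    tot = np.abs(a).sum(axis=1)
    over = tot > AMP_CLIP
    clipped = int(over.sum())
    if clipped:
        st_tot = np.abs(a[over, n_dyn:]).sum(axis=1)
        dyn_tot = np.abs(a[over, :n_dyn]).sum(axis=1)
        scale = np.clip((AMP_CLIP - st_tot) / np.maximum(dyn_tot, 1e-12),
                        0.0, 1.0)
        a[over, :n_dyn] *= scale[:, None]
    return ks, phases, a, burst, clipped


def simulate_state(params: SyntheticParams, keep_frames: bool = True) -> SyntheticRecording:
    """Generate a full state-labelled recording.

    The returned recording is reproducible bit-for-bit from (params, seed).
    Star-convexity violations are handled by rescaling the frame's amplitude
    vector (count reported in ``clipped``), so the series length is exact.
    """
    p = params
    ks, phases, a, burst, clipped = _amplitude_trajectories(p)
    c0 = (p.grid - 1) / 2.0
    t = np.arange(p.n) * p.dt
    if p.drift_velocity:
        total = p.drift_velocity * (p.n - 1) * p.dt
        xs = c0 - total / 2.0 + p.drift_velocity * t
    else:
        xs = np.full(p.n, c0)
    centers = np.column_stack([xs, np.full(p.n, c0)])

    theta_grid = np.linspace(0.0, 2.0 * math.pi, 1024, endpoint=False)
    yy, xx = np.mgrid[0:p.grid, 0:p.grid].astype(float)
    fixed_center = not p.drift_velocity
    if fixed_center:
        pth = np.arctan2(yy - c0, xx - c0)
        pr = np.hypot(xx - c0, yy - c0)
    frames = []
    for i in range(p.n):
        r = _radial_profile(theta_grid, a[i], phases, ks, p.r0)
        if r.min() <= 0.1 * p.r0:  # post-clip safety net
            raise StarConvexityError("amplitude clipping failed")
        cx, cy = centers[i]
        if not fixed_center:
            pth = np.arctan2(yy - cy, xx - cx)
            pr = np.hypot(xx - cx, yy - cy)
        rmax = r.max()
        if cx - rmax < -0.5 or cx + rmax > p.grid - 0.5 \
                or cy - rmax < -0.5 or cy + rmax > p.grid - 0.5:
            raise GridError(f"frame {i}: shape extends outside the grid")
        rb = np.interp(pth, theta_grid, r, period=2.0 * math.pi)
        g = _cleanup(pr <= rb)
        frames.append(BinaryMask(g, frame_index=i, timestamp=i * p.dt))
    return SyntheticRecording(frames=frames if keep_frames else [],
                              params=p, amplitudes=a, mode_numbers=ks,
                              phases=phases, burst=burst, centers=centers,
                              clipped=clipped, t_switch=p.t_switch)


def simulate_transition(params: SyntheticParams) -> SyntheticRecording:
    """Idling -> treadmilling switch recording (see
    :meth:`SyntheticParams.transition`)."""
    if params.t_switch is None or not (0 < params.t_switch < params.n):
        raise ValueError("transition requires 0 < t_switch < n")
    if params.state != "transition":
        raise ValueError("params.state must be 'transition'")
    return simulate_state(params)


def simulate_roundness(params: SyntheticParams, method: str = "count"):
    """Simulate and immediately reduce each frame to its roundness R.

    Memory-light path used by the pipeline and the test ensembles: frames
    are rasterized one at a time and only R(t), centroid tracks and Feret
    diameters are retained.

    Returns (RSeries, info) where info carries ``displacement_ratio``,
    ``translocating`` flag, ``clipped`` count and the ground truth arrays.
    """
    rec = simulate_state(params, keep_frames=True)
    values = np.empty(params.n)
    cents = np.empty((params.n, 2))
    max_feret = 0.0
    for i, m in enumerate(rec.frames):
        values[i] = mask_metrics(m, method=method).R
        cents[i] = centroid(m)
        max_feret = max(max_feret, feret_diameter(m))
    rec.frames = []  # release ~60 MB of masks
    disp = np.sqrt(((cents - cents[0]) ** 2).sum(1)).max()
    ratio = float(disp / max_feret)
    series = RSeries(values, dt=params.dt,
                     cell_id=f"{params.state}-{params.seed}",
                     state_label=params.state)
    info = {
        "displacement_ratio": ratio,
        "translocating": ratio >= TRANSLOCATION_THRESHOLD,
        "clipped": rec.clipped,
        "t_switch": rec.t_switch,
        "recording": rec,
    }
    return series, info
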