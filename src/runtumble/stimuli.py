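"""Stimulus families for training and probing stimulus-response surrogates.

Four families are provided, mirroring the signals used in microbial
stimulus-response experiments:

* PWC  -- piecewise constant ("step") signals; s' = 0 almost everywhere.
* PWCL -- piecewise constant segments joined by linear ramps; s'' = 0 almost
  everywhere, slopes K*_k = (c_{2k+1} - c_{2k-1}) / (T_{2k+1} - T_{2k}).
* LCC  -- linear combination of raised cosines,
  s(t) = (1/P) sum_p a_p (1 - cos(2 pi t / b_p)).
* ELCC -- exponential of a raised-cosine combination,
  s(t) = exp(sum_q a_q (1 - cos(2 pi t / b_q)) - c_q), with the offset chosen
  so that max s equals the configured upper bound.

Each generated trace carries analytic first and second derivatives plus the
locations of jumps (discontinuities of s) and kinks (discontinuities of s').
Traces can be compressed in time, s(t) -> s(t T / T1), which scales every
gradient by T / T1; this is the knob used to probe the gradient threshold of
quasi-steady-state reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusConfig",
    "SignalTrace",
    "gen_stimulus",
    "compress",
    "smax_prime",
]

_KINDS = ("PWC", "PWCL", "LCC", "ELCC")



@dataclass(frozen=True)
class StimulusConfig:
    """Configuration of one stimulus family draw.

    ``value_range`` bounds the signal (exactly for PWC/PWCL, by construction
    for LCC/ELCC), ``k_t`` is the number of constant intervals (PWC) or
    constant/ramp pairs (PWCL), ``n_terms`` the number of cosine terms
    (LCC/ELCC).  Amplitudes ``a`` and periods ``b`` are drawn uniformly from
    ``amp_range`` and ``period_range`` (seconds).
    """

    kind: str = "LCC"
    t_min: float = 0.0
    t_max: float = 200.0
    n_points: int = 2001
    value_range: tuple[float, float] = (0.0, 2.0)
    k_t: int = 10
    n_terms: int = 3
    amp_range: tuple[float, float] = (0.25, 1.0)
    period_range: tuple[float, float] = (20.0, 100.0)
    slope_max: float = 0.3
    min_seg_points: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; expected one of {_KINDS}")
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if not self.value_range[0] < self.value_range[1]:
            raise ValueError("value_range must be increasing")
        if self.kind in ("LCC", "ELCC") and (
            self.period_range[0] <= 0.0 or self.period_range[1] <= 0.0
        ):
            raise ValueError("period_range must be positive")


@dataclass
class SignalTrace:
    """A stimulus sampled on a uniform grid with analytic derivative values."""

    t: np.ndarray
    s: np.ndarray
    s_prime: np.ndarray
    s_doubleprime: np.ndarray
    jump_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    kink_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    units: str = "uM"
    # Closed-form evaluator (value, d1, d2, jumps, kinks); present for generated
    # traces, absent for traces read from files.
    func: "_StimulusFunction | None" = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __post_init__(self) -> None:
        dts = np.diff(self.t)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform")


class _StimulusFunction:
    """Closed-form stimulus: value and derivatives at arbitrary times."""

    jump_times: np.ndarray
    kink_times: np.ndarray

    def value(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def d1(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def d2(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _PWC(_StimulusFunction):
    def __init__(self, breaks: np.ndarray, values: np.ndarray):
        self.breaks = np.asarray(breaks, float)  # length K+1
        self.values = np.asarray(values, float)  # length K
        self.jump_times = self.breaks[1:-1][np.diff(self.values) != 0.0]
        self.kink_times = self.jump_times.copy()

    def value(self, t):
        idx = np.clip(np.searchsorted(self.breaks, t, side="right") - 1, 0, len(self.values) - 1)
        return self.values[idx]

    def d1(self, t):
        return np.zeros_like(np.asarray(t, float))

    def d2(self, t):
        return np.zeros_like(np.asarray(t, float))


class _PWCL(_StimulusFunction):
    """Alternating constants and linear ramps; continuous, kinked s'."""

    def __init__(self, breaks: np.ndarray, consts: np.ndarray):
        # breaks: T_1 < ... < T_{2K+1}; consts: c_1, c_3, ..., c_{2K+1} (K+1 values)
        self.breaks = np.asarray(breaks, float)
        self.consts = np.asarray(consts, float)
        self.k = (len(self.breaks) - 1) // 2
        self.slopes = (self.consts[1:] - self.consts[:-1]) / (
            self.breaks[2::2] - self.breaks[1:-1:2]
        )
        self.jump_times = np.empty(0)
        self.kink_times = self.breaks[1:-1].copy()

    def _interval(self, t):
        return np.clip(np.searchsorted(self.breaks, t, side="right") - 1, 0, 2 * self.k - 1)

    def value(self, t):
        t = np.asarray(t, float)
        idx = self._interval(t)
        pair = idx // 2  # which constant/ramp pair
        on_ramp = idx % 2 == 1
        out = self.consts[pair]
        ramp_start = self.breaks[1:-1:2]
        out = np.where(
            on_ramp, self.consts[pair] + self.slopes[np.minimum(pair, self.k - 1)] * (t - ramp_start[np.minimum(pair, self.k - 1)]), out
        )
        return out

    def d1(self, t):
        t = np.asarray(t, float)
        idx = self._interval(t)
        pair = np.minimum(idx // 2, self.k - 1)
        return np.where(idx % 2 == 1, self.slopes[pair], 0.0)

    def d2(self, t):
        return np.zeros_like(np.asarray(t, float))


class _LCC(_StimulusFunction):
    def __init__(self, a: np.ndarray, b: np.ndarray):
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)
        self.jump_times = np.empty(0)
        self.kink_times = np.empty(0)

    def value(self, t):
        t = np.asarray(t, float)[..., None]
        return np.mean(self.a * (1.0 - np.cos(2.0 * np.pi * t / self.b)), axis=-1)

    def d1(self, t):
        t = np.asarray(t, float)[..., None]
        w = 2.0 * np.pi / self.b
        return np.mean(self.a * w * np.sin(w * t), axis=-1)

    def d2(self, t):
        t = np.asarray(t, float)[..., None]
        w = 2.0 * np.pi / self.b
        return np.mean(self.a * w**2 * np.cos(w * t), axis=-1)


class _ELCC(_StimulusFunction):
    def __init__(self, a: np.ndarray, b: np.ndarray, c: float):
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)
        self.c = float(c)
        self.jump_times = np.empty(0)
        self.kink_times = np.empty(0)

    def _exponent(self, t):
        t = np.asarray(t, float)[..., None]
        return np.sum(self.a * (1.0 - np.cos(2.0 * np.pi * t / self.b)), axis=-1) - self.c

    def _e1(self, t):
        t = np.asarray(t, float)[..., None]
        w = 2.0 * np.pi / self.b
        return np.sum(self.a * w * np.sin(w * t), axis=-1)

    def _e2(self, t):
        t = np.asarray(t, float)[..., None]
        w = 2.0 * np.pi / self.b
        return np.sum(self.a * w**2 * np.cos(w * t), axis=-1)

    def value(self, t):
        return np.exp(self._exponent(t))

    def d1(self, t):
        return self.value(t) * self._e1(t)

    def d2(self, t):
        return self.value(t) * (self._e2(t) + self._e1(t) ** 2)


class _Scaled(_StimulusFunction):
    """base(t) multiplied by a constant factor (value-range rescaling)."""

    def __init__(self, base: _StimulusFunction, factor: float):
        self.base = base
        self.factor = float(factor)
        self.jump_times = base.jump_times
        self.kink_times = base.kink_times

    def value(self, t):
        return self.factor * self.base.value(t)

    def d1(self, t):
        return self.factor * self.base.d1(t)

    def d2(self, t):
        return self.factor * self.base.d2(t)


def rescale(trace: SignalTrace, factor: float) -> SignalTrace:
    """Multiply a trace (and its derivatives) by a constant positive factor."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    func = _Scaled(trace.func, factor) if trace.func is not None else None
    return SignalTrace(
        t=trace.t.copy(), s=factor * trace.s,
        s_prime=factor * trace.s_prime, s_doubleprime=factor * trace.s_doubleprime,
        jump_times=trace.jump_times.copy(), kink_times=trace.kink_times.copy(),
        units=trace.units, func=func,
    )


class _Compressed(_StimulusFunction):
    """base(t) compressed onto [t0, t0 + T1]: s_c(t) = base(t0 + (t - t0) r)."""

    def __init__(self, base: _StimulusFunction, t0: float, ratio: float):
        self.base = base
        self.t0 = float(t0)
        self.r = float(ratio)  # T / T1 >= 1 compresses
        self.jump_times = t0 + (base.jump_times - t0) / self.r
        self.kink_times = t0 + (base.kink_times - t0) / self.r

    def _map(self, t):
        return self.t0 + (np.asarray(t, float) - self.t0) * self.r

    def value(self, t):
        return self.base.value(self._map(t))

    def d1(self, t):
        return self.r * self.base.d1(self._map(t))

    def d2(self, t):
        return self.r**2 * self.base.d2(self._map(t))


def _draw_breakpoints(rng: np.random.Generator, t_min: float, t_max: float,
                      n_interior: int, min_gap: float, dt: float) -> np.ndarray:
    """Interior breakpoints, uniform then sorted, with a minimum spacing.

    Breakpoints are snapped to the sampling grid: delivered stimuli switch on
    the recording clock, and grid-aligned jumps keep simulated references and
    grid-based rollouts seeing the change at the same instant.
    """
    if n_interior <= 0:
        return np.array([t_min, t_max])

    def snap(pts):
        return t_min + np.round((pts - t_min) / dt) * dt

    for _ in range(1000):
        pts = snap(np.sort(rng.uniform(t_min, t_max, size=n_interior)))
        full = np.concatenate([[t_min], pts, [t_max]])
        if np.min(np.diff(full)) >= min_gap:
            return full
    # Fall back to jittered equal spacing if rejection keeps failing.
    base = np.linspace(t_min, t_max, n_interior + 2)
    jitter = rng.uniform(-0.25, 0.25, size=n_interior) * (t_max - t_min) / (n_interior + 1)
    full = base.copy()
    full[1:-1] = snap(full[1:-1] + jitter)
    return full


def _build_function(config: StimulusConfig, rng: np.random.Generator) -> _StimulusFunction:
    s_min, s_max = config.value_range
    dt = (config.t_max - config.t_min) / (config.n_points - 1)
    min_gap = config.min_seg_points * dt
    if config.kind == "PWC":
        breaks = _draw_breakpoints(rng, config.t_min, config.t_max, config.k_t - 1, min_gap, dt)
        values = rng.uniform(s_min, s_max, size=config.k_t)
        return _PWC(breaks, values)
    if config.kind == "PWCL":
        breaks = _draw_breakpoints(rng, config.t_min, config.t_max, 2 * config.k_t - 1, min_gap, dt)
        # Constants drawn sequentially so every ramp slope K*_k stays within
        # +-slope_max: test and training gradient ranges must be comparable
        # for the identification protocol to be meaningful.
        consts = np.empty(config.k_t + 1)
        consts[0] = rng.uniform(s_min, s_max)
        ramp_dur = breaks[2::2] - breaks[1:-1:2]
        for k in range(config.k_t):
            reach = config.slope_max * ramp_dur[k]
            lo = max(s_min, consts[k] - reach)
            hi = min(s_max, consts[k] + reach)
            consts[k + 1] = rng.uniform(lo, hi)
        return _PWCL(breaks, consts)
    a = rng.uniform(*config.amp_range, size=config.n_terms)
    b = rng.uniform(*config.period_range, size=config.n_terms)
    if config.kind == "LCC":
        return _LCC(a, b)
    # ELCC: solve the additive offset c so that max_t s(t) == s_max on the grid.
    t = np.linspace(config.t_min, config.t_max, config.n_points)
    raw = _ELCC(a, b, 0.0)
    c = float(np.max(raw._exponent(t))) - np.log(s_max)
    return _ELCC(a, b, c)


def gen_stimulus(config: StimulusConfig, rng_seed: int | None = None) -> SignalTrace:
    """Draw one stimulus trace from the configured family.

    ``rng_seed`` overrides ``config.seed``; each trace uses its own seeded
    generator so datasets are reproducible stream by stream.
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    func = _build_function(config, rng)
    t = np.linspace(config.t_min, config.t_max, config.n_points)
    trace = SignalTrace(
        t=t,
        s=func.value(t),
        s_prime=func.d1(t),
        s_doubleprime=func.d2(t),
        jump_times=func.jump_times.copy(),
        kink_times=func.kink_times.copy(),
        func=func,
    )
    lo, hi = config.value_range
    span = hi - lo
    if trace.s.min() < lo - 1e-9 * span or trace.s.max() > hi + 1e-9 * span:
        raise AssertionError("generated stimulus escaped its configured value range")
    return trace


def compress(trace: SignalTrace, T1: float) -> SignalTrace:
    """Compress a trace in time: s_c(t) = s(t * T / T1) on [t_min, t_min + T1].

    Every gradient magnitude scales by T / T1 and discontinuity times by
    T1 / T.  Requires a trace with a closed-form evaluator (i.e. generated by
    :func:`gen_stimulus`), so derivatives stay analytic.
    """
    if T1 <= 0:
        raise ValueError("T1 must be positive")
    T = trace.duration
    if T1 > T:
        raise ValueError("T1 must not exceed the original duration")
    if trace.func is None:
        raise ValueError("compress requires a trace with an analytic generator")
    t0 = float(trace.t[0])
    ratio = T / T1
    func = _Compressed(trace.func, t0, ratio)
    n1 = int(round((len(trace.t) - 1) * T1 / T)) + 1
    t = t0 + np.arange(n1) * trace.dt
    return SignalTrace(
        t=t,
        s=func.value(t),
        s_prime=func.d1(t),
        s_doubleprime=func.d2(t),
        jump_times=func.jump_times.copy(),
        kink_times=func.kink_times.copy(),
        units=trace.units,
        func=func,
    )


def smax_prime(trace: SignalTrace, exclusion_window: int = 1) -> float:
    """max_t |s'(t)| over grid points away from jump discontinuities."""
    if len(trace.t) == 0:
        raise ValueError("empty trace")
    valid = np.ones(len(trace.t), dtype=bool)
    if len(trace.jump_times):
        dist = np.min(np.abs(trace.t[:, None] - trace.jump_times[None, :]), axis=1)
        valid &= dist > exclusion_window * trace.dt
    if not valid.any():
        raise ValueError("no valid points left after masking jumps")
    return float(np.max(np.abs(trace.s_prime[valid])))
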