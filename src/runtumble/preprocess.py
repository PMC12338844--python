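"""Noise injection, spline smoothing, derivative stencils, dataset assembly.

Measured tumbling fractions carry Gaussian noise set by a signal-to-noise
ratio in dB: sigma_eps = sqrt(P_signal / 10^(SNR/10)) with
P_signal = mean(f_i^2).  Noisy responses are smoothed by a penalized cubic
spline minimizing

    p * sum_i |y_i - f~(t_i)|^2 + (1 - p) * int |f~''(t)|^2 dt,

applied independently per segment of constant stimulation when the stimulus
has jumps.  Derivatives use fixed stencils on the uniform grid:

    f'_i = (f_i - f_{i-1}) / dt            (backward)
    s'_i = (s_{i+1} - s_{i-1}) / (2 dt)    (central)
    f''_i, s''_i = second central differences,

and points near discontinuities of s (and, for second-order training, of s')
are masked out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "TimeSeriesRecord",
    "TrainingDataset",
    "add_noise",
    "smooth_spline",
    "finite_diffs",
    "mask_discontinuities",
    "build_dataset",
]


@dataclass
class TimeSeriesRecord:
    """One paired (t, s, f) trajectory with derived quantities.

    ``f`` is the noiseless response where known; ``y`` the noisy observation;
    ``f_smooth`` the smoothed reference used for training and evaluation.
    Derivative fields hold stencil (or analytic, for s) estimates; the
    ``valid_mask`` marks indices safe for training/evaluation.
    """

    t: np.ndarray
    s: np.ndarray
    f: np.ndarray | None = None
    y: np.ndarray | None = None
    f_smooth: np.ndarray | None = None
    f_prime: np.ndarray | None = None
    f_doubleprime: np.ndarray | None = None
    s_prime: np.ndarray | None = None
    s_doubleprime: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    jump_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    kink_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    units: str = "uM"
    provenance: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def f_ref(self) -> np.ndarray:
        """Reference response: smoothed if available, else the clean signal."""
        if self.f_smooth is not None:
            return self.f_smooth
        if self.f is None:
            raise ValueError("record has neither f_smooth nor f")
        return self.f

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("s", "f", "y", "f_smooth", "f_prime", "f_doubleprime",
                     "s_prime", "s_doubleprime", "valid_mask"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"field {name} has length {len(v)} != {n}")
        dts = np.diff(self.t)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6, atol=0.0):
            raise ValueError("time grid must be uniform")


def add_noise(record: TimeSeriesRecord, snr_db: float, rng_seed: int | None = None) -> TimeSeriesRecord:
    """Return a copy with y = f + eps, eps ~ N(0, sigma_eps^2) set by the SNR (dB)."""
    if record.f is None or len(record.f) == 0:
        raise ValueError("record has no clean response to perturb")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    p_signal = float(np.mean(record.f**2))
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(rng_seed)
    out = replace(record, y=record.f + rng.normal(0.0, sigma, size=len(record.f)))
    out.provenance = dict(record.provenance, snr_db=float(snr_db), sigma_eps=float(sigma))
    return out


def _segments(t: np.ndarray, breakpoints: np.ndarray | None) -> list[slice]:
    if breakpoints is None or len(breakpoints) == 0:
        return [slice(0, len(t))]
    edges = [0]
    for b in np.sort(np.asarray(breakpoints, float)):
        i = int(np.searchsorted(t, b))
        if 0 < i < len(t):
            edges.append(i)
    edges.append(len(t))
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def smooth_spline(
    t: np.ndarray,
    y: np.ndarray,
    p: float | None = None,
    breakpoints: np.ndarray | None = None,
) -> np.ndarray:
    """Penalized cubic smoothing spline evaluated on the input grid.

    ``p`` in [0, 1] weights fidelity against curvature (p = 1 interpolates,
    p -> 0 tends to the least-squares line); ``p = None`` selects the penalty
    by generalized cross-validation.  When ``breakpoints`` are given the fit
    is done independently per segment, so smoothing never bridges a jump.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    if p is not None and not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    out = np.empty_like(y)
    for seg in _segments(t, breakpoints):
        ts, ys = t[seg], y[seg]
        if len(ts) < 4:
            raise ValueError("each smoothing segment needs at least 4 points")
        if p is not None and p >= 1.0:
            out[seg] = ys
            continue
        lam = None if p is None else (1.0 - p) / p if p > 0 else None
        if p is not None and p == 0.0:
            # curvature term dominates: least-squares straight line
            coef = np.polyfit(ts, ys, 1)
            out[seg] = np.polyval(coef, ts)
            continue
        spl = make_smoothing_spline(ts, ys, lam=lam)
        out[seg] = spl(ts)
    return out


def finite_diffs(record: TimeSeriesRecord, prefer_analytic_s: bool = True) -> TimeSeriesRecord:
    """Fill derivative fields with the fixed stencils on the uniform grid.

    The response derivatives are always stencil estimates of the reference
    (smoothed when available) sequence; the stimulus derivatives keep analytic
    values already stored on the record (from the generator) unless
    ``prefer_analytic_s`` is False or they are absent.
    """
    n = len(record.t)
    if n < 3:
        raise ValueError("need at least 3 points for the stencils")
    dt = record.dt
    f = record.f_ref
    fp = np.full(n, np.nan)
    fp[1:] = (f[1:] - f[:-1]) / dt
    fpp = np.full(n, np.nan)
    fpp[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / dt**2

    out = replace(record, f_prime=fp, f_doubleprime=fpp)
    if not (prefer_analytic_s and record.s_prime is not None):
        sp = np.full(n, np.nan)
        sp[1:-1] = (record.s[2:] - record.s[:-2]) / (2.0 * dt)
        out.s_prime = sp
    if not (prefer_analytic_s and record.s_doubleprime is not None):
        spp = np.full(n, np.nan)
        spp[1:-1] = (record.s[2:] - 2.0 * record.s[1:-1] + record.s[:-2]) / dt**2
        out.s_doubleprime = spp
    return out


def mask_discontinuities(
    record: TimeSeriesRecord,
    window: int = 2,
    mode: str = "SIVM",
) -> np.ndarray:
    """Validity mask excluding stencil-incomplete endpoints and discontinuities.

    Indices within ``window`` grid steps of a jump of s are invalid in both
    modes; in DIVM mode indices near a kink of s' are additionally invalid,
    since s'' is unbounded there.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("SIVM", "DIVM"):
        raise ValueError("mode must be 'SIVM' or 'DIVM'")
    n = len(record.t)
    mask = np.ones(n, dtype=bool)
    mask[0] = mask[-1] = False  # stencil neighbors missing
    dt = record.dt
    times = [record.jump_times]
    if mode == "DIVM":
        times.append(record.kink_times)
    for arr in times:
        for tb in np.asarray(arr, float):
            mask[np.abs(record.t - tb) <= window * dt + 1e-12] = False
    record.valid_mask = mask
    return mask


@dataclass
class TrainingDataset:
    """Series-level split container feeding the SIVM/DIVM losses.

    Each entry of ``series`` is a fully preprocessed :class:`TimeSeriesRecord`
    (smoothed, differentiated, masked); ``splits`` assigns each series to
    'train', 'val' or 'test'.  Tuple extraction pools only mask-valid indices.
    """

    series: list[TimeSeriesRecord]
    splits: list[str]

    def records(self, split: str) -> list[TimeSeriesRecord]:
        return [r for r, lab in zip(self.series, self.splits) if lab == split]

    def _pool(self, split: str, columns) -> np.ndarray:
        rows = []
        for rec in self.records(split):
            if rec.valid_mask is None:
                raise ValueError("records must be masked before tuple extraction")
            m = rec.valid_mask & np.all(
                np.isfinite(np.stack([c(rec) for c in columns])), axis=0
            )
            rows.append(np.stack([c(rec)[m] for c in columns], axis=1))
        if not rows:
            raise ValueError(f"no series in split {split!r}")
        return np.concatenate(rows, axis=0)

    def tuples_sivm(self, split: str = "train"):
        """Arrays (X=(f,s), s', target f') over valid indices of the split."""
        pooled = self._pool(split, [
            lambda r: r.f_ref, lambda r: r.s,
            lambda r: r.s_prime, lambda r: r.f_prime,
        ])
        return pooled[:, :2], pooled[:, 2], pooled[:, 3]

    def tuples_divm(self, split: str = "train"):
        """Arrays (X=(f,s,f',s'), s'', target f'') over valid indices."""
        pooled = self._pool(split, [
            lambda r: r.f_ref, lambda r: r.s,
            lambda r: r.f_prime, lambda r: r.s_prime,
            lambda r: r.s_doubleprime, lambda r: r.f_doubleprime,
        ])
        return pooled[:, :4], pooled[:, 4], pooled[:, 5]

    @classmethod
    def from_splits(cls, train, val, test) -> "TrainingDataset":
        series = list(train) + list(val) + list(test)
        splits = ["train"] * len(train) + ["val"] * len(val) + ["test"] * len(test)
        return cls(series=series, splits=splits)


def build_dataset(
    records: list[TimeSeriesRecord],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    rng_seed: int = 0,
) -> TrainingDataset:
    """Shuffled series-level train/val/test split (default 70/15/15)."""
    if len(records) < 3:
        raise ValueError("need at least 3 series to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(records))
    n_train = int(round(fractions[0] * len(records)))
    n_val = int(round(fractions[1] * len(records)))
    n_test = len(records) - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("a split would receive zero series; adjust fractions")
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    splits = [""] * len(records)
    for idx, lab in zip(order, labels):
        splits[idx] = lab
    return TrainingDataset(series=list(records), splits=splits)
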