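"""Iterative prediction from trained surrogates and rollout error metrics.

Given only the stimulus trace (s, s', s'') and the reference response at the
first one (SIVM) or two (DIVM) grid points, the surrogate is integrated
forward:

    SIVM:  f^_{i+1} = f^_i + dt (G1(f^_i, s_i) + G2(f^_i, s_i) s'_i)
    DIVM:  f^_{i+1} = 2 f^_i - f^_{i-1}
                      + dt^2 (G3(f^_i, s_i, f^'_i, s'_i) + G4(...) s''_i),
           f^'_i = (f^_i - f^_{i-1}) / dt,

never touching the reference beyond initialization.  Accuracy is scored by
the mean squared error E_vali and the relative mean squared error E_test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PredictionResult", "ErrorReport", "predict", "predict_batch", "e_vali", "e_test", "evaluate"]

_DENOM_FLOOR = 1e-6


@dataclass
class PredictionResult:
    t: np.ndarray
    f_hat: np.ndarray
    f_ref: np.ndarray | None = None
    truncated_at: int | None = None  # first index where prediction went non-finite


@dataclass
class ErrorReport:
    """E_vali / E_test for one evaluation run, with per-series detail."""

    e_vali: float
    e_test: float
    per_series: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def predict_batch(surrogate, S, SP, SDD, f_init, dt, clamp=False):
    """Roll out ``k`` series of common length simultaneously.

    ``S``, ``SP``, ``SDD`` have shape (k, n); ``f_init`` has shape (k,) for
    SIVM or (k, 2) for DIVM.  Returns predictions of shape (k, n).
    """
    S = np.atleast_2d(np.asarray(S, float))
    SP = np.atleast_2d(np.asarray(SP, float))
    k, n = S.shape
    fhat = np.empty((k, n))
    bound = (-1e6, 1e6)
    truncated = None
    if surrogate.kind == "SIVM":
        fhat[:, 0] = np.asarray(f_init, float).reshape(k)
        for i in range(n - 1):
            X = np.stack([fhat[:, i], S[:, i]], axis=1)
            g1, g2 = surrogate.g_pair(X)
            step = fhat[:, i] + dt * (g1 + g2 * SP[:, i])
            if not np.all(np.isfinite(step)):
                truncated = truncated if truncated is not None else i + 1
                step = np.where(np.isfinite(step), step, fhat[:, i])
            fhat[:, i + 1] = np.clip(step, *bound)
            if clamp:
                fhat[:, i + 1] = np.clip(fhat[:, i + 1], 0.0, 1.0)
    elif surrogate.kind == "DIVM":
        SDD = np.atleast_2d(np.asarray(SDD, float))
        init = np.asarray(f_init, float).reshape(k, 2)
        fhat[:, 0] = init[:, 0]
        fhat[:, 1] = init[:, 1]
        for i in range(1, n - 1):
            fp = (fhat[:, i] - fhat[:, i - 1]) / dt
            X = np.stack([fhat[:, i], S[:, i], fp, SP[:, i]], axis=1)
            g3, g4 = surrogate.g_pair(X)
            step = 2.0 * fhat[:, i] - fhat[:, i - 1] + dt**2 * (g3 + g4 * SDD[:, i])
            if not np.all(np.isfinite(step)):
                truncated = truncated if truncated is not None else i + 1
                step = np.where(np.isfinite(step), step, fhat[:, i])
            fhat[:, i + 1] = np.clip(step, *bound)
            if clamp:
                fhat[:, i + 1] = np.clip(fhat[:, i + 1], 0.0, 1.0)
    else:
        raise ValueError(f"unknown surrogate kind {surrogate.kind!r}")
    if truncated is not None:
        warnings.warn(f"non-finite rollout value first seen at step {truncated}; value held")
    return fhat, truncated


def _stencil_derivatives(s, dt, kind, t=None, jump_times=None, window=2):
    """Central-difference s' and s'' from the sampled stimulus.

    For first-order (SIVM) rollouts the finite-difference spike at a stimulus
    jump is kept: G2 depends only on (f, s), so the spike, multiplied by an
    in-range G2 evaluation and integrated by the update rule, carries the
    response discontinuity (the integral of G2 s' across the jump).  For
    second-order (DIVM) rollouts the coefficient networks take s' as an
    *input* and are untrained at spike values, so stencils inside the jump
    window are zeroed and the crossing is traversed with the smooth dynamics.
    """
    s = np.asarray(s, float)
    sp = np.zeros_like(s)
    sp[1:-1] = (s[2:] - s[:-2]) / (2.0 * dt)
    sdd = np.zeros_like(s)
    sdd[1:-1] = (s[2:] - 2.0 * s[1:-1] + s[:-2]) / dt**2
    if kind == "DIVM" and t is not None and jump_times is not None and len(jump_times):
        for tj in np.asarray(jump_times, float):
            near = np.abs(np.asarray(t, float) - tj) <= window * dt + 1e-12
            sp[near] = 0.0
            sdd[near] = 0.0
    return sp, sdd


def _record_arrays(record, kind):
    sp, sdd = _stencil_derivatives(record.s, record.dt, kind,
                                   t=record.t, jump_times=record.jump_times)
    return record.s, sp, sdd


def predict(surrogate, record, f_init=None, dt=None, clamp=False) -> PredictionResult:
    """Roll out one series; ``f_init`` defaults to the reference start values."""
    s, sp, sdd = _record_arrays(record, surrogate.kind)
    dt = record.dt if dt is None else dt
    if f_init is None:
        ref = record.f_ref
        f_init = ref[0] if surrogate.kind == "SIVM" else ref[:2]
    fhat, truncated = predict_batch(surrogate, s[None], sp[None],
                                    None if sdd is None else sdd[None],
                                    np.asarray(f_init)[None], dt, clamp=clamp)
    ref = None
    try:
        ref = record.f_ref
    except (ValueError, AttributeError):
        pass
    return PredictionResult(t=record.t, f_hat=fhat[0], f_ref=ref, truncated_at=truncated)


def e_vali(f_hat, f_ref, mask=None) -> float:
    """Mean squared rollout error (1/N) sum (f^_i - f_i)^2."""
    f_hat = np.asarray(f_hat, float)
    f_ref = np.asarray(f_ref, float)
    if f_hat.shape != f_ref.shape:
        raise ValueError("length mismatch between prediction and reference")
    if mask is not None:
        f_hat, f_ref = f_hat[mask], f_ref[mask]
    return float(np.mean((f_hat - f_ref) ** 2))


def e_test(f_hat, f_ref, mask=None) -> float:
    """Relative mean squared rollout error (1/N) sum ((f^_i - f_i) / f_i)^2."""
    f_hat = np.asarray(f_hat, float)
    f_ref = np.asarray(f_ref, float)
    if f_hat.shape != f_ref.shape:
        raise ValueError("length mismatch between prediction and reference")
    if mask is not None:
        f_hat, f_ref = f_hat[mask], f_ref[mask]
    denom = f_ref.copy()
    small = np.abs(denom) < _DENOM_FLOOR
    if small.any():
        warnings.warn(f"{small.sum()} reference values below {_DENOM_FLOOR}; denominator floored")
        denom = np.where(small, np.sign(denom) * _DENOM_FLOOR + (denom == 0) * _DENOM_FLOOR, denom)
    return float(np.mean(((f_hat - f_ref) / denom) ** 2))


def _rollout_split(surrogate, records, clamp=False):
    """Batched rollouts over records grouped by common length."""
    groups: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(len(rec.t), []).append(i)
    fhats: list[np.ndarray | None] = [None] * len(records)
    for n, idxs in groups.items():
        recs = [records[i] for i in idxs]
        S = np.stack([r.s for r in recs])
        derivs = [_stencil_derivatives(r.s, r.dt, surrogate.kind,
                                       t=r.t, jump_times=r.jump_times) for r in recs]
        SP = np.stack([d[0] for d in derivs])
        SDD = np.stack([d[1] for d in derivs])
        if surrogate.kind == "SIVM":
            f0 = np.array([r.f_ref[0] for r in recs])
        else:
            f0 = np.stack([r.f_ref[:2] for r in recs])
        out, _ = predict_batch(surrogate, S, SP, SDD, f0, recs[0].dt, clamp=clamp)
        for j, i in enumerate(idxs):
            fhats[i] = out[j]
    return fhats


def _segment_slices(record):
    """Contiguous runs of the series delimited by stimulus jumps."""
    edges = [0]
    for tj in np.sort(np.asarray(record.jump_times, float)):
        i = int(np.searchsorted(record.t, tj))
        if 0 < i < len(record.t):
            edges.append(i)
    edges.append(len(record.t))
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b - a >= 3]


def _rollout_segmented(surrogate, records, clamp=False):
    """Per-segment rollouts: each continuous run between jumps restarts from
    the reference at its first one (SIVM) or two (DIVM) points."""
    fhats = []
    for rec in records:
        fh = np.full(len(rec.t), np.nan)
        ref = rec.f_ref
        mask = rec.valid_mask if rec.valid_mask is not None else np.ones(len(rec.t), bool)
        for seg in _segment_slices(rec):
            # start at the first unmasked index: the masked post-jump
            # neighborhood is excluded from training, so the networks are
            # only trusted (and only scored) beyond it
            valid_idx = np.flatnonzero(mask[seg])
            if len(valid_idx) < 3:
                continue
            start = seg.start + valid_idx[0]
            sub = slice(start, seg.stop)
            # stencils from the segment only: no information crosses the cut
            sp, sdd = _stencil_derivatives(rec.s[sub], rec.dt, surrogate.kind)
            f0 = ref[sub][0] if surrogate.kind == "SIVM" else ref[sub][:2]
            out, _ = predict_batch(
                surrogate, rec.s[sub][None], sp[None], sdd[None],
                np.asarray(f0)[None], rec.dt, clamp=clamp)
            fh[sub] = out[0]
        fhats.append(fh)
    return fhats


def evaluate(surrogate, dataset, split: str = "test", clamp: bool = False,
             reinit_at_jumps: bool = False) -> ErrorReport:
    """Rollout every series of a split; pool pointwise errors over valid indices.

    With ``reinit_at_jumps`` each continuous stimulation segment is rolled out
    independently from reference initial values (series are cut at the jump
    discontinuities instead of being crossed).
    """
    records = dataset.records(split)
    if not records:
        raise ValueError(f"no series in split {split!r}")
    if reinit_at_jumps:
        fhats = _rollout_segmented(surrogate, records, clamp=clamp)
    else:
        fhats = _rollout_split(surrogate, records, clamp=clamp)
    sq, rel, per = [], [], []
    for rec, fh in zip(records, fhats):
        mask = rec.valid_mask if rec.valid_mask is not None else np.ones(len(rec.t), bool)
        mask = mask & np.isfinite(fh)
        ref = rec.f_ref
        sq.append((fh[mask] - ref[mask]) ** 2)
        denom = np.where(np.abs(ref[mask]) < _DENOM_FLOOR, _DENOM_FLOOR, ref[mask])
        rel.append(((fh[mask] - ref[mask]) / denom) ** 2)
        per.append({
            "kind": rec.provenance.get("stimulus_kind"),
            "e_vali": float(np.mean(sq[-1])),
            "e_test": float(np.mean(rel[-1])),
        })
    return ErrorReport(
        e_vali=float(np.mean(np.concatenate(sq))),
        e_test=float(np.mean(np.concatenate(rel))),
        per_series=per,
        metadata={"split": split, "kind": surrogate.kind},
    )
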