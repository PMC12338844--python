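"""Study designs: stimulus-combination table, compression sweep, order inference,
extrapolation.

Every experiment is a pure function of its configuration and seed: stimuli,
simulated responses, noise draws, network initialization and minibatch order
all derive from the given master seed, so reruns reproduce every number in
single-threaded mode.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from runtumble import rollout as _rollout
from runtumble.chemotaxis import EcoliParams, simulate
from runtumble.nets import NetSpec, make_surrogate, train
from runtumble.preprocess import (
    TimeSeriesRecord,
    TrainingDataset,
    add_noise,
    finite_diffs,
    mask_discontinuities,
    smooth_spline,
)
from runtumble import stimuli as _stim
from runtumble.stimuli import SignalTrace, StimulusConfig, compress, gen_stimulus, smax_prime

__all__ = [
    "SweepResult",
    "OrderInference",
    "make_series",
    "prepare_record",
    "signal_combination_study",
    "compression_sweep",
    "infer_internal_order",
    "extrapolation_study",
]

# Default experiment grid: 200.1 s at 0.1 s spacing -> 2002 samples/series, so
# ten series give the 20,020-pair budget of the combination study.
_N_POINTS = 2002
_T_MAX = 200.1
_SNR_RANGE = (20.0, 22.0)


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2^31."""
    return [int(x) for x in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _stim_config(kind: str, seed: int, **overrides) -> StimulusConfig:
    base = dict(kind=kind, t_min=0.0, t_max=_T_MAX, n_points=_N_POINTS, seed=seed)
    base.update(overrides)
    return StimulusConfig(**base)


def prepare_record(
    rec: TimeSeriesRecord,
    mode: str,
    snr_db: float | None = None,
    noise_seed: int | None = None,
    smooth_p: float | None = None,
    mask_window: int = 15,
    s_snr_db: float | None = None,
) -> TimeSeriesRecord:
    """Noise -> per-segment smoothing -> derivative stencils -> validity mask.

    ``s_snr_db`` enables the noisy-stimulus protocol: Gaussian noise of the
    given SNR is added to s, the noisy stimulus is smoothed by the same spline
    operator, and the stimulus derivatives are then estimated by the stencils
    instead of taken analytically.
    """
    if s_snr_db is not None:
        rng = np.random.default_rng(None if noise_seed is None else noise_seed + 99991)
        sigma_s = np.sqrt(np.mean(rec.s**2) / 10.0 ** (s_snr_db / 10.0))
        s_noisy = rec.s + rng.normal(0.0, sigma_s, size=len(rec.s))
        rec = dataclasses.replace(
            rec,
            s=smooth_spline(rec.t, s_noisy, p=smooth_p, breakpoints=rec.jump_times),
            s_prime=None, s_doubleprime=None,
        )
    if snr_db is not None:
        rec = add_noise(rec, snr_db, rng_seed=noise_seed)
        rec.f_smooth = smooth_spline(rec.t, rec.y, p=smooth_p, breakpoints=rec.jump_times)
    rec = finite_diffs(rec, prefer_analytic_s=False)
    mask_discontinuities(rec, window=mask_window, mode=mode)
    return rec


def make_series(
    model_id: str,
    kind: str,
    seed: int,
    mode: str = "SIVM",
    params: EcoliParams | None = None,
    snr_db: float | None = None,
    T1: float | None = None,
    stim_overrides: dict | None = None,
) -> TimeSeriesRecord:
    """One fully preprocessed synthetic series (generate, simulate, noise, smooth)."""
    trace = gen_stimulus(_stim_config(kind, seed, **(stim_overrides or {})))
    if T1 is not None:
        trace = compress(trace, T1)
    rec = simulate(model_id, trace, params)
    rec.provenance.update(stimulus_kind=kind, seed=seed, T1=T1)
    return prepare_record(rec, mode, snr_db=snr_db, noise_seed=None if snr_db is None else seed + 1)


def _build_split_dataset(
    model_id: str,
    train_kinds: list[str],
    test_kinds: list[str],
    mode: str,
    seed: int,
    n_train: int = 7,
    n_val: int = 2,
    noisy: bool = True,
    params: EcoliParams | None = None,
    T1: float | None = None,
    stim_overrides: dict | None = None,
    test_overrides: dict | None = None,
) -> TrainingDataset:
    """Train/val series cycle over ``train_kinds``; test series are one per
    ``test_kinds`` entry.  ``n_train`` counts fitting series; ``n_val`` more
    are held out for rollout validation."""
    rng = np.random.default_rng(seed)
    seeds = _sub_seeds(seed, n_train + n_val + len(test_kinds))
    recs = {"train": [], "val": [], "test": []}
    for i in range(n_train + n_val):
        kind = train_kinds[i % len(train_kinds)]
        snr = float(rng.uniform(*_SNR_RANGE)) if noisy else None
        rec = make_series(model_id, kind, seeds[i], mode, params, snr, T1, stim_overrides)
        recs["train" if i < n_train else "val"].append(rec)
    for j, kind in enumerate(test_kinds):
        snr = float(rng.uniform(*_SNR_RANGE)) if noisy else None
        rec = make_series(model_id, kind, seeds[n_train + n_val + j], mode, params, snr, T1,
                          test_overrides if test_overrides is not None else stim_overrides)
        recs["test"].append(rec)
    return TrainingDataset.from_splits(recs["train"], recs["val"], recs["test"])


def _train_and_test(model_id, train_kinds, test_kinds, algorithm, seed, spec,
                    noisy=True, params=None, T1=None, stim_overrides=None,
                    test_overrides=None, n_train=5, n_val=2, n_test=None):
    dataset = _build_split_dataset(
        model_id, list(train_kinds), list(test_kinds), algorithm, seed,
        n_train=n_train, n_val=n_val, noisy=noisy, params=params, T1=T1,
        stim_overrides=stim_overrides, test_overrides=test_overrides,
    )
    surrogate = make_surrogate(algorithm, spec, rng_seed=seed)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        surrogate = train(surrogate, dataset, spec)
    if "coefficient_untrained" in surrogate.flags:
        return surrogate, dataset, None
    # test series are cut at stimulus jumps: each continuous segment is
    # predicted from its own reference initial values
    report = _rollout.evaluate(surrogate, dataset, split="test", reinit_at_jumps=True)
    return surrogate, dataset, report


def signal_combination_study(
    model_id: str,
    combos: list[tuple[str, ...]],
    algorithms: tuple[str, ...] = ("SIVM", "DIVM"),
    seed: int = 0,
    spec: NetSpec | None = None,
    n_replicates: int = 1,
    noisy: bool = False,
) -> pd.DataFrame:
    """Train per stimulus combination at matched budgets; evaluate on a shared
    PWC + PWCL + LCC test set.  Combos that do not excite s' (SIVM) or s''
    (DIVM) yield an 'untrained' flag instead of an error.

    The design study uses noiseless data (matched information per combo);
    set ``noisy=True`` for the measurement-noise protocol."""
    spec = spec or NetSpec()
    rows = []
    test_kinds = ["PWC", "PWCL", "LCC"]
    for combo in combos:
        if not combo:
            raise ValueError("each combo must contain at least one stimulus kind")
        for algorithm in algorithms:
            errs = []
            flag = ""
            for rep, rep_seed in enumerate(_sub_seeds(seed + 13, n_replicates)):
                _, _, report = _train_and_test(
                    model_id, combo, test_kinds, algorithm, rep_seed, spec, noisy=noisy,
                )
                if report is None:
                    flag = ("G2" if algorithm == "SIVM" else "G4") + " untrained"
                    break
                errs.append(report.e_test)
            rows.append({
                "combo": "+".join(combo),
                "algorithm": algorithm,
                "model_id": model_id,
                "flag": flag,
                "e_test_pct": float(np.mean(errs)) * 100.0 if errs else np.nan,
                "e_test_pct_std": float(np.std(errs)) * 100.0 if len(errs) > 1 else np.nan,
                "n_replicates": len(errs),
            })
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Compression-sweep outcome: per-level errors and the estimated threshold."""

    table: pd.DataFrame                  # T1, smax_prime, e_test per algorithm
    threshold_estimate: float | None     # stimulus units / s; None if censored
    criterion: float
    censored: bool = False


def _interp_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First upward crossing of y(x) through ``level``, linear in (x, y)."""
    for i in range(len(x)):
        if y[i] > level:
            if i == 0:
                return float(x[0])
            x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
            if y1 == y0:
                return float(x1)
            return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))
    return None


def compression_sweep(
    model_id: str = "II",
    T1_list: tuple[float, ...] = (200.1, 180.0, 160.0, 140.0, 120.0, 100.0),
    criterion: float = 0.05,
    seed: int = 0,
    spec: NetSpec | None = None,
    algorithms: tuple[str, ...] = ("SIVM", "DIVM"),
    params: EcoliParams | None = None,
    n_train: int = 4,
    n_val: int = 2,
    n_replicates: int = 3,
    noisy: bool = True,
) -> SweepResult:
    """Progressively compress LCC training / ELCC test stimuli; correlate test
    errors with the dataset's max |s'| and locate the SIVM failure threshold.

    Matched series counts and training budgets are used at every compression
    level; per-level errors are averaged over ``n_replicates`` seeds.
    """
    if criterion <= 0:
        raise ValueError("criterion must be positive")
    if any(t2 >= t1 for t1, t2 in zip(T1_list, T1_list[1:])):
        raise ValueError("T1_list must be strictly decreasing")
    spec = spec or NetSpec()
    rep_seeds = _sub_seeds(seed + 7, n_replicates)
    rows = []
    for T1 in T1_list:
        row = {"T1": float(T1)}
        smax = 0.0
        for algorithm in algorithms:
            errs = []
            for rep_seed in rep_seeds:
                _, dataset, report = _train_and_test(
                    model_id, ["LCC"], ["ELCC"] * 3, algorithm, rep_seed, spec,
                    noisy=noisy, params=params,
                    T1=None if T1 >= _T_MAX else T1,
                    n_train=n_train, n_val=n_val,
                )
                errs.append(report.e_test if report else np.nan)
                for rec in dataset.series:
                    sp = rec.s_prime[np.isfinite(rec.s_prime)]
                    smax = max(smax, float(np.max(np.abs(sp))))
            row[f"e_test_{algorithm}"] = float(np.mean(errs))
            row[f"e_test_{algorithm}_std"] = float(np.std(errs))
        row["smax_prime"] = smax
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("smax_prime").reset_index(drop=True)
    crossing = None
    if "SIVM" in algorithms:
        crossing = _interp_crossing(
            table["smax_prime"].to_numpy(), table["e_test_SIVM"].to_numpy(), criterion
        )
    return SweepResult(
        table=table,
        threshold_estimate=crossing,
        criterion=criterion,
        censored=crossing is None,
    )


@dataclass
class OrderInference:
    sivm_error: float
    divm_error: float
    tolerance: float
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        if self.sivm_error < 0 or self.divm_error < 0:
            raise ValueError("errors must be non-negative")
        if self.sivm_error <= self.tolerance and self.divm_error <= self.tolerance:
            self.verdict = "one_internal_variable"
        elif self.divm_error <= self.tolerance:
            self.verdict = "two_internal_variables"
        else:
            self.verdict = "inconclusive"


def infer_internal_order(sivm_error: float, divm_error: float, tolerance: float = 0.10) -> OrderInference:
    """Infer how many internal variables the hidden pathway needs.

    Both surrogates accurate -> one variable suffices; only the
    second-derivative surrogate accurate -> two are required; neither -> the
    data are uninformative at this tolerance.
    """
    return OrderInference(sivm_error, divm_error, tolerance)


# Extrapolation-study stimulus range: amplitudes up to ~K_I so the receptor's
# ligand response is genuinely nonlinear and value-range extrapolation is a
# real test (for s << K_I the response is linear in s and any surrogate
# extrapolates trivially).
_EXTRAP_OVERRIDES = {"amp_range": (2.5, 10.0), "value_range": (0.0, 20.0)}


def extrapolation_study(
    model_id: str = "II",
    deviation_kind: str = "value",
    deviation_levels: tuple[float, ...] = (0.0, 0.165, 0.33, 0.49),
    seed: int = 0,
    spec: NetSpec | None = None,
    algorithms: tuple[str, ...] = ("SIVM",),
    params: EcoliParams | None = None,
) -> pd.DataFrame:
    """Test-set stimuli exceed the training range by a relative deviation R.

    ``value`` deviation rescales each test stimulus so its maximum equals
    exactly (1 + R) times the training set's realized maximum, with periods
    pre-stretched by (1 + R) so the gradient range stays fixed; ``gradient``
    deviation compresses time by (1 + R), raising gradients while keeping
    values fixed.  Noiseless data throughout.
    """
    if deviation_kind not in ("value", "gradient"):
        raise ValueError("deviation_kind must be 'value' or 'gradient'")
    if any(r < 0 for r in deviation_levels):
        raise ValueError("deviation levels must be >= 0")
    spec = spec or NetSpec()
    rows = []
    test_seeds = _sub_seeds(seed + 101, 3)
    for algorithm in algorithms:
        # One surrogate per algorithm, trained on the in-range data, then
        # confronted with progressively out-of-range test sets.
        dataset = _build_split_dataset(
            model_id, ["LCC"], [], algorithm, seed,
            n_train=4, n_val=2, noisy=False, params=params,
            stim_overrides=_EXTRAP_OVERRIDES,
        )
        train_smax = max(float(rec.s.max()) for rec in dataset.series)
        surrogate = make_surrogate(algorithm, spec, rng_seed=seed)
        surrogate = train(surrogate, dataset, spec)
        g_train = max(float(np.nanmax(np.abs(rec.s_prime))) for rec in dataset.series)
        for R in deviation_levels:
            test_recs = []
            for ts in test_seeds:
                if deviation_kind == "value":
                    # single-cosine test stimuli: the maximum (2a) and the
                    # gradient maximum (2 pi a / b) are exact, so the value
                    # range deviates by exactly R at in-range gradients
                    a = (1.0 + R) * train_smax / 2.0
                    b_min = 2.0 * np.pi * a / (0.8 * g_train)
                    over = {
                        "n_terms": 1,
                        "amp_range": (a, a),
                        "period_range": (b_min, 2.5 * b_min),
                        "value_range": (0.0, 2.0 * a * (1.0 + 1e-9)),
                    }
                    trace = gen_stimulus(_stim_config("LCC", ts, **over))
                else:
                    trace = gen_stimulus(_stim_config("LCC", ts, **_EXTRAP_OVERRIDES))
                    if R > 0:
                        trace = compress(trace, trace.duration / (1.0 + R))
                rec = simulate(model_id, trace, params)
                rec.provenance.update(stimulus_kind="LCC", seed=ts, R=R)
                test_recs.append(prepare_record(rec, algorithm))
            test_ds = TrainingDataset.from_splits([], [], test_recs)
            report = _rollout.evaluate(surrogate, test_ds, split="test")
            rows.append({
                "deviation_kind": deviation_kind,
                "R": float(R),
                "algorithm": algorithm,
                "e_test": report.e_test,
            })
    return pd.DataFrame(rows)
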