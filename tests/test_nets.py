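"""Surrogate networks, losses, and the training loop."""

import warnings

import numpy as np
import pytest

from runtumble.nets import NetSpec, divm_loss, make_surrogate, sivm_loss, train
from runtumble.preprocess import TimeSeriesRecord, TrainingDataset, finite_diffs, mask_discontinuities
from runtumble import rollout


def linear_sivm_series(seed, t_max=80.0, dt=0.1):
    """Data from the known generator f' = -f + s (so G1 = s - f, G2 = 0)."""
    from runtumble.stimuli import StimulusConfig, gen_stimulus
    n = int(round(t_max / dt)) + 1
    trace = gen_stimulus(StimulusConfig(kind="LCC", t_max=t_max, n_points=n,
                                        value_range=(0.0, 1.0), amp_range=(0.2, 0.5),
                                        period_range=(10.0, 40.0), seed=seed))
    s = trace.s + 0.5  # offset keeps f away from zero (relative-error metric)
    f = np.empty(n)
    f[0] = s[0]
    # fine-step integration so the reference is effectively exact
    sub = 20
    state = f[0]
    for i in range(n - 1):
        for j in range(sub):
            tj = trace.t[i] + j * dt / sub
            state += (dt / sub) * (-state + float(trace.func.value(tj)) + 0.5)
        f[i + 1] = state
    rec = TimeSeriesRecord(t=trace.t, s=s, f=f,
                           s_prime=trace.s_prime, s_doubleprime=trace.s_doubleprime)
    rec = finite_diffs(rec)
    mask_discontinuities(rec)
    return rec


@pytest.fixture(scope="module")
def linear_dataset():
    train_recs = [linear_sivm_series(s) for s in (0, 1, 2, 3)]
    return TrainingDataset.from_splits(train_recs, [linear_sivm_series(10)],
                                       [linear_sivm_series(20), linear_sivm_series(21)])


class TestMakeSurrogate:
    def test_input_dims(self):
        assert make_surrogate("SIVM").net_a.dims[0] == 2
        assert make_surrogate("DIVM").net_b.dims[0] == 4

    def test_glorot_bounds(self):
        surr = make_surrogate("SIVM", rng_seed=3)
        for net in (surr.net_a, surr.net_b):
            for W in net.W:
                limit = np.sqrt(6.0 / sum(W.shape))
                assert np.all(np.abs(W) <= limit)

    def test_seeded_determinism(self):
        a = make_surrogate("DIVM", rng_seed=7)
        b = make_surrogate("DIVM", rng_seed=7)
        for wa, wb in zip(a.net_a.W + a.net_b.W, b.net_a.W + b.net_b.W):
            assert np.array_equal(wa, wb)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_surrogate("TIVM")


class TestLosses:
    def test_sivm_zero_when_relation_holds(self):
        surr = make_surrogate("SIVM", rng_seed=0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(64, 2))
        sp = rng.normal(size=64)
        g1, g2 = surr.g_pair(X)
        target = g1 + g2 * sp
        assert sivm_loss(surr, X, sp, target) == pytest.approx(0.0, abs=1e-24)

    def test_single_tuple_residual_squared(self):
        surr = make_surrogate("SIVM", rng_seed=0)
        X = np.array([[0.1, 0.2]])
        g1, g2 = surr.g_pair(X)
        target = g1 + g2 * 0.5 + 0.3
        assert sivm_loss(surr, X, np.array([0.5]), target) == pytest.approx(0.09, rel=1e-9)

    def test_quadratic_scaling(self):
        surr = make_surrogate("SIVM", rng_seed=0)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(32, 2))
        sp = rng.normal(size=32)
        g1, g2 = surr.g_pair(X)
        base = g1 + g2 * sp
        l1 = sivm_loss(surr, X, sp, base + 0.1)
        l2 = sivm_loss(surr, X, sp, base + 0.3)
        assert l2 == pytest.approx(9.0 * l1, rel=1e-9)

    def test_divm_zero_when_relation_holds(self):
        surr = make_surrogate("DIVM", rng_seed=0)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(64, 4))
        sdd = rng.normal(size=64)
        g3, g4 = surr.g_pair(X)
        assert divm_loss(surr, X, sdd, g3 + g4 * sdd) == pytest.approx(0.0, abs=1e-24)

    def test_divm_independent_of_g4_when_sdd_zero(self):
        surr = make_surrogate("DIVM", rng_seed=1)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(32, 4))
        sdd = np.zeros(32)
        target = rng.normal(size=32)
        before = divm_loss(surr, X, sdd, target)
        surr.net_b.W[0] = surr.net_b.W[0] + 1.0   # perturb the coefficient net
        assert divm_loss(surr, X, sdd, target) == pytest.approx(before, rel=1e-12)

    def test_empty_batch_rejected(self):
        surr = make_surrogate("SIVM")
        with pytest.raises(ValueError):
            sivm_loss(surr, np.empty((0, 2)), np.empty(0), np.empty(0))
        surr2 = make_surrogate("DIVM")
        with pytest.raises(ValueError):
            divm_loss(surr2, np.empty((0, 4)), np.empty(0), np.empty(0))

    def test_kind_mismatch(self):
        with pytest.raises(ValueError):
            sivm_loss(make_surrogate("DIVM"), np.zeros((1, 4)), np.zeros(1), np.zeros(1))


class TestTrain:
    def test_zero_epochs_returns_initialization(self, linear_dataset):
        spec = NetSpec(max_epochs=0)
        surr = make_surrogate("SIVM", spec, rng_seed=5)
        before = [w.copy() for w in surr.net_a.W]
        out = train(surr, linear_dataset, spec)
        for wa, wb in zip(before, out.net_a.W):
            assert np.array_equal(wa, wb)

    def test_pwc_only_flags_untrained_coefficient(self):
        # constant-stimulus series: s' = 0 everywhere -> G2 cannot be trained
        t = np.linspace(0.0, 20.0, 201)
        recs = []
        for i in range(4):
            f = np.exp(-t / (i + 1.0))
            rec = TimeSeriesRecord(t=t, s=np.full_like(t, 0.5 + 0.1 * i), f=f)
            rec = finite_diffs(rec, prefer_analytic_s=False)
            mask_discontinuities(rec)
            recs.append(rec)
        ds = TrainingDataset.from_splits(recs[:2], recs[2:3], recs[3:])
        spec = NetSpec(max_epochs=1, val_check_every=1)
        surr = make_surrogate("SIVM", spec, rng_seed=0)
        with pytest.warns(UserWarning, match="cannot be effectively trained"):
            surr = train(surr, ds, spec)
        assert "coefficient_untrained" in surr.flags

    def test_training_history_deterministic(self, linear_dataset):
        spec = NetSpec(max_epochs=60, val_check_every=20, batch_size=256)
        runs = []
        for _ in range(2):
            surr = train(make_surrogate("SIVM", spec, rng_seed=11), linear_dataset, spec)
            runs.append(surr.history)
        assert runs[0] == runs[1]

    def test_function_recovery_linear_system(self, linear_dataset):
        """SIVM trained on f' = -f + s rolls out below 1% relative error."""
        spec = NetSpec(max_epochs=400, val_check_every=50, patience=10)
        surr = train(make_surrogate("SIVM", spec, rng_seed=2), linear_dataset, spec)
        report = rollout.evaluate(surr, linear_dataset, split="test")
        assert report.e_test < 0.01

    def test_loss_trend_non_increasing(self, linear_dataset):
        spec = NetSpec(max_epochs=300, val_check_every=25)
        surr = train(make_surrogate("SIVM", spec, rng_seed=4), linear_dataset, spec)
        losses = [h["train_loss"] for h in surr.history]
        assert losses[-1] < losses[0]
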