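"""Noise model, smoothing spline, derivative stencils, masking, splitting."""

import numpy as np
import pytest

from runtumble.preprocess import (
    TimeSeriesRecord,
    add_noise,
    build_dataset,
    finite_diffs,
    mask_discontinuities,
    smooth_spline,
)


def make_record(t, f, s=None, **kw):
    s = np.zeros_like(t) if s is None else s
    return TimeSeriesRecord(t=np.asarray(t, float), s=np.asarray(s, float),
                            f=np.asarray(f, float), **kw)


class TestAddNoise:
    @pytest.mark.parametrize("snr_db,sigma", [(20.0, 0.1), (10.0, 0.31622776601683794)])
    def test_sigma_formula(self, snr_db, sigma):
        t = np.linspace(0, 10, 101)
        rec = make_record(t, np.ones_like(t))  # P_signal = 1
        out = add_noise(rec, snr_db, rng_seed=0)
        assert out.provenance["sigma_eps"] == pytest.approx(sigma, rel=1e-12)

    def test_empirical_std_within_one_percent(self):
        n = 1_000_000
        t = np.arange(n) * 0.1
        rec = make_record(t, np.ones(n))
        out = add_noise(rec, 20.0, rng_seed=1)
        emp = np.std(out.y - out.f)
        assert emp == pytest.approx(0.1, rel=0.01)

    def test_empty_series_rejected(self):
        rec = TimeSeriesRecord(t=np.empty(0), s=np.empty(0), f=np.empty(0))
        with pytest.raises(ValueError):
            add_noise(rec, 20.0)


class TestSmoothSpline:
    def setup_method(self):
        self.t = np.linspace(0.0, 10.0, 101)
        rng = np.random.default_rng(3)
        self.y = np.sin(self.t) + 0.05 * rng.normal(size=len(self.t))

    def test_p_one_interpolates(self):
        out = smooth_spline(self.t, self.y, p=1.0)
        assert np.allclose(out, self.y, atol=1e-12)

    def test_p_zero_gives_least_squares_line(self):
        out = smooth_spline(self.t, self.y, p=0.0)
        coef = np.polyfit(self.t, self.y, 1)
        assert np.allclose(out, np.polyval(coef, self.t), atol=1e-8)

    def test_noiseless_cubic_recovered_as_p_to_one(self):
        # a cubic lies in the spline space, but natural boundary conditions
        # (vanishing end curvature) bias the ends for any lam > 0; the fit
        # converges to the cubic as p -> 1 and is exact at p = 1
        y = 0.2 * self.t**3 - self.t**2 + 0.5 * self.t - 1.0
        devs = [np.max(np.abs(smooth_spline(self.t, y, p=p) - y))
                for p in (0.99, 0.9999, 1 - 1e-8)]
        assert devs[1] < devs[0] / 10
        assert devs[2] < 2e-6
        assert np.allclose(smooth_spline(self.t, y, p=1.0), y, atol=1e-12)

    def test_segmented_smoothing_respects_jumps(self):
        # discontinuous signal: per-segment smoothing must not bridge the jump
        t = np.linspace(0.0, 10.0, 201)
        y = np.where(t < 5.0, 0.0, 1.0)
        out = smooth_spline(t, y, p=0.9, breakpoints=np.array([5.0]))
        assert np.max(np.abs(out - y)) < 1e-9

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            smooth_spline(self.t[:3], self.y[:3], p=0.5)

    def test_gcv_reduces_noise_on_model_data(self):
        from runtumble.chemotaxis import simulate
        from runtumble.stimuli import StimulusConfig, gen_stimulus
        trace = gen_stimulus(StimulusConfig(kind="LCC", t_max=200.0, n_points=2001, seed=5))
        rec = simulate("II", trace)
        noisy = add_noise(rec, 21.0, rng_seed=2)
        fs = smooth_spline(noisy.t, noisy.y)
        assert np.sqrt(np.mean((fs - rec.f) ** 2)) < np.sqrt(np.mean((noisy.y - rec.f) ** 2))


class TestFiniteDiffs:
    def test_stencils_exact_on_polynomials(self):
        t = np.linspace(0.0, 5.0, 51)
        dt = t[1] - t[0]
        f_lin = 2.0 * t - 1.0                     # backward difference exact
        s_quad = t**2 + t                         # central first difference exact
        rec = make_record(t, f_lin, s=s_quad)
        rec = finite_diffs(rec, prefer_analytic_s=False)
        assert np.allclose(rec.f_prime[1:], 2.0, atol=1e-10)
        assert np.allclose(rec.s_prime[1:-1], 2.0 * t[1:-1] + 1.0, atol=1e-9)
        s_cub = t**3                              # second central difference exact
        rec2 = make_record(t, t, s=s_cub)
        rec2 = finite_diffs(rec2, prefer_analytic_s=False)
        assert np.allclose(rec2.s_doubleprime[1:-1], 6.0 * t[1:-1], atol=2e-8)

    def test_printed_examples(self):
        rec = make_record([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], s=[0.0, 1.0, 4.0])
        rec = finite_diffs(rec, prefer_analytic_s=False)
        assert rec.f_prime[1] == pytest.approx(1.0)
        assert rec.s_prime[1] == pytest.approx(2.0)
        rec2 = make_record([0.0, 1.0, 2.0], [1.0, 0.0, 1.0])
        rec2 = finite_diffs(rec2, prefer_analytic_s=False)
        assert rec2.f_doubleprime[1] == pytest.approx(2.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            finite_diffs(make_record([0.0, 1.0], [0.0, 1.0]))


class TestMasking:
    def test_jump_window(self):
        t = np.arange(0.0, 100.0, 0.1)
        rec = make_record(t, np.zeros_like(t), jump_times=np.array([50.0]))
        mask = mask_discontinuities(rec, window=2, mode="SIVM")
        inside = np.abs(t - 50.0) <= 0.2 + 1e-12
        assert not mask[inside].any()
        assert mask[1:-1][~inside[1:-1]].all()

    def test_kinks_only_masked_in_divm_mode(self):
        t = np.arange(0.0, 10.0, 0.1)
        rec = make_record(t, np.zeros_like(t), kink_times=np.array([5.0]))
        sivm = mask_discontinuities(rec, window=2, mode="SIVM")
        assert sivm[50]
        divm = mask_discontinuities(rec, window=2, mode="DIVM")
        assert not divm[50]

    def test_smooth_trace_loses_only_endpoints(self):
        t = np.arange(0.0, 10.0, 0.1)
        rec = make_record(t, np.zeros_like(t))
        mask = mask_discontinuities(rec, window=2, mode="DIVM")
        assert mask.sum() == len(t) - 2

    def test_removal_budget_per_discontinuity(self):
        t = np.arange(0.0, 100.0, 0.1)
        for w in (1, 2, 5):
            rec = make_record(t, np.zeros_like(t), jump_times=np.array([30.0, 60.0]))
            mask = mask_discontinuities(rec, window=w, mode="SIVM")
            removed = (~mask).sum() - 2  # endpoints excluded separately
            assert removed <= 2 * (2 * w + 2)


class TestBuildDataset:
    def _records(self, n):
        t = np.linspace(0.0, 5.0, 51)
        out = []
        for i in range(n):
            rec = make_record(t, np.full(51, float(i)), s=t)
            rec = finite_diffs(rec, prefer_analytic_s=False)
            mask_discontinuities(rec)
            out.append(rec)
        return out

    def test_split_sizes(self):
        ds = build_dataset(self._records(20), fractions=(0.70, 0.15, 0.15), rng_seed=0)
        from collections import Counter
        counts = Counter(ds.splits)
        assert counts == {"train": 14, "val": 3, "test": 3}

    def test_same_seed_same_split(self):
        recs = self._records(10)
        a = build_dataset(recs, rng_seed=5).splits
        b = build_dataset(recs, rng_seed=5).splits
        assert a == b

    def test_tuples_only_from_valid_indices(self):
        ds = build_dataset(self._records(10), rng_seed=1)
        X, c, y = ds.tuples_sivm("train")
        assert np.isfinite(X).all() and np.isfinite(c).all() and np.isfinite(y).all()

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            build_dataset(self._records(3), fractions=(0.9, 0.05, 0.05), rng_seed=0)
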