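"""Ring-width processing: RWL I/O, BAI, detrending, prewhitening,
chronologies, statistics, crossdating QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from larix import rings


def _series(vals, start=1900, name="s1"):
    return pd.Series(np.asarray(vals, float),
                     index=pd.Index(range(start, start + len(vals)), name="year"),
                     name=name)


class TestRwlIO:
    def test_roundtrip_both_dialects(self, tmp_path, ring_ensemble):
        series, _ = ring_ensemble
        for precision in ("0.001", "0.01"):
            path = tmp_path / f"rw_{precision}.rwl"
            if precision == "0.01":
                # 0.01-mm dialect quantizes to 10 um; use multiples of 10
                data = {k: (np.round(v / 10) * 10) for k, v in series.items()}
            else:
                data = series
            rings.write_rwl(path, data, precision=precision)
            back = rings.read_rwl(path)
            assert set(back) == set(data)
            for k in data:
                pd.testing.assert_series_equal(back[k], data[k].astype(float),
                                               check_freq=False)

    def test_partial_decade_rows(self, tmp_path):
        s = _series([1000, 1100, 1200], start=1998)
        rings.write_rwl(tmp_path / "p.rwl", {"x": s})
        back = rings.read_rwl(tmp_path / "p.rwl")
        pd.testing.assert_series_equal(back["x"], s.rename("x"))


class TestCoreAveraging:
    def test_mean_of_two_cores(self):
        a, b = _series([1000, 1000]), _series([1200, 1200])
        out = rings.average_cores_to_tree([a, b])
        assert (out == 1100).all()

    def test_missing_year_uses_other_core(self):
        a = _series([1000, np.nan, 1000])
        b = _series([1200, 1300, 1200])
        out = rings.average_cores_to_tree([a, b])
        assert out.loc[1901] == 1300

    def test_identical_cores_identity(self):
        a = _series([900, 950, 1000])
        out = rings.average_cores_to_tree([a, a.copy()])
        assert (out == a).all()

    def test_zero_overlap_rejected(self):
        a = _series([1000] * 5, start=1900)
        b = _series([1000] * 5, start=1950)
        with pytest.raises(ValueError):
            rings.average_cores_to_tree([a, b])


class TestBai:
    def test_unit_widths_closed_form(self):
        bai = rings.compute_bai(_series([1000.0] * 5))  # 1 mm rings
        expect = np.pi * np.array([1, 3, 5, 7, 9], float)
        assert np.allclose(bai, expect)

    def test_single_ring(self):
        assert rings.compute_bai(_series([2000.0])).iloc[0] == \
            pytest.approx(np.pi * 4.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_telescoping_conservation(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(100, 4000, 60)
        bai = rings.compute_bai(_series(w))
        rn = w.sum() / 1000.0
        assert bai.sum() == pytest.approx(np.pi * rn**2, rel=1e-9)


class TestDetrend:
    def test_exact_negative_exponential_gives_unit_index(self):
        t = np.arange(100)
        w = _series(2000 * np.exp(-0.02 * t) + 500)
        rwi, info = rings.detrend_series(w)
        assert info["stage1"] == "negexp"
        assert np.allclose(rwi, 1.0, atol=1e-6)

    def test_constant_series_gives_unit_index(self):
        rwi, _ = rings.detrend_series(_series([1500.0] * 60))
        assert np.allclose(rwi, 1.0, atol=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            rings.detrend_series(_series([1000.0] * 10))

    def test_noise_times_trend_mean_near_one(self):
        devs, slopes = [], []
        t = np.arange(100)
        for s in range(100):
            rng = np.random.default_rng(s)
            w = _series((2000 * np.exp(-0.02 * t) + 500)
                        * rng.lognormal(0.0, 0.2, 100))
            rwi, _ = rings.detrend_series(w)
            devs.append(rwi.mean())
            slopes.append(np.polyfit(t, rwi.to_numpy(), 1)[0])
        assert np.all(np.abs(np.array(devs) - 1.0) < 0.02)
        assert np.all(np.abs(slopes) < 1e-3)


class TestPrewhiten:
    def test_white_noise_order_zero_is_modal_and_output_close(self):
        orders, dists = [], []
        for s in range(100):
            rng = np.random.default_rng(s)
            x = _series(1.0 + 0.1 * rng.normal(size=100))
            out, p = rings.prewhiten(x)
            orders.append(p)
            common = out.index
            dists.append(np.abs(out - x.loc[common]).mean())
        counts = np.bincount(orders, minlength=4)
        assert counts[0] == counts.max()  # p = 0 is the modal selection
        assert counts[0] >= 60
        assert np.mean(dists) < 0.02  # output ~ input on white noise

    def test_ar1_input_whitened(self):
        bad = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            e = np.empty(120)
            e[0] = rng.normal()
            for i in range(1, 120):
                e[i] = 0.7 * e[i - 1] + rng.normal(0, np.sqrt(1 - 0.49))
            out, _ = rings.prewhiten(_series(1 + 0.1 * e))
            v = out.to_numpy()
            if abs(np.corrcoef(v[:-1], v[1:])[0, 1]) >= 0.1:
                bad += 1
        assert bad <= 5

    def test_level_preserved(self):
        rng = np.random.default_rng(2)
        x = _series(1.0 + 0.1 * rng.normal(size=80))
        out, _ = rings.prewhiten(x)
        assert out.mean() == pytest.approx(x.mean(), abs=0.02)

    def test_constant_series_guarded(self):
        with pytest.warns(UserWarning):
            out, p = rings.prewhiten(_series([1.0] * 50))
        assert p == 0
        assert (out == 1.0).all()


class TestBiweightChronology:
    def test_symmetric_values(self):
        assert rings.tukey_biweight_mean([0.9, 1.0, 1.1]) == pytest.approx(1.0)

    def test_outlier_discounted(self):
        vals = [1.0] * 9 + [5.0]
        assert abs(rings.tukey_biweight_mean(vals) - 1.0) < 0.02

    def test_single_series_chronology_is_itself(self):
        s = _series([1.0, 1.1, 0.9, 1.05])
        chron = rings.build_chronology(pd.DataFrame({"a": s}))
        assert np.allclose(chron["index"], s)
        assert (chron["depth"] == 1).all()

    def test_sample_depth_tracks_availability(self):
        a = _series([1.0] * 10, start=1900)
        b = _series([1.0] * 10, start=1905)
        chron = rings.build_chronology(pd.DataFrame({"a": a, "b": b}))
        assert chron.loc[1902, "depth"] == 1
        assert chron.loc[1908, "depth"] == 2


class TestChronologyStats:
    def test_constant_series_zero_sensitivity(self):
        assert rings.mean_sensitivity([5.0] * 10) == 0.0

    def test_two_one_two(self):
        assert rings.mean_sensitivity([2.0, 1.0, 2.0]) == pytest.approx(2.0 / 3.0)

    @given(k=st.floats(0.01, 100))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(1)
        w = rng.uniform(500, 3000, 50)
        assert rings.mean_sensitivity(w * k) == pytest.approx(
            rings.mean_sensitivity(w), rel=1e-9)

    def test_snr_eps_closed_form(self):
        # rbar = 0.5, N = 10: SNR = 10, EPS = 10/11
        cs = rings.ChronStats(ms=0.2, ac1=0.3, rbar=0.5, n_series=10)
        assert cs.snr == pytest.approx(10.0)
        assert cs.eps == pytest.approx(10.0 / 11.0)

    def test_eps_monotone_in_n_and_limits(self):
        eps = [rings.ChronStats(0, 0, 0.4, n).eps for n in range(2, 30)]
        assert np.all(np.diff(eps) > 0)
        assert rings.ChronStats(0, 0, 0.999, 10).eps > 0.99


class TestCrossdating:
    @staticmethod
    def _coherent_ensemble(seed, n=6, years=150, phi=0.6, noise=0.7):
        rng = np.random.default_rng(seed)
        common = np.empty(years)
        common[0] = rng.normal()
        for i in range(1, years):
            common[i] = phi * common[i - 1] + rng.normal(0, 0.8)
        return {f"s{j}": _series(1 + 0.1 * (common + rng.normal(0, noise, years)),
                                 start=1850, name=f"s{j}")
                for j in range(n)}

    def test_identical_series_unflagged(self):
        s = _series(np.sin(np.arange(150)) + 2, start=1850)
        rep = rings.crossdate_qc(pd.DataFrame({f"s{j}": s for j in range(4)}))
        assert (rep["r"] > 0.999).all()
        assert not rep["flagged"].any()

    def test_one_year_shift_detected_with_correct_lag(self):
        detected = 0
        for s in range(20):
            ens = self._coherent_ensemble(s)
            shifted = ens["s0"].copy()
            shifted.index = shifted.index + 1  # mis-dated one year late
            ens["s0"] = shifted
            rep = rings.crossdate_qc(pd.DataFrame(ens))
            r0 = rep[rep["series"] == "s0"]
            hit = r0["flagged"].any() and \
                (r0.loc[r0["flagged"], "best_lag"] == -1).any()
            detected += bool(hit)
        assert detected >= 18  # >= 90% of seeded runs

    def test_uncorrelated_series_flagged(self):
        rng = np.random.default_rng(5)
        ens = pd.DataFrame({
            "a": _series(1 + 0.1 * rng.normal(size=150), start=1850),
            "b": _series(1 + 0.1 * rng.normal(size=150), start=1850),
        })
        rep = rings.crossdate_qc(ens)
        # unrelated series cannot crossdate: nearly every segment fails
        assert rep["flagged"].mean() > 0.8


class TestSignalRecovery:
    def test_chronology_recovers_common_signal(self, monthly_station):
        from larix import synth
        series, truth = synth.gen_ringwidths(monthly_station, n_trees=10,
                                             seed=21, beta=0.0,
                                             rbar_target=0.5)
        trees = {}
        for tid in sorted({s[:-1] for s in series}):
            trees[tid] = rings.average_cores_to_tree(
                [series[s] for s in series if s.startswith(tid)], name=tid)
        rwi = pd.DataFrame({tid: rings.detrend_series(w)[0]
                            for tid, w in trees.items()})
        chron = rings.build_chronology(rwi)["index"]
        common = truth.ring_signal["common"]
        r = np.corrcoef(chron.to_numpy(), common)[0, 1]
        assert r > 0.9

    def test_rbar_target_yields_expected_eps(self, monthly_station):
        from larix import synth
        series, _ = synth.gen_ringwidths(monthly_station, n_trees=10, seed=22,
                                         beta=0.0, rbar_target=0.5)
        trees = {}
        for tid in sorted({s[:-1] for s in series}):
            trees[tid] = rings.average_cores_to_tree(
                [series[s] for s in series if s.startswith(tid)], name=tid)
        raw = pd.DataFrame(trees)
        pw = pd.DataFrame({tid: rings.prewhiten(rings.detrend_series(w)[0])[0]
                           for tid, w in trees.items()})
        stats = rings.chronology_stats(raw, pw)
        assert stats.eps == pytest.approx(10 * 0.5 / (10 * 0.5 + 0.5), abs=0.05)
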