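"""The six evaluation metrics against independent oracles and anchors."""

import numpy as np
import pytest
from scipy import stats as sps

import eegdenoise as ed


def make_pair(rng, snr_db=0.0, n=1024):
    x = ed.Segment(rng.standard_normal(n))
    a = ed.Segment(rng.standard_normal(n), label=ed.SegmentLabel.EMG)
    return ed.mix(x, a, ed.solve_lambda(x, a, snr_db))


def naive_psd(x, fs=512.0):
    """Independent periodogram: squared rFFT magnitude, density scaling."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    spec[1:] *= 2
    if n % 2 == 0:
        spec[-1] /= 2
    return spec


class TestRrmseT:
    def test_perfect_recovery_zero(self, rng):
        x = rng.standard_normal(512)
        assert ed.rrmse_t(x, x) == 0.0

    def test_identity_at_zero_db_is_one(self, rng):
        pair = make_pair(rng, snr_db=0.0)
        assert ed.rrmse_t(pair.y, pair.x) == pytest.approx(1.0, abs=1e-9)

    def test_matches_loop_oracle(self, rng):
        fy, x = rng.standard_normal(256), rng.standard_normal(256)
        num = sum((a - b) ** 2 for a, b in zip(fy, x))
        den = sum(v**2 for v in x)
        assert ed.rrmse_t(fy, x) == pytest.approx(
            (num / den) ** 0.5, rel=1e-10
        )


class TestRrmseF:
    def test_perfect_recovery_zero(self, rng):
        x = rng.standard_normal(1024)
        assert ed.rrmse_f(x, x, fs=512.0) == 0.0

    def test_matches_naive_periodogram_oracle(self, rng):
        fy, x = rng.standard_normal(1024), rng.standard_normal(1024)
        pf, px = naive_psd(fy), naive_psd(x)
        expected = np.sqrt(np.mean((pf - px) ** 2) / np.mean(px**2))
        assert ed.rrmse_f(fy, x, fs=512.0) == pytest.approx(expected, rel=1e-8)

    def test_invariant_to_common_circular_shift_of_sinusoid(self, rng):
        t = np.arange(1024) / 512.0
        x = np.sin(2 * np.pi * 12 * t) + 0.3 * np.sin(2 * np.pi * 31 * t)
        fy = x + 0.1 * np.sin(2 * np.pi * 50 * t)
        base = ed.rrmse_f(fy, x, fs=512.0)
        shifted = ed.rrmse_f(np.roll(fy, 100), np.roll(x, 100), fs=512.0)
        assert shifted == pytest.approx(base, rel=1e-9)


class TestCorrelation:
    def test_self_correlation_one(self, rng):
        x = rng.standard_normal(512)
        r, p = ed.cc(x, x)
        assert r == 1.0 and p == 0.0

    def test_anti_correlation(self, rng):
        x = rng.standard_normal(512)
        r, _ = ed.cc(x, -x)
        assert r == -1.0

    def test_affine_invariance(self, rng):
        fy, x = rng.standard_normal(256), rng.standard_normal(256)
        r0, _ = ed.cc(fy, x)
        r1, _ = ed.cc(3.7 * fy + 11.0, x)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_matches_scipy_pearsonr(self, rng):
        for _ in range(20):
            fy, x = rng.standard_normal(400), rng.standard_normal(400)
            r, p = ed.cc(fy, x)
            ref = sps.pearsonr(fy, x)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ed.DegenerateInputError):
            ed.cc(np.ones(16), np.arange(16.0))


class TestEta:
    def test_perfect_recovery_100(self, rng):
        pair = make_pair(rng)
        assert ed.eta(pair.x, pair.y, pair.x) == pytest.approx(100.0, abs=1e-9)

    def test_identity_denoiser_0(self, rng):
        pair = make_pair(rng)
        assert ed.eta(pair.y, pair.y, pair.x) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_correlations_closed_form(self, rng):
        # build fy and y with CC = 0.9201, CCb = 0.5473 against x;
        # the definition then gives (1 - 0.0799/0.4527)*100 = 82.35...
        n = 4096
        x = rng.standard_normal(n)
        e1, e2 = rng.standard_normal(n), rng.standard_normal(n)

        def with_corr(base, noise, rho):
            xc = (base - base.mean()) / base.std()
            en = noise - noise.mean()
            en -= en.dot(xc) / n * xc       # orthogonalize
            en /= en.std()
            return rho * xc + np.sqrt(1 - rho**2) * en

        fy = with_corr(x, e1, 0.9201)
        y = with_corr(x, e2, 0.5473)
        expected = (1 - (1 - 0.9201) / (1 - 0.5473)) * 100
        assert expected == pytest.approx(82.35, abs=0.005)
        assert ed.eta(fy, y, x) == pytest.approx(expected, abs=1e-6)

    def test_uncontaminated_baseline_rejected(self, rng):
        x = rng.standard_normal(128)
        with pytest.raises(ed.DegenerateInputError):
            ed.eta(x, x, x)


class TestSsim:
    def test_self_similarity_near_one(self, rng):
        x = rng.standard_normal(1024)
        assert ed.ssim(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(512), rng.standard_normal(512)
        assert ed.ssim(a, b) == pytest.approx(ed.ssim(b, a), abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        fy, x = rng.standard_normal(256), rng.standard_normal(256) * 2 + 1
        c1 = c2 = 1e-4
        mx, mf = x.mean(), fy.mean()
        cov = np.mean((x - mx) * (fy - mf))
        expected = ((2 * mx * mf + c1) * (2 * cov + c2)) / (
            (mx**2 + mf**2 + c1) * (x.var() + fy.var() + c2)
        )
        assert ed.ssim(fy, x) == pytest.approx(expected, rel=1e-12)

    def test_windowed_option_runs(self, rng):
        a, b = rng.standard_normal(128), rng.standard_normal(128)
        assert ed.ssim(a, b, window=32) <= 1.0


class TestMutualInformation:
    def test_independent_signals_near_zero(self):
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals.append(ed.mi(r.standard_normal(1024), r.standard_normal(1024)))
        assert np.mean(vals) < 0.1

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(512), rng.standard_normal(512)
        assert ed.mi(a, b) == pytest.approx(ed.mi(b, a), rel=1e-9)

    def test_self_mi_equals_binned_marginal_entropy(self, rng):
        from eegdenoise.metrics import DEFAULT_MI_BINS

        x = rng.standard_normal(1024)
        counts, _ = np.histogram(x, bins=DEFAULT_MI_BINS)
        p = counts / counts.sum()
        p = p[p > 0]
        entropy = -np.sum(p * np.log(p))
        assert ed.mi(x, x) == pytest.approx(entropy, rel=1e-9)

    def test_matches_sklearn_on_shared_binning(self, rng):
        from sklearn.metrics import mutual_info_score

        from eegdenoise.metrics import DEFAULT_MI_BINS as K

        fy, x = rng.standard_normal(1024), rng.standard_normal(1024)
        fb = np.clip(np.digitize(fy, np.linspace(fy.min(), fy.max(), K + 1)[1:-1]), 0, K - 1)
        xb = np.clip(np.digitize(x, np.linspace(x.min(), x.max(), K + 1)[1:-1]), 0, K - 1)
        assert ed.mi(fy, x) == pytest.approx(
            mutual_info_score(fb, xb), rel=1e-9
        )


class TestMonotoneFidelity:
    def test_blend_towards_clean_improves_metrics(self, rng):
        pair = make_pair(rng, snr_db=-3.0)
        alphas = np.linspace(0, 1, 11)
        ccs, rrs = [], []
        for a in alphas:
            fy = a * pair.x.samples + (1 - a) * pair.y.samples
            ccs.append(ed.cc(fy, pair.x.samples)[0])
            rrs.append(ed.rrmse_t(fy, pair.x.samples))
        assert all(b >= a - 1e-12 for a, b in zip(ccs, ccs[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(rrs, rrs[1:]))


class TestAggregate:
    def _record(self, rng, snr):
        pair = make_pair(rng, snr_db=snr)
        return ed.pair_metrics(pair.y.samples * 0.9 + pair.x.samples * 0.1,
                               pair.y.samples, pair.x.samples,
                               fs=512.0, snr_db=snr, artifact_type="EMG")

    def test_single_record_aggregate_is_itself(self, rng):
        rec = self._record(rng, 0.0)
        rep = ed.aggregate([rec])
        row = rep.summary.iloc[0]
        assert row["rrmse_t"] == pytest.approx(rec["rrmse_t"])
        assert rep.summary.iloc[-1]["level"] == "grand_mean"

    def test_permutation_invariance(self, rng):
        recs = [self._record(rng, s) for s in (-7, 0, 2) for _ in range(3)]
        a = ed.aggregate(recs).summary
        b = ed.aggregate(recs[::-1]).summary
        np.testing.assert_allclose(a["rrmse_t"].values, b["rrmse_t"].values)

    def test_ten_level_sweep_has_eleven_rows(self, rng):
        recs = [self._record(rng, s) for s in range(-7, 3)]
        rep = ed.aggregate(recs)
        assert len(rep.summary) == 11

    def test_csv_round_trip(self, rng, tmp_path):
        import pandas as pd

        rep = ed.aggregate([self._record(rng, 0.0)])
        rep.to_csv(tmp_path / "records.csv", tmp_path / "summary.csv")
        back = pd.read_csv(tmp_path / "records.csv")
        assert list(back.columns) == ed.metrics.METRIC_COLUMNS
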