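"""Filter bank, CSP against a brute-force eigendecomposition oracle, SVM."""

import numpy as np
import pytest
from scipy import linalg

import stressbci as sb
from stressbci.fbcsp import (
    CONDITION_PAIRS,
    FilterBankSpec,
    SVMSpec,
    classify_pair,
    design_filter_bank,
    extract_features,
    fit_csp,
    fit_csp_bank,
    run_all_pairs,
    train_eval_binary,
)
from stressbci.preprocess import WindowSet


def _ws(data, labels):
    return WindowSet(windows=data, labels=labels, participant_id="P",
                     length_s=data.shape[2] / 125.0, rate=125.0)


def csp_oracle(ca, cb, m):
    """Independent CSP: whiten the composite covariance explicitly, then
    eigendecompose the whitened class-a covariance."""
    comp = ca + cb
    d, u = np.linalg.eigh(comp)
    p = u @ np.diag(d**-0.5) @ u.T  # whitening: p comp p^T = I
    dd, v = np.linalg.eigh(p @ ca @ p.T)
    order = np.argsort(dd)[::-1]
    w = (p.T @ v)[:, order]
    dd = dd[order]
    keep = list(range(m)) + list(range(len(dd) - m, len(dd)))
    return w[:, keep], dd[keep]


def windows_from_cov(rng, cov, n, t=64):
    chol = np.linalg.cholesky(cov)
    return np.einsum("ij,njt->nit", chol, rng.standard_normal((n, cov.shape[0], t)))


class TestFilterBank:
    def test_default_band_layout(self):
        bands = FilterBankSpec().bands
        assert len(bands) == 9
        assert bands[0] == (4.0, 8.0)
        assert bands[-1] == (36.0, 40.0)
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            assert hi == lo

    def test_tone_lands_in_its_band(self):
        t = np.arange(125) / 125.0
        tone = np.sin(2 * np.pi * 10.0 * t)
        ws = _ws(np.tile(tone, (1, 16, 1)), np.array([0]))
        banded = design_filter_bank(ws)
        rms = np.sqrt((banded[:, 0, 0, 20:-20] ** 2).mean(axis=1))
        assert np.argmax(rms) == 1  # the (8, 12) band
        in_rms = np.sqrt((tone[20:-20] ** 2).mean())
        assert rms[4] <= 0.1 * in_rms  # the (20, 24) band

    def test_zero_window_zero_bands(self):
        ws = _ws(np.zeros((2, 16, 125)), np.array([0, 1]))
        assert np.allclose(design_filter_bank(ws), 0.0)

    def test_band_above_nyquist_rejected(self):
        ws = _ws(np.zeros((2, 16, 125)), np.array([0, 1]))
        spec = FilterBankSpec(bands=((50.0, 70.0),))
        with pytest.raises(ValueError):
            design_filter_bank(ws, spec)


class TestCSP:
    def test_two_channel_toy(self):
        """C_a = diag(2,1), C_b = diag(1,2): the most class-a-dominant filter
        is the first axis with variance ratio 2/3."""
        rng = np.random.default_rng(0)
        n = 4000
        a = windows_from_cov(rng, np.diag([2.0, 1.0]), n)
        b = windows_from_cov(rng, np.diag([1.0, 2.0]), n)
        model = fit_csp(a, b, m=1)
        w0 = model.filters[:, 0]
        assert abs(w0[0]) / np.linalg.norm(w0) > 0.99
        assert model.eigenvalues[0] == pytest.approx(2.0 / 3.0, abs=0.03)

    def test_identical_classes_half_eigenvalues(self):
        rng = np.random.default_rng(1)
        a = windows_from_cov(rng, np.eye(4), 500)
        model = fit_csp(a, a.copy(), m=2)
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_16ch(self, seed):
        rng = np.random.default_rng(seed)
        qa = rng.standard_normal((16, 16))
        qb = rng.standard_normal((16, 16))
        ca = qa @ qa.T / 16 + 1e-3 * np.eye(16)
        cb = qb @ qb.T / 16 + 1e-3 * np.eye(16)
        evals, evecs = linalg.eigh(ca, ca + cb)
        order = np.argsort(evals)[::-1]
        impl_w = evecs[:, order][:, [0, 1, 14, 15]]
        w_oracle, d_oracle = csp_oracle(ca, cb, m=2)
        for k in range(4):
            wi, wo = impl_w[:, k], w_oracle[:, k]
            wi = wi * np.sign(wi[np.argmax(np.abs(wi))])
            wo = wo * np.sign(wo[np.argmax(np.abs(wo))])
            assert np.max(np.abs(wi - wo)) < 1e-8

    def test_fitted_filters_match_oracle_and_whiten(self):
        rng = np.random.default_rng(3)
        qa, qb = rng.standard_normal((2, 16, 16))
        a = windows_from_cov(rng, qa @ qa.T / 16 + 0.1 * np.eye(16), 100)
        b = windows_from_cov(rng, qb @ qb.T / 16 + 0.1 * np.eye(16), 100)
        model = fit_csp(a, b, m=2)
        # reconstruct the class covariances exactly as the implementation does
        from stressbci.fbcsp import _class_covariance
        ca = _class_covariance(a, 1e-6)
        cb = _class_covariance(b, 1e-6)
        w_oracle, _ = csp_oracle(ca, cb, m=2)
        for k in range(4):
            wi = model.filters[:, k]
            wo = w_oracle[:, k]
            wi = wi * np.sign(wi[np.argmax(np.abs(wi))])
            wo = wo * np.sign(wo[np.argmax(np.abs(wo))])
            assert np.max(np.abs(wi - wo)) < 1e-8
        # whitening invariant: W^T (C_a + C_b) W = I on the kept filters
        gram = model.filters.T @ (ca + cb) @ model.filters
        assert np.max(np.abs(gram - np.eye(4))) < 1e-6

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            fit_csp(np.zeros((1, 4, 10)), np.zeros((5, 4, 10)), m=1)


class TestFeatures:
    def _bank_and_windows(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 16, 125))
        labels = np.array([0, 1] * (n // 2))
        ws = _ws(data, labels)
        banded = design_filter_bank(ws)
        model = fit_csp_bank(banded, labels, (0, 1), FilterBankSpec().bands, m=2)
        return model, banded

    def test_feature_layout(self):
        model, banded = self._bank_and_windows()
        feats = extract_features(model, banded)
        assert feats.shape == (40, 36)
        assert np.all(np.isfinite(feats))

    def test_scale_invariance(self):
        model, banded = self._bank_and_windows()
        feats = extract_features(model, banded)
        feats10 = extract_features(model, banded * 10.0)
        assert np.max(np.abs(feats - feats10)) < 1e-10

    def test_dominant_projection_feature_near_zero(self):
        """A window whose variance concentrates in one CSP filter has that
        filter's normalized log-variance near log(1) = 0."""
        model, banded = self._bank_and_windows()
        # synthesize a window aligned with band 0's first spatial pattern
        patterns = np.linalg.pinv(model.models[0].filters.T)
        t = np.arange(125) / 125.0
        src = np.sin(2 * np.pi * 6.0 * t)  # inside band (4, 8)
        win = np.outer(patterns[:, 0], src)
        ws1 = _ws(win[None], np.array([0]))
        banded1 = design_filter_bank(ws1)
        feats = extract_features(model, banded1)
        assert feats[0, 0] > -0.05  # log of a ratio close to 1


class TestSVM:
    def test_separable_toy(self):
        rng = np.random.default_rng(0)
        xa = rng.standard_normal((100, 4)) + 4.0
        xb = rng.standard_normal((100, 4)) - 4.0
        x = np.vstack([xa, xb])
        y = np.array([0] * 100 + [1] * 100)
        acc, _ = train_eval_binary(x, y, x, y, SVMSpec())
        assert acc == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((400, 8))
        y = rng.permutation([0] * 200 + [1] * 200)
        xt = rng.standard_normal((400, 8))
        yt = rng.permutation([0] * 200 + [1] * 200)
        acc, _ = train_eval_binary(x, y, xt, yt)
        assert 0.4 <= acc <= 0.6

    def test_single_class_rejected(self):
        x = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train_eval_binary(x, np.zeros(10, dtype=int), x, np.zeros(10, dtype=int))


class TestEndToEnd:
    def test_baseline_vs_stressor_high_accuracy(self, full_windows):
        acc = classify_pair(full_windows, ("baseline", "stressor"))
        assert acc >= 0.90

    def test_run_all_pairs_shape(self, short_windows):
        out = run_all_pairs(short_windows)
        assert set(out) == {f"{a}_vs_{b}" for a, b in CONDITION_PAIRS}
        assert all(v is not None for v in out.values())

    def test_missing_condition_reported_absent(self, short_windows):
        sub = short_windows.restrict_classes(("baseline", "stressor"))
        out = run_all_pairs(sub)
        assert out["baseline_vs_stressor"] is not None
        assert out["unguided_vs_guided"] is None

    def test_table1_column_means_match_fixture(self):
        t1 = sb.tables.load_table("table1")
        assert float(t1["baseline_vs_stressor"].mean()) == pytest.approx(87.88, abs=0.005)
        assert float(t1["guided_vs_stressor"].mean()) == pytest.approx(80.45, abs=0.005)
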