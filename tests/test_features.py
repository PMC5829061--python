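"""CSP fitting/selection and the EEG/NIRS feature extractors."""

import numpy as np
import pytest

from hbci.data import ChannelInfo, EpochSet
from hbci.features import (
    FilterBankSpec,
    csp_fit,
    csp_fit_covariances,
    csp_select,
    fbcsp_features,
    nirs_mean_features,
)


def _epochs(data, rate=200.0, labels=None, t0=0.0):
    n_tr, n_ch, n_t = data.shape
    labels = labels if labels is not None else np.array(["MA"] * n_tr)
    return EpochSet(
        data=data,
        time_axis=t0 + np.arange(n_t) / rate,
        labels=labels,
        rate=rate,
        channels=[ChannelInfo(f"ch{i}", "EEG") for i in range(n_ch)],
    )


def _gaussian_epochs(cov, n_trials, n_t=2000, rate=200.0, seed=0):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    data = np.einsum("cd,tds->tcs", L, rng.standard_normal((n_trials, cov.shape[0], n_t)))
    return _epochs(data, rate)


class TestCSP:
    def _planted(self, d=4, strength=6.0, seed=1):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((d, d))
        base = A @ A.T + d * np.eye(d)
        v = rng.standard_normal(d)
        v /= np.linalg.norm(v)
        return base + strength * np.outer(v, v), base, v

    def test_recovers_planted_direction_vs_brute_force(self):
        """Top CSP filter matches exhaustive variance-ratio maximization."""
        cov_a, cov_b, _ = self._planted()
        flt = csp_fit_covariances(cov_a, cov_b)
        w = flt.filters[:, 0]
        w /= np.linalg.norm(w)
        rng = np.random.default_rng(7)
        best_ratio, best_u = -1.0, None
        for u in rng.standard_normal((100000, 4)):
            u /= np.linalg.norm(u)
            ratio = (u @ cov_a @ u) / (u @ (cov_a + cov_b) @ u)
            if ratio > best_ratio:
                best_ratio, best_u = ratio, u
        assert abs(w @ best_u) > 0.99
        top_ratio = (w @ cov_a @ w) / (w @ (cov_a + cov_b) @ w)
        assert top_ratio >= best_ratio - 1e-9

    def test_joint_diagonalization_and_whitening(self):
        cov_a, cov_b, _ = self._planted(seed=3)
        flt = csp_fit_covariances(cov_a, cov_b)
        W = flt.filters
        comp = W.T @ (cov_a + cov_b) @ W
        assert np.abs(comp - np.eye(4)).max() < 1e-8
        proj_a = W.T @ cov_a @ W
        off = proj_a - np.diag(np.diag(proj_a))
        assert np.abs(off).max() < 1e-8

    def test_identical_classes_score_half(self):
        eps = _gaussian_epochs(np.eye(3) + 0.2, n_trials=10, seed=5)
        flt = csp_fit(eps, eps)
        assert np.allclose(flt.scores, 0.5, atol=1e-6)

    def test_class_swap_mirrors_scores(self):
        cov_a, cov_b, _ = self._planted(seed=9)
        f_ab = csp_fit_covariances(cov_a, cov_b)
        f_ba = csp_fit_covariances(cov_b, cov_a)
        assert np.allclose(f_ab.scores, (1 - f_ba.scores)[::-1], atol=1e-8)

    def test_channel_permutation_permutes_filter_rows(self):
        # generic covariances with distinct scores (no degenerate subspace)
        rng = np.random.default_rng(11)
        A, B = rng.standard_normal((2, 4, 4))
        cov_a, cov_b = A @ A.T + 4 * np.eye(4), B @ B.T + 4 * np.eye(4)
        perm = np.array([2, 0, 3, 1])
        f = csp_fit_covariances(cov_a, cov_b)
        f_p = csp_fit_covariances(cov_a[np.ix_(perm, perm)],
                                  cov_b[np.ix_(perm, perm)])
        assert np.allclose(np.abs(f_p.filters), np.abs(f.filters[perm]), atol=1e-6)

    def test_too_few_trials_rejected(self):
        eps = _gaussian_epochs(np.eye(2), n_trials=1, n_t=100)
        with pytest.raises(ValueError, match="at least 2 trials"):
            csp_fit(eps, eps)


class TestSelect:
    def test_21_channels_keep_6(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((21, 21))
        flt = csp_fit_covariances(A @ A.T + 21 * np.eye(21), 21 * np.eye(21))
        kept = csp_select(flt)
        assert kept.n_components == 6
        assert np.all(np.diff(kept.scores) <= 1e-12)

    def test_zero_components_rejected(self):
        flt = csp_fit_covariances(np.eye(3), np.eye(3))
        with pytest.raises(ValueError, match="at least one"):
            csp_select(flt, 0, 0)

    def test_small_montage_keeps_all(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 6))
        flt = csp_fit_covariances(A @ A.T + 6 * np.eye(6), 6 * np.eye(6))
        kept = csp_select(flt, 3, 3)
        assert kept.n_components == 6
        assert np.allclose(kept.scores, flt.scores)

    def test_overselection_rejected(self):
        flt = csp_fit_covariances(np.eye(4), np.eye(4))
        with pytest.raises(ValueError, match="available"):
            csp_select(flt, 3, 3)


class TestFBCSP:
    def _fitted(self, n_trials=60, n_ch=21, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_trials, n_ch, 3000))
        labels = np.array(["MA", "MI"] * (n_trials // 2))
        eps = _epochs(data, labels=labels)
        bank = FilterBankSpec()
        filters = []
        from hbci.features import bandpass_epochs

        for spec in bank.bands:
            bp = bandpass_epochs(eps, spec)
            filters.append(
                csp_select(csp_fit(
                    bp.select_trials(np.flatnonzero(labels == "MA")),
                    bp.select_trials(np.flatnonzero(labels == "MI")),
                    task_window=(0, 10),
                ))
            )
        return eps, bank, filters

    def test_60_trials_18_features(self):
        eps, bank, filters = self._fitted()
        fm = fbcsp_features(eps, bank, filters, task_window=(0, 10))
        assert fm.data.shape == (60, 18)
        assert np.all(np.isfinite(fm.data))

    def test_doubling_amplitude_shifts_logvar_by_log4(self):
        eps, bank, filters = self._fitted(n_trials=10)
        fm = fbcsp_features(eps, bank, filters, task_window=(0, 10))
        eps2 = _epochs(eps.data * 2.0, labels=eps.labels)
        fm2 = fbcsp_features(eps2, bank, filters, task_window=(0, 10))
        assert np.allclose(fm2.data - fm.data, np.log(4.0), atol=1e-10)

    def test_deterministic(self):
        eps, bank, filters = self._fitted(n_trials=10)
        a = fbcsp_features(eps, bank, filters, task_window=(0, 10)).data
        b = fbcsp_features(eps, bank, filters, task_window=(0, 10)).data
        assert np.array_equal(a, b)


class TestNIRSFeatures:
    def _hb_epochs(self, data, rate=13.3):
        n_tr, n_rows, n_t = data.shape
        chans = []
        for c in range(n_rows // 2):
            for chromo in ("HbR", "HbO"):
                chans.append(ChannelInfo(f"S{c+1}-D{c+1}:{chromo}", "NIRS",
                                         "frontal", source=c + 1, detector=c + 1))
        return EpochSet(
            data=data,
            time_axis=-5.0 + (1 + np.arange(n_t)) / rate,
            labels=np.array(["MA"] * n_tr),
            rate=rate,
            channels=chans,
        )

    def test_60_trials_64_features(self):
        rng = np.random.default_rng(0)
        eps = self._hb_epochs(rng.standard_normal((60, 32, 399)))
        fm = nirs_mean_features(eps)
        assert fm.data.shape == (60, 64)

    def test_constant_epochs_give_constant_features(self):
        eps = self._hb_epochs(np.full((4, 32, 399), 2.5))
        fm = nirs_mean_features(eps)
        assert np.allclose(fm.data, 2.5, atol=1e-12)

    def test_linear_ramp_matches_closed_form(self):
        """Window mean of a ramp a*t equals a * mean of sample times."""
        rate = 13.3
        n_t = 399
        times = -5.0 + (1 + np.arange(n_t)) / rate
        slope = 0.37
        data = np.tile(slope * times, (2, 32, 1))
        eps = self._hb_epochs(data)
        fm = nirs_mean_features(eps, windows=((5.0, 10.0),))
        mask = eps.time_mask(5.0, 10.0)
        expected = slope * times[mask].mean()
        assert np.allclose(fm.data, expected, atol=1e-12)

    def test_empty_window_rejected(self):
        eps = self._hb_epochs(np.zeros((2, 32, 399)))
        with pytest.raises(ValueError, match="empty"):
            nirs_mean_features(eps, windows=((5.001, 5.002),))
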