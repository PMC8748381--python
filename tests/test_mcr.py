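import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromforge.clusters import PeakCluster
from chromforge.mcr import (
    estimate_rank,
    extract_components,
    lack_of_fit,
    mcr_als,
    ms_noise_count,
    resolve_cluster,
    simplisma,
    unimodal_project,
)
from conftest import two_component_cluster


def _match_columns(S_fit: np.ndarray, S_true: np.ndarray) -> list[float]:
    """Best one-to-one correlation of fitted spectra to truth (handles the
    permutation ambiguity of bilinear models)."""
    r = np.corrcoef(S_fit.T, S_true.T)[: S_fit.shape[1], S_fit.shape[1] :]
    out = []
    used = set()
    for j in range(S_true.shape[1]):
        order = np.argsort(-r[:, j])
        for i in order:
            if i not in used:
                used.add(int(i))
                out.append(float(r[i, j]))
                break
    return out


class TestSimplisma:
    def test_rank_one_recovers_spectrum_direction(self):
        t = np.linspace(0, 1, 40)
        c = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        s = np.abs(np.sin(np.linspace(0, 3, 25))) + 0.1
        X = np.outer(c, s)
        spectra, purity = simplisma(X, 1)
        r = np.corrcoef(spectra[:, 0], s)[0, 1]
        assert abs(r) > 0.999

    def test_disjoint_windows_select_one_point_each(self):
        n_t, n_c = 60, 30
        c1 = np.zeros(n_t)
        c1[5:20] = np.hanning(15)
        c2 = np.zeros(n_t)
        c2[35:55] = np.hanning(20)
        s1 = np.zeros(n_c)
        s1[:12] = 1.0
        s2 = np.zeros(n_c)
        s2[15:] = 1.0
        X = np.outer(c1, s1) + np.outer(c2, s2)
        spectra, _ = simplisma(X, 2)
        # each selected spectrum belongs to exactly one block
        picks = [np.argmax(spectra[:, j]) for j in range(2)]
        assert ({p < 13 for p in picks} == {True, False})

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            simplisma(np.zeros((10, 5)), 2)

    def test_purity_scores_decrease_for_separated_blocks(self):
        X, _, _ = two_component_cluster(sep_sigma=6.0)
        _, purity = simplisma(X, 2)
        assert purity[0] >= purity[1]


class TestUnimodalProjection:
    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_is_nonnegative_and_unimodal(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=rng.integers(3, 60))
        out = unimodal_project(y)
        assert np.all(out >= 0)
        m = int(np.argmax(out))
        assert np.all(np.diff(out[: m + 1]) >= -1e-12)
        assert np.all(np.diff(out[m:]) <= 1e-12)

    def test_already_unimodal_unchanged(self):
        y = np.exp(-0.5 * ((np.arange(30) - 15) / 4.0) ** 2)
        assert np.allclose(unimodal_project(y), y)


class TestMcrAls:
    def test_noiseless_rank2_recovery(self):
        X, C_true, S_true = two_component_cluster(sep_sigma=2.0)
        init, _ = simplisma(X, 2)
        fit = mcr_als(X, init)
        rs = _match_columns(fit.S, S_true)
        assert min(rs) > 0.999
        assert fit.lof < 0.1

    def test_rank1_fit_of_rank1_data(self):
        t = np.linspace(0, 1, 50)
        c = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        s = np.linspace(1, 2, 20)
        X = np.outer(c, s)
        init, _ = simplisma(X, 1)
        fit = mcr_als(X, init)
        assert fit.lof < 1e-6
        assert abs(np.corrcoef(fit.C[:, 0], c)[0, 1]) > 0.9999

    def test_constraints_hold_exactly(self):
        X, _, _ = two_component_cluster(sep_sigma=1.5, noise_sd=1e-3)
        init, _ = simplisma(X, 2)
        fit = mcr_als(X, init)
        assert fit.C.min() >= 0
        assert fit.S.min() >= 0
        for j in range(2):
            col = fit.C[:, j]
            m = int(np.argmax(col))
            assert np.all(np.diff(col[: m + 1]) >= -1e-10)
            assert np.all(np.diff(col[m:]) <= 1e-10)
        # spectra unit-normalized
        assert np.allclose(np.linalg.norm(fit.S, axis=0), 1.0)

    def test_lof_non_increasing_on_accepted_iterations(self):
        X, _, _ = two_component_cluster(sep_sigma=1.2, noise_sd=5e-4)
        init, _ = simplisma(X, 2)
        fit = mcr_als(X, init)
        h = np.array(fit.lof_history)
        assert np.all(np.diff(h) <= 1e-9)

    def test_rank_exceeding_dims_rejected(self):
        X = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            mcr_als(X, np.abs(np.random.default_rng(1).normal(size=(3, 4))))

    def test_reconstruction_close_to_svd_truncation(self):
        """With constraints satisfied by the truth (active but not binding),
        the constrained fit cannot be much worse than the best rank-2
        approximation."""
        X, _, _ = two_component_cluster(sep_sigma=2.5, noise_sd=1e-3)
        init, _ = simplisma(X, 2)
        fit = mcr_als(X, init)
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        X2 = (U[:, :2] * sv[:2]) @ Vt[:2]
        err_svd = np.linalg.norm(X - X2)
        err_fit = np.linalg.norm(X - fit.C @ fit.S.T)
        assert err_fit <= err_svd * 1.5

    def test_strong_overlap_apex_spectrum_is_a_mixture(self):
        """Two strongly overlapped components: curve resolution recovers both
        spectra while the raw apex spectrum matches neither."""
        X, C_true, S_true = two_component_cluster(sep_sigma=1.0, amp2=0.9)
        init, _ = simplisma(X, 2)
        fit = mcr_als(X, init)
        rs = _match_columns(fit.S, S_true)
        assert min(rs) > 0.99
        apex = X[int(np.argmax(X.sum(axis=1)))]
        r_apex = [abs(np.corrcoef(apex, S_true[:, j])[0, 1]) for j in range(2)]
        assert max(r_apex) < 0.99


class TestEstimateRank:
    def test_noiseless_rank2(self):
        X, _, _ = two_component_cluster(sep_sigma=2.0)
        assert estimate_rank(X, noise_level=1e-9) == 2

    def test_rank_capped_at_six(self):
        rng = np.random.default_rng(5)
        t = np.arange(200, dtype=float)
        lam = np.arange(40, dtype=float)
        X = np.zeros((200, 40))
        for i in range(10):
            c = np.exp(-0.5 * ((t - 40 - 12 * i) / 8.0) ** 2)
            s = np.abs(rng.normal(size=40)) + 0.05
            X += np.outer(c, s)
        assert estimate_rank(X, noise_level=1e-6) <= 6

    def test_pure_noise_cluster_rank_zero(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(0, 1e-3, size=(50, 20)))
        assert estimate_rank(X, noise_level=1e-3) == 0


class TestMsNoiseCount:
    def test_printed_rule_example(self):
        # ions at 0.05 % and 0.2 % of the base peak: only the 0.2 % ion
        # counts against the 0.1 % floor
        assert ms_noise_count({100.0: 100.0, 120.0: 0.05, 140.0: 0.2}) == 1

    def test_clean_single_ion_spectrum(self):
        assert ms_noise_count({137.0: 100.0}) == 0

    def test_noisy_spectrum_counts_all_above_floor(self):
        spec = {float(50 + i): 1.0 for i in range(20)}
        spec[500.0] = 100.0
        assert ms_noise_count(spec) == 20


class TestExtraction:
    def _cluster(self, X, t0=0.0, dt=0.01):
        time = t0 + dt * np.arange(X.shape[0])
        return PeakCluster(
            run_id="run1",
            i_start=0,
            i_end=X.shape[0],
            time=time,
            submatrix=X,
            apex_times=[float(time[np.argmax(X.sum(axis=1))])],
            noise_level=1e-6,
        )

    def test_rank1_cluster_single_pure_component(self):
        t = np.linspace(0, 1, 60)
        c = np.exp(-0.5 * ((t - 0.5) / 0.08) ** 2)
        s = np.linspace(1, 2, 20)
        X = np.outer(c, s)
        fit, comps = resolve_cluster(self._cluster(X))
        assert len(comps) == 1
        assert comps[0].pure
        assert not comps[0].truncated

    def test_truncated_peak_flagged(self):
        t = np.linspace(0, 1, 60)
        c = np.exp(-0.5 * ((t - 1.1) / 0.15) ** 2)  # apex beyond the window
        s = np.linspace(1, 2, 20)
        X = np.outer(c, s)
        fit, comps = resolve_cluster(self._cluster(X))
        assert len(comps) == 1
        assert comps[0].truncated

    def test_apex_time_within_cluster_window(self):
        X, _, _ = two_component_cluster(sep_sigma=2.0)
        cl = self._cluster(X, t0=5.0)
        _, comps = resolve_cluster(cl)
        for c in comps:
            assert cl.time[0] <= c.apex_time <= cl.time[-1]

    def test_dominant_component_in_overlap_flagged_pure(self):
        """The spec of 'pure' extends beyond rank-1 clusters: a component
        that dominates the signal around its own apex elutes effectively
        pure there."""
        X, C_true, S_true = two_component_cluster(sep_sigma=6.0)
        cl = self._cluster(X)
        _, comps = resolve_cluster(cl)
        assert len(comps) == 2
        assert all(c.pure for c in comps)  # far apart: both dominate locally
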