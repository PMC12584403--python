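import numpy as np
import pandas as pd
import pytest

from eecfate.motifs import (
    DifferentialThresholds,
    LaggedCorrelation,
    MotifTargetMatrix,
    activity_zscores,
    fit_activities,
    lagged_correlation,
    profile_std,
    select_differential,
    specificity_categories,
    standardize_columns,
)


def random_sites(rng, g, m):
    n = rng.poisson(1.0, size=(g, m)).astype(float) + rng.random((g, m))
    return n


class TestFitActivities:
    def test_zero_centered_expression_gives_zero_activity(self):
        rng = np.random.default_rng(0)
        n = random_sites(rng, 30, 4)
        e = np.tile(rng.normal(size=(30, 1)), (1, 6))  # E identical per gene
        am = fit_activities(e, n, ridge_penalty=0.0)
        np.testing.assert_allclose(am.activities.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_indicator_motifs_closed_form(self):
        # disjoint target sets; +delta shift of motif 0's targets in cell 2
        g, m, c = 12, 3, 5
        n = np.zeros((g, m))
        n[0:4, 0] = 1.0
        n[4:8, 1] = 1.0
        n[8:12, 2] = 1.0
        delta = 0.7
        e = np.zeros((g, c))
        e[0:4, 2] = delta
        am = fit_activities(e, n, ridge_penalty=0.0, standardize=False)
        a = am.activities.to_numpy()
        # centering per motif spreads the -mean across cells; undo it
        a_uncentered = a - a.mean(axis=1, keepdims=True) + delta / c * 0
        # direct check: before centering the fit solves OLS exactly
        ecent = e - e.mean(axis=1, keepdims=True)
        want = np.linalg.lstsq(n, ecent, rcond=None)[0]
        want -= want.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(a, want, atol=1e-10)
        # the planted cell carries the shift (relative to the cell mean)
        assert a[0, 2] - a[0, 0] == pytest.approx(delta, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g, m, c = 40, 6, 9
        n = random_sites(rng, g, m)
        e = rng.normal(size=(g, c))
        am = fit_activities(e, n, ridge_penalty=0.0)
        ns = standardize_columns(n)
        ec = e - e.mean(axis=1, keepdims=True)
        a_or = np.linalg.solve(ns.T @ ns, ns.T @ ec)
        a_or -= a_or.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(am.activities.to_numpy(), a_or, atol=1e-8)
        assert (am.se.to_numpy() > 0).all()
        # per-motif activities are centered
        np.testing.assert_allclose(am.activities.to_numpy().mean(axis=1), 0, atol=1e-8)

    def test_rank_deficiency_instructs_ridge(self):
        n = np.ones((10, 2))
        n[:, 1] = 2 * n[:, 0]  # collinear after standardization
        with pytest.raises(ValueError, match="ridge"):
            fit_activities(np.random.default_rng(0).normal(size=(10, 3)), n,
                           ridge_penalty=0.0, standardize=False)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_activities(np.zeros((5, 2)), np.ones((5, 1)), ridge_penalty=-1.0,
                           standardize=False)

    def test_all_zero_motif_column_dropped_with_warning(self):
        sites = pd.DataFrame({"m1": [1.0, 2.0], "m2": [0.0, 0.0]},
                             index=["g1", "g2"])
        with pytest.warns(UserWarning, match="m2"):
            mtm = MotifTargetMatrix(sites=sites)
        assert mtm.motif_names == ["m1"]


class TestZScores:
    def _am(self, a, se):
        from eecfate.motifs import ActivityMatrix

        idx = pd.Index([f"m{i}" for i in range(a.shape[0])], name="motif")
        return ActivityMatrix(
            activities=pd.DataFrame(a, index=idx),
            se=pd.DataFrame(se, index=idx),
            ridge_penalty=0.0,
            residual_variance=np.ones(a.shape[1]),
        )

    def test_zero_activity_zero_z(self):
        am = self._am(np.zeros((2, 5)), np.ones((2, 5)))
        assert (activity_zscores(am) == 0).all()

    def test_activity_equal_error_gives_one(self):
        a = np.full((1, 4), 0.3)
        am = self._am(a, a.copy())
        assert activity_zscores(am).iloc[0] == pytest.approx(1.0)

    def test_invariant_to_joint_scaling(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3, 8))
        se = rng.random((3, 8)) + 0.1
        z1 = activity_zscores(self._am(a, se))
        z2 = activity_zscores(self._am(5.5 * a, 5.5 * se))
        np.testing.assert_allclose(z1, z2)


class TestProfileStd:
    def test_flat_zero(self):
        assert profile_std(np.full(50, 0.123)) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_arithmetic(self):
        assert profile_std(np.array([0.0, 0.01])) == pytest.approx(0.005)

    def test_ramp_matches_bruteforce(self):
        ramp = np.linspace(0, 1, 50)
        assert profile_std(ramp) == pytest.approx(float(np.std(ramp)))

    def test_single_bin_errors(self):
        with pytest.raises(ValueError):
            profile_std(np.array([1.0]))


class TestLaggedCorrelation:
    def test_self_correlation(self):
        x = np.sin(np.linspace(0, 3 * np.pi, 60))
        lc = lagged_correlation(x, x, max_lag_bins=10)
        assert lc.peak_lag == 0
        assert lc.peak_rho == pytest.approx(1.0)
        assert lc.role == "activator"

    def test_negation_is_repressor(self):
        x = np.sin(np.linspace(0, 3 * np.pi, 60))
        lc = lagged_correlation(x, -x, max_lag_bins=10)
        assert lc.peak_rho == pytest.approx(-1.0)
        assert lc.role == "repressor"

    def test_shifted_signal_peak_at_exact_bin(self):
        t = np.linspace(0, 4 * np.pi, 80)
        x = np.sin(t)
        shifted = np.roll(x, 7)
        lc = lagged_correlation(x[10:70], shifted[10:70], max_lag_bins=12)
        assert lc.peak_lag == 7

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import uniform_filter1d

        x = uniform_filter1d(rng.normal(size=50), 7)
        y = uniform_filter1d(rng.normal(size=50), 7)
        lc1 = lagged_correlation(x, y, max_lag_bins=8)
        lc2 = lagged_correlation(y, x, max_lag_bins=8)
        assert lc1.peak_lag == -lc2.peak_lag
        assert lc1.peak_rho == pytest.approx(lc2.peak_rho)

    def test_short_overlap_lags_excluded(self):
        x = np.arange(8.0)
        lc = lagged_correlation(x, x, max_lag_bins=7, min_overlap=5)
        assert lc.lags.min() == -3 and lc.lags.max() == 3


def _corr(rho):
    return LaggedCorrelation(lags=np.array([0]), rho=np.array([rho]),
                             peak_lag=0, peak_rho=rho,
                             role="activator" if rho >= 0.7 else
                             ("repressor" if rho <= -0.7 else "none"))


class TestSelectDifferential:
    FATES = ("EC", "XMD", "LINKSD")

    def _inputs(self):
        z = pd.Series({"mA": 2.0, "mB": 1.39, "mC": 3.0})
        ramp = np.linspace(0, 0.05, 20)
        flat = np.zeros(20)
        profiles = {}
        corrs = {}
        for m in z.index:
            for f in self.FATES:
                profiles[(m, f)] = flat
                corrs[(m, f)] = _corr(0.0)
        profiles[("mA", "EC")] = ramp
        corrs[("mA", "EC")] = _corr(0.9)
        profiles[("mB", "XMD")] = ramp
        corrs[("mB", "XMD")] = _corr(0.95)
        profiles[("mC", "XMD")] = ramp
        corrs[("mC", "XMD")] = _corr(-0.8)   # repressor, passes on |rho|
        profiles[("mC", "LINKSD")] = ramp
        corrs[("mC", "LINKSD")] = _corr(0.85)
        return z, profiles, corrs

    def test_threshold_logic_and_boundaries(self):
        z, profiles, corrs = self._inputs()
        rep = select_differential(z, profiles, corrs, fates=self.FATES)
        by_motif = rep.set_index("motif")
        assert by_motif.loc["mA", "specificity"] == "EC"
        # z = 1.39 misses the >= 1.4 cut everywhere
        assert "mB" not in by_motif.index
        assert by_motif.loc["mC", "specificity"] == "XMD+LINKSD"

    def test_monotone_under_tightening(self):
        z, profiles, corrs = self._inputs()
        base = select_differential(z, profiles, corrs, fates=self.FATES)
        tight = select_differential(
            z, profiles, corrs,
            thresholds=DifferentialThresholds(2.5, 0.004, 0.7), fates=self.FATES,
        )
        base_pairs = {(r.motif, f) for r in base.itertuples() for f in r.fates}
        tight_pairs = {(r.motif, f) for r in tight.itertuples() for f in r.fates}
        assert tight_pairs <= base_pairs

    def test_missing_fate_fails_closed(self):
        z, profiles, corrs = self._inputs()
        del profiles[("mA", "EC")]
        with pytest.warns(UserWarning, match="missing"):
            rep = select_differential(z, profiles, corrs, fates=self.FATES)
        assert "mA" not in set(rep.get("motif", []))

    def test_category_counts_conserve_total(self):
        z, profiles, corrs = self._inputs()
        rep = select_differential(z, profiles, corrs, fates=self.FATES)
        cats = specificity_categories(rep, self.FATES)
        assert cats.sum() == len(rep)
        assert cats["EC"] == 1
        assert cats["XMD+LINKSD"] == 1


def test_activity_recovery_on_synthetic_default_snr(default_dataset):
    """Estimated activity time-courses (planted-pseudotime-binned branch
    curves) correlate >= 0.9 with the planted driver curves at the
    generator's default signal-to-noise."""
    ds = default_dataset
    bio = ~ds.adata.var["is_ercc"].to_numpy()
    counts = np.asarray(ds.adata.X)[:, bio]
    lognorm = np.log1p(counts / counts.sum(axis=1, keepdims=True) * 4000.0)
    am = fit_activities(lognorm.T, ds.truth.sites)
    t = ds.truth.pseudotime
    bins = np.minimum((t * 20).astype(int), 19)
    for motif, fate in ds.truth.driver_pairs:
        on_path = (ds.truth.branch == fate) | (ds.truth.branch == "Progenitor")
        est = am.activities.loc[motif].to_numpy()
        planted = ds.truth.activities.loc[motif].to_numpy()
        est_curve, planted_curve = [], []
        for b in range(20):
            mask = on_path & (bins == b)
            if mask.any():
                est_curve.append(est[mask].mean())
                planted_curve.append(planted[mask].mean())
        r = np.corrcoef(est_curve, planted_curve)[0, 1]
        assert r >= 0.9, (motif, r)
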