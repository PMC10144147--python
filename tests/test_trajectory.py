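"""Stage 2: age bins, rescaling, trajectory structures, fits and comparison."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from hrsgrowth.config import default_univariate_growth
from hrsgrowth.simulate import generate_score_panel
from hrsgrowth.trajectory import (BIN_LOWERS, TrajectorySpec, assign_age_bins,
                                  bin_column, build_trajectory_structure,
                                  compare_models, cumulative_change,
                                  fit_bivariate_trajectory, fit_trajectory,
                                  fit_univariate_trajectories, rescale_at_bin,
                                  time_code)
from tests.conftest import make_design


def scores_df(ages, cog=None, fnc=None, pid=None):
    n = len(ages)
    return pd.DataFrame({
        "pid": pid if pid is not None else np.arange(n),
        "age_years": ages,
        "cog_score": cog if cog is not None else np.zeros(n),
        "fnc_score": fnc if fnc is not None else np.zeros(n),
    })


@pytest.fixture(scope="module")
def bin_matrix(score_panel):
    panel, _ = score_panel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assign_age_bins(panel)


class TestAssignAgeBins:
    def test_edge_age_mapping(self):
        df = scores_df([50.0, 51.9, 85.9])
        mat = assign_age_bins(df)
        assert np.isfinite(mat.data.loc[0, "cog_b50"])
        assert np.isfinite(mat.data.loc[1, "cog_b50"])
        assert np.isfinite(mat.data.loc[2, "cog_b84"])

    def test_out_of_range_ages_dropped(self):
        df = scores_df([49.9, 86.0, 60.0])
        with pytest.warns(UserWarning, match="dropped 2"):
            mat = assign_age_bins(df)
        assert mat.n_dropped_age == 2
        assert mat.data.notna().sum().sum() == 2  # one person, both processes

    def test_eighteen_bins_per_process(self, bin_matrix):
        assert bin_matrix.n_bins == 18
        assert len(bin_matrix.data.columns) == 36
        assert [bin_column("COG", b) for b in BIN_LOWERS][0] == "cog_b50"

    def test_same_bin_occasions_averaged_with_warning(self):
        df = scores_df([60.0, 60.5], cog=[1.0, 3.0], fnc=[0.0, 0.0], pid=[7, 7])
        with pytest.warns(UserWarning, match="averaged"):
            mat = assign_age_bins(df)
        assert mat.data.loc[7, "cog_b60"] == pytest.approx(2.0)
        assert mat.n_averaged == 1

    def test_time_code_centered_at_70(self):
        codes = time_code(BIN_LOWERS)
        assert codes[BIN_LOWERS.index(70)] == 0.0
        assert codes[0] == -2.0
        assert codes[-1] == 1.4


class TestRescaleAtBin:
    def test_target_bin_standardized(self, bin_matrix):
        mat = rescale_at_bin(bin_matrix, 70)
        col = mat.data["cog_b70"]
        assert col.mean() == pytest.approx(0.0, abs=1e-10)
        assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_fit_statistics_invariant_to_rescaling(self, bin_matrix):
        spec = TrajectorySpec({"COG": "spline"}, knot_bin=70)
        r_raw = fit_trajectory(bin_matrix, spec, compute_se=False)
        r_std = fit_trajectory(rescale_at_bin(bin_matrix, 70), spec,
                               compute_se=False)
        assert r_std.chi2 == pytest.approx(r_raw.chi2, abs=1e-6)
        assert r_std.tli == pytest.approx(r_raw.tli, abs=1e-6)
        assert r_std.rmsea == pytest.approx(r_raw.rmsea, abs=1e-6)
        assert r_std.df == r_raw.df

    def test_slope_estimates_scale_by_inverse_target_sd(self, bin_matrix):
        spec = TrajectorySpec({"COG": "linear"})
        r_raw = fit_trajectory(bin_matrix, spec, compute_indices=False,
                               compute_se=False)
        rescaled = rescale_at_bin(bin_matrix, 70)
        sd70 = rescaled.scale_record["COG"][1]
        r_std = fit_trajectory(rescaled, spec, compute_indices=False,
                               compute_se=False)
        assert r_std.params["mean_COG_s"] == pytest.approx(
            r_raw.params["mean_COG_s"] / sd70, rel=1e-3)

    def test_empty_target_bin_rejected(self):
        df = scores_df([60.0, 61.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = assign_age_bins(df)
        with pytest.raises(ValueError, match="target bin"):
            rescale_at_bin(mat, 70)


class TestBuildTrajectoryStructure:
    def test_center_bin_loadings(self):
        st = build_trajectory_structure(TrajectorySpec({"COG": "spline"}))
        _, lam, _, _, _ = st.fill(st.default_start())
        i70 = BIN_LOWERS.index(70)
        assert np.allclose(lam[i70], [1.0, 0.0, 0.0])

    def test_bin_50_loadings(self):
        st = build_trajectory_structure(TrajectorySpec({"COG": "spline"}))
        _, lam, _, _, _ = st.fill(st.default_start())
        assert np.allclose(lam[0], [1.0, -2.0, 0.0])
        st_lin = build_trajectory_structure(TrajectorySpec({"COG": "linear"}))
        _, lam, _, _, _ = st_lin.fill(st_lin.default_start())
        assert np.allclose(lam[0], [1.0, -2.0])

    def test_bivariate_has_single_cross_residual_parameter(self):
        st = build_trajectory_structure(
            TrajectorySpec({"COG": "spline", "FNC": "linear"}))
        assert st.param_names.count("resid_cov") == 1
        assert len(st.assign["resid_cov"]) == 18
        # 23 free parameters as in the published bivariate spline+linear fit
        assert st.n_free == 23
        m = st.n_manifest
        assert m + m * (m + 1) // 2 - st.n_free == 679

    def test_invalid_knot_refused(self):
        with pytest.raises(ValueError, match="knot"):
            TrajectorySpec({"COG": "spline"}, knot_bin=58)

    def test_linear_equals_constrained_spline_loglik(self, bin_matrix):
        # a spline whose two slopes share mean/variance/covariances is the
        # linear model; impose the constraint by construction and compare
        from hrsgrowth.sem import MomentStructure, StructuralModel
        st_lin = build_trajectory_structure(TrajectorySpec({"COG": "linear"}))
        spec = TrajectorySpec({"COG": "spline"})
        st_sp = build_trajectory_structure(spec)
        lam_tied = st_sp.templates["lam"].copy()
        # tie the two slope columns into one -> reproduce linear loadings
        st_tied = MomentStructure(
            st_sp.manifest_names, ["COG_i", "COG_s"],
            nu=st_sp.templates["nu"],
            lam=np.array([[row[0], row[1] + row[2]] for row in lam_tied.astype(float)],
                         dtype=object),
            alpha=np.array(["mean_COG_i", "mean_COG_s"], dtype=object),
            psi=np.array([["var_COG_i", "c"], ["c", "var_COG_s"]], dtype=object),
            theta=st_sp.templates["theta"], psi_cholesky=True,
            positive={"resid_COG"})
        data = bin_matrix.data[st_lin.manifest_names]
        r_lin = StructuralModel(st_lin, data).fit(compute_se=False, compute_indices=False)
        r_tied = StructuralModel(st_tied, data).fit(compute_se=False, compute_indices=False)
        assert r_tied.llf == pytest.approx(r_lin.llf, abs=1e-4)

    def test_noise_free_limit_recovers_slopes_exactly(self):
        """Latent values on the bin grid regress back to the generating slopes."""
        growth = default_univariate_growth("COG")
        coeffs = np.array([growth.latent_means])
        from hrsgrowth.simulate import latent_value_at_age
        ages = np.array(BIN_LOWERS, dtype=float)
        vals = latent_value_at_age(np.repeat(coeffs, len(ages), axis=0), ages, growth)["COG"]
        s = time_code(BIN_LOWERS)
        X = np.column_stack([np.ones_like(s), np.minimum(s, 0), np.maximum(s, 0)])
        beta = np.linalg.lstsq(X, vals, rcond=None)[0]
        assert np.allclose(beta, growth.latent_means, atol=1e-12)


class TestFitUnivariate:
    def test_spline_beats_linear_on_spline_data(self, bin_matrix):
        fits = fit_univariate_trajectories(
            bin_matrix, "COG",
            specs=[TrajectorySpec({"COG": "intercept_only"}),
                   TrajectorySpec({"COG": "linear"}),
                   TrajectorySpec({"COG": "spline"}, knot_bin=70)],
            compute_se=False)
        aics = {k: r.aic for k, r in fits.items()}
        spline = aics["COG (spline KP=70/71)"]
        linear = aics["COG (linear)"]
        intercept = aics["COG (intercept-only)"]
        assert spline < linear < intercept

    def test_linear_data_makes_spline_equivalent(self):
        growth = default_univariate_growth("COG")
        lin = dataclasses.replace(
            growth, latent_names=("COG_i", "COG_s"),
            latent_means=(0.0, -0.1), latent_sds=(0.7, 0.3),
            latent_corr=((1.0, 0.3), (0.3, 1.0)))
        design = make_design(2500, seed=31, retention=(1.0, 1.0, 1.0))
        panel, _ = generate_score_panel(lin, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = assign_age_bins(panel, processes=("COG",))
        r_lin = fit_trajectory(mat, TrajectorySpec({"COG": "linear"}),
                               compute_indices=False, compute_se=False)
        r_sp = fit_trajectory(mat, TrajectorySpec({"COG": "spline"}),
                              compute_indices=False, compute_se=True)
        d_par = r_sp.n_params - r_lin.n_params
        assert r_sp.aic - r_lin.aic < 2 * d_par  # no real knot to find
        # the two spline slope means agree within their joint MC error
        idx = [r_sp.params.index.get_loc("mean_COG_s1"),
               r_sp.params.index.get_loc("mean_COG_s2")]
        cov = r_sp.cov_robust[np.ix_(idx, idx)]
        se_diff = np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        diff = r_sp.params["mean_COG_s1"] - r_sp.params["mean_COG_s2"]
        assert abs(diff) < 3 * se_diff


class TestBivariate:
    def test_block_diagonal_separability(self, bin_matrix):
        """With cross-process latent and residual covariances fixed at zero the
        bivariate fit reproduces the univariate COG spline estimates."""
        from hrsgrowth.sem import MomentStructure, StructuralModel
        spec = TrajectorySpec({"COG": "spline", "FNC": "linear"})
        st = build_trajectory_structure(spec)
        tpl = {k: st.templates[k].copy() for k in ("nu", "lam", "alpha", "psi", "theta")}
        psi = tpl["psi"]
        cog_idx = [0, 1, 2]
        for i in cog_idx:
            for j in range(3, 5):
                psi[i, j] = psi[j, i] = 0.0
        theta = tpl["theta"]
        theta[theta == "resid_cov"] = 0.0
        st0 = MomentStructure(st.manifest_names, st.latent_names, tpl["nu"],
                              tpl["lam"], tpl["alpha"], psi, theta,
                              psi_cholesky=False,
                              positive={"resid_COG", "resid_FNC"})
        st0.set_start(**{f"var_{n}": 0.5 for n in st.latent_names},
                      resid_COG=0.4, resid_FNC=0.4)
        r_biv = StructuralModel(st0, bin_matrix.data[st.manifest_names]).fit(
            compute_se=False, compute_indices=False)
        r_uni = fit_trajectory(bin_matrix, TrajectorySpec({"COG": "spline"}),
                               compute_indices=False, compute_se=False)
        for p in ("mean_COG_i", "mean_COG_s1", "mean_COG_s2", "var_COG_i",
                  "resid_COG"):
            assert r_biv.params[p] == pytest.approx(r_uni.params[p], abs=2e-3), p

    def test_bivariate_nests_linear_linear(self, bin_matrix):
        r_sl = fit_bivariate_trajectory(
            bin_matrix, TrajectorySpec({"COG": "spline", "FNC": "linear"}),
            compute_indices=False, compute_se=False)
        r_ll = fit_bivariate_trajectory(
            bin_matrix, TrajectorySpec({"COG": "linear", "FNC": "linear"}),
            compute_indices=False, compute_se=False)
        assert r_sl.llf >= r_ll.llf - 1e-6

    def test_requires_two_processes(self, bin_matrix):
        with pytest.raises(ValueError, match="two processes"):
            fit_bivariate_trajectory(bin_matrix, TrajectorySpec({"COG": "spline"}))


class TestCompareModels:
    def test_table_consistency(self, bin_matrix):
        fits = fit_univariate_trajectories(
            bin_matrix, "COG",
            specs=[TrajectorySpec({"COG": "linear"}),
                   TrajectorySpec({"COG": "spline"}, knot_bin=70)],
            compute_se=False)
        tab = compare_models(fits)
        for (_, row), (label, r) in zip(tab.iterrows(), sorted(
                fits.items(), key=lambda kv: -kv[1].df)):
            assert row.aic == pytest.approx(-2 * r.llf + 2 * r.n_params)
        nested = tab.iloc[1]
        assert nested.delta_chi2 >= -1e-6
        assert nested.delta_df > 0
        assert tab.attrs["best"] == "COG (spline KP=70/71)"

    def test_mixed_datasets_refused(self, bin_matrix, score_panel):
        panel, _ = score_panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            other = assign_age_bins(panel.iloc[: len(panel) // 2])
        a = fit_trajectory(bin_matrix, TrajectorySpec({"COG": "linear"}),
                           compute_indices=False, compute_se=False)
        b = fit_trajectory(other, TrajectorySpec({"COG": "linear"}),
                           compute_indices=False, compute_se=False)
        with pytest.raises(ValueError, match="identical data"):
            compare_models({"a": a, "b": b})


class TestPlotting:
    def test_spaghetti_plot_smoke(self, bin_matrix):
        from hrsgrowth.plotting import plot_trajectories
        r = fit_trajectory(bin_matrix, TrajectorySpec({"COG": "spline"}),
                           compute_indices=False, compute_se=False)
        ax = plot_trajectories(r, bin_matrix, "COG", n_persons=25)
        assert len(ax.lines) > 1  # individuals + group average


class TestCumulativeChange:
    def test_decade_arithmetic(self):
        ch = cumulative_change((-0.027, -0.187))
        assert ch["50_70"] == pytest.approx(-0.054)
        assert ch["70_85"] == pytest.approx(-0.2805)

    def test_from_fitted_result(self, bin_matrix):
        r = fit_trajectory(bin_matrix, TrajectorySpec({"COG": "spline"}),
                           compute_indices=False, compute_se=False)
        ch = cumulative_change(r, "COG")
        assert ch["50_70"] == pytest.approx(2.0 * r.params["mean_COG_s1"])
        assert ch["70_85"] == pytest.approx(1.5 * r.params["mean_COG_s2"])
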