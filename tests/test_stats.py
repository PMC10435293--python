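"""ROI means, quadratic age regression, FDR, and NfL association."""

import numpy as np
import pandas as pd
import pytest

from cnoddi.simulate import make_cohort
from cnoddi.stats import fdr_adjust, nfl_association, quadratic_age_fit, roi_means


def bh_bruteforce(p):
    """Textbook Benjamini-Hochberg: sort, scale by m/rank, cummin from top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ols_normal_equations(design, y):
    """Independent OLS oracle: solve the normal equations directly."""
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    return beta, se


class TestRoiMeans:
    def test_constant_map(self):
        labels = np.array([[[1, 1], [2, 2]]])
        means = roi_means(np.full((1, 2, 2), 0.5), labels)
        assert means == {1: 0.5, 2: 0.5}

    def test_two_voxel_mean(self):
        labels = np.array([[[1, 1]]])
        means = roi_means(np.array([[[0.2, 0.6]]]), labels)
        assert means[1] == pytest.approx(0.4)

    def test_region_constants_exact(self):
        labels = np.zeros((4, 4, 2), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        values = np.where(labels == 1, 0.7, 0.3)
        means = roi_means(values, labels)
        assert means == {1: 0.7, 2: 0.3}

    def test_all_nan_roi_warns(self):
        labels = np.array([[[1, 2]]])
        values = np.array([[[np.nan, 1.0]]])
        with pytest.warns(UserWarning, match="no valid voxels"):
            means = roi_means(values, labels)
        assert np.isnan(means[1])


class TestQuadraticAgeFit:
    def _exact_table(self, beta_age=0.002, beta_age2=-4e-4, beta_sex=0.01,
                     intercept=0.6):
        ages = np.linspace(20, 80, 24)
        sexes = np.tile([0, 1], 12)
        mean_age = ages.mean()
        ndi = (intercept + beta_age * (ages - mean_age)
               + beta_age2 * (ages - mean_age) ** 2 + beta_sex * sexes)
        return pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(24)], "age": ages,
             "sex": sexes, "roi": "WB", "mean_ndi": ndi, "mean_odi": 0.3}
        ), mean_age

    def test_exact_parabola_recovered(self):
        table, mean_age = self._exact_table()
        rep = quadratic_age_fit(table, "ndi")
        row = rep.table.loc["WB"]
        assert row.beta_age == pytest.approx(0.002, abs=1e-10)
        assert row.beta_age2 == pytest.approx(-4e-4, abs=1e-10)
        assert row.beta_sex == pytest.approx(0.01, abs=1e-10)
        vertex = mean_age - 0.002 / (2 * -4e-4)
        assert row.peak_age == pytest.approx(vertex, abs=1e-8)

    def test_zero_linear_term_peaks_at_mean_age(self):
        table, mean_age = self._exact_table(beta_age=0.0)
        rep = quadratic_age_fit(table, "ndi")
        assert rep.table.loc["WB", "peak_age"] == pytest.approx(mean_age)

    def test_convex_fit_reports_missing_peak(self):
        table, _ = self._exact_table(beta_age2=+4e-4)
        rep = quadratic_age_fit(table, "ndi")
        assert np.isnan(rep.table.loc["WB", "peak_age"])

    def test_collinear_design_named(self):
        table, _ = self._exact_table()
        table["sex"] = 1  # constant column collinear with intercept
        with pytest.raises(ValueError, match="sex"):
            quadratic_age_fit(table, "ndi")

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        n = 10
        ages = rng.uniform(20, 80, n)
        sexes = rng.integers(0, 2, n)
        y = rng.normal(0.5, 0.05, n)
        table = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "age": ages,
             "sex": sexes, "roi": "WB", "mean_ndi": y, "mean_odi": 0.3}
        )
        rep = quadratic_age_fit(table, "ndi")
        age_c = ages - ages.mean()
        design = np.column_stack([np.ones(n), age_c, age_c**2, sexes])
        beta, _ = ols_normal_equations(design, y)
        row = rep.table.loc["WB"]
        np.testing.assert_allclose(
            [row.intercept, row.beta_age, row.beta_age2, row.beta_sex],
            beta, atol=1e-8,
        )


class TestFdr:
    def test_hand_computed_example(self):
        adjusted, reject = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])
        assert reject.all()

    def test_identical_pvalues_unchanged(self):
        adjusted, _ = fdr_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(adjusted, 0.2)

    def test_monotone_in_raw_order(self, rng):
        p = rng.random(50)
        adjusted, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 30))
            adjusted, _ = fdr_adjust(p)
            np.testing.assert_allclose(adjusted, bh_bruteforce(p), atol=1e-12)

    def test_empty_input(self):
        adjusted, reject = fdr_adjust([])
        assert adjusted.size == 0 and reject.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestNflAssociation:
    def test_zscore_standardization(self):
        df = make_cohort(n_subjects=50, seed=2)
        sub = df[df.roi == "WB"]
        z = np.log(sub["nfl"])
        z = (z - z.mean()) / z.std(ddof=0)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_negative_coupling_detected(self):
        df = make_cohort(n_subjects=200, seed=6)
        res = nfl_association(df, roi="WB")
        assert res["beta_ndi"] < 0
        assert res["p_ndi"] < 0.05

    def test_zero_coupling_calibration(self):
        """With NfL independent of NDI, the CI covers 0 in >= 90% of runs."""
        import statsmodels.api as sm

        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            df = make_cohort(n_subjects=50, nfl_coupling=0.0, rois=("WB",),
                             seed=2000 + rep)
            sub = df[df.roi == "WB"]
            z_nfl = np.log(sub["nfl"].to_numpy())
            z_nfl = (z_nfl - z_nfl.mean()) / z_nfl.std()
            z_ndi = sub["mean_ndi"].to_numpy()
            z_ndi = (z_ndi - z_ndi.mean()) / z_ndi.std()
            design = np.column_stack(
                [np.ones(len(sub)), z_ndi, sub["age"], sub["sex"]]
            )
            lo, hi = sm.OLS(z_nfl, design).fit().conf_int()[1]
            covered += lo <= 0.0 <= hi
        assert covered >= 0.90 * n_rep

    def test_nonpositive_nfl_excluded_with_warning(self):
        df = make_cohort(n_subjects=30, seed=3)
        df.loc[df.index[df.roi == "WB"][:2], "nfl"] = -1.0
        with pytest.warns(UserWarning, match="excluding"):
            res = nfl_association(df, roi="WB")
        assert res["n"] == 28
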