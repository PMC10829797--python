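"""Quantification preprocessing: oracles, boundaries, and invariants."""

import numpy as np
import pandas as pd
import pytest

from proteosubtype import preprocess as pp
from proteosubtype.types import OmicsMatrix, ReporterIntensityTable

from conftest import make_matrix


class TestRelativeAbundance:
    def test_hand_arithmetic(self):
        table = ReporterIntensityTable(
            pd.DataFrame(
                {"s1": [4.0, 8.0], "s2": [1.0, 2.0], "ref": [2.0, 2.0]},
                index=["f1", "f2"],
            ),
            reference_channel="ref",
        )
        out = pp.relative_abundance(table)
        # f1: log2([2, 0.5]) = [1, -1], already centered
        np.testing.assert_allclose(out.values.loc["f1"], [1.0, -1.0])
        # f2: log2([4, 1]) = [2, 0] -> centered [1, -1]
        np.testing.assert_allclose(out.values.loc["f2"], [1.0, -1.0])

    def test_equal_to_reference_gives_zeros(self):
        table = ReporterIntensityTable(
            pd.DataFrame({"s1": [3.0], "s2": [3.0], "ref": [3.0]}, index=["f1"]),
            reference_channel="ref",
        )
        np.testing.assert_allclose(pp.relative_abundance(table).values, 0.0)

    def test_zero_reference_flags_feature_na(self):
        table = ReporterIntensityTable(
            pd.DataFrame({"s1": [4.0, 4.0], "ref": [0.0, 2.0]}, index=["f1", "f2"]),
            reference_channel="ref",
        )
        out = pp.relative_abundance(table)
        assert out.values.loc["f1"].isna().all()
        assert out.values.loc["f2"].notna().all()

    def test_rows_are_zero_centered(self):
        rng = np.random.default_rng(0)
        table = ReporterIntensityTable(
            pd.DataFrame(
                rng.uniform(1, 100, size=(20, 6)),
                index=[f"f{i}" for i in range(20)],
                columns=[f"s{i}" for i in range(5)] + ["ref"],
            ),
            reference_channel="ref",
        )
        out = pp.relative_abundance(table)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-9)


class TestFilterMissingness:
    def test_boundary_inclusive(self):
        m = make_matrix(
            [
                [1, np.nan, np.nan, np.nan],  # 3/4 missing -> removed
                [1, 2, np.nan, np.nan],  # exactly 2/4 -> retained
                [1, 2, 3, 4],
            ]
        )
        out = pp.filter_missingness(m, 0.5)
        assert list(out.features) == ["F2", "F3"]

    def test_values_and_order_untouched(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 8))
        x[rng.uniform(size=x.shape) < 0.3] = np.nan
        m = make_matrix(x)
        out = pp.filter_missingness(m, 0.4)
        pd.testing.assert_frame_equal(out.values, m.values.loc[out.features])

    def test_monotone_in_strictness(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 10))
        x[rng.uniform(size=x.shape) < 0.4] = np.nan
        m = make_matrix(x)
        counts = [
            pp.filter_missingness(m, f).n_features for f in (0.1, 0.3, 0.5, 0.9)
        ]
        assert counts == sorted(counts)


class TestMedianPolish:
    def test_two_by_two_exact(self):
        out = pp.median_polish(make_matrix([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_zeros_stay_zero(self):
        out = pp.median_polish(make_matrix(np.zeros((3, 4))))
        np.testing.assert_allclose(out.values, 0.0)

    def test_residual_medians_near_zero_and_idempotent(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(20, 10)))
        out = pp.median_polish(m, tol=1e-10)
        assert np.abs(np.median(out.values, axis=1)).max() < 1e-8
        assert np.abs(np.median(out.values, axis=0)).max() < 1e-8
        again = pp.median_polish(out, tol=1e-10)
        np.testing.assert_allclose(again.values, out.values, atol=1e-7)

    def test_na_entries_ignored_and_preserved(self):
        m = make_matrix([[1.0, np.nan, 3.0], [2.0, 5.0, np.nan], [0.0, 1.0, 2.0]])
        out = pp.median_polish(m)
        assert out.values.isna().equals(m.values.isna())

    def test_center_mode_single_sweep(self):
        m = make_matrix([[1.0, 2.0, 6.0], [3.0, 4.0, 8.0]])
        out = pp.median_polish(m, mode="center")
        # one row sweep then one column sweep, by hand
        expect = np.array([[-1.0, 0.0, 4.0], [-1.0, 0.0, 4.0]])
        expect[:, :] -= np.median(expect, axis=0)
        np.testing.assert_allclose(out.values, expect)


class TestPlexCompletenessFilter:
    @pytest.fixture
    def setup(self):
        ann = pd.DataFrame(
            {"plex": ["p1", "p1", "p2", "p2", "p3", "p3"]},
            index=[f"S{i + 1}" for i in range(6)],
        )
        m = make_matrix(
            [
                [1, 2, 3, 4, 5, 6],  # all plexes observed
                [1, 2, np.nan, np.nan, 5, 6],  # p2 fully missing
                [1, 2, np.nan, 4, 5, 6],  # p2 partially observed
            ]
        )
        return m, ann

    def test_strict_and_relaxed(self, setup):
        m, ann = setup
        strict = pp.plex_completeness_filter(m, ann, 0)
        assert list(strict.features) == ["F1", "F3"]
        relaxed = pp.plex_completeness_filter(m, ann, 1)
        assert list(relaxed.features) == ["F1", "F2", "F3"]

    def test_unknown_plex_errors(self, setup):
        m, _ = setup
        ann = pd.DataFrame({"plex": ["p1"] * 5}, index=[f"S{i + 1}" for i in range(5)])
        with pytest.raises(ValueError, match="plex"):
            pp.plex_completeness_filter(m, ann, 0)


class TestKnnImpute:
    def test_identical_neighbor_k1(self):
        m = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0]])
        out = pp.knn_impute(m, k=1)
        assert out.values.loc["F2", "S3"] == 3.0

    def test_no_na_identity(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(pp.knn_impute(m, k=2).values, m.values)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 6))
        x[2, 3] = np.nan
        m = make_matrix(x)
        out = pp.knn_impute(m, k=2)
        # exhaustive neighbor search over co-observed Euclidean distance
        dists = []
        for f in range(5):
            if f == 2:
                continue
            mask = ~np.isnan(x[f]) & ~np.isnan(x[2])
            dists.append((np.sqrt(np.sum((x[f, mask] - x[2, mask]) ** 2)), f))
        best = sorted(dists)[:2]
        expect = np.mean([x[f, 3] for _, f in best])
        assert out.values.iloc[2, 3] == pytest.approx(expect)

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 8))
        x[rng.uniform(size=x.shape) < 0.2] = np.nan
        m = make_matrix(x)
        out = pp.knn_impute(m, k=3)
        obs = ~np.isnan(x)
        np.testing.assert_array_equal(out.values.to_numpy()[obs], x[obs])
        assert not out.values.isna().any().any()


class TestEBCorrection:
    def _ann(self, n, plexes=2, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "plex": [f"p{i % plexes}" for i in range(n)],
                "loading_mass": rng.uniform(30, 70, n),
            },
            index=[f"S{i + 1}" for i in range(n)],
        )

    def test_planted_slope_removed(self):
        n = 40
        ann = self._ann(n)
        mass = ann["loading_mass"].to_numpy()
        x = np.vstack([2.0 * mass + 5.0, 2.0 * mass - 1.0, 0.5 * mass])
        m = make_matrix(x, samples=list(ann.index))
        out = pp.eb_covariate_correction(m, ann, ["loading_mass"])
        mc = mass - mass.mean()
        for f in range(3):
            # residual regression slope on loading mass vanishes
            slope = out.values.iloc[f].to_numpy() @ mc / (mc @ mc)
            assert abs(slope) < 1e-6

    def test_no_shrink_matches_ols_residualization(self):
        rng = np.random.default_rng(6)
        n = 30
        ann = self._ann(n, seed=6)
        x = rng.normal(size=(8, n))
        m = make_matrix(x, samples=list(ann.index))
        out = pp.eb_covariate_correction(m, ann, ["loading_mass", "plex"], shrink=False)
        # per-feature OLS oracle with intercept
        mass = ann["loading_mass"].to_numpy()
        plex = (ann["plex"] == "p1").to_numpy(dtype=float)
        D = np.column_stack([np.ones(n), (mass - mass.mean()) / mass.std(ddof=1),
                             plex - plex.mean()])
        for f in range(8):
            beta, *_ = np.linalg.lstsq(D, x[f], rcond=None)
            resid_plus_mean = x[f] - D[:, 1:] @ beta[1:]
            np.testing.assert_allclose(
                out.values.iloc[f].to_numpy(), resid_plus_mean, atol=1e-8
            )

    def test_categorical_no_shrink_equals_level_centering(self):
        ann = pd.DataFrame(
            {"plex": ["a", "a", "b", "b"]}, index=[f"S{i + 1}" for i in range(4)]
        )
        x = np.array([[1.0, 3.0, 10.0, 14.0]])
        m = make_matrix(x, samples=list(ann.index))
        out = pp.eb_covariate_correction(m, ann, ["plex"], shrink=False)
        centered = np.array([1.0, 3.0, 10.0, 14.0])
        centered[:2] -= 2.0  # level a mean
        centered[2:] -= 12.0  # level b mean
        np.testing.assert_allclose(
            out.values.to_numpy()[0], centered + x.mean(), atol=1e-8
        )

    def test_feature_means_preserved(self, small_cohort):
        m = pp.knn_impute(
            pp.filter_missingness(small_cohort.omics["protein"]), k=5
        )
        out = pp.eb_covariate_correction(
            m, small_cohort.annotation, ["loading_mass", "plex"]
        )
        np.testing.assert_allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), atol=1e-8
        )

    def test_reduces_mass_correlation_for_every_feature(self, small_cohort):
        cohort = small_cohort
        m = pp.knn_impute(pp.filter_missingness(cohort.omics["protein"]), k=5)
        out = pp.eb_covariate_correction(
            m, cohort.annotation, ["loading_mass", "plex"]
        )
        mass = cohort.annotation["loading_mass"].to_numpy()

        def abscorr(df):
            z = df.to_numpy()
            zc = z - z.mean(axis=1, keepdims=True)
            mc = mass - mass.mean()
            return np.abs(
                (zc @ mc)
                / np.sqrt((zc**2).sum(axis=1) * (mc**2).sum())
            )

        assert (abscorr(out.values) <= abscorr(m.values) + 1e-9).all()


class TestCovariateScan:
    def test_exact_linear_function_p_zero(self):
        ann = pd.DataFrame(
            {"loading_mass": np.linspace(30, 70, 20)},
            index=[f"S{i + 1}" for i in range(20)],
        )
        m = make_matrix(
            [3.0 * ann["loading_mass"].to_numpy() + 1.0], samples=list(ann.index)
        )
        p, _, frac = pp.covariate_effect_scan(m, ann, "loading_mass")
        assert p.iloc[0] < 1e-12
        assert frac == 1.0

    def test_null_controls_fdr(self):
        rng = np.random.default_rng(8)
        n = 50
        ann = pd.DataFrame(
            {"loading_mass": rng.uniform(30, 70, n)},
            index=[f"S{i + 1}" for i in range(n)],
        )
        m = make_matrix(rng.normal(size=(1000, n)), samples=list(ann.index))
        _, _, frac = pp.covariate_effect_scan(m, ann, "loading_mass")
        assert frac <= 0.07

    def test_constant_covariate_errors(self):
        ann = pd.DataFrame(
            {"loading_mass": [50.0] * 10}, index=[f"S{i + 1}" for i in range(10)]
        )
        m = make_matrix(np.random.default_rng(9).normal(size=(5, 10)),
                        samples=list(ann.index))
        with pytest.raises(ValueError, match="constant"):
            pp.covariate_effect_scan(m, ann, "loading_mass")

    def test_phospho_inherits_global_loading_offsets(self):
        """Phospho loading normalization subtracts per-sample global medians."""
        rng = np.random.default_rng(11)
        g = make_matrix(rng.normal(size=(20, 6)) + np.arange(6), modality="protein")
        p = make_matrix(rng.normal(size=(10, 6)), modality="phospho")
        out = pp.apply_global_loading_normalization(p, g)
        offsets = g.values.median(axis=0)
        np.testing.assert_allclose(
            out.values.to_numpy(), (p.values - offsets).to_numpy(), atol=1e-12
        )

    def test_categorical_plex_scan(self, small_cohort):
        m = pp.knn_impute(pp.filter_missingness(small_cohort.omics["mrna"]), k=5)
        p, adj, frac = pp.covariate_effect_scan(m, small_cohort.annotation, "plex")
        assert ((p >= 0) & (p <= 1)).all()
        assert 0.0 <= frac <= 1.0
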