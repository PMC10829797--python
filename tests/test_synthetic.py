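"""Synthetic cohort generator: determinism, planted structure, contracts."""

import numpy as np
import pandas as pd
import pytest

from proteosubtype.synthetic import (
    DrugSpec,
    SyntheticConfig,
    generate_cohort,
    generate_drug_response,
    generate_pathway_resources,
    generate_resistance_trajectory,
)


def _clean_config(**kw):
    base = dict(
        n_samples=40,
        k_true=2,
        n_features={"mrna": 10, "protein": 10, "phospho": 10},
        noise_sd=0.0,
        missing_rate=0.0,
        mnar_strength=0.0,
        plex_offset_sd=0.0,
        loading_mass_slope_sd=0.0,
        n_plexes=2,
        mutation_rates={"FLT3_ITD": [0.2, 0.6]},
        survival_hazards=[1.0, 2.0],
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerateCohort:
    def test_zero_noise_limit(self):
        cohort = generate_cohort(_clean_config())
        for mod, m in cohort.omics.items():
            for subtype in (1, 2):
                cols = cohort.truth_labels[cohort.truth_labels == subtype].index
                within_var = m.values[cols].var(axis=1, ddof=0)
                np.testing.assert_allclose(within_var, 0.0, atol=1e-20)

    def test_determinism(self):
        cfg = SyntheticConfig(n_samples=50, seed=123,
                              n_features={"mrna": 20, "protein": 20, "phospho": 20})
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for mod in c1.omics:
            pd.testing.assert_frame_equal(c1.omics[mod].values, c2.omics[mod].values)
        pd.testing.assert_frame_equal(c1.annotation, c2.annotation)
        pd.testing.assert_frame_equal(c1.drugs, c2.drugs)
        pd.testing.assert_series_equal(c1.truth_labels, c2.truth_labels)

    def test_planted_subtype_separation_silhouette(self):
        from sklearn.metrics import silhouette_score

        cfg = SyntheticConfig(n_samples=160, k_true=4, seed=5)
        cohort = generate_cohort(cfg)
        mu = cohort.truth_effects["protein"].to_numpy()
        profiles = mu[:, cohort.truth_labels.to_numpy() - 1].T
        score = silhouette_score(profiles, cohort.truth_labels.to_numpy())
        assert score > 0.5

    def test_matrices_share_sample_axis(self, small_cohort):
        samples = small_cohort.annotation.index
        for m in small_cohort.omics.values():
            assert list(m.samples) == list(samples)
        assert list(small_cohort.drugs.index) == list(samples)
        assert set(small_cohort.truth_labels.unique()) == {1, 2, 3}

    def test_mutations_enriched_in_planted_subtype(self, default_cohort):
        ann, labels = default_cohort.annotation, default_cohort.truth_labels
        rate_s2 = ann.loc[labels == 2, "FLT3_ITD"].mean()
        rate_rest = ann.loc[labels != 2, "FLT3_ITD"].mean()
        assert rate_s2 > rate_rest

    def test_mnar_raises_missingness_at_low_abundance(self):
        cfg = SyntheticConfig(
            n_samples=100, missing_rate=0.0, mnar_strength=0.4, seed=3
        )
        cohort = generate_cohort(cfg)
        m = cohort.omics["protein"].values.to_numpy()
        # regenerate the complete matrix: missing entries were low-abundance
        na = np.isnan(m)
        assert na.mean() > 0.02
        observed_mean = np.nanmean(m)
        cfg0 = SyntheticConfig(
            n_samples=100, missing_rate=0.0, mnar_strength=0.0, seed=3
        )
        full = generate_cohort(cfg0).omics["protein"].values.to_numpy()
        assert np.nanmean(full) < observed_mean  # dropout removed low values

    @pytest.mark.parametrize(
        "kw", [
            {"k_true": 1},
            {"missing_rate": 1.5},
            {"mnar_strength": -1.0},
            {"n_plexes": 0},
            {"mutation_rates": {"FLT3_ITD": [0.5]}},
            {"survival_hazards": [1.0]},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            generate_cohort(_clean_config(**kw))


class TestDrugResponse:
    def _labels(self, n=30, k=3, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(n)]
        labels = pd.Series(rng.integers(1, k + 1, n), index=idx)
        muts = pd.DataFrame({"FLT3_ITD": rng.integers(0, 2, n)}, index=idx)
        return labels, muts

    def test_noiseless_baseline(self):
        labels, muts = self._labels()
        t = generate_drug_response(
            labels, muts, [DrugSpec("d", 150.0, {}, {}, 0.0, 1.0)], seed=0
        )
        np.testing.assert_allclose(t["d"], 150.0)

    def test_clamped_to_upper_bound(self):
        labels, muts = self._labels(seed=1)
        t = generate_drug_response(
            labels, muts, [DrugSpec("d", 400.0, {}, {}, 0.0, 1.0)], seed=0
        )
        np.testing.assert_allclose(t["d"], 300.0)

    def test_subtype_shift_lowers_group_mean(self):
        labels, muts = self._labels(n=200, seed=2)
        t = generate_drug_response(
            labels, muts, [DrugSpec("d", 200.0, {2: -80.0}, {}, 10.0, 1.0)], seed=0
        )
        assert t.loc[labels == 2, "d"].mean() < t.loc[labels != 2, "d"].mean() - 40

    def test_sparsity_fraction(self):
        labels, muts = self._labels(n=500, seed=3)
        t = generate_drug_response(
            labels, muts, [DrugSpec("d", 150.0, {}, {}, 5.0, 0.6)], seed=0
        )
        assert t["d"].notna().mean() == pytest.approx(0.6, abs=0.07)

    def test_empty_specs_error(self):
        labels, muts = self._labels()
        with pytest.raises(ValueError, match="nonempty"):
            generate_drug_response(labels, muts, [], seed=0)


class TestPathwayResources:
    def test_single_set_of_requested_size(self):
        ids = [f"F{i}" for i in range(20)]
        sets, _ = generate_pathway_resources(ids, n_sets=1, set_size=(5, 5), seed=0)
        assert len(sets) == 1
        members = next(iter(sets.values()))
        assert len(members) == 5 and set(members) <= set(ids)

    def test_seeded_reproducibility(self):
        ids = [f"F{i}" for i in range(50)]
        a = generate_pathway_resources(ids, seed=9)
        b = generate_pathway_resources(ids, seed=9)
        assert a == b

    def test_every_kinase_has_substrates(self):
        ids = [f"PHOS_{i}" for i in range(60)]
        _, kin = generate_pathway_resources(ids, n_kinases=12, seed=1)
        assert len(kin) == 12
        assert all(len(v) >= 1 for v in kin.values())

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError, match="set size"):
            generate_pathway_resources(["a", "b"], set_size=(5, 10))


class TestTrajectory:
    def test_column_count_and_stage_labels(self, small_cohort):
        traj = generate_resistance_trajectory(
            small_cohort, 2, 3, n_stages=4, n_reps=4, seed=0
        )
        for m in traj.omics.values():
            assert m.n_samples == 16
        assert traj.stages.value_counts().eq(4).all()

    def test_endpoints_match_subtype_profiles(self, small_cohort):
        traj = generate_resistance_trajectory(
            small_cohort, 1, 3, n_stages=3, n_reps=2, noise_sd=0.0, seed=0
        )
        eff = small_cohort.truth_effects["protein"]
        first = traj.omics["protein"].values.iloc[:, 0]
        last = traj.omics["protein"].values.iloc[:, -1]
        np.testing.assert_allclose(first, eff.iloc[:, 0], atol=1e-12)
        np.testing.assert_allclose(last, eff.iloc[:, 2], atol=1e-12)

    def test_classifier_recovers_trajectory_endpoints(
        self, small_cohort, protein_phospho_small, small_labels
    ):
        from proteosubtype import classifier as clf

        model = clf.fit_multinomial_elasticnet(
            protein_phospho_small, small_labels, alpha=0.9, lam=0.02, seed=0
        )
        # map consensus label ids onto planted ids via majority vote
        mapping = {
            c: int(small_cohort.truth_labels[small_labels == c].mode()[0])
            for c in small_labels.unique()
        }
        inv = {v: k for k, v in mapping.items()}
        traj = generate_resistance_trajectory(
            small_cohort, from_subtype=1, to_subtype=2, n_stages=3, n_reps=4, seed=1
        )
        both = pd.concat(
            [traj.omics["protein"].values, traj.omics["phospho"].values]
        )
        from proteosubtype.types import OmicsMatrix

        _, pred = clf.predict_proba(model, OmicsMatrix(both))
        first_stage = pred[traj.stages == 0]
        last_stage = pred[traj.stages == 2]
        assert (first_stage == inv[1]).mean() > 0.5
        assert (last_stage == inv[2]).mean() > 0.5

    @pytest.mark.parametrize("kw", [{"n_stages": 1}, {"from_subtype": 9}])
    def test_invalid_arguments(self, small_cohort, kw):
        args = dict(from_subtype=1, to_subtype=2, n_stages=3)
        args.update(kw)
        with pytest.raises(ValueError):
            generate_resistance_trajectory(small_cohort, **args)


def test_loading_mass_scan_null_vs_planted():
    """Mass-effect scan flags most features when slopes are planted and
    about the nominal rate when they are not."""
    from proteosubtype import preprocess as pp

    cfg = SyntheticConfig(n_samples=120, seed=21,
                          n_features={"mrna": 300, "protein": 300, "phospho": 300})
    cohort = generate_cohort(cfg)
    m = pp.knn_impute(pp.filter_missingness(cohort.omics["protein"]), k=5)
    _, _, frac = pp.covariate_effect_scan(m, cohort.annotation, "loading_mass")
    assert frac >= 0.9

    cfg0 = SyntheticConfig(
        n_samples=120, seed=21, loading_mass_slope_sd=0.0,
        n_features={"mrna": 300, "protein": 300, "phospho": 300},
    )
    cohort0 = generate_cohort(cfg0)
    m0 = pp.knn_impute(pp.filter_missingness(cohort0.omics["protein"]), k=5)
    _, _, frac0 = pp.covariate_effect_scan(m0, cohort0.annotation, "loading_mass")
    assert frac0 <= 0.07
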