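"""Synthetic cohort generator: structure, trait calibration, volumes."""

import numpy as np
import pandas as pd
import pytest

from twinmorph import (ClusterSpec, CohortConfig, ConfigurationError,
                       TraitSpec, assign_medication, build_covariate_matrix,
                       adjusted_regression, default_trait_specs,
                       generate_cohort, generate_volume_maps,
                       simulate_ace_latent, simulate_ace_pairs,
                       voxelwise_glm)


class TestStructure:
    def test_study_scale_counts(self):
        """The full-size configuration reproduces the emulated cohort shape:
        634 MZ and 2,826 DZ/sibling subjects out of 11,502."""
        cfg = CohortConfig(n_subjects=11502, n_mz_pairs=317, n_dz_pairs=1413,
                           seed=0, trait_specs=[])
        df = generate_cohort(cfg)
        assert len(df) == 11502
        assert (df.zygosity == "MZ").sum() == 634
        assert (df.zygosity == "DZ").sum() == 2826
        frac_f = (df.sex == "F").mean()
        assert frac_f == pytest.approx(5464 / 11502, abs=0.02)

    def test_empty_cohort(self):
        df = generate_cohort(CohortConfig(n_subjects=0, n_mz_pairs=0,
                                          n_dz_pairs=0))
        assert len(df) == 0

    def test_determinism(self):
        cfg = CohortConfig(n_subjects=300, n_mz_pairs=20, n_dz_pairs=40,
                           seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigurationError, match="exceeds"):
            CohortConfig(n_subjects=10, n_mz_pairs=3, n_dz_pairs=3).validate()

    def test_mz_cotwins_share_family_and_sex(self, small_cohort):
        mz = small_cohort[small_cohort.zygosity == "MZ"]
        for _, grp in mz.groupby("family_id"):
            assert len(grp) == 2
            assert grp.sex.nunique() == 1
            assert grp.age_months.nunique() == 1
            assert grp.site_id.nunique() == 1

    def test_floor_and_positivity_invariants(self, small_cohort):
        assert (small_cohort.adhd_t >= 50.0).all()
        assert (small_cohort.adhd_t <= 80.0).all()
        assert (small_cohort.tiv > 0).all()
        assert small_cohort.nback2_acc.between(0, 100).all()


class TestAceStructure:
    def test_perfect_heritability_makes_mz_twins_identical(self, rng):
        zyg = np.array(["MZ", "MZ", "MZ", "MZ"])
        fam = np.array(["a", "a", "b", "b"])
        lat = simulate_ace_latent(zyg, fam, 1.0, 0.0, 0.0, rng)
        assert lat[0] == lat[1] and lat[2] == lat[3]

    def test_pure_noise_gives_uncorrelated_mz_pairs(self):
        r = np.random.default_rng(3)
        mz, _ = simulate_ace_pairs(10_000, 0, 0.0, 0.0, 1.0, r)
        assert abs(np.corrcoef(mz[:, 0], mz[:, 1])[0, 1]) < 0.03

    def test_twin_correlations_converge_to_ace_expectations(self):
        """r_MZ -> a2 + c2 and r_DZ -> 0.5 a2 + c2 (10,000 pairs, tol 0.02)."""
        r = np.random.default_rng(10)
        a2, c2, e2 = 0.5, 0.2, 0.3
        mz, dz = simulate_ace_pairs(10_000, 10_000, a2, c2, e2, r)
        r_mz = np.corrcoef(mz[:, 0], mz[:, 1])[0, 1]
        r_dz = np.corrcoef(dz[:, 0], dz[:, 1])[0, 1]
        assert r_mz == pytest.approx(a2 + c2, abs=0.02)
        assert r_dz == pytest.approx(0.5 * a2 + c2, abs=0.02)

    def test_negative_component_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            simulate_ace_pairs(10, 10, -0.1, 0.4, 0.7, rng)


@pytest.fixture(scope="module")
def big_boys_cohort():
    cfg = CohortConfig(n_subjects=50_000, frac_female=0.0, n_mz_pairs=0,
                       n_dz_pairs=0, seed=101)
    return generate_cohort(cfg)


class TestTraitCalibration:
    def test_moment_matching_per_sex(self):
        """Realized mean and SD per sex within 1% of spec at n = 50,000."""
        cfg = CohortConfig(n_subjects=50_000, frac_female=0.5, n_mz_pairs=0,
                           n_dz_pairs=0, seed=55)
        df = generate_cohort(cfg)
        spec = {s.name: s for s in default_trait_specs()}
        for trait in ("adhd_t", "nback2_acc"):
            for sx in ("F", "M"):
                sub = df[df.sex == sx][trait]
                assert sub.mean() == pytest.approx(
                    spec[trait].mean_by_sex[sx],
                    rel=0.01), (trait, sx, "mean")
                assert sub.std() == pytest.approx(
                    spec[trait].sd_by_sex[sx], rel=0.02), (trait, sx, "sd")

    def test_partial_correlation_target_recovered(self, big_boys_cohort):
        """Adjusted 2-back/ADHD partial correlation within 0.01 of the
        configured boys' target at n = 50,000."""
        df = big_boys_cohort
        cov = build_covariate_matrix(
            df, ["age_months", "tiv", "site_id", "scanner_id"])
        res = adjusted_regression(df.nback2_acc, df.adhd_t, cov)
        assert res.partial_r == pytest.approx(-0.133, abs=0.01)

    def test_confounding_makes_unadjusted_differ(self, big_boys_cohort):
        df = big_boys_cohort
        raw = np.corrcoef(df.nback2_acc, df.adhd_t)[0, 1]
        cov = build_covariate_matrix(
            df, ["age_months", "tiv", "site_id", "scanner_id"])
        adj = adjusted_regression(df.nback2_acc, df.adhd_t, cov).partial_r
        assert abs(raw - adj) > 0.005

    def test_null_target_gives_null_partial_correlation(self):
        specs = [
            TraitSpec(name="a", a2=0.5, c2=0.0, e2=0.5,
                      mean_by_sex={"F": 0, "M": 0},
                      sd_by_sex={"F": 1, "M": 1}),
            TraitSpec(name="b", a2=0.5, c2=0.0, e2=0.5,
                      mean_by_sex={"F": 0, "M": 0},
                      sd_by_sex={"F": 1, "M": 1},
                      target_partial_correlations=[("a", 0.0, "all")]),
        ]
        cfg = CohortConfig(n_subjects=10_000, n_mz_pairs=0, n_dz_pairs=0,
                           seed=8, trait_specs=specs)
        df = generate_cohort(cfg)
        cov = build_covariate_matrix(
            df, ["age_months", "tiv", "site_id", "scanner_id"])
        res = adjusted_regression(df.b, df.a, cov)
        assert abs(res.partial_r) < 0.02

    def test_diagnosis_tail_rates_are_plausible(self, big_boys_cohort):
        # soft diagnostic: the floored gamma marginal puts a few percent of
        # boys at or above the clinical cutoffs (printed rates: 7.5% / 3.2%)
        p65 = (big_boys_cohort.adhd_t >= 65).mean()
        p70 = (big_boys_cohort.adhd_t >= 70).mean()
        assert 0.02 < p65 < 0.15
        assert 0.005 < p70 < 0.08
        assert p70 < p65

    def test_invalid_target_correlation_rejected(self):
        with pytest.raises(ConfigurationError, match="< 1"):
            TraitSpec(name="x", a2=1.0, c2=0.0, e2=0.0,
                      mean_by_sex={"F": 0, "M": 0}, sd_by_sex={"F": 1, "M": 1},
                      target_partial_correlations=[("y", 1.5, "all")]).validate()

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            TraitSpec(name="x", a2=0.5, c2=0.5, e2=0.5,
                      mean_by_sex={"F": 0, "M": 0},
                      sd_by_sex={"F": 1, "M": 1}).validate()


class TestMedication:
    def test_prevalence_and_tilt(self):
        cfg = CohortConfig(n_subjects=11_502, n_mz_pairs=317, n_dz_pairs=1413,
                           seed=17)
        df = generate_cohort(cfg)
        prev = df.med_stimulant.mean()
        assert prev == pytest.approx(0.082, abs=0.005)
        assert df.loc[df.med_stimulant == 1, "adhd_t"].mean() > \
            df.loc[df.med_stimulant == 0, "adhd_t"].mean()

    def test_zero_link_gives_equal_means(self, small_cohort):
        rng = np.random.default_rng(4)
        out = assign_medication(small_cohort, 0.3, 0.0, rng)
        diff = out.loc[out.med_stimulant == 1, "adhd_t"].mean() - \
            out.loc[out.med_stimulant == 0, "adhd_t"].mean()
        assert abs(diff) < 1.5  # no systematic tilt, only sampling noise

    def test_positive_link_tilts_in_every_seed(self):
        cfg = CohortConfig(n_subjects=10_000, n_mz_pairs=0, n_dz_pairs=0,
                           seed=1)
        df = generate_cohort(cfg)
        for s in range(5):
            rng = np.random.default_rng(s)
            out = assign_medication(df, 0.082, 0.3, rng,
                                    flag_col="_flag")
            assert out.loc[out._flag == 1, "adhd_t"].mean() > \
                out.loc[out._flag == 0, "adhd_t"].mean()

    def test_invalid_prevalence_rejected(self, small_cohort, rng):
        with pytest.raises(ConfigurationError):
            assign_medication(small_cohort, 1.5, 0.1, rng)


class TestVolumeMaps:
    def test_deterministic_under_seed(self, small_cohort):
        sub = small_cohort.head(10)
        a = generate_volume_maps(sub, grid_shape=(8, 8, 8), seed=3)
        b = generate_volume_maps(sub, grid_shape=(8, 8, 8), seed=3)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.grid, vb.grid)

    def test_cluster_outside_grid_rejected(self, small_cohort):
        bad = ClusterSpec(center=(30, 4, 4), radius=2, amplitude=1.0)
        with pytest.raises(ConfigurationError, match="outside"):
            generate_volume_maps(small_cohort.head(5), grid_shape=(8, 8, 8),
                                 effect_clusters=[bad])

    def test_planted_cluster_recovered_by_glm(self, small_cohort):
        """The voxelwise GLM peak lands inside the planted sphere in nearly
        every seed."""
        sub = small_cohort.head(80)
        cl = ClusterSpec(center=(8, 8, 8), radius=3, amplitude=-1.2,
                         trait="adhd_t")
        region = cl.mask((16, 16, 16))
        cov = build_covariate_matrix(sub, ["age_months", "tiv"])
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            vols = generate_volume_maps(sub, grid_shape=(16, 16, 16),
                                        effect_clusters=[cl], seed=100 + s)
            smap = voxelwise_glm(vols, sub.adhd_t.to_numpy(), cov)
            peak = np.unravel_index(np.nanargmin(smap.t), smap.t.shape)
            hits += bool(region[peak])
        assert hits >= int(0.9 * n_seeds)

    def test_tiv_scales_global_component(self, small_cohort):
        sub = small_cohort.head(30)
        vols = generate_volume_maps(sub, grid_shape=(8, 8, 8), seed=0,
                                    noise_sd=0.1)
        means = np.array([v.grid.mean() for v in vols])
        tiv = sub.tiv.to_numpy()
        assert np.corrcoef(means, tiv)[0, 1] > 0.9
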