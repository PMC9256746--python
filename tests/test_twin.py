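"""Twin correlations and ACE maximum-likelihood decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinmorph import (CohortConfig, PairSet, assess_fit,
                       classify_heritability, compare_group_heritability,
                       compare_pair_groups, falconer, fit_ace,
                       fit_ace_from_cov, generate_cohort, make_pairs,
                       pair_correlation, simulate_ace_pairs, ur_resample)
from twinmorph.twin import _nll_and_grad, _suffstats


def _corr_matrix(r):
    return np.array([[1.0, r], [r, 1.0]])


class TestFitAce:
    def test_falconer_oracle_on_exact_covariances(self):
        """r_MZ = 0.8, r_DZ = 0.5 decompose exactly into (0.6, 0.2, 0.2)."""
        fit = fit_ace_from_cov(_corr_matrix(0.8), _corr_matrix(0.5))
        assert fit.a2 == pytest.approx(0.6, abs=1e-4)
        assert fit.c2 == pytest.approx(0.2, abs=1e-4)
        assert fit.e2 == pytest.approx(0.2, abs=1e-4)
        assert fit.converged
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_pure_environment_when_twin_correlations_vanish(self):
        fit = fit_ace_from_cov(_corr_matrix(0.0), _corr_matrix(0.0))
        assert fit.a2 == pytest.approx(0.0, abs=1e-4)
        assert fit.c2 == pytest.approx(0.0, abs=1e-4)
        assert fit.e2 == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("r_mz,r_dz", [(0.8, 0.5), (0.6, 0.3),
                                           (0.59, 0.295), (0.85, 0.5)])
    def test_matches_falconer_closed_form_on_population_input(self, r_mz, r_dz):
        fit = fit_ace_from_cov(_corr_matrix(r_mz), _corr_matrix(r_dz))
        a2, c2, e2 = falconer(r_mz, r_dz)
        assert fit.a2 == pytest.approx(a2, abs=1e-4)
        assert fit.c2 == pytest.approx(c2, abs=1e-4)

    def test_components_sum_to_one(self, rng):
        mz, dz = simulate_ace_pairs(100, 300, 0.5, 0.2, 0.3, rng)
        fit = fit_ace(PairSet(mz[:, 0], mz[:, 1], "MZ"),
                      PairSet(dz[:, 0], dz[:, 1], "DZ"))
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-6)

    def test_optimum_at_least_as_good_as_falconer_start(self, rng):
        """The multi-start ML never ends below the Falconer starting point."""
        mz, dz = simulate_ace_pairs(80, 200, 0.6, 0.1, 0.3, rng)
        n_mz, S_mz = _suffstats(mz)
        n_dz, S_dz = _suffstats(dz)
        fit = fit_ace(PairSet(mz[:, 0], mz[:, 1], "MZ"),
                      PairSet(dz[:, 0], dz[:, 1], "DZ"))
        stats = [(1.0, n_mz, S_mz), (0.5, n_dz, S_dz)]
        r_mz = S_mz[0, 1] / n_mz / ((S_mz[0, 0] + S_mz[1, 1]) / (2 * n_mz))
        r_dz = S_dz[0, 1] / n_dz / ((S_dz[0, 0] + S_dz[1, 1]) / (2 * n_dz))
        v = (S_mz[0, 0] + S_mz[1, 1] + S_dz[0, 0] + S_dz[1, 1]) / \
            (2 * (n_mz + n_dz))
        a2, c2, e2 = falconer(r_mz, r_dz)
        nll_start, _ = _nll_and_grad(v * np.array([a2, max(c2, 1e-3), e2]),
                                     stats)
        assert -fit.loglik <= nll_start + 1e-9

    def test_parameter_recovery_across_generating_values(self):
        """Mean estimate over replicates of 317 MZ + 1,413 DZ pairs stays
        within 0.03 of the generating proportions."""
        for a2, c2, e2 in [(0.59, 0.0, 0.41), (0.30, 0.0, 0.70)]:
            vals = []
            for s in range(25):
                r = np.random.default_rng(500 + s)
                mz, dz = simulate_ace_pairs(317, 1413, a2, c2, e2, r)
                fit = fit_ace(PairSet(mz[:, 0], mz[:, 1], "MZ"),
                              PairSet(dz[:, 0], dz[:, 1], "DZ"))
                vals.append(fit.a2)
            assert np.mean(vals) == pytest.approx(a2, abs=0.03)

    def test_ci_width_grows_with_fewer_pairs(self, rng):
        mz_l, dz_l = simulate_ace_pairs(400, 1200, 0.6, 0.1, 0.3, rng)
        mz_s, dz_s = simulate_ace_pairs(40, 120, 0.6, 0.1, 0.3, rng)
        big = fit_ace(PairSet(mz_l[:, 0], mz_l[:, 1], "MZ"),
                      PairSet(dz_l[:, 0], dz_l[:, 1], "DZ"))
        small = fit_ace(PairSet(mz_s[:, 0], mz_s[:, 1], "MZ"),
                        PairSet(dz_s[:, 0], dz_s[:, 1], "DZ"))
        assert small.se_a2 > big.se_a2

    def test_bound_components_keeps_nonnegative_estimates(self):
        # exact input with r_DZ > r_MZ pushes the genetic share negative;
        # the bounded variant clips at zero
        fit = fit_ace_from_cov(_corr_matrix(0.2), _corr_matrix(0.3))
        bounded = fit_ace_from_cov(_corr_matrix(0.2), _corr_matrix(0.3))
        from twinmorph import fit_ace_suffstats
        bounded = fit_ace_suffstats(1000, 1000 * _corr_matrix(0.2),
                                    1000, 1000 * _corr_matrix(0.3),
                                    bound_components=True)
        assert fit.a2 < 0
        assert bounded.a2 >= 0


class TestClassification:
    @pytest.mark.parametrize("a2,label", [
        (0.25, "low"), (0.30, "moderate"), (0.45, "moderate"),
        (0.60, "moderate"), (0.61, "high"), (0.77, "high")])
    def test_printed_thresholds(self, a2, label):
        assert classify_heritability(a2) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_heritability(1.2)


class TestAssessFit:
    def test_exact_fit_limit_is_good(self):
        fit = fit_ace_from_cov(_corr_matrix(0.8), _corr_matrix(0.5))
        flags = assess_fit(fit)
        assert flags["chi2_df_ok"] and flags["rmsea_ok"] and flags["tli_ok"]
        assert flags["good_fit"]

    def test_self_consistency_on_model_generated_data(self):
        """Data generated by the ACE model itself is judged well-fitting in
        the vast majority of replicates."""
        good = 0
        n_rep = 40
        for s in range(n_rep):
            r = np.random.default_rng(3000 + s)
            mz, dz = simulate_ace_pairs(200, 600, 0.6, 0.1, 0.3, r)
            fit = fit_ace(PairSet(mz[:, 0], mz[:, 1], "MZ"),
                          PairSet(dz[:, 0], dz[:, 1], "DZ"))
            good += assess_fit(fit)["good_fit"]
        assert good >= int(0.9 * n_rep)


class TestCompareGroupHeritability:
    def test_identical_fits_give_zero(self):
        fit = fit_ace_from_cov(_corr_matrix(0.8), _corr_matrix(0.5))
        z, p = compare_group_heritability(fit, fit)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_inputs(self):
        """a2 0.6 (SE 0.05) vs 0.4 (SE 0.05): z = 0.2/sqrt(0.005) = 2.828."""
        f1 = fit_ace_from_cov(_corr_matrix(0.8), _corr_matrix(0.5))
        f2 = fit_ace_from_cov(_corr_matrix(0.8), _corr_matrix(0.5))
        f1.a2, f1.se_a2 = 0.6, 0.05
        f2.a2, f2.se_a2 = 0.4, 0.05
        z, p = compare_group_heritability(f1, f2)
        assert z == pytest.approx(2.828, abs=1e-3)

    def test_type_i_rate_for_equal_generating_values(self):
        rejections = 0
        n_rep = 60
        for s in range(n_rep):
            r = np.random.default_rng(4000 + s)
            fits = []
            for _ in range(2):
                mz, dz = simulate_ace_pairs(160, 700, 0.56, 0.0, 0.44, r)
                fits.append(fit_ace(PairSet(mz[:, 0], mz[:, 1], "MZ"),
                                    PairSet(dz[:, 0], dz[:, 1], "DZ")))
            _, p = compare_group_heritability(*fits)
            rejections += p < 0.05
        assert rejections / n_rep < 0.15


class TestPairConstruction:
    def test_mz_pair_count_and_shared_family(self, small_cohort):
        pairs = make_pairs(small_cohort, "MZ", "adhd_t",
                           ["age_months", "site_id"], seed=0)
        assert pairs.n_pairs == 40
        fams = small_cohort.set_index("subject_id")["family_id"]
        for s1, s2 in pairs.subject_ids:
            assert fams[s1] == fams[s2]

    def test_singleton_cohort_rejected(self):
        cfg = CohortConfig(n_subjects=50, n_mz_pairs=0, n_dz_pairs=0, seed=2)
        cohort = generate_cohort(cfg)
        with pytest.raises(ValueError, match="MZ"):
            make_pairs(cohort, "MZ", "adhd_t", None, seed=0)

    def test_member_order_deterministic_under_seed(self, small_cohort):
        a = make_pairs(small_cohort, "DZ", "adhd_t", None, seed=5)
        b = make_pairs(small_cohort, "DZ", "adhd_t", None, seed=5)
        assert a.subject_ids == b.subject_ids
        np.testing.assert_array_equal(a.value_1, b.value_1)

    def test_subject_in_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            PairSet(np.zeros(2), np.ones(2), "MZ",
                    subject_ids=[("a", "b"), ("b", "c")])


class TestPairCorrelation:
    def test_perfect_correlation(self):
        v = np.linspace(-2, 2, 30)
        tc = pair_correlation(PairSet(v, v.copy(), "MZ"))
        assert tc.r == pytest.approx(1.0)
        assert tc.slope == pytest.approx(1.0)

    def test_generated_mz_correlation_matches_heritability(self):
        """MZ pairs generated at a2 = 0.59 (no shared environment) show a
        pair correlation close to 0.59 at 10,000 pairs."""
        r = np.random.default_rng(7)
        mz, _ = simulate_ace_pairs(10_000, 0, 0.59, 0.0, 0.41, r)
        tc = pair_correlation(PairSet(mz[:, 0], mz[:, 1], "MZ"))
        assert 0.57 <= tc.r <= 0.61
        assert tc.ci_low < tc.r < tc.ci_high

    def test_swap_invariance(self, rng):
        mz, _ = simulate_ace_pairs(500, 0, 0.6, 0.1, 0.3, rng)
        fwd = pair_correlation(PairSet(mz[:, 0], mz[:, 1], "MZ"))
        rev = pair_correlation(PairSet(mz[:, 1], mz[:, 0], "MZ"))
        assert fwd.r == pytest.approx(rev.r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pair_correlation(PairSet(np.ones(10), np.arange(10.0), "MZ"))


class TestURResample:
    def test_null_mean_r_near_zero(self):
        r = np.random.default_rng(21)
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(10_000)],
            "family_id": [f"f{i}" for i in range(10_000)],
            "zygosity": "SINGLETON", "sex": "F",
            "trait": r.normal(size=10_000)})
        out = ur_resample(table, "trait", None, n_rep=100, seed=3)
        assert abs(out["mean_r"]) < 0.01

    def test_deterministic_per_rep_sequence(self, small_cohort):
        a = ur_resample(small_cohort, "adhd_t", None, n_rep=20, seed=9)
        b = ur_resample(small_cohort, "adhd_t", None, n_rep=20, seed=9)
        np.testing.assert_array_equal(a["r"], b["r"])

    def test_duplicated_trait_cohort_orders_ur_below_mz(self):
        """When each subject's trait is duplicated in exactly one MZ co-twin,
        random UR pairing yields far lower correlation than true MZ pairing."""
        cfg = CohortConfig(n_subjects=400, n_mz_pairs=200, n_dz_pairs=0,
                           seed=5, trait_specs=[])
        cohort = generate_cohort(cfg)
        r = np.random.default_rng(0)
        from twinmorph import simulate_ace_latent
        cohort["dup"] = simulate_ace_latent(
            cohort["zygosity"].to_numpy(), cohort["family_id"].to_numpy(),
            1.0, 0.0, 0.0, r)  # identical within MZ pairs
        mz = make_pairs(cohort, "MZ", "dup", None, seed=1)
        tc = pair_correlation(mz)
        ur = ur_resample(cohort, "dup", None, n_rep=50, seed=1)
        assert ur["mean_r"] < 0.2 < 0.9 < tc.r

    def test_too_small_sample_rejected(self):
        table = pd.DataFrame({"trait": [1.0, 2.0]})
        with pytest.raises(ValueError, match="4 subjects"):
            ur_resample(table, "trait", None)


class TestComparePairGroups:
    def test_identical_groups_zero(self, rng):
        mz, _ = simulate_ace_pairs(300, 0, 0.6, 0.1, 0.3, rng)
        tc = pair_correlation(PairSet(mz[:, 0], mz[:, 1], "MZ"))
        st_ = compare_pair_groups(tc, tc)
        assert st_.t == 0.0

    def test_high_heritability_beats_ur_null(self):
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            r = np.random.default_rng(6000 + s)
            mz, _ = simulate_ace_pairs(1000, 0, 0.8, 0.0, 0.2, r)
            x = r.normal(size=1000)
            y = r.normal(size=1000)
            tc_mz = pair_correlation(PairSet(mz[:, 0], mz[:, 1], "MZ"))
            tc_ur = pair_correlation(PairSet(x, y, "UR"))
            hits += compare_pair_groups(tc_mz, tc_ur).p < 0.05
        assert hits == n_rep

    def test_antisymmetry(self, rng):
        mz, dz = simulate_ace_pairs(300, 300, 0.6, 0.1, 0.3, rng)
        tc1 = pair_correlation(PairSet(mz[:, 0], mz[:, 1], "MZ"))
        tc2 = pair_correlation(PairSet(dz[:, 0], dz[:, 1], "DZ"))
        assert compare_pair_groups(tc1, tc2).t == pytest.approx(
            -compare_pair_groups(tc2, tc1).t, abs=1e-12)


def test_generated_correlation_ordering_mz_dz_ur():
    """Whenever a2 > 0 the generated pair correlations order r_MZ > r_DZ > r_UR."""
    r = np.random.default_rng(77)
    mz, dz = simulate_ace_pairs(2000, 2000, 0.6, 0.1, 0.3, r)
    ur = np.column_stack([r.normal(size=2000), r.normal(size=2000)])
    r_mz = np.corrcoef(mz[:, 0], mz[:, 1])[0, 1]
    r_dz = np.corrcoef(dz[:, 0], dz[:, 1])[0, 1]
    r_ur = np.corrcoef(ur[:, 0], ur[:, 1])[0, 1]
    assert r_mz > r_dz > r_ur


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
@settings(derandomize=True, max_examples=60)
def test_falconer_always_admissible(r_mz, r_dz):
    a2, c2, e2 = falconer(r_mz, r_dz)
    assert 0 <= a2 <= 1 and 0 <= c2 <= 1 and e2 > 0
    assert a2 + c2 + e2 == pytest.approx(1.0, abs=1e-3)
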