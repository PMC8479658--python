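"""Distance normalization and the DCI statistic against independent oracles."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicdci import (
    ContactMatrix,
    SimulationConfig,
    adjust_for_coverage,
    bound_vs_unbound_test,
    compute_dci_profile,
    coverage_vectors,
    dci_score,
    extract_contact_score_array,
    fisher_combine,
    normalize_by_distance,
    paired_t,
    simulate_contact_maps,
)
from hicdci.dci_core import P_FLOOR, ContactScoreArray
from hicdci.errors import ConfigurationError, ValidationError

from conftest import make_matrix, random_symmetric_counts


# --- independent oracles -------------------------------------------------

def paired_t_oracle(a, b):
    """Textbook paired t from first principles (no scipy.stats.ttest_rel)."""
    d = np.asarray(b, float) - np.asarray(a, float)
    L = len(d)
    mean = d.sum() / L
    sd = math.sqrt(((d - mean) ** 2).sum() / (L - 1))
    t = mean / (sd / math.sqrt(L))
    # two-sided p via the regularized incomplete beta (survival of |t|)
    from scipy.special import betainc

    nu = L - 1
    p = betainc(nu / 2, 0.5, nu / (nu + t * t))
    return t, p


def chi2_sf_even_df(x, k):
    """Closed-form chi-square survival at 2k df: e^{-x/2} Σ (x/2)^i / i!."""
    h = x / 2.0
    return math.exp(-h) * sum(h**i / math.factorial(i) for i in range(k))


# --- normalization -------------------------------------------------------

class TestNormalizeByDistance:
    def test_hand_computed_band(self):
        m = make_matrix([[4, 2, 1], [2, 6, 3], [1, 3, 8]])
        nm = normalize_by_distance(m, 2)
        np.testing.assert_allclose(nm.band[0], [4 / 6, 1.0, 8 / 6])
        np.testing.assert_allclose(nm.band[1][:2], [0.8, 1.2])
        np.testing.assert_allclose(nm.band[2][:1], [1.0])

    def test_constant_strata_normalize_to_one(self):
        n = 10
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = make_matrix((d + 1.0) * 3)
        nm = normalize_by_distance(m, 5)
        for dist in range(6):
            np.testing.assert_allclose(nm.band[dist][: n - dist], 1.0)

    def test_all_zero_matrix_stays_zero(self):
        nm = normalize_by_distance(make_matrix(np.zeros((6, 6))), 3)
        assert not nm.band.any()

    def test_distance_bound_exceeding_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_by_distance(make_matrix(np.zeros((4, 4))), 4)

    def test_depth_invariance_exact_for_binary_scalings(self):
        rng = np.random.default_rng(0)
        c = random_symmetric_counts(rng, 20)
        base = normalize_by_distance(make_matrix(c), 8).band
        for k in (2.0, 0.25, 1024.0):
            scaled = normalize_by_distance(make_matrix(c * k), 8).band
            np.testing.assert_array_equal(scaled, base)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(5, 25),
        seed=st.integers(0, 10_000),
        k=st.floats(0.1, 50, allow_nan=False),
    )
    def test_stratum_means_are_one_and_scaling_invariant(self, n, seed, k):
        rng = np.random.default_rng(seed)
        c = random_symmetric_counts(rng, n)
        d_bins = min(8, n - 1)
        nm = normalize_by_distance(make_matrix(c), d_bins)
        for dist in range(d_bins + 1):
            stratum = nm.band[dist][: n - dist]
            if stratum.any():
                assert abs(stratum.mean() - 1.0) < 1e-9
        scaled = normalize_by_distance(make_matrix(c * k), d_bins)
        np.testing.assert_allclose(scaled.band, nm.band, rtol=1e-12, atol=1e-12)


class TestContactScoreArray:
    def test_interior_bin_has_two_d_flanks(self):
        rng = np.random.default_rng(1)
        nm = normalize_by_distance(make_matrix(random_symmetric_counts(rng, 100)), 40)
        a = extract_contact_score_array(nm, 50)
        assert len(a.values) == 80
        assert a.positions[0] == -40 and a.positions[-1] == 40
        assert 0 not in a.positions  # self-interaction excluded

    def test_first_bin_truncated_to_downstream_only(self):
        rng = np.random.default_rng(1)
        nm = normalize_by_distance(make_matrix(random_symmetric_counts(rng, 100)), 40)
        a = extract_contact_score_array(nm, 0)
        assert len(a.values) == 40
        assert (a.positions > 0).all()

    def test_middle_bin_of_three_with_unit_distance(self):
        m = make_matrix([[4, 2, 1], [2, 6, 3], [1, 3, 8]])
        nm = normalize_by_distance(m, 1)
        a = extract_contact_score_array(nm, 1)
        np.testing.assert_array_equal(a.positions, [-1, 1])
        np.testing.assert_allclose(a.values, [0.8, 1.2])  # n_10, n_12


def arr(values, positions=None):
    values = np.asarray(values, float)
    if positions is None:
        positions = np.arange(1, len(values) + 1)
    return ContactScoreArray(0, np.asarray(positions), values)


class TestPairedT:
    def test_identical_arrays_give_t0_p1(self):
        t, p = paired_t(arr([1, 2, 3]), arr([1, 2, 3]))
        assert t == 0 and p == 1

    def test_constant_shift_hits_p_floor_with_positive_sign(self):
        t, p = paired_t(arr([1, 1, 1, 1]), arr([2, 2, 2, 2]))
        assert t > 0 and p == P_FLOOR

    def test_matches_closed_form_oracle(self):
        a, b = [1.0, 2.0, 3.0], [1.5, 2.0, 3.1]
        t, p = paired_t(arr(a), arr(b))
        t_ref, p_ref = paired_t_oracle(a, b)
        assert abs(np.mean(np.subtract(b, a)) - 0.2) < 1e-12
        assert abs(t - t_ref) < 1e-10
        assert abs(p - p_ref) < 1e-10

    def test_mismatched_positions_rejected(self):
        with pytest.raises(ValidationError):
            paired_t(arr([1, 2], positions=[1, 2]), arr([1, 2], positions=[-1, 1]))

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            paired_t(arr([1.0]), arr([2.0]))


class TestFisherCombine:
    def test_even_df_closed_form(self):
        p = fisher_combine([0.5, 0.5])
        chi2 = -2 * (math.log(0.5) + math.log(0.5))
        assert abs(p - chi2_sf_even_df(chi2, 2)) < 1e-12
        assert abs(p - 0.5966) < 1e-4

    def test_single_p_is_identity(self):
        for p in (1.0, 0.3, 1e-8):
            assert abs(fisher_combine([p]) - p) < 1e-12

    def test_zero_p_clamped_not_crashing(self):
        assert fisher_combine([0.0, 0.5]) >= P_FLOOR

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            fisher_combine([])


class TestDciScore:
    def test_identical_conditions_are_null(self):
        a = arr([1.0, 2.0, 0.5, 1.5])
        assert dci_score([a], [a]) == (0.0, 1.0, 0)

    def test_uniform_positive_shift_forces_positive_sign(self):
        s, p, sign = dci_score([arr([1, 1, 1, 1.2])], [arr([2, 2, 2, 2.2])])
        assert sign == 1 and s > 0

    def test_two_vs_two_matches_brute_force_composition(self):
        rng = np.random.default_rng(42)
        controls = [arr(rng.gamma(2, 1, 30)) for _ in range(2)]
        treatments = [arr(rng.gamma(2, 1.2, 30)) for _ in range(2)]
        s, p, sign = dci_score(controls, treatments)
        # oracle: 4 closed-form paired t p-values + even-df chi-square survival
        ts, ps = zip(
            *(paired_t_oracle(c.values, t.values) for c in controls for t in treatments)
        )
        chi2 = -2 * sum(math.log(x) for x in ps)
        p_ref = chi2_sf_even_df(chi2, 4)
        sign_ref = int(np.sign(sum(ts)))
        assert sign == sign_ref
        assert abs(p - p_ref) / p_ref < 1e-10
        assert abs(s - sign_ref * -math.log10(p_ref)) < 1e-9


class TestComputeDciProfile:
    def test_swapping_conditions_negates_scores_exactly(self, small_cfg):
        t = simulate_contact_maps(small_cfg, "treatment")
        c = simulate_contact_maps(small_cfg, "control")
        fwd = compute_dci_profile(t, c, 200_000)
        rev = compute_dci_profile(c, t, 200_000)
        np.testing.assert_array_equal(fwd.scores, -rev.scores)
        np.testing.assert_array_equal(fwd.p_values, rev.p_values)

    def test_gained_block_bins_carry_top_scores(self, small_cfg):
        t = simulate_contact_maps(small_cfg, "treatment")
        c = simulate_contact_maps(small_cfg, "control")
        prof = compute_dci_profile(t, c, 200_000)
        block = np.zeros(prof.bins.n_bins, bool)
        for chrom, (lo, hi), _ in small_cfg.blocks:
            off = prof.bins.offset(chrom)
            block[off + lo : off + hi] = True
        # block mean exceeds the 95th percentile of the background
        assert prof.scores[block].mean() > np.quantile(prof.scores[~block], 0.95)

    def test_block_score_monotone_in_fold_change(self, small_cfg):
        means = []
        for fold in (1.5, 2.0, 3.0):
            cfg = dataclasses.replace(
                small_cfg, blocks=[("chr1", (40, 60), fold)], n_chroms=1
            )
            t = simulate_contact_maps(cfg, "treatment")
            c = simulate_contact_maps(cfg, "control")
            prof = compute_dci_profile(t, c, 200_000)
            means.append(prof.scores[40:60].mean())
        assert means[0] <= means[1] <= means[2]

    def test_distance_not_multiple_of_bin_size_rejected(self, small_cfg):
        t = simulate_contact_maps(small_cfg, "treatment")
        c = simulate_contact_maps(small_cfg, "control")
        with pytest.raises(ConfigurationError):
            compute_dci_profile(t, c, 199_999)

    def test_profile_consistent_with_scalar_dci_score(self, small_cfg):
        """Spot-check: the vectorized scan equals per-bin dci_score calls."""
        from hicdci import extract_contact_score_array, normalize_by_distance

        cfg = dataclasses.replace(small_cfg, n_chroms=1)
        t = simulate_contact_maps(cfg, "treatment")
        c = simulate_contact_maps(cfg, "control")
        prof = compute_dci_profile(t, c, 200_000)
        d_bins = 40
        nms_c = [normalize_by_distance(r["chr1"], d_bins) for r in c.replicates]
        nms_t = [normalize_by_distance(r["chr1"], d_bins) for r in t.replicates]
        for b in (0, 17, 60, 119):
            s, p, sign = dci_score(
                [extract_contact_score_array(nm, b) for nm in nms_c],
                [extract_contact_score_array(nm, b) for nm in nms_t],
            )
            assert abs(prof.scores[b] - s) < 1e-9
            assert abs(prof.p_values[b] - p) < 1e-12
            assert prof.signs[b] == sign


class TestCoverageAdjustment:
    def make_profile(self, small_cfg):
        t = simulate_contact_maps(small_cfg, "treatment")
        c = simulate_contact_maps(small_cfg, "control")
        prof = compute_dci_profile(t, c, 200_000)
        return prof, t, c

    def test_constant_covariate_returns_unchanged(self, small_cfg):
        prof, t, c = self.make_profile(small_cfg)
        cov = [np.ones(prof.bins.n_bins)]
        adj = adjust_for_coverage(prof, cov, cov)
        np.testing.assert_array_equal(adj.scores, prof.scores)

    def test_perfectly_linear_scores_reduce_to_zero(self, small_cfg):
        prof, *_ = self.make_profile(small_cfg)
        rng = np.random.default_rng(2)
        tc = [rng.gamma(5, 100, prof.bins.n_bins)]
        cc = [rng.gamma(5, 100, prof.bins.n_bins)]
        x = np.log2((tc[0] + 1) / (cc[0] + 1))
        prof.scores[:] = 3.0 * x - 1.0
        adj = adjust_for_coverage(prof, tc, cc)
        np.testing.assert_allclose(adj.scores[~adj.no_data], 0.0, atol=1e-9)

    def test_residuals_match_closed_form_ols(self, small_cfg):
        prof, t, c = self.make_profile(small_cfg)
        tc = coverage_vectors(t, 200_000)
        cc = coverage_vectors(c, 200_000)
        adj = adjust_for_coverage(prof, tc, cc)
        x = np.log2((np.mean(tc, axis=0) + 1) / (np.mean(cc, axis=0) + 1))
        m = ~prof.no_data
        xs, ys = x[m], prof.scores[m]
        slope = np.mean((xs - xs.mean()) * (ys - ys.mean())) / np.var(xs)
        resid = ys - (ys.mean() + slope * (xs - xs.mean()))
        np.testing.assert_allclose(adj.scores[m], resid, atol=1e-10)

    def test_coverage_vectors_are_band_row_sums(self):
        counts = np.array([[4, 2, 1], [2, 6, 3], [1, 3, 8]], float)
        from hicdci import SampleSet

        cm = make_matrix(counts)
        ss = SampleSet("control", [{"chr1": cm}])
        (cov,) = coverage_vectors(ss, 5000)  # D_bins = 1
        np.testing.assert_array_equal(cov, [6, 11, 11])


class TestBoundVsUnbound:
    def make_profile_with_scores(self, scores):
        cfg = SimulationConfig(n_chroms=1, bins_per_chrom=len(scores), n_replicates=1)
        t = simulate_contact_maps(cfg, "treatment")
        c = simulate_contact_maps(cfg, "control")
        prof = compute_dci_profile(t, c, 2 * cfg.bin_size)
        prof.scores[:] = scores
        prof.no_data[:] = False
        return prof

    def test_complete_separation_matches_exact_enumeration(self):
        prof = self.make_profile_with_scores([1, 2, 3, 10, 20, 30])
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 5000, 10000], "end": [5000, 10000, 15000]}
        )
        w, p = bound_vs_unbound_test(prof, sites)
        assert w == 6.0  # bound scores are the three smallest ranks
        assert abs(p - 0.1) < 1e-12  # 2 / C(6,3) extreme splits

    def test_identical_groups_are_null(self):
        prof = self.make_profile_with_scores([5.0] * 8)
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20000]})
        w, p = bound_vs_unbound_test(prof, sites)
        assert p == 1.0

    def test_empty_partition_rejected(self):
        prof = self.make_profile_with_scores([1.0] * 6)
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [30000]})
        with pytest.raises(ValidationError):
            bound_vs_unbound_test(prof, sites)
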