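"""Filtering, the overdispersion-corrected per-CpG test, and FDR calling."""

import numpy as np
import pandas as pd
import pytest

from rrbsdiff.dms import (
    ComparisonSpec,
    adjust_and_call,
    filter_by_coverage,
    pooled_difference,
    test_comparison as run_comparison,
    test_site as run_site,
)
from rrbsdiff.io import MethylationMatrix
from _oracles import bh_qvalues, brute_force_test


def matrix_from_counts(meth, cov, samples=None):
    meth = np.asarray(meth, float)
    cov = np.asarray(cov, float)
    n = meth.shape[0]
    if samples is None:
        samples = [f"s{j}" for j in range(meth.shape[1])]
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(n, dtype=np.int64) * 1000, "strand": "+"}
    )
    return MethylationMatrix(sites=sites, samples=list(samples), meth=meth, cov=cov)


def spec_for(matrix, na, **kw):
    return ComparisonSpec(
        name="t", group_a=matrix.samples[:na], group_b=matrix.samples[na:], **kw
    )


class TestFilter:
    def test_coverage_nine_dropped_ten_kept(self):
        m = matrix_from_counts(
            [[1, 1, 1, 1]], [[9, 10, 10, 10]]
        )
        spec = spec_for(m, 2, min_coverage=10, min_samples_per_group=1)
        out = filter_by_coverage(m, spec)
        assert out.n_sites == 1
        assert np.isnan(out.cov[0, 0])  # the 9x cell is gone
        assert out.cov[0, 1] == 10

    def test_four_of_six_rule_retains(self):
        cov_a = [10, 10, 10, 10, 9, np.nan]   # 4 usable of 6
        cov_b = [10, 10, 10, 10, 10, 9]       # 5 usable of 6
        m = matrix_from_counts([[0] * 12], [cov_a + cov_b])
        spec = spec_for(m, 6, min_coverage=10, min_samples_per_group=4)
        assert filter_by_coverage(m, spec).n_sites == 1

    def test_three_of_six_dropped(self):
        cov_a = [10, 10, 10, 9, 9, np.nan]    # only 3 usable
        cov_b = [10] * 6
        m = matrix_from_counts([[0] * 12], [cov_a + cov_b])
        spec = spec_for(m, 6, min_coverage=10, min_samples_per_group=4)
        assert filter_by_coverage(m, spec).n_sites == 0

    def test_strict_default_requires_all_samples(self):
        cov = [[10, 10, np.nan, 10, 10, 10]]
        m = matrix_from_counts([[0] * 6], cov)
        spec = spec_for(m, 3, min_coverage=10)
        assert filter_by_coverage(m, spec).n_sites == 0


class TestPooledDifference:
    @pytest.mark.parametrize(
        "a, b, expect",
        [
            ([(5, 10), (5, 10)], [(5, 10), (5, 10)], 0.0),
            ([(0, 10), (0, 10)], [(10, 10), (10, 10)], 100.0),
            ([(3, 10), (7, 10)], [(2, 10), (2, 10)], -30.0),
        ],
    )
    def test_pooled_proportion_arithmetic(self, a, b, expect):
        assert pooled_difference(a, b) == pytest.approx(expect, abs=1e-12)

    def test_zero_group_coverage_undefined(self):
        with pytest.raises(ValueError, match="zero total coverage"):
            pooled_difference([(0, 0), (0, 0)], [(1, 10), (2, 10)])


class TestTestSite:
    def test_identical_groups_give_p_one(self):
        counts = [(5, 10), (6, 12), (4, 10)]
        stat, p, est = run_site(counts, counts)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_saturated_boundary_fit_is_finite_and_tiny_p(self):
        stat, p, est = run_site([(0, 20)] * 3, [(20, 20)] * 3)
        assert np.isfinite(stat)
        assert p < 1e-6
        # boundary fit has no residual scatter: phi clamps at 1
        assert est.phi == 1.0

    def test_matches_brute_force_oracle_example(self):
        a = [(2, 10), (3, 10), (1, 10)]
        b = [(7, 10), (6, 10), (8, 10)]
        stat, p, est = run_site(a, b)
        stat_o, p_o, phi_o = brute_force_test(a, b)
        assert stat == pytest.approx(stat_o, abs=1e-6)
        assert p == pytest.approx(p_o, abs=1e-6)
        assert est.raw_phi == pytest.approx(phi_o, abs=1e-6)

    def test_overdispersed_counts_estimate_phi_above_one(self):
        # within-group scatter far beyond binomial
        a = [(0, 30), (15, 30), (29, 30)]
        b = [(1, 30), (16, 30), (30, 30)]
        _, _, est = run_site(a, b)
        assert est.raw_phi > 1
        assert est.phi == est.raw_phi

    def test_dispersion_clamped_below_at_one(self):
        a = [(5, 10), (5, 10), (5, 10)]
        b = [(6, 10), (6, 10), (6, 10)]
        _, _, est = run_site(a, b)
        assert est.raw_phi < 1
        assert est.phi == 1.0


class TestComparisonProperties:
    def random_matrix(self, rng, n_sites=50, na=3, nb=3):
        cov = rng.integers(10, 51, size=(n_sites, na + nb)).astype(float)
        p = rng.uniform(0.05, 0.95, size=(n_sites, 1))
        meth = rng.binomial(cov.astype(int), p).astype(float)
        return matrix_from_counts(meth, cov)

    def test_group_swap_negates_diff_keeps_p(self):
        rng = np.random.default_rng(42)
        m = self.random_matrix(rng)
        fwd = run_comparison(m, spec_for(m, 3))
        # swap: reorder columns b-first
        swapped = matrix_from_counts(
            np.hstack([m.meth[:, 3:], m.meth[:, :3]]),
            np.hstack([m.cov[:, 3:], m.cov[:, :3]]),
        )
        rev = run_comparison(swapped, spec_for(swapped, 3))
        np.testing.assert_allclose(
            fwd["meth_diff"], -rev["meth_diff"], atol=1e-9
        )
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-9)

    def test_overdispersion_correction_never_anticonservative(self):
        """Where raw_phi > 1, the corrected p is >= the uncorrected p."""
        rng = np.random.default_rng(7)
        # beta-binomial counts: extra-binomial scatter
        cov = rng.integers(15, 40, size=(300, 6)).astype(float)
        lat = rng.beta(2, 2, size=(300, 1))
        p_s = rng.beta(lat * 20, (1 - lat) * 20)
        meth = rng.binomial(cov.astype(int), p_s).astype(float)
        m = matrix_from_counts(meth, cov)
        rec = run_comparison(m, spec_for(m, 3))
        from scipy import stats

        uncorrected = stats.chi2.sf(rec["statistic"] * rec["phi"], df=1)
        over = rec["raw_phi"] > 1
        assert over.any()
        assert (rec.loc[over, "p"] >= uncorrected[over] - 1e-12).all()

    def test_statistic_monotone_in_effect_size(self):
        """Median statistic never decreases as |true delta| grows."""
        rng = np.random.default_rng(3)
        medians = []
        for delta in (0.0, 0.1, 0.2, 0.3, 0.4):
            cov = np.full((400, 6), 30.0)
            pa, pb = 0.5, 0.5 + delta
            meth = np.hstack(
                [
                    rng.binomial(30, pa, size=(400, 3)),
                    rng.binomial(30, pb, size=(400, 3)),
                ]
            ).astype(float)
            m = matrix_from_counts(meth, cov)
            rec = run_comparison(m, spec_for(m, 3))
            medians.append(rec["statistic"].median())
        assert all(b >= a for a, b in zip(medians, medians[1:]))


class TestAdjustAndCall:
    def records(self, pvals, diffs=None):
        n = len(pvals)
        if diffs is None:
            diffs = [10.0] * n
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n, dtype=np.int64),
                "strand": "+",
                "meth_diff": diffs,
                "statistic": 1.0,
                "p": pvals,
                "raw_phi": 1.0,
                "phi": 1.0,
                "df": 4,
            }
        )

    def test_bh_hand_arithmetic(self):
        rec = adjust_and_call(
            self.records([0.001, 0.02, 0.04, 0.9]),
            spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2),
        )
        np.testing.assert_allclose(
            rec["q"], [0.004, 0.04, 0.04 * 4 / 3, 0.9], rtol=1e-12
        )
        assert list(rec["is_dms"]) == [True, False, False, False]

    def test_bh_matches_hand_oracle_on_random_pvalues(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=500)
        rec = adjust_and_call(
            self.records(p), spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2)
        )
        # adjust_and_call sorts by position == original order here
        np.testing.assert_allclose(rec["q"], bh_qvalues(p), rtol=1e-12)

    def test_all_p_one_no_dms(self):
        rec = adjust_and_call(
            self.records([1.0, 1.0, 1.0]),
            spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2),
        )
        assert not rec["is_dms"].any()

    def test_small_difference_still_called(self):
        """No minimum-difference threshold: 1 point at q<0.01 is a DMS."""
        rec = adjust_and_call(
            self.records([1e-6, 0.5], diffs=[1.0, 50.0]),
            spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2),
        )
        assert bool(rec.loc[0, "is_dms"])

    def test_zero_difference_never_dms(self):
        rec = adjust_and_call(
            self.records([1e-6], diffs=[0.0]),
            spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2),
        )
        assert not rec["is_dms"].any()

    def test_tie_at_threshold_is_not_dms(self):
        """q < 0.01 is strict: q exactly at the threshold is not called."""
        rec = adjust_and_call(
            self.records([0.01]),
            spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2),
        )
        assert rec.loc[0, "q"] == pytest.approx(0.01)
        assert not rec["is_dms"].any()

    def test_empty_input_empty_output(self):
        rec = adjust_and_call(
            self.records([]).iloc[:0],
            spec_for(matrix_from_counts([[0] * 4], [[10] * 4]), 2),
        )
        assert len(rec) == 0
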