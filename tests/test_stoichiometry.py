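"""The subtraction estimator: defining arithmetic, clamping, replicate
aggregation, simplex and monotonicity properties, grid-recovery
consistency and the condition comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcabseq import (
    aggregate_replicates,
    call_modified_sites,
    compare_conditions,
    estimate_from_counts,
    estimate_site,
)
from fcabseq.stoichiometry import NOT_ESTIMABLE, estimates_from_frame, estimates_frame

counts_st = st.integers(min_value=0, max_value=5000)


def _est(gene, pos, bs, fcab):
    return estimate_from_counts(gene, pos, bs[0], bs[1], fcab[0], fcab[1])


class TestEstimateSite:
    def test_defining_arithmetic(self):
        est = _est("MT-TM", 34, (570, 430), (920, 80))
        assert est.f_m5c == pytest.approx(0.57)
        assert est.f_f5c == pytest.approx(0.35)
        assert est.f_unmod == pytest.approx(0.08)

    def test_fully_unmodified(self):
        est = _est("G", 1, (0, 100), (0, 100))
        assert est.triple == (1.0, 0.0, 0.0)

    def test_clamping_when_bs_exceeds_fcab(self):
        est = _est("G", 1, (100, 0), (90, 10))
        assert est.f_f5c == 0.0
        assert est.f_m5c == 1.0
        assert est.f_unmod == 0.0

    def test_zero_coverage_reported_not_raised(self):
        bs = {"gene_id": "G", "position": 1, "n_unconverted": 0, "n_converted": 0}
        fcab = {"gene_id": "G", "position": 1, "n_unconverted": 5, "n_converted": 5}
        assert estimate_site(bs, fcab) is NOT_ESTIMABLE

    def test_mismatched_sites_rejected(self):
        bs = {"gene_id": "G", "position": 1, "n_unconverted": 1, "n_converted": 1}
        fcab = {"gene_id": "G", "position": 2, "n_unconverted": 1, "n_converted": 1}
        with pytest.raises(ValueError):
            estimate_site(bs, fcab)

    def test_wilson_interval_brackets_estimate(self):
        est = _est("G", 1, (570, 430), (920, 80))
        assert est.ci_m5c[0] < est.f_m5c < est.ci_m5c[1]
        assert est.ci_f5c[0] <= est.f_f5c <= est.ci_f5c[1]

    @given(bs_u=counts_st, bs_c=counts_st, f_u=counts_st, f_c=counts_st)
    @settings(max_examples=300, derandomize=True)
    def test_triple_on_simplex(self, bs_u, bs_c, f_u, f_c):
        if bs_u + bs_c == 0 or f_u + f_c == 0:
            return
        est = _est("G", 1, (bs_u, bs_c), (f_u, f_c))
        assert est.f_unmod + est.f_m5c + est.f_f5c == pytest.approx(1.0, abs=1e-12)
        for f in est.triple:
            assert 0.0 <= f <= 1.0

    def test_simplex_on_10000_random_count_pairs(self):
        rng = np.random.default_rng(42)
        draws = rng.integers(0, 2000, size=(10_000, 4))
        for bs_u, bs_c, f_u, f_c in draws:
            if bs_u + bs_c == 0 or f_u + f_c == 0:
                continue
            est = _est("G", 1, (int(bs_u), int(bs_c)), (int(f_u), int(f_c)))
            total = est.f_unmod + est.f_m5c + est.f_f5c
            assert abs(total - 1.0) < 1e-12
            assert min(est.triple) >= 0.0 and max(est.triple) <= 1.0

    @given(extra=st.integers(min_value=1, max_value=50))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_unconverted_counts(self, extra):
        cov_b, cov_f = 200, 200
        base = _est("G", 1, (60, cov_b - 60), (120, cov_f - 120))
        more_fcab = _est("G", 1, (60, cov_b - 60), (120 + extra, cov_f - 120 - extra))
        assert more_fcab.f_f5c >= base.f_f5c
        more_bs = _est("G", 1, (60 + extra, cov_b - 60 - extra), (120, cov_f - 120))
        assert more_bs.f_m5c >= base.f_m5c


class TestAggregate:
    def test_mean_of_fraction_triples(self):
        reps = [_est("G", 1, (30, 70), (50, 50)), _est("G", 1, (40, 60), (40, 60))]
        assert reps[0].triple == pytest.approx((0.5, 0.3, 0.2))
        assert reps[1].triple == pytest.approx((0.6, 0.4, 0.0))
        agg = aggregate_replicates(reps)
        assert agg.triple == pytest.approx((0.55, 0.35, 0.10))
        assert agg.n_replicates == 2

    def test_single_replicate_is_identity(self):
        est = _est("G", 1, (570, 430), (920, 80))
        agg = aggregate_replicates([est])
        assert agg.triple == pytest.approx(est.triple)

    def test_pooled_counts_mode(self):
        reps = [_est("G", 1, (30, 70), (50, 50)), _est("G", 1, (60, 140), (100, 100))]
        agg = aggregate_replicates(reps, mode="pooled_counts")
        assert agg.p_bs == pytest.approx(90 / 300)
        assert agg.p_fcab == pytest.approx(150 / 300)

    def test_inconsistent_sites_rejected(self):
        reps = [_est("G", 1, (1, 1), (1, 1)), _est("G", 2, (1, 1), (1, 1))]
        with pytest.raises(ValueError, match="inconsistent"):
            aggregate_replicates(reps)

    def test_grid_recovery_within_3_binomial_se(self):
        """Ideal-chemistry binomial sampling at n=10,000 recovers every
        normalised truth triple from the {0, .25, .5, .75, 1}^3 grid."""
        rng = np.random.default_rng(7)
        n = 10_000
        grid = set()
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            for b in (0.0, 0.25, 0.5, 0.75, 1.0):
                for c in (0.0, 0.25, 0.5, 0.75, 1.0):
                    if a + b + c > 0:
                        s = a + b + c
                        grid.add((round(a / s, 6), round(b / s, 6), round(c / s, 6)))
        for f_unmod, f_m5c, f_f5c in sorted(grid):
            p_bs = f_m5c
            p_fcab = f_m5c + f_f5c
            bs_u = int(rng.binomial(n, p_bs))
            fcab_u = int(rng.binomial(n, p_fcab))
            est = _est("G", 1, (bs_u, n - bs_u), (fcab_u, n - fcab_u))
            # every component is a (clamped) linear map of the two sampled
            # proportions, so their combined SE bounds each component's SE
            se = np.sqrt(
                (p_bs * (1 - p_bs) + p_fcab * (1 - p_fcab)) / n
            )
            for observed, expected in zip(est.triple, (f_unmod, f_m5c, f_f5c)):
                assert abs(observed - expected) <= 3 * se + 1e-9


class TestModifiedSiteCall:
    def _reps(self, gene, pos, fractions):
        out = []
        for i, (m5c, f5c) in enumerate(fractions, start=1):
            bs_u = int(round(m5c * 1000))
            fcab_u = int(round((m5c + f5c) * 1000))
            est = _est(gene, pos, (bs_u, 1000 - bs_u), (fcab_u, 1000 - fcab_u))
            est.replicate = i
            out.append(est)
        return out

    def test_threshold_in_all_replicates(self):
        ests = self._reps("A", 10, [(0.3, 0.0), (0.25, 0.0)]) + self._reps(
            "B", 5, [(0.3, 0.0), (0.1, 0.0)]
        )
        flagged, per_gene = call_modified_sites(ests, 0.20)
        assert flagged == {("A", 10)}
        assert per_gene == {"A": [10]}

    def test_unattainable_threshold_empty(self):
        ests = self._reps("A", 10, [(0.9, 0.1), (0.9, 0.1)])
        flagged, _ = call_modified_sites(ests, 1.01)
        assert flagged == set()


class TestCompareConditions:
    def test_eightfold_unmodified_change(self):
        cov = 10_000
        kd = _est("MT-TM", 34, (3500, cov - 3500), (3600, cov - 3600))
        wt = _est("MT-TM", 34, (5700, cov - 5700), (9200, cov - 9200))
        assert kd.f_unmod == pytest.approx(0.64)
        assert wt.f_unmod == pytest.approx(0.08)
        df = compare_conditions([kd], [wt])
        assert df.loc[0, "fold_change_unmod"] == pytest.approx(8.0, rel=1e-3)
        assert df.loc[0, "p_value"] < 1e-10

    def test_identical_conditions(self):
        est = _est("G", 1, (570, 430), (920, 80))
        df = compare_conditions([est], [est])
        assert df.loc[0, "fold_change_unmod"] == pytest.approx(1.0)
        assert df.loc[0, "delta_f5c"] == 0.0
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_missing_site_flagged_not_tested(self):
        a = _est("G", 1, (10, 90), (10, 90))
        b = _est("G", 2, (10, 90), (10, 90))
        df = compare_conditions([a], [b]).set_index("position")
        assert df.loc[1, "missing_in"] == "B"
        assert df.loc[2, "missing_in"] == "A"
        assert np.isnan(df.loc[1, "p_value"])

    def test_fold_change_finite_at_boundary_counts(self):
        a = _est("G", 1, (100, 0), (100, 0))  # zero converted in fCAB
        b = _est("G", 1, (0, 100), (0, 100))
        df = compare_conditions([a], [b])
        fc = df.loc[0, "fold_change_unmod"]
        assert np.isfinite(fc) and fc > 0

    def test_bh_correction_across_sites(self):
        ests_a, ests_b = [], []
        for pos in range(1, 6):
            ests_a.append(_est("G", pos, (100, 100), (150, 50)))
            ests_b.append(_est("G", pos, (100, 100), (150 - 10 * pos, 50 + 10 * pos)))
        df = compare_conditions(ests_a, ests_b)
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()

    def test_estimates_frame_roundtrip(self):
        ests = [_est("G", 1, (570, 430), (920, 80)), _est("G", 2, (1, 99), (2, 98))]
        back = estimates_from_frame(estimates_frame(ests))
        for a, b in zip(ests, back):
            assert a.triple == pytest.approx(b.triple)
            assert a.coverage_fcab == b.coverage_fcab
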