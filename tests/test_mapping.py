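"""Map distance estimators and the NPD interference statistic."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetramap import (
    SporeCounts,
    TetradClassCounts,
    interference_test,
    map_table,
    papazian_expected_npd_fraction,
    perkins_distance,
    random_spore_distance,
    spore_pool_counts,
)

from conftest import binom_two_sided_oracle, make_tetrad


def counts(pd, tt, npd, interval=("A", "B")) -> TetradClassCounts:
    return TetradClassCounts(interval=interval, PD=pd, TT=tt, NPD=npd)


class TestRandomSpore:
    def test_control_interval(self):
        # 27% recombinants among 756 colonies: the published control interval
        est = random_spore_distance(SporeCounts(r=204, t=756))
        assert est.cM_rounded == 27
        assert est.SE_rounded == 1.6

    def test_no_recombinants(self):
        est = random_spore_distance(SporeCounts(r=0, t=100))
        assert est.cM == 0.0 and est.SE == 0.0

    def test_se_at_half(self):
        est = random_spore_distance(SporeCounts(r=50, t=100))
        assert est.SE == pytest.approx(5.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SporeCounts(r=5, t=0)
        with pytest.raises(ValueError):
            SporeCounts(r=5, t=4)

    @given(t=st.integers(10, 400), r=st.integers(0, 400))
    @settings(max_examples=100, deadline=None)
    def test_se_maximal_at_half_and_shrinks_with_t(self, t, r):
        if r > t:
            return
        est = random_spore_distance(SporeCounts(r=r, t=t))
        at_half = 100.0 * math.sqrt(0.25 / t)
        assert est.SE <= at_half + 1e-12
        assert est.cM <= 100.0
        bigger = random_spore_distance(SporeCounts(r=4 * r, t=4 * t))
        assert bigger.SE == pytest.approx(est.SE / 2.0)

    def test_pool_counts_skip_missing_calls(self):
        pool = make_tetrad(["AB", "Ab", "a.", "ab"]).spores
        sc = spore_pool_counts(pool, "A", "B")
        assert (sc.r, sc.t) == (1, 3)


class TestPerkins:
    @pytest.mark.parametrize(
        "pd, tt, npd, cm",
        [(100, 0, 0, 0.0), (50, 50, 0, 25.0), (70, 27, 3, 22.5)],
    )
    def test_point_estimates(self, pd, tt, npd, cm):
        est = perkins_distance(counts(pd, tt, npd), n_boot=100, rng=0)
        assert est.cM == pytest.approx(cm)

    def test_bootstrap_se_is_seeded_and_plausible(self):
        est1 = perkins_distance(counts(70, 27, 3), rng=1)
        est2 = perkins_distance(counts(70, 27, 3), rng=1)
        assert est1.SE == est2.SE
        # binomial-scale sanity: TT/2 term alone gives SE ~ 100*sqrt(pq/n)/2
        assert 1.0 < est1.SE < 6.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            perkins_distance(counts(0, 0, 0))


class TestPapazian:
    def test_boundaries(self):
        assert papazian_expected_npd_fraction(0.0) == 0.0
        assert papazian_expected_npd_fraction(2.0 / 3.0) == pytest.approx(1.0 / 6.0)

    def test_mid_value(self):
        # 0.5*(1 - 0.4 - 0.4^(2/3)) with 0.4^(2/3) = 0.542884
        assert papazian_expected_npd_fraction(0.4) == pytest.approx(0.0285582, abs=1e-6)

    @pytest.mark.parametrize("bad", [-0.01, 0.67, 1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            papazian_expected_npd_fraction(bad)

    @given(st.floats(0.0, 2.0 / 3.0 - 1e-9))
    @settings(max_examples=200, deadline=None)
    def test_monotone_increasing_and_bounded(self, f):
        lo = papazian_expected_npd_fraction(f)
        hi = papazian_expected_npd_fraction(min(f + 1e-6, 2.0 / 3.0))
        assert 0.0 <= lo <= 1.0 / 6.0 + 1e-12
        assert hi >= lo - 1e-15


class TestInterference:
    def test_expected_count_and_ratio(self):
        res = interference_test(counts(59, 40, 1))
        assert res.npd_exp == pytest.approx(2.8558, abs=2e-4)
        assert res.ratio == pytest.approx(1 / 2.8558, abs=1e-3)

    def test_degenerate_no_tetratypes(self):
        res = interference_test(counts(100, 0, 0))
        assert math.isnan(res.ratio)
        assert res.p_two_sided == 1.0

    def test_observed_matching_expectation_is_insignificant(self):
        # choose TT so the expected NPD count is close to the observed one
        res = interference_test(counts(150, 138, 12))
        assert res.p_two_sided > 0.5
        assert res.ratio == pytest.approx(1.0, abs=0.2)

    def test_fisher2x2_mode_runs_and_agrees_in_direction(self):
        binom = interference_test(counts(250, 40, 10))
        fisher = interference_test(counts(250, 40, 10), mode="fisher2x2")
        assert fisher.mode == "fisher2x2"
        assert (binom.ratio > 1) == (fisher.ratio > 1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            interference_test(counts(10, 5, 1), mode="bogus")

    @given(
        n=st.integers(5, 50),
        tt_frac=st.floats(0.05, 0.6),
        npd=st.integers(0, 6),
    )
    @settings(max_examples=100, deadline=None)
    def test_binomial_p_matches_enumeration_oracle(self, n, tt_frac, npd):
        tt = int(round(tt_frac * n))
        pd = n - tt - npd
        if pd < 0 or tt == 0:
            return
        res = interference_test(counts(pd, tt, npd))
        expected_frac = papazian_expected_npd_fraction(tt / n)
        assert res.p_two_sided == pytest.approx(
            binom_two_sided_oracle(npd, n, expected_frac), rel=1e-8
        )


class TestMapTable:
    def test_total_is_sum_of_intervals(self):
        ests = [
            random_spore_distance(SporeCounts(r, 756), iv)
            for r, iv in [(204, ("HIS4", "CEN3")), (144, ("CEN3", "MAT")), (242, ("MAT", "RAD18"))]
        ]
        df = map_table({"control": ests})
        total = df[df["interval"] == "Total"]["cM"].iloc[0]
        assert total == pytest.approx(sum(e.cM for e in ests))
        assert len(df) == 4

    def test_single_interval_table(self):
        df = map_table({"s": [random_spore_distance(SporeCounts(10, 100))]})
        assert list(df["interval"]) == ["A-B", "Total"]
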