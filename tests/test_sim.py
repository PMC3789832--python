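"""Meiosis simulator: crossover placement, segregation and viability."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tetramap import (
    MarkerMap,
    P1,
    P2,
    SimulationConfig,
    TetradClass,
    build_study_scenario,
    chromosome_iii_map,
    classify_interval,
    count_interval_classes,
    expected_tetratype_fraction,
    place_crossovers,
    select_two_spore_viable,
    simulate_tetrads,
    viability_distribution,
)

from conftest import haldane_r


def two_locus(d: float) -> MarkerMap:
    return MarkerMap("X", [("A", 0.0), ("B", d)], centromere_locus="A")


class TestPlaceCrossovers:
    def test_zero_length_gives_no_crossovers(self):
        rng = np.random.default_rng(0)
        assert len(place_crossovers(0.0, 0, rng)) == 0

    def test_mean_crossover_count_no_interference(self):
        # 100 cM region: two crossovers per bivalent on average (one Morgan
        # per chromatid, each crossover involves two of the four chromatids)
        rng = np.random.default_rng(1)
        total = sum(len(place_crossovers(100.0, 0, rng)) for _ in range(20_000))
        assert total / 20_000 == pytest.approx(2.0, abs=0.03)

    def test_thinning_preserves_mean_rate(self):
        rng = np.random.default_rng(2)
        total = sum(len(place_crossovers(100.0, 4, rng)) for _ in range(20_000))
        assert total / 20_000 == pytest.approx(2.0, abs=0.05)

    def test_interference_induces_negative_count_correlation(self):
        """Adjacent-interval crossover counts: independent at m=0, negatively
        correlated under strong interference (m=4)."""
        rng = np.random.default_rng(3)
        corr = {}
        for m in (0, 4):
            left, right = [], []
            for _ in range(8_000):
                pos = place_crossovers(50.0, m, rng)
                left.append(int(np.sum(pos < 25.0)))
                right.append(int(np.sum(pos >= 25.0)))
            corr[m] = np.corrcoef(left, right)[0, 1]
        assert abs(corr[0]) < 0.05
        assert corr[4] < -0.10

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            place_crossovers(-1.0, 0, np.random.default_rng(0))


class TestExpectedTetratypeFraction:
    def test_limits(self):
        assert expected_tetratype_fraction(0.0) == 0.0
        assert expected_tetratype_fraction(1e6) == pytest.approx(2.0 / 3.0)

    def test_twenty_cm(self):
        # (2/3)(1 - e^(-0.6)) = 0.300792
        assert expected_tetratype_fraction(20.0) == pytest.approx(0.300792, abs=1e-6)


class TestSimulateTetrads:
    def test_determinism_given_seed(self):
        config = build_study_scenario("control_het", n_meioses=40, seed=9)
        assert simulate_tetrads(config) == simulate_tetrads(config)

    def test_tiny_distances_give_only_parental_ditypes(self):
        mm = MarkerMap("X", [("A", 0.0), ("B", 1e-9)], centromere_locus="A")
        tetrads = simulate_tetrads(SimulationConfig(marker_map=mm, n_meioses=200, seed=1))
        classes = {classify_interval(t, "A", "B") for t in tetrads}
        assert classes == {TetradClass.PD}

    def test_lethal_het_gives_exactly_two_viable(self):
        config = SimulationConfig(
            marker_map=chromosome_iii_map((27.0, 19.0, 32.0)),
            n_meioses=300,
            lethal_locus_present=True,
            seed=5,
        )
        dist = viability_distribution(simulate_tetrads(config))
        assert dist.counts == {4: 0, 3: 0, 2: 300, 1: 0, 0: 0}

    def test_lethal_pool_size(self):
        config = SimulationConfig(
            marker_map=chromosome_iii_map((27.0, 19.0, 32.0)),
            n_meioses=100,
            lethal_locus_present=True,
            seed=6,
        )
        assert len(select_two_spore_viable(simulate_tetrads(config))) == 200

    def test_reciprocity_without_conversion(self):
        """Every locus segregates exactly 2:2 when conversion is off."""
        config = SimulationConfig(
            marker_map=chromosome_iii_map((27.0, 19.0, 32.0), lethal=False),
            n_meioses=400,
            seed=7,
        )
        for tetrad in simulate_tetrads(config):
            for locus in ("HIS4", "CEN3", "MAT", "RAD18"):
                calls = [s.alleles[locus] for s in tetrad.spores]
                assert calls.count(P1) == 2 and calls.count(P2) == 2

    def test_conversion_produces_three_to_one_segregation(self):
        config = SimulationConfig(
            marker_map=two_locus(20.0),
            n_meioses=2_000,
            conversion_rate=0.05,
            seed=8,
        )
        non_mendelian = 0
        for tetrad in simulate_tetrads(config):
            for locus in ("A", "B"):
                calls = [s.alleles[locus] for s in tetrad.spores]
                if calls.count(P1) != 2:
                    non_mendelian += 1
                    assert calls.count(P1) in (1, 3)  # 3:1 either way
        # ~2000 * 2 loci * 0.05 events expected
        assert 120 < non_mendelian < 280

    def test_linked_lethal_masks_carrier_spores(self):
        mm = MarkerMap(
            "X",
            [("A", 0.0), ("L", 10.0), ("B", 20.0)],
            centromere_locus="A",
            lethal_locus="L",
        )
        config = SimulationConfig(
            marker_map=mm, n_meioses=150, lethal_locus_present=True, seed=10
        )
        for tetrad in simulate_tetrads(config):
            for spore in tetrad.spores:
                assert spore.viable == (spore.alleles["L"] == P1)

    def test_background_death_thins_viability(self):
        config = SimulationConfig(
            marker_map=two_locus(20.0),
            n_meioses=3_000,
            background_death_rate=0.1,
            seed=11,
        )
        dist = viability_distribution(simulate_tetrads(config))
        frac_viable = sum(k * dist[k] for k in range(5)) / (4 * dist.total_tetrads)
        assert frac_viable == pytest.approx(0.9, abs=0.02)

    def test_invalid_config_rejected_before_simulation(self):
        mm = two_locus(20.0)
        with pytest.raises(ValueError):
            simulate_tetrads(SimulationConfig(marker_map=mm, n_meioses=0))
        with pytest.raises(ValueError):
            simulate_tetrads(
                SimulationConfig(marker_map=mm, n_meioses=5, background_death_rate=1.5)
            )
        with pytest.raises(ValueError):
            # lethal flagged but no lethal locus named on the map
            simulate_tetrads(
                SimulationConfig(marker_map=mm, n_meioses=5, lethal_locus_present=True)
            )


class TestStatisticalFidelity:
    def test_tetratype_fraction_matches_closed_form(self):
        """Simulated fTT at 20 cM, m=0 agrees with (2/3)(1-e^(-3d/100))."""
        config = SimulationConfig(marker_map=two_locus(20.0), n_meioses=20_000, seed=12)
        cc = count_interval_classes(simulate_tetrads(config), "A", "B")
        expected = expected_tetratype_fraction(20.0)
        mc_se = math.sqrt(expected * (1 - expected) / cc.n)
        assert abs(cc.f_tt - expected) < 3 * mc_se

    def test_interior_interval_recombination_matches_haldane(self):
        """Recombinant-spore fraction of the middle interval of a three-
        interval map matches the Haldane expectation (map additivity)."""
        config = SimulationConfig(
            marker_map=chromosome_iii_map((27.0, 19.0, 32.0), lethal=False),
            n_meioses=8_000,
            seed=13,
        )
        tetrads = simulate_tetrads(config)
        r = t = 0
        for tetrad in tetrads:
            for spore in tetrad.spores:
                t += 1
                r += spore.alleles["CEN3"] != spore.alleles["MAT"]
        expected = haldane_r(19.0)
        assert abs(r / t - expected) < 3 * math.sqrt(expected * (1 - expected) / t)


class TestScenarios:
    def test_known_scenarios(self):
        control = build_study_scenario("control_het", seed=1)
        assert control.lethal_locus_present
        assert control.marker_map.positions == (0.0, 27.0, 46.0, 78.0)
        sumo = build_study_scenario("sumo_diminished", seed=1)
        assert sumo.marker_map.positions == (0.0, 34.0, 69.0, 109.0)
        pch2 = build_study_scenario("pch2_like", seed=1)
        assert not pch2.lethal_locus_present

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_study_scenario("wild_type_mars")
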