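"""Generators: transduction model, growth/dropout kinetics, reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest

from mirhts.competition import project
from mirhts.quantitation import StandardCurve, is_undetermined
from mirhts.simulate import (
    HIT_MIRS,
    NON_HIT_MIRS,
    CompetitionScenario,
    ScreenScenario,
    detection_probability,
    plant_utr_sites,
    simulate_competition,
    simulate_prediction_universe,
    simulate_qpcr_plate,
    simulate_screen,
)
from mirhts.target_filter import build_sets, filter_targets, find_seed_sites


class TestScreenScenario:
    def test_poisson_zero_class_transduced_fraction(self):
        # closed form: P(>=1 integration) = 1 - e^-MOI
        scenario = ScreenScenario()
        assert scenario.transduced_fraction == pytest.approx(1 - math.exp(-0.3))
        assert scenario.transduced_fraction == pytest.approx(0.259, abs=5e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"library_size": 0},
            {"moi": -0.1},
            {"timepoints": (4, 4, 12)},
            {"fitness_map": {"lenti-miR-0001": 0.0}},
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScreenScenario(**kwargs)

    def test_skewed_representation_must_sum_to_one(self):
        s = ScreenScenario(library_size=2)
        names = s.constructs
        with pytest.raises(ValueError):
            ScreenScenario(
                library_size=2, representation={names[0]: 0.6, names[1]: 0.5}
            )


class TestSimulateScreen:
    def test_neutral_null_shares_match_representation(self):
        """All w=1, no floor: per-construct share equals its library fraction
        at every timepoint (binomial sampling error only)."""
        scenario = ScreenScenario(library_size=20, rng_seed=3)
        ds = simulate_screen(scenario)
        expected = scenario.transduced_fraction * scenario.cells_sampled_per_tp / 20
        for tab in ds.replicates:
            shares = tab.groupby("timepoint_day")["abundance"].sum()
            per_construct = tab.pivot_table(
                index="construct", columns="timepoint_day", values="abundance"
            )
            assert np.allclose(per_construct.mean(axis=1), expected, rtol=0.05)
            assert tab["detected"].all()

    def test_inhibitory_construct_share_strictly_decreasing(self):
        """Brute-force expectation over the growth model: a w=0.85 clone's
        share of the sample declines at every later timepoint."""
        scenario = ScreenScenario(
            library_size=50,
            fitness_map={"lenti-miR-0001": 0.85},
            n_replicates=3,
            rng_seed=8,
        )
        ds = simulate_screen(scenario)
        stacked = pd.concat(ds.replicates)
        hit = stacked[stacked["construct"] == "lenti-miR-0001"]
        mean_by_tp = hit.groupby("timepoint_day")["abundance"].mean()
        assert (mean_by_tp.diff().dropna() < 0).all()
        # closed-form expectation at the first/last timepoint, pooled cells
        n0 = scenario.transduced_fraction * scenario.n_cells_infected / 50
        for t in (4.0, 28.0):
            weight = n0 * 0.85**t
            total = scenario.n_cells_infected - n0 * 50 + n0 * 49 + weight
            expect = scenario.cells_sampled_per_tp * weight / total
            assert mean_by_tp[t] == pytest.approx(expect, rel=0.15)

    def test_reproducible_under_fixed_seed(self):
        a = simulate_screen(ScreenScenario(library_size=10, rng_seed=5))
        b = simulate_screen(ScreenScenario(library_size=10, rng_seed=5))
        for ta, tb in zip(a.replicates, b.replicates):
            pd.testing.assert_frame_equal(ta, tb)

    def test_detection_probability_shape(self):
        copies = np.array([0.0, 10.0, 100.0, 1000.0])
        p = detection_probability(copies, dropout_floor=100.0, slope=4.0)
        assert p[0] == 0.0
        assert p[2] == pytest.approx(0.5)
        assert np.all(np.diff(p) >= 0)
        assert np.all(detection_probability(copies, 0.0) == [0, 1, 1, 1])


class TestSimulateCompetition:
    def test_neutral_series_stays_at_half(self):
        (series,) = simulate_competition(
            CompetitionScenario(n_replicates=1, rng_seed=1)
        )
        assert np.allclose(series.pct_gfp, 0.5, atol=0.02)

    def test_printed_trajectory_truth(self):
        # logit closed form: 46% at day 0 under s=-0.0582 reaches ~10% at 35
        assert project(0.46, -0.0582, 35) == pytest.approx(0.100, abs=5e-4)

    def test_mean_converges_to_deterministic_curve(self):
        scenario = CompetitionScenario(
            p0=0.4, s=-0.04, events_per_measurement=1_000_000, n_replicates=2, rng_seed=4
        )
        for series in simulate_competition(scenario):
            truth = [project(0.4, -0.04, t) for t in series.days]
            assert np.allclose(series.pct_gfp, truth, atol=2e-3)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            CompetitionScenario(events_per_measurement=0)

    def test_reproducible_under_fixed_seed(self):
        a = simulate_competition(CompetitionScenario(rng_seed=6))
        b = simulate_competition(CompetitionScenario(rng_seed=6))
        for sa, sb in zip(a, b):
            assert sa.pct_gfp == sb.pct_gfp


class TestSimulateQpcrPlate:
    CURVE = StandardCurve(slope=-3.3219, intercept=37.0)

    def test_single_copy_hits_intercept(self):
        assert simulate_qpcr_plate([1.0], self.CURVE)[0] == pytest.approx(37.0)

    def test_thousand_copies(self):
        assert simulate_qpcr_plate([1000.0], self.CURVE)[0] == pytest.approx(
            37.0 - 3.3219 * 3
        )

    def test_zero_copies_undetermined(self):
        assert is_undetermined(simulate_qpcr_plate([0.0], self.CURVE)[0])

    def test_noise_reproducible(self):
        a = simulate_qpcr_plate([100.0] * 8, self.CURVE, ct_sd=0.2, rng_seed=9)
        b = simulate_qpcr_plate([100.0] * 8, self.CURVE, ct_sd=0.2, rng_seed=9)
        assert a == b


class TestPredictionUniverse:
    def test_planted_targets_survive_filter(self, small_universe):
        predictions, expression, _ = small_universe
        sets = build_sets(predictions, HIT_MIRS, NON_HIT_MIRS, expression)
        assert {"TGTA", "TGTB"} <= filter_targets(*sets)

    def test_zero_rates_without_planting_is_empty(self):
        predictions, expression, _ = simulate_prediction_universe(
            n_genes=100, planted_targets=[], overlap_rates={}, rng_seed=2
        )
        sets = build_sets(predictions, HIT_MIRS, NON_HIT_MIRS, expression)
        assert filter_targets(*sets) == set()

    def test_region_counts_match_oracle_recount(self):
        """Recount every Venn region directly from the generated tables."""
        predictions, expression, _ = simulate_prediction_universe(
            n_genes=1000, planted_targets=["TGT1"], rng_seed=13
        )
        set1, set2, set3 = build_sets(predictions, HIT_MIRS, NON_HIT_MIRS, expression)
        # independent recount, row by row
        o1, o2, o3 = set(), set(), set()
        for row in predictions.itertuples():
            if row.mir in HIT_MIRS:
                o1.add(row.gene)
            if row.mir in NON_HIT_MIRS:
                o2.add(row.gene)
        for row in expression.itertuples():
            if row.call in ("marginal", "present"):
                o3.add(row.gene)
        assert (set1, set2, set3) == (o1, o2, o3)
        for region, members in {
            "s1_only": o1 - o2 - o3,
            "s1s3": (o1 & o3) - o2,
            "all": o1 & o2 & o3,
        }.items():
            assert members == {
                g
                for g in set1 | set2 | set3
                if (g in o1, g in o2, g in o3)
                == {
                    "s1_only": (True, False, False),
                    "s1s3": (True, False, True),
                    "all": (True, True, True),
                }[region]
            }

    def test_funnel_shape_strictly_decreasing(self, small_universe):
        predictions, expression, annotations = small_universe
        from mirhts.target_filter import annotate_and_shortlist

        set1, set2, set3 = build_sets(predictions, HIT_MIRS, NON_HIT_MIRS, expression)
        survivors = filter_targets(set1, set2, set3)
        shortlist = annotate_and_shortlist(survivors, annotations, predictions, HIT_MIRS)
        n_growth = len(shortlist)
        n_short = int(shortlist["shortlisted"].sum())
        assert len(set1) > len(survivors) > n_growth > n_short > 0


class TestPlantUtrSites:
    def test_published_geometry(self, planted_utr, mir_seq):
        sites = find_seed_sites(str(planted_utr.seq), mir_seq)
        assert [(s.start, s.end, s.site_class) for s in sites] == [
            (66, 72, "7mer-m8"),
            (759, 766, "8mer-A1"),
        ]
        assert len(planted_utr.seq) == 803

    def test_background_is_match_free(self, mir_seq):
        record = plant_utr_sites(500, mir_seq, [], [], rng_seed=21)
        assert find_seed_sites(str(record.seq), mir_seq) == []

    def test_edge_site_at_position_one(self, mir_seq):
        record = plant_utr_sites(60, mir_seq, [1], ["8mer-A1"], rng_seed=22)
        sites = find_seed_sites(str(record.seq), mir_seq)
        assert [(s.start, s.end) for s in sites] == [(1, 8)]

    def test_overlapping_sites_rejected(self, mir_seq):
        with pytest.raises(ValueError):
            plant_utr_sites(100, mir_seq, [10, 12], ["7mer-m8", "7mer-m8"], rng_seed=0)

    def test_out_of_bounds_rejected(self, mir_seq):
        with pytest.raises(ValueError):
            plant_utr_sites(50, mir_seq, [48], ["8mer-A1"], rng_seed=0)

    def test_reproducible_under_fixed_seed(self, mir_seq):
        a = plant_utr_sites(200, mir_seq, [30], ["7mer-A1"], rng_seed=17)
        b = plant_utr_sites(200, mir_seq, [30], ["7mer-A1"], rng_seed=17)
        assert str(a.seq) == str(b.seq)
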