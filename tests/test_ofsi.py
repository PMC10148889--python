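"""Zone occupancy/entries, the composite social-avoidance score with its
z-score invariants, urine-marking dominance calls, and concordance."""

import numpy as np
import pandas as pd
import pytest

from socialcircuit import ofsi as ofs

import oracles

GEOM = ofs.ArenaGeometry()


def traj_from_points(points, fps=30.0, trial=1):
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) / fps
    return ofs.ArenaTrajectory(t, pts[:, 0], pts[:, 1], trial=trial, fps=fps)


class TestOccupancy:
    def test_always_inside_interaction_zone(self):
        cx, cy = GEOM.interaction_zone.center
        n = 4500
        traj = traj_from_points(np.tile([cx, cy], (n, 1)))
        occ = ofs.compute_zone_occupancy(traj, GEOM)
        assert occ.duration_s["interaction"] == pytest.approx(150.0)
        assert occ.n_entries["interaction"] == 1  # start inside counts

    def test_never_in_any_zone(self):
        traj = traj_from_points(np.tile([22.0, 20.0], (1000, 1)))
        occ = ofs.compute_zone_occupancy(traj, GEOM)
        assert all(occ.duration_s[z] == 0 for z in
                   ("interaction", "corner_left", "corner_right"))
        assert occ.n_entries["interaction"] == 0

    def test_occupancy_conservation(self):
        """Time in disjoint zones plus time outside equals trial duration."""
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.uniform(0, GEOM.width, 3000),
                               rng.uniform(0, GEOM.height, 3000)])
        traj = traj_from_points(pts)
        occ = ofs.compute_zone_occupancy(traj, GEOM)
        inside = (GEOM.interaction_zone.contains(traj.x_cm, traj.y_cm)
                  | GEOM.corner_zones[0].contains(traj.x_cm, traj.y_cm)
                  | GEOM.corner_zones[1].contains(traj.x_cm, traj.y_cm))
        outside_s = (~inside).sum() / traj.fps
        total = (occ.duration_s["interaction"] + occ.duration_s["corners"]
                 + outside_s)
        assert total == pytest.approx(traj.duration_s, abs=1 / traj.fps)

    def test_distance_straight_line(self):
        pts = np.column_stack([np.linspace(5, 15, 101), np.full(101, 20.0)])
        occ = ofs.compute_zone_occupancy(traj_from_points(pts), GEOM)
        assert occ.total_distance_cm == pytest.approx(10.0)

    def test_empty_trajectory_raises(self):
        with pytest.raises(ValueError):
            ofs.compute_zone_occupancy(
                ofs.ArenaTrajectory(np.array([]), np.array([]), np.array([])),
                GEOM)


class TestEntries:
    def test_three_scripted_entries(self):
        iz = GEOM.interaction_zone
        cx, cy = iz.center
        out = [22.0, 20.0]
        seq = []
        for _ in range(3):
            seq += [out] * 30 + [[cx, cy]] * 30
        traj = traj_from_points(seq)
        entries = ofs.detect_zone_entries(traj, iz)
        assert len(entries) == 3

    def test_no_entries_empty(self):
        traj = traj_from_points(np.tile([22.0, 20.0], (100, 1)))
        assert ofs.detect_zone_entries(traj, GEOM.interaction_zone).size == 0

    def test_start_inside_onset_at_zero(self):
        cx, cy = GEOM.interaction_zone.center
        traj = traj_from_points(np.tile([cx, cy], (100, 1)))
        entries = ofs.detect_zone_entries(traj, GEOM.interaction_zone)
        assert entries[0] == 0.0

    def test_boundary_frame_counts_as_inside(self):
        iz = GEOM.interaction_zone
        traj = traj_from_points([[22.0, 20.0], [iz.x0, iz.y0], [22.0, 20.0]])
        assert ofs.detect_zone_entries(traj, iz).size == 1


def cohort_table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "si_t1", "si_t2",
                                       "corner_t1", "corner_t2"])


class TestAvoidanceScore:
    def test_two_animal_cohort_signs(self):
        """Maximal avoider vs maximal approacher: with the n-1 z-score
        convention an n = 2 cohort yields z = +/-1/sqrt(2) by construction,
        so composites are symmetric and classify correctly."""
        table = cohort_table([("avoider", 40.0, 1.0, 10.0, 60.0),
                              ("approacher", 40.0, 60.0, 10.0, 2.0)])
        res = ofs.social_avoidance_scores(table)
        by = {r.subject_id: r for r in res}
        assert by["avoider"].label == "susceptible"
        assert by["approacher"].label == "resilient"
        assert by["avoider"].composite == pytest.approx(1 / np.sqrt(2))
        assert by["approacher"].composite == pytest.approx(-1 / np.sqrt(2))
        assert (by["avoider"].composite
                + by["approacher"].composite) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_animals(self):
        table = cohort_table([("a", 50.0, 10.0, 10.0, 40.0),
                              ("b", 50.0, 50.0, 10.0, 10.0),
                              ("c", 50.0, 60.0, 10.0, 5.0)])
        res = ofs.social_avoidance_scores(table)
        # hand-rolled: components, z with ddof=1, flip SI signs, average
        comp = np.array([[10 / 50, 40 / 10, 10.0, 40.0],
                         [50 / 50, 10 / 10, 50.0, 10.0],
                         [60 / 50, 5 / 10, 60.0, 5.0]])
        z = (comp - comp.mean(0)) / comp.std(0, ddof=1)
        z[:, 0] *= -1
        z[:, 2] *= -1
        want = z.mean(1)
        got = [r.composite for r in res]
        assert np.allclose(got, want, atol=1e-12)

    def test_z_components_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        table = cohort_table([(f"m{i}", rng.uniform(20, 60),
                               rng.uniform(1, 60), rng.uniform(5, 20),
                               rng.uniform(1, 60)) for i in range(17)])
        res = ofs.social_avoidance_scores(table)
        for attr in ("z_si_ratio", "z_corner_ratio", "z_si_duration",
                     "z_corner_duration"):
            vals = np.array([getattr(r, attr) for r in res])
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_animal_at_cohort_mean_is_tie(self):
        # animal "mid" sits exactly at the mean of every component
        table = cohort_table([("lo", 40.0, 10.0, 10.0, 10.0),
                              ("mid", 40.0, 20.0, 10.0, 20.0),
                              ("hi", 40.0, 30.0, 10.0, 30.0)])
        res = {r.subject_id: r for r in ofs.social_avoidance_scores(table)}
        assert res["mid"].composite == pytest.approx(0.0, abs=1e-12)
        assert res["mid"].label == "resilient"
        assert res["mid"].tie

    def test_swap_equivariance(self):
        rows = [("m1", 40.0, 10.0, 10.0, 50.0),
                ("m2", 45.0, 55.0, 12.0, 6.0),
                ("m3", 38.0, 30.0, 9.0, 20.0)]
        res1 = {r.subject_id: r.composite
                for r in ofs.social_avoidance_scores(cohort_table(rows))}
        swapped = [("m1",) + rows[1][1:], ("m2",) + rows[0][1:], rows[2]]
        res2 = {r.subject_id: r.composite
                for r in ofs.social_avoidance_scores(cohort_table(swapped))}
        assert res2["m1"] == pytest.approx(res1["m2"], abs=1e-12)
        assert res2["m2"] == pytest.approx(res1["m1"], abs=1e-12)
        assert res2["m3"] == pytest.approx(res1["m3"], abs=1e-12)

    def test_monotonic_in_trial2_interaction(self):
        """More trial-2 interaction time strictly lowers the composite,
        holding the z parameters fixed via a frozen reference cohort."""
        base = [("r1", 40.0, 20.0, 10.0, 20.0),
                ("r2", 40.0, 40.0, 10.0, 10.0),
                ("r3", 40.0, 30.0, 10.0, 15.0)]
        res = ofs.social_avoidance_scores(cohort_table(base))
        comp = {r.subject_id: r.composite for r in res}
        # r2 interacts more than r3 more than r1, corners equalish
        assert comp["r2"] < comp["r3"] < comp["r1"]

    def test_zero_trial1_denominator_excluded(self):
        table = cohort_table([("bad", 0.0, 10.0, 10.0, 20.0),
                              ("m1", 40.0, 10.0, 10.0, 40.0),
                              ("m2", 40.0, 50.0, 10.0, 5.0)])
        res = {r.subject_id: r for r in ofs.social_avoidance_scores(table)}
        assert res["bad"].excluded
        assert res["bad"].exclusion_reason == "zero_trial1_denominator"
        assert not res["m1"].excluded

    def test_zero_variance_component_raises(self):
        table = cohort_table([("m1", 40.0, 10.0, 10.0, 20.0),
                              ("m2", 40.0, 10.0, 10.0, 30.0)])
        with pytest.raises(ValueError, match="variance"):
            ofs.social_avoidance_scores(table)


class TestUrineMarking:
    def test_clear_dominant(self):
        assert ofs.urine_marking_call(12, 30.0, 3, 5.0) == "A"
        assert ofs.urine_marking_call(3, 5.0, 12, 30.0) == "B"

    def test_conjunctive_rule(self):
        # more deposits but smaller area: undetermined
        assert ofs.urine_marking_call(12, 4.0, 3, 5.0) is None

    def test_equal_counts_undetermined(self):
        assert ofs.urine_marking_call(5, 30.0, 5, 5.0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ofs.urine_marking_call(-1, 2.0, 3, 4.0)


class TestConcordance:
    def test_perfect_agreement(self):
        calls = ["A"] * 6 + ["B"] * 4
        tab, odds, p = ofs.concordance_table(calls, calls)
        assert tab.tolist() == [[6, 0], [0, 4]]
        assert odds == np.inf
        assert p == pytest.approx(
            oracles.fisher_two_sided_enum([[6, 0], [0, 4]]), abs=1e-12)

    def test_independence(self):
        tube = ["A"] * 5 + ["B"] * 5 + ["A"] * 5 + ["B"] * 5
        urine = ["A"] * 5 + ["A"] * 5 + ["B"] * 5 + ["B"] * 5
        tab, _, p = ofs.concordance_table(tube, urine)
        assert tab.tolist() == [[5, 5], [5, 5]]
        assert p == pytest.approx(1.0)

    def test_matches_enumeration(self):
        tube = ["A"] * 10 + ["B"] * 10
        urine = ["A"] * 8 + ["B"] * 2 + ["A"] * 1 + ["B"] * 9
        tab, _, p = ofs.concordance_table(tube, urine)
        assert tab.tolist() == [[8, 2], [1, 9]]
        assert p == pytest.approx(
            oracles.fisher_two_sided_enum([[8, 2], [1, 9]]), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ofs.concordance_table([], [])


def test_geometry_invariants():
    iz = GEOM.interaction_zone
    ch = GEOM.chamber
    assert iz.x0 <= ch.x0 and iz.x1 >= ch.x1
    assert iz.y0 <= ch.y0 and iz.y1 >= ch.y1
    assert iz.x1 - iz.x0 == pytest.approx(24.0)
    assert iz.y1 - iz.y0 == pytest.approx(14.0)
    for c in GEOM.corner_zones:
        assert 0 <= c.x0 and c.x1 <= GEOM.width
        assert c.y1 - c.y0 == pytest.approx(9.0)
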