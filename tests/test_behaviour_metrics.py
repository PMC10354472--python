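import numpy as np
import pytest

from nestwatch import behaviour_metrics as bm
from nestwatch.io_formats import Detection, NestMap

from conftest import make_segment, random_segment


class TestOccupancy:
    def test_stationary_bee_single_bin(self, small_nest):
        seg = make_segment({"a": [(f, 12.0, 12.0) for f in range(5)]})
        g = bm.occupancy_distribution(seg, "a", 20.0, small_nest.arena_bounds)
        assert g.probabilities.max() == pytest.approx(1.0)
        assert g.probabilities.sum() == pytest.approx(1.0)

    def test_four_distinct_bins(self, small_nest):
        seg = make_segment({"a": [(0, 5.0, 5.0), (1, 45.0, 5.0),
                                  (2, 5.0, 45.0), (3, 45.0, 45.0)]})
        g = bm.occupancy_distribution(seg, "a", 20.0, small_nest.arena_bounds)
        vals = np.sort(g.probabilities.ravel())[-4:]
        np.testing.assert_allclose(vals, 0.25)

    def test_normalization_sweep(self, rng):
        for _ in range(1000):
            seg = random_segment(rng, n_bees=1, n_frames=int(rng.integers(1, 15)))
            g = bm.occupancy_distribution(seg, "bee00", float(rng.uniform(5, 40)),
                                          (0.0, 0.0, 100.0, 100.0))
            assert abs(g.probabilities.sum() - 1.0) < 1e-12

    def test_no_detections_flagged(self, small_nest):
        seg = make_segment({"a": [(0, 5.0, 5.0)]})
        with pytest.raises(bm.MetricsError):
            bm.occupancy_distribution(seg, "ghost", 20.0, small_nest.arena_bounds)


class TestElementInteraction:
    def test_all_mass_on_three_brood_bin(self):
        nest = NestMap(((10.0, 10.0), (11.0, 11.0), (12.0, 12.0)), (),
                       (0.0, 0.0, 100.0, 100.0), 0.5)
        seg = make_segment({"a": [(f, 10.0, 10.0) for f in range(4)]})
        g = bm.occupancy_distribution(seg, "a", 20.0, nest.arena_bounds)
        assert bm.element_interaction_rate(g, nest, "brood") == pytest.approx(3.0)

    def test_no_elements_zero(self, small_nest):
        nest = NestMap(((40.0, 30.0),), (), small_nest.arena_bounds, 0.5)
        seg = make_segment({"a": [(0, 5.0, 5.0)]})
        g = bm.occupancy_distribution(seg, "a", 20.0, nest.arena_bounds)
        assert bm.element_interaction_rate(g, nest, "pot") == 0.0

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            n_el = int(rng.integers(1, 6))
            elements = tuple((float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
                             for _ in range(n_el))
            nest = NestMap(elements, (), (0.0, 0.0, 100.0, 100.0), 0.5)
            seg = random_segment(rng, n_bees=1, n_frames=8)
            bin_px = float(rng.uniform(10, 35))
            g = bm.occupancy_distribution(seg, "bee00", bin_px, nest.arena_bounds)
            # brute force: for each detection bin, count elements sharing it
            expected = 0.0
            for iy in range(g.probabilities.shape[0]):
                for ix in range(g.probabilities.shape[1]):
                    count = 0
                    for (ex, ey) in elements:
                        exc = min(ex, g.x_edges[-1] - 1e-9)
                        eyc = min(ey, g.y_edges[-1] - 1e-9)
                        if (g.x_edges[ix] <= exc < g.x_edges[ix + 1]
                                and g.y_edges[iy] <= eyc < g.y_edges[iy + 1]):
                            count += 1
                    expected += g.probabilities[iy, ix] * count
            got = bm.element_interaction_rate(g, nest, "brood")
            assert got == pytest.approx(expected, abs=1e-9)

    def test_linear_in_element_counts(self, rng):
        seg = random_segment(rng, n_bees=1, n_frames=10)
        el = ((30.0, 30.0),)
        nest1 = NestMap(el, (), (0.0, 0.0, 100.0, 100.0), 0.5)
        nest2 = NestMap(el * 3, (), (0.0, 0.0, 100.0, 100.0), 0.5)
        g = bm.occupancy_distribution(seg, "bee00", 20.0, nest1.arena_bounds)
        assert bm.element_interaction_rate(g, nest2, "brood") == pytest.approx(
            3 * bm.element_interaction_rate(g, nest1, "brood"))


class TestSpatialCorrelation:
    def test_identical_grids(self, rng):
        seg = random_segment(rng, n_bees=1, n_frames=10)
        g = bm.occupancy_distribution(seg, "bee00", 20.0, (0.0, 0.0, 100.0, 100.0))
        assert bm.spatial_correlation(g, g) == pytest.approx(1.0)

    def test_disjoint_two_bin_grids(self):
        seg_a = make_segment({"a": [(0, 10.0, 10.0)]})
        seg_b = make_segment({"b": [(0, 90.0, 10.0)]})
        bounds = (0.0, 0.0, 100.0, 50.0)
        ga = bm.occupancy_distribution(seg_a, "a", 50.0, bounds)
        gb = bm.occupancy_distribution(seg_b, "b", 50.0, bounds)
        assert bm.spatial_correlation(ga, gb) == pytest.approx(-1.0)

    def test_constant_grid_skipped(self):
        bounds = (0.0, 0.0, 30.0, 30.0)  # single bin with size 40 -> constant
        seg = make_segment({"a": [(0, 10.0, 10.0)]})
        g = bm.occupancy_distribution(seg, "a", 40.0, bounds)
        assert bm.spatial_correlation(g, g) is None

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            seg = random_segment(rng, n_bees=2, n_frames=12)
            bounds = (0.0, 0.0, 100.0, 100.0)
            ga = bm.occupancy_distribution(seg, "bee00", 25.0, bounds)
            gb = bm.occupancy_distribution(seg, "bee01", 25.0, bounds)
            a, b = ga.probabilities.ravel(), gb.probabilities.ravel()
            expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
            assert bm.spatial_correlation(ga, gb) == pytest.approx(expected, abs=1e-9)

    def test_vectorized_matches_pairwise(self, rng):
        seg = random_segment(rng, n_bees=5, n_frames=10)
        bounds = (0.0, 0.0, 100.0, 100.0)
        grids = {b: bm.occupancy_distribution(seg, b, 25.0, bounds)
                 for b in seg.bee_ids()}
        fast = bm.mean_spatial_correlations(grids)
        for b, g in grids.items():
            corrs = [bm.spatial_correlation(g, go)
                     for ob, go in grids.items() if ob != b]
            corrs = [c for c in corrs if c is not None]
            assert fast[b] == pytest.approx(np.mean(corrs), abs=1e-9)


class TestContacts:
    def test_glued_pair(self):
        seg = make_segment({"a": [(f, 10.0, 10.0) for f in range(6)],
                            "b": [(f, 11.0, 10.0) for f in range(6)]})
        events = bm.contact_events(seg, mm_per_px=0.5, threshold_mm=10.0)
        stats = bm.contact_stats(seg, events).set_index("bee_id")
        assert len(events) == 6
        assert stats.loc["a", "mean_contact_rate"] == pytest.approx(1.0)
        assert stats.loc["a", "degree_centrality"] == 1

    def test_far_apart_trio(self):
        seg = make_segment({"a": [(0, 0.0, 0.0)], "b": [(0, 90.0, 0.0)],
                            "c": [(0, 0.0, 90.0)]})
        events = bm.contact_events(seg, mm_per_px=0.5, threshold_mm=10.0)
        assert events == []
        stats = bm.contact_stats(seg, events)
        assert (stats["mean_contact_rate"] == 0).all()
        assert (stats["degree_centrality"] == 0).all()

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            seg = random_segment(rng, n_bees=int(rng.integers(2, 6)),
                                 n_frames=int(rng.integers(1, 6)))
            thr = float(rng.uniform(5, 30))
            events = bm.contact_events(seg, mm_per_px=0.5, threshold_mm=thr)
            got = {(e.frame_index, e.bee_a, e.bee_b) for e in events}
            expected = set()
            dets = seg.detections
            for i in range(len(dets)):
                for j in range(len(dets)):
                    a, b = dets[i], dets[j]
                    if a.frame_index != b.frame_index or a.bee_id >= b.bee_id:
                        continue
                    d = 0.5 * np.hypot(a.x_px - b.x_px, a.y_px - b.y_px)
                    if d < thr:
                        expected.add((a.frame_index, a.bee_id, b.bee_id))
            assert got == expected

    def test_degree_sum_equals_twice_edges(self, rng):
        import networkx as nx

        seg = random_segment(rng, n_bees=6, n_frames=10)
        events = bm.contact_events(seg, mm_per_px=0.5, threshold_mm=30.0)
        g = bm.contact_graph(events)
        stats = bm.contact_stats(seg, events)
        assert stats["degree_centrality"].sum() == 2 * g.number_of_edges()

    def test_missing_scale_fails(self, rng):
        seg = random_segment(rng)
        with pytest.raises(bm.MetricsError):
            bm.contact_events(seg, mm_per_px=0.0)


class TestActivityThreshold:
    def test_bimodal_valley(self, rng):
        speeds = np.concatenate([rng.normal(0.2, 0.05, 400),
                                 rng.normal(5.0, 0.5, 400)])
        thr, method = bm.activity_threshold(speeds)
        assert 0.5 < thr < 4.0
        assert method == "kde_valley"
        # brute-force valley of the same KDE
        from scipy.stats import gaussian_kde
        grid = np.linspace(speeds.min(), speeds.max(), 512)
        dens = gaussian_kde(speeds)(grid)
        lo, hi = np.searchsorted(grid, 0.2), np.searchsorted(grid, 5.0)
        assert thr == pytest.approx(grid[lo + np.argmin(dens[lo:hi])], abs=0.2)

    def test_unimodal_fallback_flagged(self, rng):
        speeds = rng.normal(3.0, 0.3, 500)
        thr, method = bm.activity_threshold(speeds)
        assert method in ("gmm_boundary", "median_fallback")

    def test_permutation_invariance(self, rng):
        speeds = np.concatenate([rng.normal(0.2, 0.05, 200),
                                 rng.normal(5.0, 0.5, 200)])
        t1, _ = bm.activity_threshold(speeds)
        t2, _ = bm.activity_threshold(rng.permutation(speeds))
        assert t1 == pytest.approx(t2)

    def test_identical_speeds_fail(self):
        with pytest.raises(bm.MetricsError):
            bm.activity_threshold(np.full(200, 2.0))

    def test_too_few_samples_fail(self, rng):
        with pytest.raises(bm.MetricsError):
            bm.activity_threshold(rng.normal(size=50))


class TestMovingSpeed:
    def test_constant_motion(self):
        seg = make_segment({"a": [(f, 5.0 * f, 0.0) for f in range(10)]})
        ms, act = bm.moving_speed_and_activity(seg.track("a"), threshold=1.0)
        assert ms == pytest.approx(5.0)
        assert act == pytest.approx(1.0)

    def test_stationary_bee(self):
        seg = make_segment({"a": [(f, 5.0, 5.0) for f in range(10)]})
        ms, act = bm.moving_speed_and_activity(seg.track("a"), threshold=1.0)
        assert np.isnan(ms)
        assert act == 0.0

    def test_hand_worked_six_frame_example(self):
        # frames 0..5 at x = 0, 0, 4, 4, 10, 10; y = 0
        # speeds: 0, 4, 0, 6, 0 -> above threshold 1: {4, 6}
        seg = make_segment({"a": [(0, 0.0, 0.0), (1, 0.0, 0.0), (2, 4.0, 0.0),
                                  (3, 4.0, 0.0), (4, 10.0, 0.0), (5, 10.0, 0.0)]})
        ms, act = bm.moving_speed_and_activity(seg.track("a"), threshold=1.0)
        assert ms == pytest.approx(5.0)
        assert act == pytest.approx(2.0 / 5.0)

    def test_gap_rule(self):
        # gap of 2 frames -> speed = displacement / gap; gap of 5 -> track breaks
        track = [Detection(0, 0.0, "a", 0.0, 0.0),
                 Detection(2, 1.3, "a", 6.0, 0.0),
                 Detection(7, 4.7, "a", 100.0, 0.0)]
        frames, speeds = bm.frame_speeds(track)
        assert list(frames) == [0]
        assert speeds[0] == pytest.approx(3.0)

    def test_single_detection_missing(self):
        ms, act = bm.moving_speed_and_activity([Detection(0, 0.0, "a", 1.0, 1.0)], 1.0)
        assert np.isnan(ms) and np.isnan(act)


class TestDistanceMetrics:
    def test_bee_at_centre(self, small_nest):
        seg = make_segment({"a": [(f, 10.0, 10.0) for f in range(5)]})
        centre = bm.nest_centre(seg)
        dm = bm.distance_metrics(seg.track("a"), centre, small_nest)
        assert dm["distance_to_centre"] == pytest.approx(0.0)

    def test_single_brood_constant_distance(self):
        nest = NestMap(((60.0, 10.0),), (), (0.0, 0.0, 100.0, 100.0), 0.5)
        seg = make_segment({"a": [(f, 10.0, 10.0) for f in range(5)]})
        dm = bm.distance_metrics(seg.track("a"), (10.0, 10.0), nest)
        assert dm["median_dist_all_brood"] == pytest.approx(50.0)
        assert dm["min_dist_closest_brood"] == pytest.approx(50.0)

    def test_no_pots_flagged_missing(self):
        nest = NestMap(((60.0, 10.0),), (), (0.0, 0.0, 100.0, 100.0), 0.5)
        seg = make_segment({"a": [(0, 10.0, 10.0)]})
        dm = bm.distance_metrics(seg.track("a"), (10.0, 10.0), nest)
        assert np.isnan(dm["median_dist_all_pots"])
        assert np.isnan(dm["min_dist_closest_pot"])

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            n_brood = int(rng.integers(1, 4))
            n_pots = int(rng.integers(1, 4))
            nest = NestMap(
                tuple((float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
                      for _ in range(n_brood)),
                tuple((float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
                      for _ in range(n_pots)),
                (0.0, 0.0, 100.0, 100.0), 0.5)
            seg = random_segment(rng, n_bees=2, n_frames=int(rng.integers(1, 8)))
            centre = bm.nest_centre(seg)
            track = seg.track("bee00")
            dm = bm.distance_metrics(track, centre, nest)
            d_centre = [np.hypot(d.x_px - centre[0], d.y_px - centre[1]) for d in track]
            assert dm["distance_to_centre"] == pytest.approx(np.mean(d_centre), abs=1e-9)
            all_b = [np.hypot(d.x_px - bx, d.y_px - by)
                     for d in track for bx, by in nest.brood_centroids]
            assert dm["median_dist_all_brood"] == pytest.approx(np.median(all_b), abs=1e-9)
            closest = [min(np.hypot(d.x_px - bx, d.y_px - by)
                           for bx, by in nest.brood_centroids) for d in track]
            assert dm["min_dist_closest_brood"] == pytest.approx(np.median(closest),
                                                                 abs=1e-9)


class TestOnOffNest:
    nest = NestMap(((40.0, 30.0),), (), (0.0, 0.0, 200.0, 200.0), 0.5)

    def test_5mm_is_on(self):
        # 5 mm = 10 px at 0.5 mm/px
        assert bm.classify_on_off_nest((50.0, 30.0), self.nest) == "on"

    def test_25mm_is_off(self):
        assert bm.classify_on_off_nest((90.0, 30.0), self.nest) == "off"

    def test_15mm_intermediate(self):
        assert bm.classify_on_off_nest((70.0, 30.0), self.nest) == "intermediate"

    def test_no_brood_fails(self):
        nest = NestMap((), ((5.0, 5.0),), (0.0, 0.0, 10.0, 10.0), 0.5)
        with pytest.raises(bm.MetricsError):
            bm.classify_on_off_nest((1.0, 1.0), nest)


class TestColdRampDirection:
    def test_clustering_direction_under_cooling(self):
        """With thermotaxis on, cooling pulls bees toward the nest centre:
        distance_to_centre falls and brood_interaction_rate rises (sign test
        across 20 seeds)."""
        import pandas as pd
        from nestwatch import synthetic_colony as sc

        closer = 0
        broodier = 0
        n_seeds = 20
        for seed in range(n_seeds):
            params, proto, nest = sc.cold_experiment_setup(6, False, 500 + seed,
                                                           delta_ai_imid=0.0)
            segs, gt = sc.simulate_colony(params, proto, nest)
            thr, _ = bm.pooled_activity_threshold(segs)
            recs = []
            for s in segs:
                recs.extend(bm.compute_behaviour_records(s, nest, thr))
            df = pd.DataFrame([r.__dict__ for r in recs])
            vid_temp = gt.per_frame.groupby("video_id")["T_air_C"].mean()
            df["T_air"] = df["video_id"].map(vid_temp)
            cold = df[df["T_air"] < 12]
            warm = df[df["T_air"] > 22]
            closer += cold["distance_to_centre"].mean() < warm["distance_to_centre"].mean()
            broodier += cold["brood_interaction_rate"].mean() > warm["brood_interaction_rate"].mean()
        assert closer >= 15
        assert broodier >= 15


class TestTranslationInvariance:
    def test_all_metrics_translation_invariant(self, rng):
        dx, dy = 17.0, -9.0
        seg = random_segment(rng, n_bees=3, n_frames=12, bounds=(20, 20, 80, 80))
        nest = NestMap(((40.0, 40.0), (60.0, 50.0)), ((30.0, 70.0),),
                       (0.0, 0.0, 100.0, 100.0), 0.5)
        shifted = make_segment({
            b: [(d.frame_index, d.x_px + dx, d.y_px + dy) for d in seg.track(b)]
            for b in seg.bee_ids()})
        nest2 = NestMap(
            tuple((x + dx, y + dy) for x, y in nest.brood_centroids),
            tuple((x + dx, y + dy) for x, y in nest.pot_centroids),
            (dx, dy, 100.0 + dx, 100.0 + dy), 0.5)
        recs1 = bm.compute_behaviour_records(seg, nest, threshold=2.0)
        recs2 = bm.compute_behaviour_records(shifted, nest2, threshold=2.0)
        for r1, r2 in zip(recs1, recs2):
            for f in ("brood_interaction_rate", "mean_contact_rate",
                      "degree_centrality", "moving_speed", "distance_to_centre",
                      "median_dist_all_brood", "min_dist_closest_brood",
                      "activity_fraction", "mean_dist_nestmates"):
                v1, v2 = getattr(r1, f), getattr(r2, f)
                if np.isnan(v1):
                    assert np.isnan(v2)
                else:
                    assert v1 == pytest.approx(v2, abs=1e-9), f
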