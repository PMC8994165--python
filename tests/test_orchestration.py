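"""Growth pattern, neighbor-conditioned priors and whole-field runs."""

import numpy as np
import pytest

import perimetry as pm
from perimetry.orchestration import OrchestrationError
from perimetry.tessellation import neighbors_map


class TestGrowthWaves:
    def test_seeds_are_wave_one_and_bfs_invariant(self, grid24, plan24):
        waves = plan24.waves
        for s in plan24.seeds:
            assert waves[s] == 1
        for i in range(len(grid24)):
            if i in plan24.seeds:
                continue
            nb_waves = [waves[j] for j in plan24.neighbors[i]]
            assert waves[i] == 1 + min(nb_waves)

    def test_default_24_2_seeds_at_nine_nine(self, grid24, plan24):
        coords = {tuple(grid24.coords()[s]) for s in plan24.seeds}
        assert coords == {(9.0, 9.0), (-9.0, 9.0), (-9.0, -9.0),
                          (9.0, -9.0)}

    def test_seed_voronoi_neighbors_are_wave_two(self, grid24, plan24,
                                                 adj24):
        nbrs = neighbors_map(adj24, len(grid24))
        for s in plan24.seeds:
            for j in nbrs[s]:
                if j not in plan24.seeds:
                    assert plan24.waves[j] == 2

    def test_single_location_grid(self):
        g = pm.generate_custom_grid(
            {"mode": "explicit", "name": "one", "points": [[0, 0]]})
        plan = pm.build_growth_plan(g, seeds=[0])
        assert plan.waves.tolist() == [1]

    def test_unreachable_location_errors(self, grid24):
        g = pm.generate_custom_grid({
            "mode": "explicit", "name": "two-clusters",
            "points": [[0, 0], [1, 0], [50, 50], [51, 50]],
        })
        adjacency = {(0, 1), (1, 0), (2, 3), (3, 2)}
        with pytest.raises(OrchestrationError, match="unreachable"):
            pm.assign_growth_waves(g, [0], adjacency)

    def test_empty_seeds_rejected(self, grid24, adj24):
        with pytest.raises(OrchestrationError):
            pm.assign_growth_waves(grid24, [], adj24)


class TestNeighborPrediction:
    @pytest.fixture()
    def line_plan(self):
        # target 0 at origin; neighbors at distance 1 (idx 1) and 3 (idx 2)
        g = pm.generate_custom_grid({
            "mode": "explicit", "name": "line3",
            "points": [[0, 0], [1, 0], [-3, 0]],
        })
        adjacency = {(0, 1), (1, 0), (0, 2), (2, 0)}
        return pm.assign_growth_waves(g, [1, 2], adjacency)

    def test_single_finished_neighbor(self, line_plan):
        assert pm.neighbor_prediction(line_plan, {1: 28.0}, 0) == 28.0

    def test_equidistant_mean(self):
        g = pm.generate_custom_grid({
            "mode": "explicit", "name": "sym2",
            "points": [[0, 0], [2, 0], [-2, 0]],
        })
        plan = pm.assign_growth_waves(
            g, [1, 2], {(0, 1), (1, 0), (0, 2), (2, 0)})
        assert pm.neighbor_prediction(plan, {1: 20.0, 2: 30.0}, 0) == 25.0

    def test_inverse_distance_weights(self, line_plan):
        # (30/1 + 10/3) / (1 + 1/3) = 25
        pred = pm.neighbor_prediction(line_plan, {1: 30.0, 2: 10.0}, 0)
        assert pred == pytest.approx(25.0)

    def test_none_without_finished_neighbors(self, line_plan):
        assert pm.neighbor_prediction(line_plan, {}, 0) is None


class TestRunStaticTest:
    def _run(self, grid, plan, observer, machine_seed=0, sched_seed=1,
             procedure=None):
        machine = pm.open_machine({"seed": machine_seed}, observer)
        return pm.run_static_test(
            grid, procedure or {"procedure": "zest"}, machine,
            rng=sched_seed, plan=plan)

    def test_single_location_deterministic_observer(self):
        g = pm.generate_custom_grid(
            {"mode": "explicit", "name": "one", "points": [[0, 0]]})
        obs = pm.SimulatedObserver(thresholds=np.array([25.0]),
                                   fos_sd=0.01)
        machine = pm.open_machine({"seed": 0}, obs)
        field, log = pm.run_static_test(g, {"procedure": "zest"}, machine,
                                        seeds=[0])
        assert field.sensitivities[0] == pytest.approx(25.0, abs=1.5)
        assert len(log) == len(log.for_location(0))

    def test_fixed_seed_reproducible(self, grid24, plan24):
        logs = []
        for _ in range(2):
            obs = pm.SimulatedObserver(
                thresholds=np.full(54, 28.0), fos_sd=1.0, fp=0.03,
                fn=0.03)
            _, log = self._run(grid24, plan24, obs, machine_seed=7,
                               sched_seed=11)
            logs.append(log.records)
        assert logs[0] == logs[1]

    def test_scheduling_respects_growth_order(self, grid24, plan24):
        """No location is presented before a lower-wave neighbor has
        finished (wave-1 locations are free)."""
        obs = pm.SimulatedObserver(thresholds=np.full(54, 28.0),
                                   fos_sd=1.0, fp=0.03, fn=0.03)
        _, log = self._run(grid24, plan24, obs)
        finish_idx: dict[int, int] = {}
        per_loc: dict[int, list] = {}
        for r in log.records:
            per_loc.setdefault(r.location, []).append(r.presentation)
        for loc, pres in per_loc.items():
            finish_idx[loc] = max(pres)
        waves = plan24.waves
        bs = grid24.blind_spot_mask
        for loc, pres in per_loc.items():
            if waves[loc] == 1:
                continue
            lower = [
                j for j in plan24.neighbors[loc]
                if waves[j] < waves[loc] and (bs[j] or j in finish_idx)
            ]
            assert any(
                bs[j] or finish_idx[j] < min(pres) for j in lower
            ), f"location {loc} (wave {waves[loc]}) opened too early"

    def test_presentation_counts_within_bounds(self, grid24, plan24):
        obs = pm.SimulatedObserver(thresholds=np.full(54, 28.0),
                                   fos_sd=1.0, fp=0.03, fn=0.03)
        field, log = self._run(grid24, plan24, obs)
        bs = grid24.blind_spot_mask
        for i in range(54):
            n = len(log.for_location(i))
            if bs[i]:
                assert n == 0
                assert np.isnan(field.sensitivities[i])
            else:
                assert 4 <= n <= 25
                assert np.isfinite(field.sensitivities[i])

    def test_presentation_indices_strictly_increasing(self, grid24,
                                                      plan24):
        obs = pm.SimulatedObserver(thresholds=np.full(54, 28.0),
                                   fos_sd=1.0, fp=0.03, fn=0.03)
        _, log = self._run(grid24, plan24, obs)
        idx = [r.presentation for r in log.records]
        assert idx == sorted(idx) and len(set(idx)) == len(idx)

    def test_fourtwo_whole_field(self, grid24, plan24):
        obs = pm.SimulatedObserver(thresholds=np.full(54, 28.0),
                                   fos_sd=0.5)
        field, _ = self._run(grid24, plan24, obs,
                             procedure={"procedure": "fourTwo"})
        err = np.abs(field.sensitivities - 28.0)
        assert np.nanmean(err) < 3.0

    def test_catch_trial_rates_copied_from_observer(self, grid24, plan24):
        obs = pm.SimulatedObserver(thresholds=np.full(54, 28.0),
                                   fos_sd=1.0, fp=0.05, fn=0.02)
        field, _ = self._run(grid24, plan24, obs)
        assert field.fpr == 0.05 and field.fnr == 0.02
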