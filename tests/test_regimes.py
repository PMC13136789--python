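"""Trajectory dissimilarity geometry and the dDis / dBD / dEve metrics."""

import numpy as np
import pytest

from stochassembly import regimes as rg


def horizontal(y, rid="t", x0=0.0, x1=1.0, n=2):
    xs = np.linspace(x0, x1, n)
    return rg.Trajectory(rid, np.arange(n), np.column_stack([xs, np.full(n, y)]))


class TestSegmentPathDissimilarity:
    def test_identical_trajectories_zero(self):
        t = horizontal(0.0, n=4)
        assert rg.segment_path_dissimilarity(t, t) == 0.0

    def test_parallel_offset_equals_offset(self):
        a, b = horizontal(0.0), horizontal(0.25)
        assert rg.segment_path_dissimilarity(a, b) == pytest.approx(0.25)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rg.Trajectory("a", [0, 1, 2], rng.random((3, 2)))
            b = rg.Trajectory("b", [0, 1, 2], rng.random((3, 2)))
            assert rg.segment_path_dissimilarity(a, b) == pytest.approx(
                rg.segment_path_dissimilarity(b, a))
            assert rg.segment_path_dissimilarity(a, b) >= 0.0

    def test_direction_respected(self):
        """A reversed copy of a segment is farther than the copy itself."""
        fwd = horizontal(0.0)
        rev = rg.Trajectory("r", [0, 1], [[1.0, 0.0], [0.0, 0.0]])
        same = rg.segment_path_dissimilarity(fwd, fwd)
        opposite = rg.segment_path_dissimilarity(fwd, rev)
        assert opposite > same

    def test_single_state_trajectory_invalid(self):
        with pytest.raises(ValueError):
            rg.Trajectory("x", [0], [[0.0, 0.0]])


class TestRepresentativeTrajectory:
    def test_single_trajectory_under_every_criterion(self):
        t = horizontal(0.0)
        for crit in rg.CRITERIA:
            assert rg.representative_trajectory([t], crit) is t

    def test_medoid_by_brute_force(self):
        trajs = [horizontal(y, rid=f"t{y}") for y in (0.0, 0.1, 0.5)]
        dmat = rg.trajectory_dissimilarity_matrix(trajs)
        sums = dmat.sum(axis=1)
        expect = trajs[int(np.argmin(sums))]
        assert rg.representative_trajectory(trajs, "medoid") is expect

    def test_all_criteria_return_an_input(self):
        rng = np.random.default_rng(1)
        trajs = [rg.Trajectory(f"t{i}", [0, 1, 2], rng.random((3, 2)))
                 for i in range(4)]
        for crit in rg.CRITERIA:
            assert rg.representative_trajectory(trajs, crit) in trajs

    def test_criteria_agree_on_central_trajectory(self):
        """With one obviously central, longest, best-sampled trajectory all
        five criteria pick it."""
        center = rg.Trajectory("c", [0, 1, 2],
                               [[0, 0.0], [0.5, 0.0], [1.0, 0.0]])
        cloud = [horizontal(dy, rid=f"o{i}")
                 for i, dy in enumerate((-0.02, 0.02, -0.01, 0.01))]
        trajs = [center] + cloud
        for crit in rg.CRITERIA:
            assert rg.representative_trajectory(trajs, crit) is center


class TestRegimeMetrics:
    def test_ddis_hand_value(self):
        """Parallel offsets 0 / 0.2 / 0.4 with the first as reference."""
        trajs = [horizontal(0.0, "a"), horizontal(0.2, "b"),
                 horizontal(0.4, "c")]
        assert rg.dynamic_dispersion(trajs, trajs[0]) == pytest.approx(0.2)

    def test_ddis_identical_zero_and_mean_bound(self):
        trajs = [horizontal(0.0, f"t{i}") for i in range(3)]
        assert rg.dynamic_dispersion(trajs, trajs[0]) == 0.0
        spread = [horizontal(y) for y in (0.0, 0.1, 0.7)]
        dmat = rg.trajectory_dissimilarity_matrix(spread)
        assert rg.dynamic_dispersion(spread, spread[0], dmat) <= dmat[0].max()

    def test_dbd_hand_values(self):
        trajs = [horizontal(0.0), horizontal(0.1), horizontal(0.3)]
        # pairwise distances 0.1, 0.3, 0.2 -> mean 0.2
        assert rg.dynamic_beta_diversity(trajs) == pytest.approx(0.2)
        two = trajs[:2]
        assert rg.dynamic_beta_diversity(two) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            rg.dynamic_beta_diversity(trajs[:1])

    def test_deve_worked_example(self):
        """MST edge weights {0.1, 0.9}: dEve = (0.6 - 0.5) / (1 - 0.5) = 0.2."""
        dmat = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 1.0], [0.9, 1.0, 0.0]])
        assert rg.dynamic_evenness(dmat=dmat) == pytest.approx(0.2)

    def test_deve_equal_edges_is_one(self):
        trajs = [horizontal(y) for y in (0.0, 0.2, 0.4)]
        assert rg.dynamic_evenness(trajs) == pytest.approx(1.0)

    def test_deve_all_identical_is_one_with_warning(self):
        trajs = [horizontal(0.0, f"t{i}") for i in range(3)]
        with pytest.warns(UserWarning, match="zero"):
            assert rg.dynamic_evenness(trajs) == 1.0

    def test_deve_in_unit_interval_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = int(rng.integers(3, 8))
            D = rng.random((m, m))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            assert 0.0 <= rg.dynamic_evenness(dmat=D) <= 1.0

    def test_medoid_reference_beats_worst_case(self):
        trajs = [horizontal(y) for y in (0.0, 0.1, 0.2, 0.9)]
        dmat = rg.trajectory_dissimilarity_matrix(trajs)
        medoid = rg.representative_trajectory(trajs, "medoid", dmat)
        worst = trajs[int(np.argmax(dmat.sum(axis=1)))]
        assert rg.dynamic_dispersion(trajs, medoid, dmat) <= \
            rg.dynamic_dispersion(trajs, worst, dmat)


class TestRegimeReport:
    def test_metrics_invariant_to_replicate_relabeling(self, small_table):
        import pandas as pd

        rng = np.random.default_rng(0)
        coords = pd.DataFrame(rng.random((small_table.n_samples, 2)),
                              index=small_table.counts.columns,
                              columns=["mds1", "mds2"])
        base = rg.regime_report(small_table, coords)
        shuffled = small_table.meta.copy()
        remap = {0: 3, 1: 2, 2: 1, 3: 0}
        shuffled["replicate"] = shuffled["replicate"].map(remap)
        from stochassembly import CommunityTable

        table2 = CommunityTable(small_table.counts, shuffled)
        perm = rg.regime_report(table2, coords)
        for col in ("dDis", "dBD", "dEve"):
            assert np.allclose(base[col].to_numpy(), perm[col].to_numpy())

    def test_single_attractor_zero_noise(self):
        """Identical replicate trajectories give dDis = dBD = 0."""
        import pandas as pd

        from stochassembly import CommunityTable

        ids, rows, meta = [], {}, []
        for rep in range(4):
            for day in (2, 4):
                sid = f"s_r{rep}_t{day}"
                rows[sid] = [10, 20, 30]
                meta.append({"sample_id": sid, "source": "s", "dilution": 1.0,
                             "replicate": rep, "day": day})
                ids.append(sid)
        table = CommunityTable(pd.DataFrame(rows, index=["a", "b", "c"]),
                               pd.DataFrame(meta).set_index("sample_id"))
        coords = pd.DataFrame([[d, 0.0] for _ in range(4) for d in (0.0, 1.0)],
                              index=ids, columns=["mds1", "mds2"])
        with pytest.warns(UserWarning):
            rep = rg.regime_report(table, coords)
        assert rep["dDis"].iloc[0] == 0.0
        assert rep["dBD"].iloc[0] == 0.0
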