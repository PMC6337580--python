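import numpy as np
import pandas as pd
import pytest

from dockmd import lfel, synthetic


def _proj(xy, replicate=0):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "replicate": replicate,
            "frame": np.arange(len(xy)),
            "pc1": xy[:, 0],
            "pc2": xy[:, 1],
        }
    )


def _two_state_proj(population_a=0.8, n_frames=100_000, seed=17, sep=4.0,
                    noise=0.15, n_replicates=1):
    """1D two-state projections built from the trajectory generator."""
    a = np.zeros((2, 3))
    b = a.copy()
    b[:, 0] += sep / np.sqrt(6)  # projection separation == sep along (1,..)/sqrt(6)
    spec = synthetic.TwoStateSpec(
        population_a, a, b, noise_sigma=noise, n_frames=n_frames,
        n_replicates=n_replicates, seed=seed,
    )
    trajs = synthetic.gen_two_state_trajectory(spec)
    frames_list = []
    for t in trajs:
        flat = t.coords.reshape(t.n_frames, -1)
        direction = (b - a).ravel()
        direction = direction / np.linalg.norm(direction)
        pc1 = (flat - flat.mean(axis=0)) @ direction
        pc2 = np.zeros_like(pc1)
        frames_list.append(
            pd.DataFrame(
                {"replicate": t.replicate_id, "frame": np.arange(t.n_frames),
                 "pc1": pc1, "pc2": pc2}
            )
        )
    labels = np.concatenate([t.metadata["true_state_a"] for t in trajs])
    return pd.concat(frames_list, ignore_index=True), labels


class TestGrid:
    def test_counts_conserved(self, rng):
        proj = _proj(rng.normal(size=(100, 2)))
        grid = lfel.grid_microstates(proj)
        assert grid.counts.sum() == 100
        assert len(grid.assignments) == 100

    def test_identical_frames_single_bin(self):
        proj = _proj(np.tile([1.5, -2.0], (40, 1)))
        grid = lfel.grid_microstates(proj)
        assert (grid.pooled_counts > 0).sum() == 1

    def test_interior_edge_goes_to_higher_bin(self):
        # bins over [0, 2] with margin 0: edge at 1.0 belongs to the upper bin
        proj = _proj([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        grid = lfel.grid_microstates(proj, n_bins=(2, 1), margin=0.0)
        a = grid.assignments.sort_values("frame")
        assert a["ix"].tolist() == [0, 1, 1]

    def test_empty_projection_rejected(self):
        with pytest.raises(ValueError):
            lfel.grid_microstates(_proj(np.empty((0, 2))))


class TestWham:
    def test_zero_bias_equals_bruteforce_boltzmann(self, rng):
        # 10-line histogram oracle on random projections
        proj = _proj(rng.normal(size=(5000, 2)))
        grid = lfel.grid_microstates(proj, n_bins=(8, 8))
        out = lfel.wham_free_energy(grid)
        pooled = grid.pooled_counts
        occ = pooled > 0
        oracle = -np.log(pooled[occ] / pooled.sum())
        oracle -= oracle.min()
        oracle = np.minimum(oracle, 10.0)
        np.testing.assert_allclose(out.free_energy[occ], oracle, atol=1e-12)

    def test_two_state_delta_f(self):
        proj, labels = _two_state_proj(0.8, 100_000)
        grid = lfel.grid_microstates(proj, n_bins=(2, 1))
        out = lfel.wham_free_energy(grid)
        df = out.free_energy.max() - out.free_energy.min()
        assert df == pytest.approx(np.log(4.0), abs=0.05)

    def test_unoccupied_bins_capped(self, rng):
        proj = _proj(np.vstack([np.zeros((50, 2)), np.full((50, 2), 10.0)]))
        grid = lfel.grid_microstates(proj, n_bins=(16, 16))
        out = lfel.wham_free_energy(grid)
        unocc = grid.pooled_counts == 0
        assert unocc.any()
        assert np.all(out.free_energy[unocc] == 10.0)

    def test_doubling_counts_leaves_min_referenced_f_unchanged(self, rng):
        proj = _proj(rng.normal(size=(2000, 2)))
        grid = lfel.grid_microstates(proj, n_bins=(6, 6))
        out1 = lfel.wham_free_energy(grid)
        grid2 = lfel.LandscapeGrid(
            x_edges=grid.x_edges, y_edges=grid.y_edges, counts=grid.counts * 2,
            replicate_ids=grid.replicate_ids, assignments=grid.assignments,
        )
        out2 = lfel.wham_free_energy(grid2)
        np.testing.assert_allclose(out1.free_energy, out2.free_energy, atol=1e-12)

    def test_docked_reference_mode_zeroes_docked_bin(self, rng):
        proj = _proj(rng.normal(size=(4000, 2)))
        grid = lfel.grid_microstates(proj, n_bins=(8, 8))
        out = lfel.wham_free_energy(grid, reference="docked", docked_point=(0.0, 0.0))
        bx, by = out.bin_of(0.0, 0.0)
        assert out.free_energy[bx, by] == 0.0

    def test_pooling_replicates_equals_concatenation(self, rng):
        xy = rng.normal(size=(3000, 2))
        split = pd.concat(
            [_proj(xy[:1000], replicate=0), _proj(xy[1000:], replicate=1)],
            ignore_index=True,
        )
        merged = _proj(xy)
        ga = lfel.grid_microstates(split, n_bins=(6, 6))
        gb = lfel.grid_microstates(merged, n_bins=(6, 6))
        fa = lfel.wham_free_energy(ga).free_energy
        fb = lfel.wham_free_energy(gb).free_energy
        np.testing.assert_allclose(fa, fb, atol=1e-12)

    def test_constant_bias_absorbed_by_normalization(self, rng):
        # a flat bias per replicate shifts f_j, not the landscape
        proj = pd.concat(
            [_proj(rng.normal(size=(2000, 2)), replicate=r) for r in (0, 1)],
            ignore_index=True,
        )
        grid = lfel.grid_microstates(proj, n_bins=(6, 6))
        unbiased = lfel.wham_free_energy(grid)
        nx, ny = grid.n_bins
        series = np.zeros((2, 4, nx, ny))
        series[0] += 3.0  # kcal/mol, flat in state space
        series[1] += -1.5
        bias = lfel.BiasModel(series=series, times=np.array([0.0, 1, 2, 3]),
                              t_eq=0.5, t_sim=3.0)
        biased = lfel.wham_free_energy(grid, bias=bias)
        np.testing.assert_allclose(
            biased.free_energy, unbiased.free_energy, atol=1e-6
        )

    def test_single_replicate_known_bias_reweighting(self, rng):
        # one replicate: F(a) = -ln n_a - V_a/kT + const, analytically
        proj = _proj(rng.normal(size=(3000, 2)))
        grid = lfel.grid_microstates(proj, n_bins=(4, 4))
        nx, ny = grid.n_bins
        kt = lfel.KB_KCAL * 300.0
        v_kt = rng.uniform(0, 2, size=(nx, ny))  # kT units
        series = (v_kt * kt)[None, None].repeat(3, axis=1)
        bias = lfel.BiasModel(series=series, times=np.array([0.0, 1, 2]),
                              t_eq=-1.0, t_sim=2.0)
        out = lfel.wham_free_energy(grid, bias=bias)
        pooled = grid.pooled_counts
        occ = pooled > 0
        expected = -np.log(pooled[occ].astype(float)) - v_kt[occ]
        expected -= expected.min()
        got = out.free_energy[occ]
        # both are min-referenced; the cap may clip the rare high bins
        keep = expected < 10.0
        np.testing.assert_allclose(got[keep], expected[keep], atol=1e-6)

    def test_parameter_recovery_across_populations(self):
        for pa in (0.9, 0.8, 0.6):
            proj, labels = _two_state_proj(pa, 40_000, seed=int(pa * 100))
            grid = lfel.grid_microstates(proj, n_bins=(2, 1))
            out = lfel.wham_free_energy(grid)
            df = out.free_energy.max() - out.free_energy.min()
            n = len(labels)
            se = np.sqrt(1.0 / (n * pa) + 1.0 / (n * (1 - pa)))
            assert abs(df - np.log(pa / (1 - pa))) < 3 * se


class TestMinimum:
    def test_single_occupied_bin(self):
        proj = _proj(np.tile([0.5, 0.5], (10, 1)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(4, 4)))
        m = lfel.find_minimum(grid)
        assert grid.pooled_counts[m.ix, m.iy] == 10

    def test_tie_broken_by_count(self):
        # two bins, equal F by construction is impossible with unequal counts;
        # build equal counts in two bins and a synthetic tie via direct grid
        xy = np.vstack([np.tile([0.25, 0.5], (40, 1)), np.tile([0.75, 0.5], (60, 1))])
        proj = _proj(xy)
        grid = lfel.grid_microstates(proj, n_bins=(2, 1), margin=0.0)
        out = lfel.wham_free_energy(grid)
        out.free_energy[:] = 0.0  # force the tie
        m = lfel.find_minimum(out)
        assert grid.pooled_counts[m.ix, m.iy] == 60

    def test_planted_deep_state_recovered(self):
        proj, labels = _two_state_proj(0.8, 20_000, seed=5)
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(2, 1)))
        m = lfel.find_minimum(grid)
        # the minimum bin must hold majority-state frames
        members = grid.assignments[
            (grid.assignments["ix"] == m.ix) & (grid.assignments["iy"] == m.iy)
        ]
        frac_a = labels[members["frame"].to_numpy()].mean()
        assert frac_a > 0.95


class TestNeighborhood:
    def test_all_frames_sorted_by_distance(self, rng):
        proj = _proj(rng.normal(size=(200, 2)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(4, 4)))
        m = lfel.find_minimum(grid)
        nb = lfel.collect_neighborhood(proj, m, n_frames=200)
        assert len(nb) == 200
        assert np.all(np.diff(nb["distance"]) >= -1e-12)

    def test_single_frame_is_representative(self, rng):
        proj = _proj(rng.normal(size=(50, 2)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(4, 4)))
        m = lfel.find_minimum(grid)
        nb = lfel.collect_neighborhood(proj, m, n_frames=1)
        assert nb.iloc[0]["frame"] == m.frame
        assert nb.iloc[0]["distance"] == pytest.approx(0.0)

    def test_selected_within_kth_distance(self, rng):
        proj = _proj(rng.normal(size=(500, 2)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(6, 6)))
        m = lfel.find_minimum(grid)
        nb = lfel.collect_neighborhood(proj, m, n_frames=100)
        xy = proj[["pc1", "pc2"]].to_numpy()
        d = np.linalg.norm(xy - [m.pc1, m.pc2], axis=1)
        kth = np.sort(d)[99]
        assert np.all(nb["distance"] <= kth + 1e-12)

    def test_too_many_frames_rejected(self, rng):
        proj = _proj(rng.normal(size=(10, 2)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(2, 2)))
        m = lfel.find_minimum(grid)
        with pytest.raises(ValueError):
            lfel.collect_neighborhood(proj, m, n_frames=11)


class TestExport:
    def test_matrix_shape_and_min(self, rng):
        proj = _proj(rng.normal(size=(300, 2)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(12, 9)))
        heat, surface, docked_bin = lfel.export_maps(grid)
        assert heat.shape == (12, 9)
        m = lfel.find_minimum(grid)
        assert heat.to_numpy().min() == pytest.approx(m.f_kt)
        assert len(surface) == 12 * 9

    def test_tsv_roundtrip_precision(self, rng, tmp_path):
        proj = _proj(rng.normal(size=(300, 2)))
        grid = lfel.wham_free_energy(lfel.grid_microstates(proj, n_bins=(8, 8)))
        path = tmp_path / "heat.tsv"
        lfel.write_heatmap_tsv(grid, path)
        back = lfel.read_heatmap_tsv(path)
        np.testing.assert_allclose(back.to_numpy(), grid.free_energy, atol=1e-12)
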