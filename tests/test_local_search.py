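import numpy as np
import pytest

import pclfit as pf
from pclfit.local_search import SearchConfig, brute_force_fit


def straight_cubic(n):
    return pf.Conformation([[k, 0, 0] for k in range(n)], pf.CUBIC)


class TestPullMoves:
    def test_end_pull_reaches_l_shape(self):
        C = straight_cubic(4)
        neighbors = pf.pull_move_neighbors(C, 3)
        l_shape = pf.Conformation([[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]], pf.CUBIC)
        assert any(n == l_shape for n in neighbors)

    def test_all_neighbors_valid_and_distinct(self):
        _, C = pf.lattice_walk_backbone(15, pf.FCC, seed=6)
        for i in (0, 7, 14):
            for nb in pf.pull_move_neighbors(C, i):
                assert pf.validate(nb) == []
                assert nb != C
                # changed run is contiguous and includes i
                changed = np.nonzero((nb.points != C.points).any(axis=1))[0]
                assert i in changed
                assert np.array_equal(changed, np.arange(changed[0], changed[-1] + 1))

    def test_enclosed_end_point_has_no_moves(self):
        # the chain wraps around so that every neighbor of p0 and of p1 is
        # occupied: the end residue can neither relocate nor drag the chain
        pts = [
            [0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 0, -1], [1, 0, -1],
            [0, 0, -1], [0, 1, -1], [0, 1, 0], [1, 1, 0], [1, 1, 1],
            [1, 0, 1], [0, 0, 1], [-1, 0, 1], [-1, 0, 0], [-1, -1, 0],
            [0, -1, 0], [1, -1, 0],
        ]
        C = pf.Conformation(np.array(pts), pf.CUBIC)
        assert pf.validate(C) == []
        assert pf.pull_move_neighbors(C, 0) == []
        assert pf.jump_move_neighbors(C, [0]) == []

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            pf.pull_move_neighbors(straight_cubic(4), 7)


class TestJumpMoves:
    def test_corner_flip_finds_alternative_corner(self):
        C = pf.Conformation([[0, 0, 0], [1, 0, 0], [1, 1, 0]], pf.CUBIC)
        neighbors = pf.jump_move_neighbors(C, [1])
        flipped = pf.Conformation([[0, 0, 0], [0, 1, 0], [1, 1, 0]], pf.CUBIC)
        assert neighbors == [flipped]  # (0,1,0) is the only other mutual neighbor

    def test_straight_interior_point_has_no_jump(self):
        C = straight_cubic(5)
        assert pf.jump_move_neighbors(C, [2]) == []

    def test_terminal_relocations_bounded_by_basis_size(self):
        _, C = pf.lattice_walk_backbone(10, pf.FCC, seed=3)
        neighbors = pf.jump_move_neighbors(C, [9])
        assert 0 < len(neighbors) <= 11  # 12 neighbors of p8 minus occupied
        for nb in neighbors:
            assert pf.validate(nb) == []
            assert np.array_equal(nb.points[:9], C.points[:9])

    def test_multi_point_sequential_moves_valid(self):
        _, C = pf.lattice_walk_backbone(12, pf.FCC, seed=4)
        neighbors = pf.jump_move_neighbors(C, [2, 5, 8], move_size=3)
        for nb in neighbors:
            assert pf.validate(nb) == []
            assert nb != C

    def test_move_size_validation(self):
        with pytest.raises(ValueError):
            pf.jump_move_neighbors(straight_cubic(5), [1, 2], move_size=0)


class TestBruteForce:
    def test_n2_single_step_error(self):
        B = pf.Backbone("AG", np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        _, val = brute_force_fit(B, pf.CUBIC)
        assert val == pytest.approx(abs(3.8 - 5.0))

    def test_colinear_backbone_optimum_is_straight_walk(self, colinear_backbone):
        conf, val = brute_force_fit(colinear_backbone, pf.CUBIC)
        assert val == pytest.approx(0.0, abs=1e-12)
        steps = np.diff(conf.points, axis=0)
        assert np.array_equal(steps[0], steps[1])  # colinear

    def test_never_above_chain_growth(self):
        for s in range(3):
            B = pf.offlattice_backbone(6, seed=50 + s)
            _, opt = brute_force_fit(B, pf.CUBIC)
            init = pf.drmsd(B, pf.chain_growth_init(B, pf.CUBIC))
            assert opt <= init + 1e-12

    def test_guard_on_large_n(self):
        B = pf.offlattice_backbone(12, seed=0)
        with pytest.raises(ValueError):
            brute_force_fit(B, pf.FCC)


class TestSearchConfig:
    def test_defaults_match_contract(self):
        cfg = SearchConfig()
        assert cfg.move_size_init == 1
        assert cfg.factor > 1

    @pytest.mark.parametrize(
        "kwargs", [{"factor": 1.0}, {"move_size_init": 0}, {"stagnation_init": 0}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchConfig(**kwargs)


class TestPclfSearch:
    def test_exact_walk_floor_is_kept(self):
        B, _ = pf.lattice_walk_backbone(20, pf.FCC, seed=30)
        res = pf.pclf_search(B, pf.FCC, SearchConfig(seed=0, max_iterations=500))
        assert res.best_objective == pytest.approx(0.0, abs=1e-9)

    def test_trace_monotone_nonincreasing(self, small_coil):
        res = pf.pclf_search(small_coil, pf.FCC, SearchConfig(seed=1, max_iterations=800))
        vals = np.array([v for _, v in res.trace])
        assert np.all(np.diff(vals) <= 0)

    def test_seed_reproducibility(self, small_coil):
        cfg = SearchConfig(seed=42, max_iterations=400)
        a = pf.pclf_search(small_coil, pf.FCC, cfg)
        b = pf.pclf_search(small_coil, pf.FCC, cfg)
        assert a.best_objective == b.best_objective
        assert a.trace == b.trace
        assert np.array_equal(a.best.points, b.best.points)

    def test_result_valid_and_not_above_initial(self, small_coil):
        res = pf.pclf_search(small_coil, pf.CUBIC, SearchConfig(seed=2, max_iterations=600))
        assert pf.validate(res.best) == []
        assert res.best_objective <= res.initial_objective + 1e-12

    def test_stagnation_escalates_move_size(self, small_coil, monkeypatch):
        """After stagnation_init non-improving iterations the jump size grows."""
        import pclfit.local_search as ls

        sizes = []
        orig = ls._jump_candidates

        def spy(points, occupied, indices, lat, bound):
            sizes.append(len(list(indices)))
            return orig(points, occupied, indices, lat, bound)

        monkeypatch.setattr(ls, "_jump_candidates", spy)
        pf.pclf_search(
            small_coil,
            pf.FCC,
            SearchConfig(seed=5, max_iterations=300, stagnation_init=50, tabu_tenure=0),
        )
        assert max(sizes) >= 2  # escalated beyond the initial size of 1

    def test_energy_objective_minimizes_energy(self):
        B = pf.offlattice_backbone(15, seed=9)
        model = pf.load_energy_model("hp-basic")
        res = pf.pclf_search(
            B, pf.FCC, SearchConfig(seed=3, max_iterations=400), objective=model
        )
        vals = np.array([v for _, v in res.trace])
        assert np.all(np.diff(vals) <= 0)
        assert res.best_objective == pytest.approx(
            pf.total_energy(res.best, B.sequence, model)
        )
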