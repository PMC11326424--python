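"""U-map computation, Upp, and data-adaptive (minimal-Upp) selection."""

import numpy as np
import pytest

from daugs.core import LabelMask, MYOCARDIUM
from daugs.patches import PatchGrid, PatchProbabilityStack, build_grid
from daugs.pool import ModelPool, PoolMember, TrainConfig
from daugs.uncertainty import (
    compute_umap,
    compute_upp,
    daugs_select,
    total_energy_metric,
)

from test_pool import _MockModel, make_member


def stack_of(values, image=(1, 1)):
    """Stack in which every pixel is covered by len(values) patches."""
    grid = PatchGrid(image[0], 1, tuple([(0, 0)] * len(values)), image)
    pm = np.array(values, float).reshape(-1, 1, 1) * np.ones(
        (len(values), image[0], image[0])
    )
    return PatchProbabilityStack(grid, pm)


class TestComputeUmap:
    def test_identical_probs_give_zero(self):
        assert compute_umap(stack_of([0.7, 0.7, 0.7]))[0, 0] == 0.0

    def test_binary_pair_attains_half(self):
        assert compute_umap(stack_of([0.0, 1.0]))[0, 0] == pytest.approx(0.5)

    def test_population_std_convention(self):
        # {0.2, 0.8}: population std = 0.3 (sample std would be ~0.424)
        assert compute_umap(stack_of([0.2, 0.8]))[0, 0] == pytest.approx(
            0.3, abs=1e-12
        )

    def test_matches_brute_force_per_pixel(self, rng):
        grid = build_grid((12, 12), 6, 3)
        pm = rng.random((grid.n_patches, 6, 6))
        stack = PatchProbabilityStack(grid, pm)
        umap = compute_umap(stack)
        for r in range(12):
            for c in range(12):
                vals = stack.probabilities_at(r, c)
                expected = np.sqrt(np.mean((vals - vals.mean()) ** 2))
                assert umap[r, c] == pytest.approx(expected, abs=1e-12)

    def test_single_coverage_pixels_are_zero(self):
        grid = build_grid((8, 8), 4, 4)  # non-overlapping tiling
        stack = PatchProbabilityStack(
            grid, np.random.default_rng(0).random((grid.n_patches, 4, 4))
        )
        assert np.all(compute_umap(stack) == 0.0)


class TestComputeUpp:
    def test_zero_umap_gives_zero(self):
        mask = LabelMask(np.ones((5, 5), dtype=int))
        assert compute_upp(np.zeros((5, 5)), mask) == 0.0

    def test_direct_arithmetic(self):
        umap = np.zeros((5, 5))
        umap[2, 2] = 0.5
        mask = LabelMask(np.full((5, 5), MYOCARDIUM, dtype=int))
        assert compute_upp(umap, mask) == pytest.approx(0.25 / 25)

    def test_empty_myocardium_is_infinite(self):
        mask = LabelMask(np.zeros((5, 5), dtype=int))
        assert compute_upp(np.zeros((5, 5)), mask) == float("inf")

    def test_negative_umap_rejected(self):
        mask = LabelMask(np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError):
            compute_upp(np.array([[-0.1, 0], [0, 0]]), mask)

    def test_invariant_to_non_myocardium_relabeling(self):
        rng = np.random.default_rng(0)
        umap = rng.random((6, 6)) * 0.5
        labels = rng.integers(0, 3, (6, 6))
        swapped = labels.copy()
        swapped[labels == 0] = 2
        swapped[labels == 2] = 0
        assert compute_upp(umap, LabelMask(labels)) == compute_upp(
            umap, LabelMask(swapped)
        )


class TestTotalEnergy:
    def test_identities(self, rng):
        umap = rng.random((8, 8)) * 0.5
        assert total_energy_metric(np.zeros((4, 4))) == 0.0
        assert total_energy_metric(0.5 * umap) == pytest.approx(
            0.25 * total_energy_metric(umap)
        )
        labels = np.zeros((8, 8), dtype=int)
        labels[:3, :3] = MYOCARDIUM
        mask = LabelMask(labels)
        assert total_energy_metric(umap) == pytest.approx(
            compute_upp(umap, mask) * 9
        )


def _prob_model(myo_patch_fn):
    """Mock whose myocardium probability per patch comes from a callable."""

    def fn(x):
        n, _, p, _ = x.shape
        out = np.zeros((n, p, p, 3))
        for i in range(n):
            m = myo_patch_fn(i, p)
            out[i, ..., 1] = m
            out[i, ..., 0] = 1 - m
        return out

    return _MockModel(fn)


class TestDaugsSelect:
    def _series(self):
        from daugs.core import PerfusionSeries

        rng = np.random.default_rng(0)
        return PerfusionSeries(rng.random((16, 16, 3)))

    def test_singleton_pool_returns_its_solution(self):
        pool = ModelPool(
            [make_member(_prob_model(lambda i, p: 0.9), 0.9)], TrainConfig()
        )
        grid = build_grid((16, 16), 8, 4)
        sol = daugs_select(pool, self._series(), grid)
        assert sol.member_id == pool.members[0].member_id

    def test_consistent_model_beats_alternating_model(self):
        consistent = _prob_model(lambda i, p: 0.9)
        alternating = _prob_model(lambda i, p: 1.0 if i % 2 == 0 else 0.0)
        pool = ModelPool(
            [make_member(alternating, 0.95, epoch=1),
             make_member(consistent, 0.90, epoch=2)],
            TrainConfig(),
        )
        grid = build_grid((16, 16), 8, 4)
        log = []
        sol = daugs_select(pool, self._series(), grid, log=log)
        assert sol.member_id == pool.members[1].member_id
        assert sol.upp == 0.0
        assert len(log) == 2 and log[0]["upp"] > 0

    def test_all_empty_predictions_diagnosed(self):
        empty = _prob_model(lambda i, p: 0.0)
        pool = ModelPool([make_member(empty, 0.9)], TrainConfig())
        grid = build_grid((16, 16), 8, 4)
        with pytest.raises(RuntimeError, match="empty myocardium"):
            daugs_select(pool, self._series(), grid)

    def test_unknown_metric_rejected(self):
        pool = ModelPool([make_member(_prob_model(lambda i, p: 0.9), 0.9)],
                         TrainConfig())
        with pytest.raises(ValueError):
            daugs_select(pool, self._series(), build_grid((16, 16), 8, 4),
                         selection_metric="entropy")
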