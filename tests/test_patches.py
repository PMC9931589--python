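import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfdenoise3d import (
    SceneParams,
    TrainingPair,
    VideoStack,
    add_noise,
    augment,
    deinterleave,
    enumerate_forms,
    extract_training_pairs,
    make_scene,
    NoiseModel,
    pearson,
    plan_tiles,
    reinterleave,
    render_clean,
    total_voxels,
)


def brute_force_cover(shape, windows):
    """Oracle: count how many windows touch each voxel."""
    cover = np.zeros(shape, dtype=int)
    for (x0, x1), (y0, y1), (t0, t1) in windows:
        cover[x0:x1, y0:y1, t0:t1] += 1
    return cover


class TestPlanTiles:
    def test_benchmark_geometry_gives_75_windows(self):
        plan = plan_tiles((490, 490, 300), (150, 150, 150), 0.4)
        assert len(plan.windows) == 75
        assert total_voxels(plan) == 253_125_000

    def test_whole_stack_is_one_window(self):
        plan = plan_tiles((64, 48, 32), (64, 48, 32), 0.4)
        assert plan.windows == [((0, 64), (0, 48), (0, 32))]

    def test_boundary_clamp_example(self):
        # stride 90 would give starts {0, 90}; 90 > 200 - 150 so the final
        # start clamps to 50 (brute-force covering starts for this geometry)
        plan = plan_tiles((200, 150, 150), (150, 150, 150), 0.4)
        assert len(plan.windows) == 2
        assert sorted(w[0][0] for w in plan.windows) == [0, 50]

    def test_window_count_formula(self):
        for n, p, f in [(490, 150, 0.4), (300, 150, 0.4), (128, 32, 0.25)]:
            plan = plan_tiles((n, p, p), (p, p, p), f)
            stride = round(p * (1 - f))
            per_axis = int(np.ceil((n - p) / stride)) + 1
            assert len({w[0][0] for w in plan.windows}) == per_axis

    @given(
        n=st.integers(8, 60),
        p=st.integers(4, 40),
        f=st.floats(0.0, 0.9),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_coverage_property(self, n, p, f):
        if p > n:
            with pytest.raises(ValueError):
                plan_tiles((n, 8, 8), (p, 4, 4), f)
            return
        plan = plan_tiles((n, 8, 8), (p, 4, 4), f)
        cover = brute_force_cover(plan.source_shape, plan.windows)
        assert (cover >= 1).all()
        for ax in range(3):
            starts = sorted({w[ax][0] for w in plan.windows})
            assert starts == sorted(set(starts))  # strictly increasing
            assert all(0 <= s <= plan.source_shape[ax] - plan.patch[ax] for s in starts)

    def test_voxel_accounting(self):
        single = plan_tiles((150, 150, 150), (150, 150, 150), 0.4)
        assert total_voxels(single) == 3_375_000
        # doubling the t extent doubles the total for a fixed window count
        p1 = plan_tiles((32, 32, 64), (32, 32, 16), 0.0)
        p2 = plan_tiles((32, 32, 64), (32, 32, 32), 0.0)
        assert len(p1.windows) == 2 * len(p2.windows)
        assert total_voxels(p1) == total_voxels(p2)
        assert total_voxels(p2) == len(p2.windows) * 32 * 32 * 32


class TestDeinterleave:
    def test_parity_definition(self):
        block = np.arange(6)[None, None, :] * np.ones((2, 2, 1))
        inp, tgt = deinterleave(block)
        np.testing.assert_array_equal(inp[0, 0], [0, 2, 4])
        np.testing.assert_array_equal(tgt[0, 0], [1, 3, 5])

    def test_odd_t_extent_rejected(self):
        with pytest.raises(ValueError, match="even"):
            deinterleave(np.zeros((2, 2, 5)))

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(1, 8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bijection_property(self, nx, ny, half_t):
        rng = np.random.default_rng(nx * 100 + ny * 10 + half_t)
        block = rng.standard_normal((nx, ny, 2 * half_t))
        np.testing.assert_array_equal(reinterleave(*deinterleave(block)), block)

    def test_streams_statistically_exchangeable(self):
        # on a static noisy scene, input and target substreams have equal means
        p = SceneParams(fov=(32, 32), n_frames=200, n_cells=0, neuropil_fluct=0.0)
        clean = render_clean(make_scene(p, seed=1))
        noisy = add_noise(clean, NoiseModel(photon_scale=0.5), seed=2)
        inp, tgt = deinterleave(noisy.data)
        var = clean.data.mean() / 0.5
        se = np.sqrt(2 * var / inp.size)
        assert abs(inp.mean() - tgt.mean()) < 3 * se


class TestExtractTrainingPairs:
    def _stack(self, shape=(40, 40, 64)):
        rng = np.random.default_rng(0)
        return VideoStack(data=rng.uniform(0, 1, shape).astype(np.float32))

    def test_requested_count_and_shapes(self):
        pairs = extract_training_pairs(self._stack(), 5, (16, 16, 8), seed=0)
        assert len(pairs) == 5
        for p in pairs:
            assert p.input.shape == p.target.shape == (16, 16, 8)

    def test_single_pair_starts_at_zero(self):
        (pair,) = extract_training_pairs(self._stack(), 1, (16, 16, 8), seed=0)
        assert pair.origin[2] == (0, 16)

    def test_exact_fit_gives_consecutive_blocks(self):
        # nt = 2*st*k with n_pairs=k -> non-overlapping stride-2st blocks
        stack = self._stack((20, 20, 48))
        pairs = extract_training_pairs(stack, 3, (8, 8, 8), seed=1)
        assert [p.origin[2] for p in pairs] == [(0, 16), (16, 32), (32, 48)]

    def test_pair_frames_interleave_source_block(self):
        stack = self._stack()
        (pair,) = extract_training_pairs(stack, 1, (16, 16, 8), seed=3)
        (x0, x1), (y0, y1), (t0, t1) = pair.origin
        block = stack.data[x0:x1, y0:y1, t0:t1]
        np.testing.assert_array_equal(reinterleave(pair.input, pair.target), block)

    def test_too_short_stack_errors(self):
        with pytest.raises(ValueError, match="feasible"):
            extract_training_pairs(self._stack((20, 20, 10)), 2, (8, 8, 8), seed=0)


def _asym_pair(sx=4, sy=4, st_=2):
    rng = np.random.default_rng(7)
    return TrainingPair(
        input=rng.standard_normal((sx, sy, st_)),
        target=rng.standard_normal((sx, sy, st_)),
        origin=((0, sx), (0, sy), (0, 2 * st_)),
    )


class TestAugmentation:
    def test_twelve_distinct_labelled_forms(self):
        forms = enumerate_forms(_asym_pair())
        assert len(forms) == 12
        assert sorted(f.form_id for f in forms) == list(range(12))
        flat = [np.concatenate([f.input.ravel(), f.target.ravel()]) for f in forms]
        for i in range(12):
            for j in range(i + 1, 12):
                assert not np.array_equal(flat[i], flat[j])

    def test_constant_pair_collapses_to_two_assignments(self):
        pair = TrainingPair(
            input=np.zeros((3, 3, 2)), target=np.ones((3, 3, 2)),
            origin=((0, 3), (0, 3), (0, 4)),
        )
        outcomes = {
            (float(f.input[0, 0, 0]), float(f.target[0, 0, 0]))
            for f in enumerate_forms(pair)
        }
        assert outcomes == {(0.0, 1.0), (1.0, 0.0)}

    def test_form_frequencies_uniform(self):
        rng = np.random.default_rng(123)
        pair = _asym_pair()
        n = 12_000
        counts = np.zeros(12, dtype=int)
        for _ in range(n):
            counts[augment(pair, rng).form_id] += 1
        p = 1.0 / 12.0
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3 * se)

    def test_flips_and_180_are_involutions(self):
        pair = _asym_pair()
        for form_id in (1, 2, 4):  # hflip, vflip, rot180 without swap
            twice = enumerate_forms(enumerate_forms(pair)[form_id])[form_id]
            np.testing.assert_array_equal(twice.input, pair.input)
            np.testing.assert_array_equal(twice.target, pair.target)

    def test_left_then_right_rotation_is_identity(self):
        pair = _asym_pair()
        left = enumerate_forms(pair)[3]
        back = enumerate_forms(left)[5]
        np.testing.assert_array_equal(back.input, pair.input)

    def test_transforms_preserve_input_target_correlation(self):
        pair = _asym_pair()
        r0 = pearson(pair.input, pair.target)
        for f in enumerate_forms(pair):
            assert pearson(f.input, f.target) == pytest.approx(r0, abs=1e-12)

    def test_non_square_patches_degrade_to_shape_preserving_forms(self):
        pair = _asym_pair(sx=4, sy=6)
        forms = enumerate_forms(pair)
        assert len(forms) == 8
        for f in forms:
            assert f.input.shape == pair.input.shape
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert augment(pair, rng).input.shape == pair.input.shape
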