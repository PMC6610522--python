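import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmhseg.errors import ContractViolation, DegenerateSliceError, ParameterError
from wmhseg.lots_iam import (
    IAMConfig,
    age_grid,
    age_value,
    blend_age_maps,
    compute_age_map,
    compute_iam,
    extract_source_patches,
    patch_difference,
    penalize_and_normalize,
    sample_target_patches,
)


# ---------------------------------------------------------------- patches


@pytest.mark.parametrize(
    "shape,size,expected",
    [((256, 256), 8, 1024), ((64, 64), 8, 64), ((10, 10), 4, 9)],
)
def test_source_patch_count(shape, size, expected):
    ps = extract_source_patches(np.zeros(shape), size)
    assert len(ps) == expected


def test_source_patches_tile_disjointly():
    sl = np.arange(64).reshape(8, 8).astype(float)
    ps = extract_source_patches(sl, 2)
    seen = np.zeros_like(sl, dtype=int)
    for p, (r, c) in zip(ps.patches, ps.origins):
        assert np.array_equal(p, sl[r : r + 2, c : c + 2])
        seen[r : r + 2, c : c + 2] += 1
    assert (seen == 1).all()  # union covers the slice, pairwise disjoint


def test_size_one_enumerates_pixels():
    ps = extract_source_patches(np.zeros((4, 5)), 1)
    assert ps.origins == [(r, c) for r in range(4) for c in range(5)]


def test_oversized_patch_rejected():
    with pytest.raises(ParameterError):
        extract_source_patches(np.zeros((4, 4)), 8)


def test_target_sampling_inside_mask_and_deterministic():
    rng = np.random.default_rng(0)
    sl = rng.normal(size=(16, 16))
    mask = np.zeros((16, 16), bool)
    mask[4:12, 5:13] = True
    a = sample_target_patches(sl, mask, 4, 32, seed=5)
    b = sample_target_patches(sl, mask, 4, 32, seed=5)
    assert a.origins == b.origins
    for r, c in a.origins:
        assert mask[r : r + 4, c : c + 4].all()


def test_target_sampling_degenerate_mask():
    with pytest.raises(DegenerateSliceError):
        sample_target_patches(np.zeros((8, 8)), np.zeros((8, 8), bool), 4, 8, seed=0)


# ---------------------------------------------------------------- difference / age


def test_patch_difference_hand_value():
    s = np.array([[1.0, 2.0], [3.0, 4.0]])
    t = np.zeros((2, 2))
    assert patch_difference(s, t, 0.5) == pytest.approx(3.25, abs=1e-12)


def test_patch_difference_identical_and_theta_one(rng):
    s = rng.normal(size=(4, 4))
    assert patch_difference(s, s, 0.5) == 0.0
    t = rng.normal(size=(4, 4))
    assert patch_difference(s, t, 1.0) == pytest.approx(abs((s - t).max()), abs=1e-12)


def test_patch_difference_shape_mismatch():
    with pytest.raises(ContractViolation):
        patch_difference(np.zeros((2, 2)), np.zeros((3, 3)), 0.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    theta=st.floats(0, 1),
    vals=st.lists(st.floats(-50, 50), min_size=4, max_size=16),
)
def test_patch_difference_matches_bruteforce(theta, vals):
    n = 2
    arr = np.array(vals[: n * n * 2] + [0.0] * max(0, n * n * 2 - len(vals)))
    s, t = arr[: n * n].reshape(n, n), arr[n * n :].reshape(n, n)
    d = s - t
    expect = theta * abs(max(d.ravel())) + (1 - theta) * abs(sum(d.ravel()) / d.size)
    assert patch_difference(s, t, theta) == pytest.approx(expect, abs=1e-12)


def test_age_value_cases():
    assert age_value([7.0] * 100 + [1.0] * 50, 100) == pytest.approx(7.0)
    assert age_value([5.0, 1.0, 2.0], 100) == pytest.approx(8.0 / 3.0, abs=1e-12)
    assert age_value([0.0, 0.0], 100) == 0.0
    with pytest.raises(ContractViolation):
        age_value([], 100)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=40), st.integers(1, 20))
def test_age_value_equals_sorted_mean(vals, top_m):
    k = min(top_m, len(vals))
    expect = float(np.mean(sorted(vals, reverse=True)[:k]))
    assert age_value(vals, top_m) == pytest.approx(expect, abs=1e-9)


# ---------------------------------------------------------------- age maps


def _bruteforce_age_grid(sl, mask, size, cfg, targets):
    """Independent double-loop evaluation of the difference + top-m average."""
    gh, gw = -(-sl.shape[0] // size), -(-sl.shape[1] // size)
    grid = np.zeros((gh, gw))
    for gi in range(gh):
        for gj in range(gw):
            r, c = gi * size, gj * size
            if not mask[r : r + size, c : c + size].any():
                continue
            s = sl[r : r + size, c : c + size]
            diffs = [patch_difference(s, t, cfg.theta) for t in targets.patches]
            grid[gi, gj] = age_value(diffs, cfg.top_m)
    return grid


def test_age_grid_matches_bruteforce_oracle(rng):
    sl = rng.normal(loc=10, size=(8, 8))
    mask = np.ones((8, 8), bool)
    cfg = IAMConfig(patch_sizes=(2,), blend_weights=(1.0,), top_m=5, n_targets=16)
    targets = sample_target_patches(sl, mask, 2, 16, seed=3)
    fast = age_grid(sl, mask, 2, cfg, targets)
    slow = _bruteforce_age_grid(sl, mask, 2, cfg, targets)
    np.testing.assert_allclose(fast, slow, atol=1e-12)


def test_uniform_slice_gives_zero_map():
    sl = np.full((32, 32), 4.2)
    mask = np.ones((32, 32), bool)
    cfg = IAMConfig(n_targets=64)
    m = compute_age_map(sl, mask, 4, cfg, rng=1)
    assert np.all(m == 0)


def test_bright_square_dominates_age_map(rng):
    sl = np.full((32, 32), 10.0) + rng.normal(0, 0.01, (32, 32))
    sl[12:16, 20:24] = 30.0
    mask = np.ones((32, 32), bool)
    m = compute_age_map(sl, mask, 4, IAMConfig(n_targets=256), rng=2)
    r, c = np.unravel_index(m.argmax(), m.shape)
    assert 10 <= r < 18 and 18 <= c < 26
    assert 0.0 <= m.min() and m.max() <= 1.0


def test_empty_mask_yields_zero_map():
    m = compute_age_map(np.zeros((16, 16)), np.zeros((16, 16), bool), 2, IAMConfig())
    assert m.shape == (16, 16) and np.all(m == 0)


# ---------------------------------------------------------------- blend / final


def test_blend_identity_and_weighting(rng):
    m = rng.uniform(size=(8, 8))
    out = blend_age_maps([m, m, m, m], (0.65, 0.2, 0.1, 0.05))
    np.testing.assert_allclose(out, m, atol=1e-12)
    ones = np.ones((8, 8))
    zeros = np.zeros((8, 8))
    out = blend_age_maps([ones, zeros, zeros, zeros], (0.65, 0.2, 0.1, 0.05))
    np.testing.assert_allclose(out, 0.65, atol=1e-12)
    assert np.all(blend_age_maps([zeros] * 4, (0.65, 0.2, 0.1, 0.05)) == 0)


def test_blend_bounded_by_max_input(rng):
    maps = [rng.uniform(size=(6, 6)) for _ in range(4)]
    out = blend_age_maps(maps, (0.4, 0.3, 0.2, 0.1))
    assert (out <= np.maximum.reduce(maps) + 1e-12).all()


def test_blend_weight_validation():
    with pytest.raises(ParameterError):
        blend_age_maps([np.zeros((2, 2))] * 2, (0.6, 0.6))


def test_penalize_minmax_contract(rng):
    blended = rng.uniform(size=(8, 8, 3))
    flair = rng.uniform(1, 2, size=(8, 8, 3))
    mask = np.zeros((8, 8, 3), bool)
    mask[2:6, 2:6, :] = True
    out = penalize_and_normalize(blended, flair, mask)
    assert out[mask].min() == 0.0 and out[mask].max() == 1.0
    assert (out[~mask] == 0).all()
    prod = blended * flair
    assert np.argmax(out * mask) == np.argmax(np.where(mask, prod, -np.inf))


def test_penalize_scale_invariance(rng):
    blended = rng.uniform(size=(6, 6, 2))
    flair = rng.uniform(1, 3, size=(6, 6, 2))
    mask = np.ones((6, 6, 2), bool)
    a = penalize_and_normalize(blended, flair, mask)
    b = penalize_and_normalize(blended, 2.0 * flair, mask)
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_penalize_zero_blend_gives_zero():
    out = penalize_and_normalize(
        np.zeros((4, 4, 2)), np.ones((4, 4, 2)), np.ones((4, 4, 2), bool)
    )
    assert np.all(out == 0)


# ---------------------------------------------------------------- volume level


def test_compute_iam_lesion_separation(phantom_bundle, phantom_iam):
    from wmhseg.preprocess import brain_tissue_mask

    b = phantom_bundle
    brain = brain_tissue_mask(b.icv, b.csf).data.astype(bool)
    lesions = b.labels.data == 2
    fm = phantom_iam.final_map
    assert fm[lesions].mean() > fm[brain & ~lesions].mean()
    assert fm.min() >= 0.0 and fm.max() <= 1.0
    assert (fm[~brain] == 0).all()


def test_lesioned_vs_lesion_free_paired_comparison():
    """Same seed with and without lesions: at the lesion sites the lesioned
    twin must score far higher irregularity than the healthy twin (the global
    min-max fixes each map's maximum at 1, so site-wise means are the
    comparable statistic)."""
    from wmhseg.phantom import PhantomSpec, generate_phantom

    cfg = IAMConfig(n_targets=128, seed=1)
    lesioned = generate_phantom(PhantomSpec(shape=(64, 64, 5), lesion_count=4, seed=21))
    healthy = generate_phantom(PhantomSpec(shape=(64, 64, 5), lesion_count=0, seed=21))
    sites = lesioned.labels.data == 2
    iam_l = compute_iam(lesioned.flair, lesioned.icv, lesioned.csf, cfg)
    iam_h = compute_iam(healthy.flair, healthy.icv, healthy.csf, cfg)
    assert iam_l.final_map[sites].mean() > iam_h.final_map[sites].mean()


def test_lesion_contrast_monotonicity():
    from wmhseg.phantom import PhantomSpec, generate_phantom
    from wmhseg.preprocess import brain_tissue_mask

    cfg = IAMConfig(n_targets=128, seed=4)
    lesion_means = []
    for contrast in (1.3, 1.6, 2.0):
        b = generate_phantom(
            PhantomSpec(shape=(64, 64, 5), lesion_count=4, lesion_contrast=contrast, seed=33)
        )
        iam = compute_iam(b.flair, b.icv, b.csf, cfg)
        lesions = b.labels.data == 2
        lesion_means.append(iam.final_map[lesions].mean())
    assert lesion_means == sorted(lesion_means)


def test_compute_iam_deterministic(phantom_bundle):
    b = phantom_bundle
    cfg = IAMConfig(n_targets=64, patch_sizes=(2, 4), blend_weights=(0.7, 0.3), seed=9)
    a = compute_iam(b.flair, b.icv, b.csf, cfg)
    c = compute_iam(b.flair, b.icv, b.csf, cfg)
    np.testing.assert_array_equal(a.final_map, c.final_map)


def test_config_validation():
    with pytest.raises(ParameterError):
        IAMConfig(blend_weights=(0.5, 0.5, 0.1, -0.1))
    with pytest.raises(ParameterError):
        IAMConfig(patch_sizes=(4, 2))
    with pytest.raises(ParameterError):
        IAMConfig(theta=1.5)
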