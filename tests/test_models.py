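import numpy as np
import pytest
from scipy import ndimage

from wmhseg.errors import ParameterError
from wmhseg.models import (
    ArchitectureSpec,
    build_model,
    count_parameters,
    depth_sweep_specs,
    dilated_conv2d_reference,
    load_weights,
    receptive_field,
    save_weights,
    summarize,
)
from wmhseg.nn import Conv2d

TABLE1 = {
    ("unet", 1): 7_859_715,
    ("unet", 2): 7_861_315,
    ("saliency_unet", 1): 2_756_803,
    ("dilated_saliency_unet", 1): 2_623_683,
}


# ------------------------------------------------------------ dilated conv


def test_reference_conv_k1_equals_standard_correlation(rng):
    I = rng.normal(size=(9, 9))
    W = rng.normal(size=(3, 3))
    out = dilated_conv2d_reference(I, W, k=1)
    expect = ndimage.correlate(I, W, mode="constant", cval=0.0)
    np.testing.assert_allclose(out, expect, atol=1e-12)


def test_reference_conv_impulse_footprint():
    I = np.zeros((11, 11))
    I[5, 5] = 1.0
    W = np.arange(9, dtype=float).reshape(3, 3) + 1
    out = dilated_conv2d_reference(I, W, k=2)
    nz_r, nz_c = np.nonzero(out)
    # 5x5 footprint with one-pixel gaps between taps
    assert nz_r.max() - nz_r.min() == 4 and nz_c.max() - nz_c.min() == 4
    assert len(nz_r) == 9
    # impulse reproduces the (flipped-index) kernel taps on the dilated grid
    taps = sorted(out[nz_r, nz_c])
    assert taps == sorted(W.ravel())


def test_reference_conv_all_ones_interior_sums_kernel(rng):
    W = rng.normal(size=(3, 3))
    out = dilated_conv2d_reference(np.ones((9, 9)), W, k=1)
    assert out[4, 4] == pytest.approx(W.sum(), abs=1e-12)
    out2 = dilated_conv2d_reference(np.ones((13, 13)), W, k=3)
    assert out2[6, 6] == pytest.approx(W.sum(), abs=1e-12)


def test_reference_conv_validation():
    with pytest.raises(ParameterError):
        dilated_conv2d_reference(np.zeros((4, 4)), np.zeros((2, 2)), 1)
    with pytest.raises(ParameterError):
        dilated_conv2d_reference(np.zeros((4, 4)), np.zeros((3, 3)), 0)


@pytest.mark.parametrize("k", [1, 2, 3])
def test_reference_matches_fast_layer(k, rng):
    """The literal double-sum agrees with the vectorised im2col layer."""
    I = rng.normal(size=(12, 12))
    layer = Conv2d(1, 1, 3, dilation=k, rng=rng)
    layer.bias.value[...] = 0.0
    W = layer.weight.value[0, 0]
    fast = layer.forward(I[None, None])[0, 0]
    slow = dilated_conv2d_reference(I, W, k=k)
    np.testing.assert_allclose(fast, slow, atol=1e-5)


# ------------------------------------------------------------ receptive field


@pytest.mark.parametrize("n,k,expect", [(3, 1, 3), (3, 3, 7), (3, 2, 5), (5, 1, 5)])
def test_receptive_field_formula(n, k, expect):
    assert receptive_field(n, k) == expect


def test_receptive_field_agrees_with_impulse_footprint():
    for k in (1, 2, 3):
        I = np.zeros((15, 15))
        I[7, 7] = 1.0
        out = dilated_conv2d_reference(I, np.ones((3, 3)), k=k)
        nz = np.nonzero(out)[0]
        assert nz.max() - nz.min() + 1 == receptive_field(3, k)


def test_receptive_field_validation():
    with pytest.raises(ParameterError):
        receptive_field(0, 1)
    with pytest.raises(ParameterError):
        receptive_field(3, 0)


# ------------------------------------------------------------ architectures


@pytest.mark.parametrize("family,channels", list(TABLE1))
def test_published_parameter_counts(family, channels):
    spec = ArchitectureSpec(family=family, in_channels=channels)
    assert count_parameters(build_model(spec)) == TABLE1[(family, channels)]


def test_two_channel_unet_adds_first_layer_weights():
    one = count_parameters(build_model(ArchitectureSpec(family="unet", in_channels=1)))
    two = count_parameters(build_model(ArchitectureSpec(family="unet", in_channels=2)))
    assert two - one == 5 * 5 * 64  # kernel area x first-layer channels


def test_dilation_adds_no_parameters():
    base = ArchitectureSpec(family="dilated_saliency_unet", dilation_schedule=(1, 2, 4, 2))
    for sched in [(1, 2, 2, 4), (4, 2, 2, 1)]:
        other = ArchitectureSpec(family="dilated_saliency_unet", dilation_schedule=sched)
        assert count_parameters(build_model(other), include_running_stats=False) == \
            count_parameters(build_model(base), include_running_stats=False)


def test_saliency_family_smaller_than_unet():
    unet = count_parameters(build_model(ArchitectureSpec(family="unet", in_channels=2)))
    for fam in ("saliency_unet", "dilated_saliency_unet"):
        assert count_parameters(build_model(ArchitectureSpec(family=fam))) < unet


@pytest.mark.parametrize("family", ["unet", "saliency_unet", "dilated_saliency_unet"])
def test_output_shape_and_softmax(family, rng):
    spec = ArchitectureSpec(family=family, in_channels=2 if family == "unet" else 1,
                            base_width=4)
    m = build_model(spec, seed=0)
    x = rng.normal(size=(2, 2, 32, 32))
    probs = m.predict_proba(x)
    assert probs.shape == (2, 3, 32, 32)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)


def test_block_count_and_depth_sweep():
    base = ArchitectureSpec(family="saliency_unet", base_width=4)
    m14 = build_model(base)
    assert len(m14.conv_blocks()) == 14
    counts = []
    for depth in (14, 20, 26):
        spec = depth_sweep_specs(base, depth)
        m = build_model(spec)
        assert len(m.conv_blocks()) == depth
        counts.append(count_parameters(m))
    assert counts == sorted(counts) and len(set(counts)) == 3
    # growing 14 -> 20 adds exactly 6 CONV blocks
    assert len(build_model(depth_sweep_specs(base, 20)).conv_blocks()) - 14 == 6
    with pytest.raises(ParameterError):
        depth_sweep_specs(base, 17)
    with pytest.raises(ParameterError):
        depth_sweep_specs(ArchitectureSpec(family="unet"), 20)


def test_deeper_models_still_segment(rng):
    spec = depth_sweep_specs(ArchitectureSpec(family="saliency_unet", base_width=2), 20)
    m = build_model(spec)
    x = rng.normal(size=(1, 2, 32, 32))
    assert m.predict_proba(x).shape == (1, 3, 32, 32)


def test_summary_records_convention():
    text = summarize(build_model(ArchitectureSpec(family="unet", base_width=4)))
    assert "count_convention: total" in text
    text = summarize(build_model(ArchitectureSpec(family="saliency_unet", base_width=4)))
    assert "count_convention: trainable" in text


def test_weight_checkpoint_round_trip(tmp_path, rng):
    spec = ArchitectureSpec(family="saliency_unet", base_width=2)
    m = build_model(spec, seed=1)
    x = rng.normal(size=(1, 2, 16, 16))
    before = m.predict_proba(x)
    save_weights(m, tmp_path / "w.npz")
    m2 = build_model(spec, seed=99)
    load_weights(m2, tmp_path / "w.npz")
    np.testing.assert_array_equal(before, m2.predict_proba(x))
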