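"""Architecture variants: shapes, shuffles, and exact parameter audits.

The parameter oracle here is closed-form arithmetic written
independently of the package's module-walking counter: one formula per
block type, summed by hand over the known layer layout.
"""

import numpy as np
import pytest

from litchidet.architecture import (CBAM, C3, CBAM_LADDER_CONVENTION, ConvBN,
                                    DetectionModel, ShuffleV2Block, SPPF,
                                    VARIANTS, VariantSpec, build_variant,
                                    channel_shuffle, count_parameters)
from litchidet.nn import Tensor


# --- independent closed-form ledger (deployed convention) ------------------

def conv_bn(c1, c2, k, g=1):
    return c1 * c2 * k * k // g + c2


def c3_params(c1, c2, n):
    c_ = c2 // 2
    t = 2 * conv_bn(c1, c_, 1) + conv_bn(2 * c_, c2, 1)
    return t + n * (conv_bn(c_, c_, 1) + conv_bn(c_, c_, 3))


def sppf_params(c1, c2):
    c_ = c1 // 2
    return conv_bn(c1, c_, 1) + conv_bn(4 * c_, c2, 1)


def shublock_params(c1, c2, stride):
    bf = c2 // 2
    if stride == 1:
        h = c1 // 2
        return conv_bn(h, bf, 1) + conv_bn(bf, bf, 3, g=bf) + conv_bn(bf, bf, 1)
    return (conv_bn(c1, c1, 3, g=c1) + conv_bn(c1, bf, 1)
            + conv_bn(c1, bf, 1) + conv_bn(bf, bf, 3, g=bf) + conv_bn(bf, bf, 1))


def csp_backbone_params():
    return (conv_bn(3, 32, 6) + conv_bn(32, 64, 3) + c3_params(64, 64, 1)
            + conv_bn(64, 128, 3) + c3_params(128, 128, 2)
            + conv_bn(128, 256, 3) + c3_params(256, 256, 3)
            + conv_bn(256, 512, 3) + c3_params(512, 512, 1)
            + sppf_params(512, 512))


def shuffle_backbone_params(stem=24):
    t = conv_bn(3, stem, 6)
    c = stem
    for out, reps in ((116, 4), (232, 8), (464, 4)):
        t += shublock_params(c, out, 2)
        t += (reps - 1) * shublock_params(out, out, 1)
        c = out
    return t + sppf_params(464, 464)


def neck_params(ch3, ch4, ch5, cut=False):
    t = (conv_bn(ch5, ch4, 1) + c3_params(2 * ch4, ch4, 1)
         + conv_bn(ch4, ch3, 1) + c3_params(2 * ch3, ch3, 1)
         + conv_bn(ch3, ch3, 3) + c3_params(2 * ch3, ch4, 1))
    if not cut:
        t += conv_bn(ch4, ch4, 3) + c3_params(2 * ch4, ch5, 1)
    return t


def head_params(channels, nc=2):
    out = 3 * (5 + nc)
    return sum(c * out + out for c in channels)


def cbam_params(c, reduction=16, hidden_bias=False, sam_bn=False):
    h = c // reduction
    t = 2 * c * h + (h if hidden_bias else 0) + 2 * 7 * 7
    return t + (2 if sam_bn else 0)


# ---------------------------------------------------------------------------

class TestChannelShuffle:
    def test_two_channels_two_groups_is_identity(self):
        x = np.arange(2, dtype=np.float32).reshape(1, 2, 1, 1)
        out = channel_shuffle(Tensor(x))
        assert np.array_equal(out.data, x)

    def test_four_channel_interleave(self):
        x = np.array([1, 2, 3, 4], dtype=np.float32).reshape(1, 4, 1, 1)
        out = channel_shuffle(Tensor(x))
        assert list(out.data.ravel()) == [1, 3, 2, 4]

    def test_shuffle_is_a_permutation(self, rng):
        x = rng.normal(size=(2, 8, 3, 3)).astype(np.float32)
        out = channel_shuffle(Tensor(x)).data
        assert np.allclose(np.sort(out, axis=1), np.sort(x, axis=1))

    def test_indivisible_channels_error(self):
        with pytest.raises(ValueError):
            channel_shuffle(Tensor(np.zeros((1, 3, 1, 1))), groups=2)


class TestShuBlock:
    def test_stride1_preserves_shape(self, rng):
        blk = ShuffleV2Block(16, 16, 1)
        out = blk(Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32)))
        assert out.shape == (1, 16, 8, 8)

    def test_stride2_halves_spatial_and_sets_channels(self, rng):
        blk = ShuffleV2Block(16, 32, 2)
        out = blk(Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32)))
        assert out.shape == (1, 32, 4, 4)

    def test_stride1_requires_matching_even_channels(self):
        with pytest.raises(ValueError):
            ShuffleV2Block(16, 32, 1)
        with pytest.raises(ValueError):
            ShuffleV2Block(15, 15, 1)

    def test_parameter_ledger_116_stride1(self):
        blk = ShuffleV2Block(116, 116, 1)
        from litchidet.architecture import _count
        # hand-summed: two 1x1 convs (58*58+58 each) + depthwise (58*9+58)
        assert _count(blk, deployed=True) == 2 * (58 * 58 + 58) + (58 * 9 + 58)
        assert _count(blk, deployed=True) == shublock_params(116, 116, 1) == 7424


class TestBackboneShapes:
    def test_shufflenet_tap_strides_and_channels(self, rng):
        model = build_variant("shufflenet").eval()
        x = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        taps = model.backbone(x)
        assert [t.shape for t in taps] == [(1, 116, 16, 16), (1, 232, 8, 8),
                                           (1, 464, 4, 4)]  # strides 8/16/32

    def test_csp_tap_strides_and_channels(self, rng):
        model = build_variant("yolov5s").eval()
        x = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        taps = model.backbone(x)
        assert [t.shape for t in taps] == [(1, 128, 16, 16), (1, 256, 8, 8),
                                           (1, 512, 4, 4)]


class TestCBAM:
    def test_parameter_count_for_128_channels(self):
        from litchidet.architecture import _count
        assert _count(CBAM(128, 16), deployed=True) == 2 * 128 ** 2 // 16 + 98 == 2146

    def test_baseline_tap_cbam_total_is_published_delta(self):
        total = sum(cbam_params(c) for c in (128, 256, 512))
        assert total == 43302
        base = count_parameters(build_variant("yolov5s")).total
        with_cbam = count_parameters(build_variant("yolov5s_cbam")).total
        assert with_cbam - base == 43302

    def test_uniform_input_leaves_pooling_paths_equal(self, rng):
        m = CBAM(16, 4).eval()
        x = np.full((1, 16, 6, 6), 0.7, dtype=np.float32)
        mx = Tensor(x).max_spatial().data
        av = Tensor(x).mean(axis=(2, 3)).data
        assert np.allclose(mx, av)
        out = m(Tensor(x))
        assert out.shape == (1, 16, 6, 6)

    def test_insertion_preserves_feature_shapes(self, rng):
        m = CBAM(32, 16).eval()
        x = Tensor(rng.normal(size=(2, 32, 5, 7)).astype(np.float32))
        assert m(x).shape == (2, 32, 5, 7)


class TestVariants:
    def test_cut_variant_emits_two_heads_with_correct_channels(self, rng):
        model = build_variant("full_cut", input_size=128).eval()
        outs = model(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        assert [o.shape for o in outs] == [(1, 21, 16, 16), (1, 21, 8, 8)]
        assert model.neck.out_channels == (116, 232)

    def test_baseline_emits_three_21_channel_heads(self, rng):
        model = build_variant("yolov5s", input_size=64).eval()
        outs = model(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
        assert [o.shape[1] for o in outs] == [21, 21, 21]  # 3 anchors x (5+2)

    def test_forward_is_finite_at_initialization(self, rng):
        model = build_variant("full_cut", input_size=96).eval()
        outs = model(rng.normal(size=(1, 3, 96, 96)).astype(np.float32))
        assert all(np.isfinite(o.data).all() for o in outs)

    def test_parameter_count_invariant_to_input_size(self):
        a = count_parameters(build_variant("yolov5s")).total
        b = count_parameters(build_variant("yolov5s_1280")).total
        assert a == b

    def test_ablation_ladder_parameter_ordering(self):
        totals = {name: count_parameters(build_variant(name)).total
                  for name in ("full_cut", "shufflenet", "shufflenet_cbam",
                               "yolov5s", "yolov5s_cbam")}
        assert (totals["full_cut"] < totals["shufflenet"]
                < totals["shufflenet_cbam"] < totals["yolov5s"]
                < totals["yolov5s_cbam"])


class TestParameterAudit:
    def test_baseline_matches_closed_form_ledger(self):
        want = (csp_backbone_params() + neck_params(128, 256, 512)
                + head_params((128, 256, 512)))
        got = count_parameters(build_variant("yolov5s")).total
        assert got == want == 7015519

    def test_shufflenet_matches_closed_form_ledger(self):
        want = (shuffle_backbone_params() + neck_params(116, 232, 464)
                + head_params((116, 232, 464)))
        got = count_parameters(build_variant("shufflenet")).total
        assert got == want

    def test_cut_variant_matches_closed_form_ledger(self):
        want = (shuffle_backbone_params() + neck_params(116, 232, 464, cut=True)
                + head_params((116, 232))
                + sum(cbam_params(c, hidden_bias=True, sam_bn=True)
                      for c in (116, 232, 464)))
        got = count_parameters(build_variant("full_cut")).total
        assert got == want

    def test_breakdown_sums_to_total(self):
        rep = count_parameters(build_variant("full_cut"))
        assert sum(c for _, c in rep.breakdown) == rep.total

    def test_training_convention_equals_raw_parameter_sum(self):
        m = build_variant("shufflenet_cbam")
        raw = sum(p.size for p in m.parameters())
        assert count_parameters(m, "training").total == raw

    def test_ladder_cbam_convention_reproduces_shuffle_row_delta(self):
        base = count_parameters(build_variant("shufflenet")).total
        plus = count_parameters(build_variant("shufflenet_cbam")).total
        assert plus - base == 35382  # published +CBAM increment on these taps


class TestSpecValidation:
    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec(backbone="resnet")

    def test_input_size_must_be_multiple_of_32(self):
        with pytest.raises(ValueError):
            VariantSpec(input_size=100)

    def test_unknown_variant_name(self):
        with pytest.raises(KeyError):
            build_variant("nope")
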