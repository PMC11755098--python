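"""Graph assembly, forward shapes, DFL decoding, prototype-mask assembly and
NMS — each nontrivial decode checked against a brute-force oracle."""

import time

import numpy as np
import pytest

from alsseg import blocks as B
from alsseg.geometry import BBox, box_iou
from alsseg.network import (
    HeadOutput,
    LayerSpec,
    LevelOutput,
    NetworkSpec,
    PrototypeBank,
    assemble_mask,
    build_network,
    decode_boxes,
    postprocess,
    summarize,
)

# expected "Output" column of the default 25-layer graph: (C, H, W) per layer
EXPECTED_SHAPES = {
    0: (3, 640, 640), 1: (8, 320, 320), 2: (16, 160, 160), 3: (16, 160, 160),
    4: (24, 160, 160), 5: (24, 80, 80), 6: (48, 80, 80), 7: (88, 40, 40),
    8: (88, 40, 40), 9: (176, 20, 20), 10: (176, 20, 20), 11: (176, 40, 40),
    12: (264, 40, 40), 13: (88, 40, 40), 14: (88, 80, 80), 15: (136, 80, 80),
    16: (136, 80, 80), 17: (48, 80, 80), 18: (48, 40, 40), 19: (136, 40, 40),
    20: (88, 40, 40), 21: (88, 20, 20), 22: (264, 20, 20), 23: (176, 20, 20),
}

EXACT_PARAM_ROWS = {
    1: 232, 2: 1184, 3: 2336, 4: 3504, 10: 77968, 11: 0, 12: 0, 14: 0,
    15: 0, 16: 7248, 18: 20832, 19: 0, 21: 69872, 22: 0,
}


@pytest.fixture(scope="module")
def default_net():
    return build_network(NetworkSpec.default(), seed=0)


class TestBuild:
    def test_default_graph_has_25_layers(self):
        assert len(NetworkSpec.default().layers) == 25

    def test_all_output_shapes_match_reference(self, default_net):
        for idx, (c, h, w) in EXPECTED_SHAPES.items():
            assert default_net.shapes[idx] == (h, w, c), f"layer {idx}"

    def test_concat_widths(self, default_net):
        assert default_net.shapes[12][2] == 176 + 88 == 264
        assert default_net.shapes[15][2] == 88 + 48 == 136

    def test_exact_param_rows(self, default_net):
        for idx, expected in EXACT_PARAM_ROWS.items():
            assert default_net.layer_params(idx) == expected, f"layer {idx}"

    def test_bad_concat_width_names_layer(self):
        spec = NetworkSpec(
            layers=[
                LayerSpec(0, "input"),
                LayerSpec(1, "conv", out_channels=8),
                LayerSpec(2, "conv", out_channels=8),
                LayerSpec(3, "concat", sources=(1, 2), out_channels=99),
                LayerSpec(4, "segment", sources=(3,)),
            ],
            input_size=(16, 16, 3),
        )
        with pytest.raises(B.ConfigError, match="layer 3"):
            build_network(spec)

    def test_two_segment_layers_rejected(self):
        with pytest.raises(B.ConfigError):
            NetworkSpec(
                layers=[
                    LayerSpec(0, "input"),
                    LayerSpec(1, "segment", sources=(0,)),
                    LayerSpec(2, "segment", sources=(0,)),
                ]
            )

    def test_single_conv_spec_runnable(self):
        spec = NetworkSpec(
            layers=[
                LayerSpec(0, "input"),
                LayerSpec(1, "conv", out_channels=4, kernel=3, stride=1),
                LayerSpec(2, "segment", sources=(1,)),
            ],
            input_size=(16, 16, 3),
            num_prototypes=4,
            reg_max=4,
        )
        net = build_network(spec)
        assert net.layer_params(1) == B.count_params(B.ConvSpec(3, 4, 3))

    def test_summary_table_layout(self, default_net):
        text = summarize(default_net)
        lines = text.strip().splitlines()
        assert len(lines) == 1 + 25 + 1  # header, 25 layers, Total
        assert "Total" in lines[-1]
        assert str(default_net.total_params) in lines[-1]

    def test_summary_total_is_sum_of_rows(self, default_net):
        assert default_net.total_params == sum(
            r.learnable_params for r in default_net.reports
        )

    def test_layer1_macs_match_gflops_within_rounding(self, default_net):
        # 216 weight MACs per output pixel at 320x320; 2*MAC convention ~0.04G
        macs = default_net.reports[1].macs
        assert macs == 216 * 320 * 320
        assert abs(2 * macs / 1e9 - 0.04) < 0.005


class TestForward:
    def test_full_forward_levels_and_prototypes(self, default_net):
        t0 = time.time()
        head, protos = default_net.forward(np.zeros((640, 640, 3), np.float32))
        assert time.time() - t0 < 10.0
        sizes = [(lvl.box_dist.shape[0], lvl.stride) for lvl in head.levels]
        assert sizes == [(80, 8), (40, 16), (20, 32)]
        assert protos.maps.shape == (160, 160, 32)
        for lvl in head.levels:
            assert lvl.box_dist.shape[-1] == 4 * 24
            assert np.all(np.abs(lvl.coefficients) <= 1.0)

    def test_wrong_input_size_raises(self, default_net):
        with pytest.raises(B.ShapeError):
            default_net.forward(np.zeros((320, 320, 3), np.float32))

    def test_forward_deterministic(self):
        spec = NetworkSpec(
            layers=[
                LayerSpec(0, "input"),
                LayerSpec(1, "conv", out_channels=4, stride=2),
                LayerSpec(2, "segment", sources=(1,)),
            ],
            input_size=(32, 32, 3), num_prototypes=4, reg_max=4,
        )
        x = np.random.default_rng(0).normal(size=(32, 32, 3)).astype(np.float32)
        h1, p1 = build_network(spec, seed=3).forward(x)
        h2, p2 = build_network(spec, seed=3).forward(x)
        assert np.array_equal(p1.maps, p2.maps)
        assert np.array_equal(h1.levels[0].cls_logits, h2.levels[0].cls_logits)


class TestDecodeBoxes:
    def test_one_hot_bin(self):
        logits = np.full(4 * 8, -40.0)
        logits[5] = 40.0  # side 0, bin 5
        d = decode_boxes(logits, reg_max=8, stride=4)
        assert d[0] == pytest.approx(5 * 4, abs=1e-6)

    def test_uniform_logits_symmetric_expectation(self):
        d = decode_boxes(np.zeros(4 * 24), reg_max=24, stride=8)
        assert np.allclose(d, 11.5 * 8)

    def test_matches_bruteforce_softmax_expectation(self, rng):
        logits = rng.normal(size=(5, 5, 4 * 16))
        d = decode_boxes(logits, reg_max=16, stride=16)
        for i in range(5):
            for j in range(5):
                for s in range(4):
                    l = logits[i, j, s * 16 : (s + 1) * 16]
                    p = np.exp(l) / np.exp(l).sum()
                    expected = (np.arange(16) * p).sum() * 16
                    assert d[i, j, s] == pytest.approx(expected, rel=1e-6)

    def test_range_bounds(self, rng):
        d = decode_boxes(rng.normal(size=(3, 3, 4 * 24)), reg_max=24, stride=8)
        assert np.all(d >= 0) and np.all(d <= 23 * 8)


class TestAssembleMask:
    def test_one_hot_coefficient_selects_prototype(self, rng):
        maps = rng.normal(size=(8, 8, 4)).astype(np.float32)
        protos = PrototypeBank(maps)
        c = np.zeros(4, np.float32)
        c[2] = 1.0
        box = BBox(0, 0, 7, 7)
        m = assemble_mask(c, protos, box, (8, 8))
        assert np.array_equal(m.mask, B.sigmoid(maps[:, :, 2]) > 0.5)

    def test_zero_coefficients_empty_mask(self, rng):
        protos = PrototypeBank(rng.normal(size=(8, 8, 4)).astype(np.float32))
        m = assemble_mask(np.zeros(4), protos, BBox(0, 0, 7, 7), (8, 8))
        assert not m.mask.any()  # sigma(0)=0.5, strict > breaks tie to background

    def test_matches_pixel_bruteforce(self, rng):
        maps = rng.normal(size=(8, 8, 6)).astype(np.float32)
        c = rng.uniform(-1, 1, size=6).astype(np.float32)
        box = BBox(1, 2, 6, 7)
        m = assemble_mask(c, PrototypeBank(maps), box, (8, 8))
        oracle = np.zeros((8, 8), bool)
        for y in range(8):
            for x in range(8):
                if 1 <= x <= 6 and 2 <= y <= 7:
                    v = sum(c[j] * maps[y, x, j] for j in range(6))
                    oracle[y, x] = 1.0 / (1.0 + np.exp(-v)) > 0.5
        assert np.array_equal(m.mask, oracle)

    def test_crop_zeroes_outside_box(self, rng):
        maps = np.full((8, 8, 1), 5.0, np.float32)  # sigmoid ~ 1 everywhere
        m = assemble_mask(np.ones(1), PrototypeBank(maps), BBox(2, 2, 5, 5), (8, 8))
        assert m.mask[3, 3] and not m.mask[0, 0]


def _random_head(rng, h=8, nc=1, k=3, reg_max=4, stride=2):
    lvl = LevelOutput(
        box_dist=rng.normal(size=(h, h, 4 * reg_max)).astype(np.float32),
        cls_logits=rng.normal(size=(h, h, nc)).astype(np.float32) * 2,
        coefficients=np.tanh(rng.normal(size=(h, h, k))).astype(np.float32),
        stride=stride,
    )
    protos = PrototypeBank(rng.normal(size=(h * stride, h * stride, k)).astype(np.float32))
    return HeadOutput([lvl]), protos


class TestPostprocess:
    def test_conf_one_empty(self, rng):
        head, protos = _random_head(rng)
        assert postprocess(head, protos, conf_thresh=1.0) == []

    def test_duplicate_boxes_suppressed(self, rng):
        head, protos = _random_head(rng)
        # force two cells to identical geometry, different scores
        head.levels[0].cls_logits[:] = -10
        head.levels[0].cls_logits[2, 2, 0] = 2.2  # sigma ~ 0.9
        head.levels[0].cls_logits[2, 3, 0] = 1.4  # sigma ~ 0.8
        head.levels[0].box_dist[:] = 0.0
        d = np.full(4 * 4, -30.0)
        # both cells decode to (almost) the full frame -> IoU ~ 1
        head.levels[0].box_dist[2, 2] = np.tile(np.eye(4)[3] * 30 - 15, 4)
        head.levels[0].box_dist[2, 3] = np.tile(np.eye(4)[3] * 30 - 15, 4)
        out = postprocess(head, protos, conf_thresh=0.5, nms_iou=0.5)
        assert len(out) == 1
        assert out[0].score == pytest.approx(1 / (1 + np.exp(-2.2)), rel=1e-5)

    def test_matches_allpairs_suppression_oracle(self, rng):
        head, protos = _random_head(rng, h=8)
        conf, nms = 0.5, 0.4
        out = postprocess(head, protos, conf_thresh=conf, nms_iou=nms)
        # oracle: rebuild candidates independently, suppress all-pairs greedily
        lvl = head.levels[0]
        scores = 1 / (1 + np.exp(-lvl.cls_logits))
        dists = decode_boxes(lvl.box_dist, 4, lvl.stride)
        cands = []
        order = 0
        for y in range(8):
            for x in range(8):
                for c in range(scores.shape[2]):
                    if scores[y, x, c] > conf:
                        cx, cy = (x + 0.5) * lvl.stride, (y + 0.5) * lvl.stride
                        l, t, r, b = dists[y, x]
                        box = BBox(cx - l, cy - t, cx + r, cy + b,
                                   score=float(scores[y, x, c]), class_id=c).clip(16, 16)
                        cands.append((float(scores[y, x, c]), order, c, box))
                        order += 1
        cands.sort(key=lambda t: (-t[0], t[1]))
        keep = []
        for s, o, c, box in cands:
            if all(cc != c or box_iou(box, bb) <= nms for _, cc, bb in keep):
                keep.append((s, c, box))
        assert len(out) == len(keep)
        for got, (s, c, box) in zip(out, keep):
            assert got.score == pytest.approx(s, rel=1e-6)
            assert got.bbox.as_tuple() == pytest.approx(box.as_tuple(), abs=1e-4)

    def test_invariant_to_candidate_order(self, rng):
        # identical scores across cells: output fixed by the documented
        # (score desc, cell index asc) tie-break
        head, protos = _random_head(rng)
        head.levels[0].cls_logits[:] = 1.0
        out1 = postprocess(head, protos, conf_thresh=0.5, nms_iou=0.9)
        out2 = postprocess(head, protos, conf_thresh=0.5, nms_iou=0.9)
        assert [o.bbox.as_tuple() for o in out1] == [o.bbox.as_tuple() for o in out2]
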