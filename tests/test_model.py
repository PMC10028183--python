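"""Architecture conformance and behavioural properties of CAMBNet."""

import numpy as np
import pytest

from cambnet.model import (
    CAMBNet,
    CambnetConfig,
    EXPECTED_STAGE_INPUTS,
    StageShapeError,
    build_cambnet,
)
from cambnet.nn import tensor as T


@pytest.fixture(scope="module")
def model():
    return build_cambnet(seed=0)


def _batch(n=1, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3, 64, 64)).astype(np.float32)


def expected_parameter_count(cfg: CambnetConfig) -> int:
    """Layer-by-layer arithmetic, written independently of the model code.

    Conventions: convs are bias-free (batch norm supplies the shift) except
    the spatial-attention conv; batch norm contributes 2C; SE/attention
    bottlenecks and the classifier are biased linear layers.
    """
    def conv(co, ci, kh, kw):
        return co * ci * kh * kw

    def bn(c):
        return 2 * c

    def se(c, ratio):
        hidden = max(c // ratio, 4)
        return (c * hidden + hidden) + (hidden * c + c)

    cs, ce = cfg.stem_channels, cfg.sfe_expansion_channels
    r = cfg.se_reduction_ratio
    total = conv(cs, cfg.in_channels, 3, 3) + bn(cs)                # stem
    total += conv(ce, cs, 1, 1) + bn(ce)                            # Conv1_1
    total += ce * 3 * 3 + bn(ce)                                    # Dwconv1_2
    total += se(ce, r)                                              # SEB1_3
    total += conv(cs, ce, 1, 1) + bn(cs)                            # Conv1_4
    cb = cfg.ltt1_bottleneck_channels
    total += conv(cb, cs, 1, 1) + bn(cb)                            # Conv2_1
    total += cb * 3 * 3 + bn(cb)                                    # Dwconv2_2
    total += conv(cfg.branch_out_channels, cb, 1, 1) + bn(cs)       # Conv2_3
    plan = cfg.ltt2_channel_plan
    total += conv(plan[0], cs, 1, 1) + bn(plan[0])                  # Conv3_1
    in_ch = plan[0]
    for i, out_ch in enumerate(plan[1:]):                           # Conv3_2..5
        kh, kw = (1, 3) if i % 2 == 0 else (3, 1)
        total += conv(out_ch, in_ch, kh, kw) + bn(out_ch)
        in_ch = out_ch
    total += se(cfg.branch_out_channels, r)                         # channel att
    k = cfg.attention_kernel_size
    total += k * k + 1                                              # spatial att
    fused = 2 * cfg.branch_out_channels
    total += conv(cfg.dfem_expansion_channels, fused, 1, 1) + bn(128)  # Conv4_2
    total += cfg.dfem_expansion_channels * 9 + bn(128)              # Dwconv4_3
    total += se(cfg.dfem_expansion_channels, r)                     # SEB4_4
    total += conv(cfg.dfem_out_channels, 128, 1, 1) + bn(64)        # Conv4_5
    total += cfg.dfem_out_channels * cfg.n_classes + cfg.n_classes  # Fc4_7
    return total


def test_stage_table_conformance(model):
    """Every per-stage input dimension matches the reference table."""
    realized = model.stage_input_shapes()
    assert realized == EXPECTED_STAGE_INPUTS


def test_forward_returns_two_logits(model):
    model.eval()
    with T.no_grad():
        out = model(_batch(1))
    assert out.shape == (1, 2)


def test_n_classes_generalizes():
    m = build_cambnet(CambnetConfig(n_classes=4), seed=1)
    m.eval()
    with T.no_grad():
        assert m(_batch(1)).shape == (1, 4)


def test_parameter_count_matches_hand_count(model):
    assert model.parameter_count() == expected_parameter_count(model.config)


def test_asymmetric_branch_is_cheaper_than_square_kernels():
    cfg = CambnetConfig()
    plan = cfg.ltt2_channel_plan
    asym = square = 0
    in_ch = plan[0]
    for i, out_ch in enumerate(plan[1:]):
        asym += out_ch * in_ch * 3  # 1x3 or 3x1
        square += out_ch * in_ch * 9
        in_ch = out_ch
    assert asym < square


def test_wrong_input_side_raises(model):
    with pytest.raises(StageShapeError):
        model(np.zeros((1, 3, 32, 32), dtype=np.float32))
    with pytest.raises(StageShapeError):
        model(np.zeros((1, 5, 64, 64), dtype=np.float32))


def test_inconsistent_channel_plan_rejected():
    with pytest.raises(ValueError, match="branch_out_channels"):
        CambnetConfig(ltt2_channel_plan=(4, 8, 8, 8, 32))


def test_residual_identity_when_conv_branch_zeroed():
    m = build_cambnet(seed=2)
    m.eval()
    m.bn1_4.weight.data[:] = 0.0
    m.bn1_4.bias.data[:] = 0.0
    with T.no_grad():
        m(_batch(1, seed=3))
    stem = m.stages["Pre_layer"].data
    assert np.allclose(m.stages["SFEpath"].data, stem, atol=1e-6)


def test_se_block_rescales_by_its_channel_weights(model, rng):
    se = model.seb1_3
    x = T.Tensor(rng.normal(size=(2, 128, 8, 8)).astype(np.float32))
    with T.no_grad():
        out = se(x)
        w = se.channel_weights(x).data
    assert np.allclose(out.data, x.data * w[:, :, None, None], atol=1e-6)
    assert (w > 0).all() and (w < 1).all()


def test_attention_gates_strictly_in_unit_interval(model):
    model.eval()
    with T.no_grad():
        model(_batch(2, seed=4))
    cw = model.stages["channel_weights"].data
    sw = model.stages["spatial_weights"].data
    for w in (cw, sw):
        assert (w > 0).all() and (w < 1).all()


def test_cross_attention_identity_when_weights_forced_to_one(model):
    model.eval()
    rng = np.random.default_rng(5)
    a = T.Tensor(rng.normal(size=(1, 16, 64, 64)).astype(np.float32))
    b = T.Tensor(rng.normal(size=(1, 16, 64, 64)).astype(np.float32))
    orig_c, orig_s = model.channel_att, model.spatial_att
    try:
        model.channel_att = lambda x: T.Tensor(np.ones((1, 16, 1, 1), np.float32))
        model.spatial_att = lambda x: T.Tensor(np.ones((1, 1, 64, 64), np.float32))
        out_a, out_b = model.cross_attention(a, b)
    finally:
        model.channel_att, model.spatial_att = orig_c, orig_s
    assert np.array_equal(out_a.data, a.data)
    assert np.array_equal(out_b.data, b.data)


def test_fuse_concatenation_order_round_trips(model):
    rng = np.random.default_rng(6)
    sfe = T.Tensor(rng.normal(size=(1, 16, 64, 64)).astype(np.float32))
    a = T.Tensor(rng.normal(size=(1, 16, 64, 64)).astype(np.float32))
    zero = T.Tensor(np.zeros((1, 16, 64, 64), np.float32))
    fused = model.fuse_branches(sfe, a, zero)
    assert fused.shape == (1, 32, 64, 64)
    # additive identity: first 16 channels equal att_a; last 16 equal sfe
    assert np.allclose(fused.data[:, :16], a.data, atol=1e-6)
    assert np.array_equal(fused.data[:, 16:], sfe.data)


def test_batch_equivariance(model):
    model.eval()
    x = _batch(5, seed=7)
    perm = np.array([3, 0, 4, 1, 2])
    with T.no_grad():
        out = model(x).data
        out_p = model(x[perm]).data
    assert np.allclose(out[perm], out_p, atol=1e-5)


def test_forward_is_deterministic(model):
    model.eval()
    x = _batch(2, seed=8)
    with T.no_grad():
        a = model(x).data.copy()
        b = model(x).data.copy()
    assert np.array_equal(a, b)


def test_every_parameter_receives_gradient():
    """One loss backward on random data leaves no dead branch."""
    m = build_cambnet(seed=9)
    m.train()
    x = _batch(8, seed=9)
    y = np.array([0, 1] * 4)
    loss = T.cross_entropy(m(x), y)
    m.zero_grad()
    loss.backward()
    for name, p in m.named_parameters():
        assert p.grad is not None, f"no gradient for {name}"
        assert np.linalg.norm(p.grad) > 0, f"zero gradient norm for {name}"


def test_both_cross_wirings_run_and_differ():
    x = _batch(1, seed=10)
    outs = []
    for wiring in ("ltt1_channel", "ltt2_channel"):
        m = build_cambnet(CambnetConfig(cross_wiring=wiring), seed=11)
        m.eval()
        with T.no_grad():
            outs.append(m(x).data.copy())
    assert not np.allclose(outs[0], outs[1])


def test_checkpoint_round_trip(tmp_path, model):
    model.eval()
    x = _batch(1, seed=12)
    with T.no_grad():
        before = model(x).data.copy()
    path = tmp_path / "ckpt.npz"
    model.save(path)
    restored = CAMBNet.load(path)
    with T.no_grad():
        after = restored(x).data
    assert np.array_equal(before, after)
    assert restored.config == model.config
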