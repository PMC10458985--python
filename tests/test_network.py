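"""Network tests: autodiff correctness, layer contracts, variants, checkpoints."""

import numpy as np
import pytest

from fpmnet import autodiff as ad
from fpmnet.autodiff import Tensor
from fpmnet.network import (
    RHAN,
    ChannelAttention,
    Conv2d,
    NetworkConfig,
    SpatialAttention,
    TINY_CONFIG,
    build_network,
    load_checkpoint,
    parameter_count,
    save_checkpoint,
)
from fpmnet.training import ssim_loss

MICRO = NetworkConfig(base_channels=8, n_hags=1, n_rhabs_per_hag=1, ca_reduction=4)


# ---------------------------------------------------------------------------
# Autodiff engine
# ---------------------------------------------------------------------------

def _numerical_grad(f, tensor: Tensor, indices, eps: float = 1e-6):
    flat = tensor.data.reshape(-1)
    grads = {}
    for i in indices:
        orig = flat[i]
        flat[i] = orig + eps
        fp = float(f().data)
        flat[i] = orig - eps
        fm = float(f().data)
        flat[i] = orig
        grads[i] = (fp - fm) / (2 * eps)
    return grads


@pytest.mark.parametrize("dilation,padding", [(1, 1), (2, 2), (3, 3)])
def test_conv2d_gradients_match_finite_differences(rng, dilation, padding):
    x = Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
    w = Tensor(rng.normal(size=(4, 3, 3, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=4), requires_grad=True)

    def f():
        return ad.mean(ad.sigmoid(ad.conv2d(x, w, b, padding=padding, dilation=dilation)))

    out = f()
    for t in (x, w, b):
        t.zero_grad()
    out = f()
    out.backward()
    for t in (x, w, b):
        idx = rng.choice(t.data.size, size=min(5, t.data.size), replace=False)
        num = _numerical_grad(f, t, idx)
        for i, g in num.items():
            assert t.grad.reshape(-1)[i] == pytest.approx(g, rel=1e-4, abs=1e-7)


def test_composite_ops_gradients(rng):
    a = Tensor(rng.normal(size=(1, 8, 4, 4)), requires_grad=True)

    def f():
        y = ad.pixel_shuffle(ad.leaky_relu(a, 0.2), 2)
        z = ad.div(y, ad.spatial_mean(ad.mul(y, y)) + 1.0)
        return ad.mean(ad.mul(z, ad.sigmoid(z)))

    a.zero_grad()
    f().backward()
    num = _numerical_grad(f, a, rng.choice(a.data.size, size=8, replace=False))
    for i, g in num.items():
        assert a.grad.reshape(-1)[i] == pytest.approx(g, rel=1e-4, abs=1e-7)


def test_whole_network_gradcheck(rng):
    model = RHAN(MICRO, "RHAN", seed=1)
    for p in model.parameters():
        p.data = p.data.astype(np.float64)
    x = rng.uniform(0, 1, size=(1, 2, 16, 16))
    t = rng.uniform(0, 1, size=(1, 2, 16, 16))

    def f():
        model.zero_grad()
        return ssim_loss(model(Tensor(x)), t)

    f().backward()
    grads = {name: p.grad.copy() for name, p in model.named_parameters()}
    for name, p in list(model.named_parameters())[::5]:
        idx = rng.choice(p.data.size, size=min(3, p.data.size), replace=False)
        num = _numerical_grad(f, p, idx)
        for i, g in num.items():
            assert grads[name].reshape(-1)[i] == pytest.approx(
                g, rel=1e-3, abs=1e-8
            ), name


def test_pixel_shuffle_shape_and_inverse(rng):
    x = rng.normal(size=(2, 8, 3, 5))
    y = ad.pixel_shuffle(Tensor(x), 2)
    assert y.data.shape == (2, 2, 6, 10)
    with pytest.raises(ValueError):
        ad.pixel_shuffle(Tensor(rng.normal(size=(1, 3, 4, 4))), 2)


def test_conv2d_channel_mismatch_raises(rng):
    with pytest.raises(ValueError, match="channels"):
        ad.conv2d(
            Tensor(rng.normal(size=(1, 3, 8, 8))),
            Tensor(rng.normal(size=(4, 2, 3, 3))),
        )


def test_conv2d_kernel_larger_than_input_raises(rng):
    with pytest.raises(ValueError, match="exceeds"):
        ad.conv2d(
            Tensor(rng.normal(size=(1, 1, 4, 4))),
            Tensor(rng.normal(size=(1, 1, 3, 3))),
            padding=0,
            dilation=3,
        )


# ---------------------------------------------------------------------------
# Config and variants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"base_channels": 8, "ca_reduction": 16},
        {"base_channels": 10, "ca_reduction": 4},
        {"sa_dilations": ()},
        {"sa_dilations": (0,)},
        {"upscale": 0},
    ],
)
def test_config_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        NetworkConfig(**kwargs)


def test_variant_parameter_containment_and_counts():
    full = build_network(TINY_CONFIG, "RHAN", seed=0)
    rcn = build_network(TINY_CONFIG, "RCN", seed=0)
    rsn = build_network(TINY_CONFIG, "RSN", seed=0)
    n_full, n_rcn, n_rsn = map(parameter_count, (full, rcn, rsn))
    assert n_rcn < n_full
    assert n_rsn < n_full
    names = {v: {n for n, _ in m.named_parameters()} for v, m in
             [("RHAN", full), ("RCN", rcn), ("RSN", rsn)]}
    assert names["RCN"] <= names["RHAN"]
    assert names["RSN"] <= names["RHAN"]
    with pytest.raises(ValueError):
        build_network(TINY_CONFIG, "XYZ")


def test_seeded_builds_identical():
    a = build_network(TINY_CONFIG, "RHAN", seed=3)
    b = build_network(TINY_CONFIG, "RHAN", seed=3)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        assert np.array_equal(pa.data, pb.data)


# ---------------------------------------------------------------------------
# Layer contracts
# ---------------------------------------------------------------------------

def test_shallow_extraction_shape_and_linearity(rng):
    conv = Conv2d(np.random.default_rng(0), 2, 8, 3, bias=False)
    x = rng.normal(size=(2, 2, 12, 12)).astype(np.float32)
    y = conv(Tensor(x)).data
    assert y.shape == (2, 8, 12, 12)
    assert np.allclose(conv(Tensor(np.zeros_like(x))).data, 0.0)
    y3 = conv(Tensor(3.0 * x)).data
    assert np.allclose(y3, 3.0 * y, rtol=1e-5, atol=1e-6)


def test_channel_attention_gate_and_constant_input(rng):
    ca = ChannelAttention(np.random.default_rng(0), 8, 4, slope=0.2)
    x = np.broadcast_to(
        rng.uniform(0.1, 1.0, size=(1, 8, 1, 1)), (1, 8, 6, 6)
    ).astype(np.float32).copy()
    y = ca(Tensor(x)).data
    assert ca.last_gate.shape == (1, 8, 1, 1)
    assert np.all(ca.last_gate > 0) and np.all(ca.last_gate < 1)
    # spatially constant input -> output is a per-channel rescaling
    assert np.allclose(y, x * ca.last_gate, rtol=1e-6)


def test_channel_attention_permutation_equivariance(rng):
    ca = ChannelAttention(np.random.default_rng(1), 8, 4, slope=0.2)
    x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
    y = ca(Tensor(x)).data
    perm = np.random.default_rng(2).permutation(8)
    ca_p = ChannelAttention(np.random.default_rng(1), 8, 4, slope=0.2)
    ca_p.down.weight.data = ca.down.weight.data[:, perm]
    ca_p.up.weight.data = ca.up.weight.data[perm]
    ca_p.up.bias.data = ca.up.bias.data[perm]
    y_p = ca_p(Tensor(x[:, perm])).data
    assert np.allclose(y_p, y[:, perm], rtol=1e-5, atol=1e-6)


def test_spatial_attention_contract(rng):
    sa = SpatialAttention(np.random.default_rng(0), 8, (1, 2), slope=0.2)
    x = rng.normal(size=(2, 8, 7, 9)).astype(np.float32)
    y = sa(Tensor(x)).data
    assert y.shape == x.shape
    assert np.all(sa.last_gate > 0) and np.all(sa.last_gate < 1)
    assert sa.last_gate.shape == (2, 1, 7, 9)
    # dilations 1 and 2 with 3x3 kernels give 3x3 and 5x5 receptive fields
    assert sa.branches[0].dilation == 1 and sa.branches[0].padding == 1
    assert sa.branches[1].dilation == 2 and sa.branches[1].padding == 2


def test_rhab_gradients_reach_both_attention_paths(rng):
    model = build_network(MICRO, "RHAN", seed=0)
    x = Tensor(rng.uniform(0, 1, size=(1, 2, 16, 16)).astype(np.float32))
    model.zero_grad()
    loss = ssim_loss(model(x), rng.uniform(0, 1, size=(1, 2, 16, 16)))
    loss.backward()
    block = model.hags[0].blocks[0]
    for module in (block.sa, block.ca):
        norms = [np.linalg.norm(p.grad) for p in module.parameters()]
        assert all(n > 0 for n in norms)


def test_rcn_block_is_conv_plus_ca_plus_identity(rng):
    model = build_network(MICRO, "RCN", seed=0)
    block = model.hags[0].blocks[0]
    assert block.sa is None
    x = Tensor(rng.normal(size=(1, 8, 10, 10)).astype(np.float32))
    y = block(x).data
    feats = block.conv2(ad.leaky_relu(block.conv1(x), block.slope))
    manual = x.data + block.ca(feats).data
    assert np.allclose(y, manual, rtol=1e-6, atol=1e-7)


def test_rsn_block_drops_channel_attention():
    model = build_network(MICRO, "RSN", seed=0)
    block = model.hags[0].blocks[0]
    assert block.ca is None and block.sa is not None


# ---------------------------------------------------------------------------
# Full forward
# ---------------------------------------------------------------------------

def test_forward_preserves_shape_at_upscale_1(rng):
    model = build_network(TINY_CONFIG, "RHAN", seed=0)
    x = rng.uniform(0, 1, size=(2, 2, 24, 24)).astype(np.float32)
    assert model.predict(x).shape == (2, 2, 24, 24)


def test_forward_upscale_2_doubles_spatial_dims(rng):
    cfg = NetworkConfig(
        base_channels=8, n_hags=1, n_rhabs_per_hag=1, ca_reduction=4, upscale=2
    )
    model = build_network(cfg, "RHAN", seed=0)
    x = rng.uniform(0, 1, size=(1, 2, 48, 48)).astype(np.float32)
    assert model.predict(x).shape == (1, 2, 96, 96)


def test_zeroed_head_gives_constant_output(rng):
    model = build_network(MICRO, "RHAN", seed=0)
    model.head2.weight.data[:] = 0.0
    model.head2.bias.data[:] = 0.25
    y1 = model.predict(rng.uniform(0, 1, size=(1, 2, 16, 16)).astype(np.float32))
    y2 = model.predict(rng.uniform(0, 1, size=(1, 2, 16, 16)).astype(np.float32))
    assert np.allclose(y1, 0.25) and np.allclose(y2, 0.25)


def test_forward_backward_finite_over_seeds(rng):
    for seed in range(20):
        model = build_network(MICRO, "RHAN", seed=seed)
        x = Tensor(
            np.random.default_rng(seed).uniform(0, 1, (1, 2, 16, 16)).astype(np.float32)
        )
        model.zero_grad()
        loss = ssim_loss(model(x), np.random.default_rng(seed + 1).uniform(0, 1, (1, 2, 16, 16)))
        assert np.isfinite(loss.data)
        loss.backward()
        for p in model.parameters():
            assert np.all(np.isfinite(p.grad))
        for g in model.attention_gates():
            assert np.all(g > 0) and np.all(g < 1)


def test_default_config_overfits_single_pair(rng):
    """The full-depth architecture can drive the SSIM loss below 0.05 on one
    training pair within 500 optimizer steps (trainability sanity)."""
    from fpmnet.training import AdamW

    model = build_network(NetworkConfig(), "RHAN", seed=0)
    x = rng.uniform(0, 1, (1, 2, 24, 24)).astype(np.float32)
    t = rng.uniform(0, 1, (1, 2, 24, 24)).astype(np.float32)
    opt = AdamW(model.parameters(), lr=1e-3, weight_decay=0.0)
    reached = False
    for _ in range(500):
        model.zero_grad()
        loss = ssim_loss(model(Tensor(x)), t)
        if float(loss.data) < 0.05:
            reached = True
            break
        loss.backward()
        opt.step()
    assert reached


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path, rng):
    model = build_network(TINY_CONFIG, "RSN", seed=4)
    x = rng.uniform(0, 1, size=(1, 2, 16, 16)).astype(np.float32)
    want = model.predict(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    again = load_checkpoint(path)
    assert again.variant == "RSN"
    assert again.config == TINY_CONFIG
    assert np.array_equal(again.predict(x), want)
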