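"""Naive reference implementations used as oracles in tests.

Everything here is written with explicit Python loops in float64 and stays
deliberately independent of the package's compute core: the only interaction
with the production code is reading the layer weights.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def conv3d_loops(x, w, b=None, dilation=(1, 1, 1), padding=None):
    """Same-padding stride-1 3D convolution, nested loops, float64.

    x: (C, D, H, W); w: (Cout, C, kd, kh, kw).
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    cout, cin, kd, kh, kw = w.shape
    if padding is None:
        padding = tuple(d * (k - 1) // 2 for k, d in zip((kd, kh, kw), dilation))
    C, D, H, W = x.shape
    xp = np.pad(x, ((0, 0),) + tuple((p, p) for p in padding))
    out = np.zeros((cout, D, H, W))
    for o in range(cout):
        for z in range(D):
            for y in range(H):
                for xx in range(W):
                    s = 0.0
                    for c in range(cin):
                        for a in range(kd):
                            for bb in range(kh):
                                for cc in range(kw):
                                    s += (xp[c, z + a * dilation[0],
                                             y + bb * dilation[1],
                                             xx + cc * dilation[2]]
                                          * w[o, c, a, bb, cc])
                    out[o, z, y, xx] = s
        if b is not None:
            out[o] += float(b[o])
    return out


def conv1d_loops(v, w, b=None):
    """Same-padding 1D convolution of a vector with a (1, 1, k) kernel."""
    v = np.asarray(v, dtype=np.float64)
    k = w.shape[-1]
    pad = (k - 1) // 2
    vp = np.pad(v, (pad, pad))
    out = np.zeros_like(v)
    for i in range(len(v)):
        s = 0.0
        for j in range(k):
            s += vp[i + j] * float(w[0, 0, j])
        out[i] = s + (float(b[0]) if b is not None else 0.0)
    return out


def spatial_attention_loops(x, block):
    """Channel-pooled avg/max -> k^3 conv -> sigmoid -> gate, per voxel."""
    x = np.asarray(x, dtype=np.float64)
    avg = x.mean(axis=0, keepdims=True)
    mx = x.max(axis=0, keepdims=True)
    cat = np.concatenate([avg, mx], axis=0)
    w = block.conv.weight.data
    b = block.conv.bias.data
    m = sigmoid(conv3d_loops(cat, w, b))
    return x * m


def dilated_eca_loops(x, block):
    x = np.asarray(x, dtype=np.float64)
    gc = block.group_channels
    outs = []
    for i, d in enumerate(block.rates):
        xi = x[i * gc:(i + 1) * gc]
        dw_layer = getattr(block, f"depthwise{i}")
        pw_layer = getattr(block, f"pointwise{i}")
        # depthwise: one (1,1,k,k,k) kernel per channel
        dw_out = np.zeros_like(xi)
        for c in range(gc):
            wc = dw_layer.weight.data[c:c + 1]
            dw_out[c] = conv3d_loops(xi[c:c + 1], wc, dilation=(d, d, d))[0]
            dw_out[c] += float(dw_layer.bias.data[c])
        pw = conv3d_loops(dw_out, pw_layer.weight.data, pw_layer.bias.data)
        outs.append(pw)
    xc = np.concatenate(outs, axis=0)
    gap = xc.mean(axis=(1, 2, 3))
    gate = sigmoid(np.maximum(
        conv1d_loops(gap, block.conv1d.weight.data, block.conv1d.bias.data), 0.0))
    return xc * gate[:, None, None, None], gate


def se_loops(x, block):
    x = np.asarray(x, dtype=np.float64)
    gap = x.mean(axis=(1, 2, 3))
    h = np.maximum(gap @ block.fc1.weight.data + block.fc1.bias.data, 0.0)
    s = sigmoid(h @ block.fc2.weight.data + block.fc2.bias.data)
    return x * s[:, None, None, None], s


def cbam_loops(x, block):
    x = np.asarray(x, dtype=np.float64)

    def mlp(v):
        h = np.maximum(v @ block.fc1.weight.data + block.fc1.bias.data, 0.0)
        return h @ block.fc2.weight.data + block.fc2.bias.data

    avg = x.mean(axis=(1, 2, 3))
    mx = x.max(axis=(1, 2, 3))
    if block.gate_mode == "summed_logits":
        gate = sigmoid(mlp(avg) + mlp(mx))
    else:
        gate = sigmoid(mlp(avg)) + sigmoid(mlp(mx))
    f_c = x * gate[:, None, None, None]
    savg = f_c.mean(axis=0, keepdims=True)
    smx = f_c.max(axis=0, keepdims=True)
    cat = np.concatenate([savg, smx], axis=0)
    m = sigmoid(conv3d_loops(cat, block.spatial_conv.weight.data,
                             block.spatial_conv.bias.data))
    return f_c * m
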