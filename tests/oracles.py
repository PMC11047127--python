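"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested Python loops (or the most
direct dense formula) in float64, deliberately sharing no code with the
package's vectorized implementations.
"""

import numpy as np


# ---------------------------------------------------------------------------
# Scalar-loop building blocks (channel-last: b, H, W, D, C)
# ---------------------------------------------------------------------------

def loop_conv3d(x, w, b=None):
    """Same-padded stride-1 3-D cross-correlation by nested loops."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    k = w.shape[0]
    pad = k // 2
    bs, H, W, D, Cin = x.shape
    Cout = w.shape[4]
    out = np.zeros((bs, H, W, D, Cout))
    for n in range(bs):
        for i in range(H):
            for j in range(W):
                for kk in range(D):
                    for co in range(Cout):
                        acc = 0.0
                        for a in range(k):
                            for bb in range(k):
                                for c in range(k):
                                    ii, jj, dd = i + a - pad, j + bb - pad, kk + c - pad
                                    if 0 <= ii < H and 0 <= jj < W and 0 <= dd < D:
                                        for ci in range(Cin):
                                            acc += x[n, ii, jj, dd, ci] * w[a, bb, c, ci, co]
                        out[n, i, j, kk, co] = acc + (b[co] if b is not None else 0.0)
    return out


def loop_batchnorm(y, gamma, beta, eps=1e-5):
    """Batch normalization with batch statistics per channel."""
    y = np.asarray(y, dtype=np.float64)
    out = np.empty_like(y)
    for c in range(y.shape[-1]):
        vals = y[..., c]
        mu = vals.mean()
        var = ((vals - mu) ** 2).mean()
        out[..., c] = gamma[c] * (vals - mu) / np.sqrt(var + eps) + beta[c]
    return out


def loop_gap(y):
    """Global average pooling to (b, 1, 1, 1, C)."""
    y = np.asarray(y, dtype=np.float64)
    bs, H, W, D, C = y.shape
    out = np.zeros((bs, 1, 1, 1, C))
    for n in range(bs):
        for c in range(C):
            acc = 0.0
            for i in range(H):
                for j in range(W):
                    for k in range(D):
                        acc += y[n, i, j, k, c]
            out[n, 0, 0, 0, c] = acc / (H * W * D)
    return out


def _softmax_channels(s):
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def loop_saeb(x, p):
    """SAEB forward: conv -> BN -> GAP -> reduce/restore -> softmax -> scale -> ReLU.

    ``p`` holds conv_w, conv_b, gamma, beta, eps, reduce_w, reduce_b,
    restore_w, restore_b (NumPy arrays).
    """
    y = loop_conv3d(x, p["conv_w"], p["conv_b"])
    y_bn = loop_batchnorm(y, p["gamma"], p["beta"], p["eps"])
    s = loop_gap(y_bn)
    s = np.maximum(0.0, loop_conv3d(s, p["reduce_w"], p["reduce_b"]))
    s = loop_conv3d(s, p["restore_w"], p["restore_b"])
    a = _softmax_channels(s)                     # (b,1,1,1,C)
    z = a * y_bn
    return np.maximum(0.0, z)


def loop_daeb(x, p):
    """DAEB forward: conv -> (channel attention, spatial attention) -> add."""
    t = loop_conv3d(x, p["conv_w"], p["conv_b"])
    ca = loop_gap(t)
    ca = np.maximum(0.0, loop_conv3d(ca, p["reduce_w"], p["reduce_b"]))
    ca = _sigmoid(loop_conv3d(ca, p["restore_w"], p["restore_b"]))
    pooled = np.stack([t.max(axis=-1), t.mean(axis=-1)], axis=-1)
    sa = _sigmoid(loop_conv3d(pooled, p["spatial_w"], p["spatial_b"]))
    return t * ca + t * sa


def loop_segpath(x, branches, eps=1e-5):
    """SegPath forward: sum over n parallel (1x1x1 + 3x3x3) branch pairs."""
    x = np.asarray(x, dtype=np.float64)
    if not branches:
        return x.copy()
    z = np.zeros(x.shape[:4] + (branches[0]["c1_w"].shape[4],))
    for br in branches:
        y1 = np.maximum(0.0, loop_batchnorm(
            loop_conv3d(x, br["c1_w"], br["c1_b"]), br["bn1_gamma"],
            br["bn1_beta"], eps))
        y2 = np.maximum(0.0, loop_batchnorm(
            loop_conv3d(x, br["c3_w"], br["c3_b"]), br["bn3_gamma"],
            br["bn3_beta"], eps))
        z = z + y1 + y2
    return z


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------

def brute_force_ahd(p_points, l_points, spacing=(1.0, 1.0, 1.0)):
    """O(|P| * |L|) double-loop average Hausdorff distance."""
    sp = np.asarray(spacing, dtype=np.float64)
    p = np.asarray(p_points, dtype=np.float64) * sp
    l = np.asarray(l_points, dtype=np.float64) * sp
    d_pl = sum(min(np.sqrt(((pp - ll) ** 2).sum()) for ll in l) for pp in p) / len(p)
    d_lp = sum(min(np.sqrt(((pp - ll) ** 2).sum()) for pp in p) for ll in l) / len(l)
    return 0.5 * (d_pl + d_lp)


def dense_gaussian_filter(img, sigma, truncate=4.0):
    """Direct dense convolution with a normalized 3-D Gaussian kernel."""
    r = int(truncate * sigma + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-ax ** 2 / (2.0 * sigma ** 2))
    k1 /= k1.sum()
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    H, W, D = img.shape
    out = np.zeros_like(img, dtype=np.float64)
    for i in range(H):
        for j in range(W):
            for k in range(D):
                acc = 0.0
                for a in range(-r, r + 1):
                    for b in range(-r, r + 1):
                        for c in range(-r, r + 1):
                            # reflect boundary, matching scipy's default
                            ii = _reflect(i + a, H)
                            jj = _reflect(j + b, W)
                            kk = _reflect(k + c, D)
                            acc += img[ii, jj, kk] * kernel[a + r, b + r, c + r]
                out[i, j, k] = acc
    return out


def _reflect(i, n):
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        else:
            i = 2 * n - i - 1
    return i


# ---------------------------------------------------------------------------
# Parameter extraction helpers (bridge package blocks -> loop oracles)
# ---------------------------------------------------------------------------

def saeb_params(block):
    return {
        "conv_w": block.conv.w.data, "conv_b": block.conv.b.data,
        "gamma": block.bn.gamma.data, "beta": block.bn.beta.data,
        "eps": block.bn.eps,
        "reduce_w": block.reduce.w.data, "reduce_b": block.reduce.b.data,
        "restore_w": block.restore.w.data, "restore_b": block.restore.b.data,
    }


def daeb_params(block):
    return {
        "conv_w": block.conv.w.data, "conv_b": block.conv.b.data,
        "reduce_w": block.reduce.w.data, "reduce_b": block.reduce.b.data,
        "restore_w": block.restore.w.data, "restore_b": block.restore.b.data,
        "spatial_w": block.spatial.w.data, "spatial_b": block.spatial.b.data,
    }


def segpath_branches(block):
    out = []
    for br in block.branches:
        out.append({
            "c1_w": br["c1"].w.data, "c1_b": br["c1"].b.data,
            "bn1_gamma": br["bn1"].gamma.data, "bn1_beta": br["bn1"].beta.data,
            "c3_w": br["c3"].w.data, "c3_b": br["c3"].b.data,
            "bn3_gamma": br["bn3"].gamma.data, "bn3_beta": br["bn3"].beta.data,
        })
    return out
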