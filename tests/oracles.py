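"""Independent scalar-loop reference implementations used as test oracles.

Everything here is written with explicit Python loops over positions and
channels, deliberately sharing no code with the package's vectorised paths.
"""

from __future__ import annotations

import math

import numpy as np


def sga_loop(x, groups, eps=1e-5, gamma=None, beta=None):
    """Per-group spatial gating, one scalar at a time."""
    x = np.asarray(x, dtype=np.float64)
    b, c, h, w = x.shape
    cg = c // groups
    if gamma is None:
        gamma = np.ones(groups)
    if beta is None:
        beta = np.zeros(groups)
    out = np.zeros_like(x)
    for bi in range(b):
        for g in range(groups):
            chans = list(range(g * cg, (g + 1) * cg))
            ctx = []
            for ch in chans:
                total = 0.0
                for i in range(h):
                    for j in range(w):
                        total += x[bi, ch, i, j]
                ctx.append(total / (h * w))
            coeff = np.zeros((h, w))
            for i in range(h):
                for j in range(w):
                    dot = 0.0
                    for k, ch in enumerate(chans):
                        dot += x[bi, ch, i, j] * ctx[k]
                    coeff[i, j] = dot
            mu = coeff.sum() / (h * w)
            var = ((coeff - mu) ** 2).sum() / (h * w)
            sd = math.sqrt(var)
            for i in range(h):
                for j in range(w):
                    t = (coeff[i, j] - mu) / (sd + eps)
                    gate = 1.0 / (1.0 + math.exp(-(gamma[g] * t + beta[g])))
                    for ch in chans:
                        out[bi, ch, i, j] = x[bi, ch, i, j] * gate
    return out


def se_loop(u, w1, w2):
    """Squeeze -> excite -> scale, scalar arithmetic only."""
    u = np.asarray(u, dtype=np.float64)
    b, c, h, w = u.shape
    hidden_dim = w1.shape[0]
    out = np.zeros_like(u)
    for bi in range(b):
        z = [u[bi, ch].sum() / (h * w) for ch in range(c)]
        hid = []
        for q in range(hidden_dim):
            acc = sum(w1[q, ch] * z[ch] for ch in range(c))
            hid.append(max(acc, 0.0))
        gates = []
        for ch in range(c):
            acc = sum(w2[ch, q] * hid[q] for q in range(hidden_dim))
            gates.append(1.0 / (1.0 + math.exp(-acc)))
        for ch in range(c):
            out[bi, ch] = u[bi, ch] * gates[ch]
    return out


def conv2d_loop(x, weight, bias=None, stride=1, padding=0, dilation=1):
    """Direct four-loop 2-D cross-correlation."""
    x = np.asarray(x, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    b, cin, h, w = x.shape
    cout, _, kh, kw = weight.shape
    h_out = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    w_out = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((b, cout, h_out, w_out))
    for bi in range(b):
        for co in range(cout):
            for oi in range(h_out):
                for oj in range(w_out):
                    acc = 0.0
                    for ci in range(cin):
                        for ki in range(kh):
                            for kj in range(kw):
                                ii = oi * stride + ki * dilation - padding
                                jj = oj * stride + kj * dilation - padding
                                if 0 <= ii < h and 0 <= jj < w:
                                    acc += x[bi, ci, ii, jj] * weight[co, ci, ki, kj]
                    if bias is not None:
                        acc += bias[co]
                    out[bi, co, oi, oj] = acc
    return out


def confusion_loop(pred, gt):
    """Pixel-by-pixel confusion tallies."""
    tp = tn = fp = fn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p == 1 and g == 1:
            tp += 1
        elif p == 0 and g == 0:
            tn += 1
        elif p == 1 and g == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def finite_difference_grad(f, x, eps=1e-2):
    """Central-difference gradient of scalar f with respect to array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
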