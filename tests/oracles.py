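"""Independent brute-force reference implementations.

Deliberately written as explicit loops over subjects/voxels/time with
two-pass means, sharing no code with the package, so they can serve as
oracles for the vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_loop(x, y):
    """Textbook two-pass Pearson correlation of two sequences."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[t] - mx) * (y[t] - my) for t in range(n))
    dx = sum((x[t] - mx) ** 2 for t in range(n))
    dy = sum((y[t] - my) ** 2 for t in range(n))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / math.sqrt(dx * dy)


def correlation_maps_loop(values):
    """Seed-based correlation maps for a (I, J, V, T) array, one loop at a time."""
    ii, jj, vv, tt = values.shape
    out = np.empty((ii, jj, vv))
    for i in range(ii):
        for j in range(jj):
            seed = [sum(values[i, j, v, t] for v in range(vv)) / vv for t in range(tt)]
            for v in range(vv):
                out[i, j, v] = pearson_loop(list(values[i, j, v]), seed)
    return out


def variance_components_loop(v1, v2):
    """Per-voxel Var{U}, Var{V}, Var{X} from two (I, V) session matrices."""
    ii, vv = v1.shape
    var_u = np.empty(vv)
    var_v = np.empty(vv)
    for v in range(vv):
        d = [v2[i, v] - v1[i, v] for i in range(ii)]
        d_bar = sum(d) / ii
        var_u[v] = 0.5 * sum((di - d_bar) ** 2 for di in d) / (ii - 1)
        total = 0.0
        for sess in (v1, v2):
            m = sum(sess[i, v] for i in range(ii)) / ii
            total += sum((sess[i, v] - m) ** 2 for i in range(ii)) / (ii - 1)
        var_v[v] = total / 2.0
    var_x = np.maximum(var_v - var_u, 0.0)
    return var_u, var_v, var_x


def mse_loop(pred, obs):
    """Per-subject mean squared error over voxels, skipping NaN pairs."""
    ii, vv = pred.shape
    out = np.empty(ii)
    for i in range(ii):
        total, n = 0.0, 0
        for v in range(vv):
            if math.isnan(pred[i, v]) or math.isnan(obs[i, v]):
                continue
            total += (pred[i, v] - obs[i, v]) ** 2
            n += 1
        out[i] = total / n
    return out
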