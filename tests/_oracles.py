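"""Independent scalar (loop-based) reference implementations.

Deliberately written without NumPy vector tricks so they share no code
path with the package: plain Python loops and `math` only. Tests compare
the package's vectorized implementations against these.
"""

from __future__ import annotations

import math


# -- regression metrics ------------------------------------------------------

def r_squared_scalar(y_true, y_pred) -> float:
    n = len(y_true)
    ybar = sum(y_true) / n
    ss_res = 0.0
    ss_tot = 0.0
    for yt, yp in zip(y_true, y_pred):
        ss_res += (yt - yp) ** 2
        ss_tot += (yt - ybar) ** 2
    return 1.0 - ss_res / ss_tot


def rmse_scalar(y_true, y_pred) -> float:
    total = 0.0
    for yt, yp in zip(y_true, y_pred):
        total += (yt - yp) ** 2
    return math.sqrt(total / len(y_true))


def rrmse_scalar(y_true, y_pred) -> float:
    ybar = sum(y_true) / len(y_true)
    return rmse_scalar(y_true, y_pred) / ybar * 100.0


# -- piecewise-linear interpolation ------------------------------------------

def interpolate_scalar(values, mask):
    """Fill unobserved entries: linear between neighbors, constant at edges."""
    n = len(values)
    observed = [i for i in range(n) if mask[i]]
    out = list(values)
    for i in range(n):
        if mask[i]:
            continue
        left = None
        right = None
        for j in observed:
            if j < i:
                left = j
            elif j > i and right is None:
                right = j
        if left is None:
            out[i] = values[right]
        elif right is None:
            out[i] = values[left]
        else:
            frac = (i - left) / (right - left)
            out[i] = values[left] + frac * (values[right] - values[left])
    return out


# -- point-cloud traits ------------------------------------------------------

def spectral_indices_scalar(points):
    """points: list of (x, y, z, b, g, r, nir). Returns dict of 4 indices,
    skipping zero-denominator points per index."""
    sums = {"GNDVI": 0.0, "CVI": 0.0, "NCPI": 0.0, "MCARI": 0.0}
    counts = {k: 0 for k in sums}
    for (_, _, _, b, g, r, nir) in points:
        if nir + g != 0:
            sums["GNDVI"] += (nir - g) / (nir + g)
            counts["GNDVI"] += 1
        if g != 0:
            sums["CVI"] += (nir / g) * (r / g)
            counts["CVI"] += 1
        if r + b != 0:
            sums["NCPI"] += (r - b) / (r + b)
            counts["NCPI"] += 1
        if r != 0:
            sums["MCARI"] += ((nir - r) - 0.2 * (nir - g)) * (nir / r)
            counts["MCARI"] += 1
    return {k: sums[k] / counts[k] for k in sums if counts[k] > 0}


def percentile_scalar(values, q) -> float:
    """Linear-interpolation percentile between order statistics."""
    s = sorted(values)
    rank = q / 100.0 * (len(s) - 1)
    lo = math.floor(rank)
    hi = math.ceil(rank)
    if lo == hi:
        return s[lo]
    return s[lo] + (rank - lo) * (s[hi] - s[lo])


def structural_traits_scalar(points, grid_cell, voxel):
    zs = [p[2] for p in points]
    hmean = sum(zs) / len(zs)
    h99 = percentile_scalar(zs, 99)
    cells = set()
    voxels = set()
    for (x, y, z, *_ ) in points:
        cells.add((math.floor(x / grid_cell), math.floor(y / grid_cell)))
        voxels.add((math.floor(x / voxel), math.floor(y / voxel),
                    math.floor(z / voxel)))
    pla = len(cells) * (grid_cell / 1000.0) ** 2
    volume = len(voxels) * (voxel / 1000.0) ** 3
    return {"Hmean": hmean, "H99": h99, "PLA": pla, "Volume": volume}
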