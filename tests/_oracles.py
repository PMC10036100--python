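"""Independent brute-force oracles, deliberately naive.

These re-derive DVH quantiles and shift-scan margins by direct enumeration
over dense voxel coordinate arrays, sharing no code path with the package.
"""

import numpy as np


def oracle_dvh_quantile(values, mask, q):
    """Largest dose D with at least q*N masked voxels receiving >= D."""
    v = values[mask]
    best = None
    for cand in np.unique(v):
        if np.count_nonzero(v >= cand) >= q * v.size:
            best = cand if best is None else max(best, cand)
    return best


def _dense_coords(grid):
    axes = [grid.origin[i] + grid.spacing[i] * np.arange(grid.shape[i]) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def oracle_margin(dose, center, radius, axis_index, threshold, q=0.95,
                  shift_step=1.0, shift_range=20.0):
    """Margin by exhaustive shift enumeration with direct mask translation.

    For every scanned shift the sphere mask is rebuilt at the translated
    center and the quantile taken by plain sorting; the extent stops at the
    first failing shift (contiguity).  Returns (margin, pos, neg).
    """
    X, Y, Z = _dense_coords(dose.grid)
    n = int(np.floor(shift_range / shift_step + 1e-9))

    def d95_at(s):
        c = list(center)
        c[axis_index] -= s
        inside = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius**2
        v = np.sort(dose.values[inside])
        k = int(np.ceil(q * v.size))
        return v[v.size - k]

    def extent(sign):
        ext = 0.0
        for k in range(1, n + 1):
            if d95_at(sign * k * shift_step) >= threshold:
                ext = k * shift_step
            else:
                break
        return ext

    if d95_at(0.0) < threshold:
        return 0.0, 0.0, 0.0
    pos, neg = extent(+1), extent(-1)
    return min(pos, neg), pos, neg
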