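"""Independent brute-force / textbook-formula oracles used by the tests.

Everything here is deliberately written as plain loops and explicit
formulas, independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

NEIGHBOURS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def brute_max_in_sphere(values, spacing, seed, radius_mm):
    """Exhaustive SUVmax search over a sphere around the seed voxel."""
    best = -np.inf
    s = np.asarray(seed, float) * np.asarray(spacing, float)
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = np.array([i, j, k], float) * np.asarray(spacing, float)
                if np.sum((p - s) ** 2) <= radius_mm**2:
                    best = max(best, values[i, j, k])
    return best


def flood_fill(values, seed, threshold, strict=False):
    """26-connected component of the super-level set containing the seed."""
    above = values > threshold if strict else values >= threshold
    out = np.zeros(values.shape, dtype=bool)
    if not above[tuple(seed)]:
        return out
    stack = [tuple(seed)]
    out[tuple(seed)] = True
    shape = values.shape
    while stack:
        i, j, k = stack.pop()
        for di, dj, dk in NEIGHBOURS_26:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                if above[a, b, c] and not out[a, b, c]:
                    out[a, b, c] = True
                    stack.append((a, b, c))
    return out


def brute_mtv_ml(mask, spacing):
    total = 0
    for v in np.asarray(mask).ravel():
        if v:
            total += 1
    return total * spacing[0] * spacing[1] * spacing[2] / 1000.0


def pearson_formula(x, y):
    """Explicit covariance / sd formula with two-sided t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    cov = np.sum((x - mx) * (y - my))
    r = cov / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * _st.t.sf(abs(t), n - 2)
    return r, p


def paired_t_formula(x, y, alpha=0.05):
    """Textbook paired t test: statistic, two-sided p and CI."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    mean = d.sum() / n
    var = np.sum((d - mean) ** 2) / (n - 1)
    se = np.sqrt(var / n)
    t = mean / se
    p = 2 * _st.t.sf(abs(t), n - 1)
    tcrit = _st.t.ppf(1 - alpha / 2, n - 1)
    return mean, (mean - tcrit * se, mean + tcrit * se), p


def icc21_anova(x):
    """ICC(2,1) from explicitly computed two-way ANOVA mean squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def sphere_labels(radius_mm, spacing=1.0, margin_mm=4.0, center_offset=0.0):
    """Rasterised solid sphere as a tumour LabelVolume."""
    from petmtv.volumes import LabelVolume

    half = radius_mm + margin_mm
    n = int(np.ceil(2 * half / spacing)) + 1
    ax = np.arange(n) * spacing
    c = ax[n // 2] + center_offset
    x = ax[:, None, None]
    y = ax[None, :, None]
    z = ax[None, None, :]
    inside = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_mm**2
    return LabelVolume(inside.astype(np.int64), (spacing,) * 3, (0.0, 0.0, 0.0))
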