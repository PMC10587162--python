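"""Independent brute-force / textbook-formula oracles used by the tests.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the implementation: Pearson/Bland–Altman/ICC from their definitional
formulas, OLS from the normal equations, Dice from coordinate-set
intersection, and caliper widths from a pixel-corner rotation construction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_formula(x, y):
    """Product-moment correlation and two-sided p from the textbook formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(r), float(p)


def bland_altman_formula(reference, test):
    """Mean difference (test − reference) and 1.96-SD limits of agreement."""
    d = np.asarray(test, float) - np.asarray(reference, float)
    md = d.mean()
    sd = d.std(ddof=1)
    return float(md), float(md - 1.96 * sd), float(md + 1.96 * sd)


def icc21_formula(reference, test):
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    x = np.column_stack([np.asarray(reference, float), np.asarray(test, float)])
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - gm) ** 2).sum() / (n - 1)
    msc = n * ((col_means - gm) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + gm) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def ols_normal_equations(x, y, degree):
    """Polynomial OLS coefficients (ascending powers) by the normal equations."""
    X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def dice_bruteforce(labels_a, labels_b, label):
    """Dice from explicit coordinate sets."""
    a = {tuple(idx) for idx in np.argwhere(labels_a == label)}
    b = {tuple(idx) for idx in np.argwhere(labels_b == label)}
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def corner_width_oracle(mask, direction, step_mm):
    """Max caliper width by rotating the pixel-corner point set.

    Every foreground pixel contributes its four corner points in mm; corners
    are projected onto the axis/perpendicular frame and the maximum per-bin
    perpendicular span is returned.
    """
    sr, sc = mask.spacing_mm
    centers = np.argwhere(mask.pixels) * np.array([sr, sc])
    corners = np.concatenate(
        [
            centers + [dr * sr / 2, dc * sc / 2]
            for dr in (-1, 1)
            for dc in (-1, 1)
        ]
    )
    u = np.asarray(direction, float)
    v = np.array([-u[1], u[0]])
    centroid = centers.mean(axis=0)
    rel = corners - centroid
    t = rel @ u
    w = rel @ v
    tmin = t.min()
    nbins = max(1, int(np.ceil((t.max() - tmin) / step_mm - 1e-12)))
    idx = np.clip(np.floor((t - tmin) / step_mm).astype(int), 0, nbins - 1)
    best = 0.0
    for b in range(nbins):
        sel = idx == b
        if sel.any():
            best = max(best, w[sel].max() - w[sel].min())
    return best


def ellipse_mask(a_mm, b_mm, angle_deg, spacing_mm, pad_mm=3.0):
    """Rasterize a rotated ellipse (half-axes a along the rotated row axis)
    from its implicit inequality at pixel centers."""
    from fetalbiom import BinaryMask

    sr, sc = spacing_mm
    theta = np.deg2rad(angle_deg)
    ext_r = np.hypot(a_mm * np.cos(theta), b_mm * np.sin(theta)) + pad_mm
    ext_c = np.hypot(a_mm * np.sin(theta), b_mm * np.cos(theta)) + pad_mm
    nr = int(np.ceil(2 * ext_r / sr)) + 1
    nc = int(np.ceil(2 * ext_c / sc)) + 1
    rows = (np.arange(nr) * sr - ext_r)[:, None]
    cols = (np.arange(nc) * sc - ext_c)[None, :]
    p = rows * np.cos(theta) + cols * np.sin(theta)
    q = -rows * np.sin(theta) + cols * np.cos(theta)
    return BinaryMask((p / a_mm) ** 2 + (q / b_mm) ** 2 <= 1.0, (sr, sc))


def rectangle_mask(n_rows, n_cols, angle_deg, spacing_mm):
    """Rasterize a rotated rectangle of n_rows × n_cols pixels (at the given
    spacing) from its inequality definition, not by resampling."""
    from fetalbiom import BinaryMask

    sr, sc = spacing_mm
    half_r, half_c = n_rows * sr / 2, n_cols * sc / 2
    theta = np.deg2rad(angle_deg)
    ext = np.hypot(half_r, half_c) + 2 * max(sr, sc)
    nr = int(np.ceil(2 * ext / sr)) + 1
    nc = int(np.ceil(2 * ext / sc)) + 1
    rows = (np.arange(nr) * sr - ext)[:, None]
    cols = (np.arange(nc) * sc - ext)[None, :]
    p = rows * np.cos(theta) + cols * np.sin(theta)
    q = -rows * np.sin(theta) + cols * np.cos(theta)
    return BinaryMask((np.abs(p) <= half_r) & (np.abs(q) <= half_c), (sr, sc))
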