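"""Independent oracles used by the tests.

These deliberately re-derive quantities along a different numerical path
from the package implementation (per-window least squares on materialized
windows vs prefix sums; explicit loops vs vectorization) so agreement is
meaningful.
"""

from __future__ import annotations

import numpy as np

# same tie convention as the implementation: slopes within one part in 1e9
# are tied and the earliest window wins
TIE_RTOL = 1e-9


def brute_force_mmr_window(
    t: np.ndarray,
    y: np.ndarray,
    window_min_s: float = 180.0,
    r2_min: float = 0.95,
):
    """Enumerate every window of duration >= ``window_min_s`` at 1-sample
    start steps; per-window OLS via explicit centered dot products on the
    materialized window.  Returns (start_idx, width, slope, r2) of the
    steepest admissible window, scanning shorter widths first and replacing
    only on strictly steeper slopes (earliest window within a width).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    dt = t[1] - t[0]
    w_min = int(np.ceil(window_min_s / dt)) + 1
    best = None
    best_slope = np.inf
    for w in range(w_min, n + 1):
        win_y = np.lib.stride_tricks.sliding_window_view(y, w)
        win_t = np.lib.stride_tricks.sliding_window_view(t, w)
        tc = win_t - win_t.mean(axis=1, keepdims=True)
        yc = win_y - win_y.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", tc, tc)
        sxy = np.einsum("ij,ij->i", tc, yc)
        syy = np.einsum("ij,ij->i", yc, yc)
        slope = sxy / sxx
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)
        ok = r2 > r2_min
        if not ok.any():
            continue
        cand = np.where(ok, slope, np.inf)
        m = float(cand.min())
        tol = TIE_RTOL * max(abs(m), 1e-30)
        i = int(np.argmax(cand <= m + tol))
        if best is None or m < best_slope - TIE_RTOL * abs(best_slope):
            best_slope = m
            best = (i, w, float(cand[i]), float(r2[i]))
    return best


def naive_mmr_window_small(t, y, window_min_s=180.0, r2_min=0.95):
    """Same enumeration with scipy.stats.linregress per window — the slow
    reference used on a handful of slices."""
    from scipy.stats import linregress

    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    dt = t[1] - t[0]
    w_min = int(np.ceil(window_min_s / dt)) + 1
    best = None
    best_slope = np.inf
    for w in range(w_min, n + 1):
        fits = []
        for s in range(0, n - w + 1):
            lr = linregress(t[s : s + w], y[s : s + w])
            r2 = lr.rvalue**2
            if r2 > r2_min:
                fits.append((s, float(lr.slope), float(r2)))
        if not fits:
            continue
        m = min(f[1] for f in fits)
        tol = TIE_RTOL * max(abs(m), 1e-30)
        s, slope, r2 = next(f for f in fits if f[1] <= m + tol)
        if best is None or m < best_slope - TIE_RTOL * abs(best_slope):
            best_slope = m
            best = (s, w, slope, r2)
    return best


def anova_2x2_by_hand(df):
    """Balanced two-way ANOVA sums of squares computed from textbook
    formulas (cell/marginal means), returning F statistics for the two main
    effects and the interaction."""
    a_levels = sorted(df["treatment"].unique())
    b_levels = sorted(df["sex"].unique())
    n_cell = len(df) // (len(a_levels) * len(b_levels))
    grand = df["value"].mean()
    cell = df.groupby(["treatment", "sex"])["value"].mean()
    a_means = df.groupby("treatment")["value"].mean()
    b_means = df.groupby("sex")["value"].mean()
    ss_a = n_cell * len(b_levels) * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n_cell * len(a_levels) * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n_cell * sum(
        (cell[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_err = sum(
        (row.value - cell[(row.treatment, row.sex)]) ** 2 for row in df.itertuples()
    )
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(df) - len(a_levels) * len(b_levels)
    ms_err = ss_err / df_err
    return {
        "treatment": (ss_a / df_a) / ms_err,
        "sex": (ss_b / df_b) / ms_err,
        "treatment:sex": (ss_ab / df_ab) / ms_err,
        "df_err": df_err,
    }
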