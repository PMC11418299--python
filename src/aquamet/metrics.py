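"""Whole-animal metabolic metrics from processed respirometry cycles.

* MMR — steepest-slope sliding window (>=180 s, 1-s steps, r2 > 0.95) over
  the first post-exhaustion measurement.
* RMR — the 0.10 quantile of all validated cycle uptakes (r2 > 0.90),
  defined only when at least 60 validated cycles exist.
* Aerobic scope — absolute (MMR - RMR) and factorial (MMR / RMR).
* EPOC — the area between a shape-preserving cubic interpolant of the
  recovery curve and the RMR line, from MMR until uptake returns to RMR;
  its duration is the time of that return.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .records import FishRecord, O2Trace, RespirometryProtocol
from .traces import fit_cycle_slope, mdot_from_slope, process_trace, segment_cycles

#: relative tolerance below which two window slopes count as tied
SLOPE_TIE_RTOL = 1e-9


@dataclass
class MMRWindowResult:
    """Steepest admissible window of the first measurement."""

    window_start: float  # s
    window_end: float  # s
    slope: float  # mg l-1 s-1
    r2: float
    mmr: float  # mg O2 kg-1 min-1


@dataclass
class RMRResult:
    value: float  # mg O2 kg-1 min-1 (nan when undefined)
    n_cycles: int
    ok: bool


@dataclass
class EPOCResult:
    epoc: float  # mg O2 kg-1
    duration: float  # min
    censored: bool  # record ended before uptake returned to RMR


@dataclass
class MetabolicSummary:
    """Per-fish metabolic phenotype."""

    fish_id: str
    rmr: float = float("nan")
    mmr: float = float("nan")
    aas: float = float("nan")
    fas: float = float("nan")
    epoc: float = float("nan")
    epoc_duration: float = float("nan")
    n_valid_cycles: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


def _window_stats(t: np.ndarray, y: np.ndarray, w: int, step: int):
    """Slopes and r2 of every length-``w`` window (start stride ``step``),
    via prefix sums — O(n) per window length."""
    n = len(t)
    c1 = np.concatenate([[0.0], np.cumsum(t)])
    c2 = np.concatenate([[0.0], np.cumsum(t * t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    starts = np.arange(0, n - w + 1, step)
    ends = starts + w
    sx = c1[ends] - c1[starts]
    sxx = c2[ends] - c2[starts]
    sy = cy[ends] - cy[starts]
    syy = cyy[ends] - cyy[starts]
    sxy = cty[ends] - cty[starts]
    vx = w * sxx - sx * sx
    vy = w * syy - sy * sy
    cov = w * sxy - sx * sy
    slope = cov / vx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(vy > 0, cov * cov / (vx * vy), 0.0)
    return starts, slope, r2


def estimate_mmr(
    time_s: np.ndarray,
    o2: np.ndarray,
    fish: FishRecord,
    window_min: float = 180.0,
    step: float = 1.0,
    r2_min: float = 0.95,
    lengths: str | np.ndarray = "all",
) -> MMRWindowResult | None:
    """Sliding-window MMR over the first post-exhaustion measurement slice.

    Windows of every duration >= ``window_min`` are advanced across the
    slice in ``step``-second increments; the steepest O2 decline among
    windows with r2 > ``r2_min`` is returned.  Tie-break is reproducible:
    shorter windows are scanned first and a longer window replaces the
    incumbent only if strictly steeper; within one length the earliest
    window wins.

    ``lengths="all"`` enumerates every window length (exact; the default —
    first-measurement slices are short).  Passing an array of durations in
    seconds restricts the scan, e.g. a geometric ladder for very long
    slices.  Returns ``None`` when no window passes the r2 gate (MMR
    undetermined; callers must flag, never fill).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2, dtype=float)
    if len(t) < 3:
        raise ValueError("slice too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("sliding-window MMR requires uniform sampling")
    rate = 1.0 / dt[0]
    span = t[-1] - t[0]
    if span < window_min:
        raise ValueError(
            f"slice spans {span:.0f} s, shorter than the {window_min:.0f} s minimum window"
        )
    w_min = int(np.ceil(window_min * rate)) + 1
    step_samples = max(1, int(round(step * rate)))
    n = len(t)
    if isinstance(lengths, str) and lengths == "all":
        widths = range(w_min, n + 1)
    else:
        widths = sorted(
            {min(n, int(np.ceil(float(d) * rate)) + 1) for d in np.asarray(lengths)}
        )
        widths = [w for w in widths if w >= w_min]
    t0 = t - t[0]  # slope invariant to the shift; improves conditioning
    ybar = y - y.mean()
    best = None
    best_slope = np.inf
    for w in widths:
        starts, slope, r2 = _window_stats(t0, ybar, w, step_samples)
        ok = r2 > r2_min
        if not ok.any():
            continue
        slope_ok = np.where(ok, slope, np.inf)
        m = float(slope_ok.min())
        # slopes within one part in 1e9 are tied; the earliest window wins
        tol = SLOPE_TIE_RTOL * max(abs(m), 1e-30)
        i = int(np.argmax(slope_ok <= m + tol))
        if best is None or m < best_slope - SLOPE_TIE_RTOL * abs(best_slope):
            best_slope = m
            s = starts[i]
            best = MMRWindowResult(
                window_start=float(t[s]),
                window_end=float(t[s + w - 1]),
                slope=float(slope_ok[i]),
                r2=float(r2[i]),
                mmr=mdot_from_slope(float(slope_ok[i]), fish),
            )
    return best


def estimate_rmr(
    mdots: np.ndarray, quantile: float = 0.10, min_cycles: int = 60
) -> RMRResult:
    """Resting metabolic rate: low quantile of validated cycle uptakes.

    Uses the linear-interpolation quantile convention (numpy's default).
    Returns an undefined (NaN) value with ``ok=False`` when fewer than
    ``min_cycles`` validated measurements are available.
    """
    mdots = np.asarray(mdots, dtype=float)
    n = len(mdots)
    if n < min_cycles:
        return RMRResult(float("nan"), n, False)
    return RMRResult(float(np.quantile(mdots, quantile)), n, True)


def aerobic_scope(mmr: float, rmr: float) -> tuple[float, float]:
    """Absolute (MMR - RMR) and factorial (MMR / RMR) aerobic scope."""
    if not rmr > 0:
        raise ValueError(f"rmr must be positive, got {rmr}")
    return mmr - rmr, mmr / rmr


def estimate_epoc(
    t_min: np.ndarray,
    mdot: np.ndarray,
    rmr: float,
    grid_step_min: float = 0.1,
) -> EPOCResult:
    """Excess post-exercise oxygen consumption and its duration.

    The cycle-level recovery points (starting at the MMR ordinate) are
    interpolated with a monotone shape-preserving cubic (PCHIP — avoids the
    overshoot below RMR a natural cubic can produce).  Recovery ends at the
    first down-crossing of the interpolant through ``rmr`` that stays at or
    below ``rmr`` until the midpoint of the following inter-sample gap; EPOC
    is the integral of (uptake - rmr) from the first point to that time.
    If uptake never returns to RMR within the record, the result is censored:
    duration is the record length and EPOC the lower bound integrated over
    the whole record.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(mdot, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two recovery points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("recovery times must be strictly increasing")
    if np.all(y <= rmr):
        return EPOCResult(0.0, 0.0, False)
    f = PchipInterpolator(t, y)
    excess = lambda x: f(x) - rmr  # noqa: E731
    grid = np.arange(t[0], t[-1] + grid_step_min, grid_step_min)
    grid = grid[grid <= t[-1]]
    vals = excess(grid)
    tol = 1e-9 * max(1.0, abs(rmr))

    def hold_horizon(x: float) -> float:
        nxt = np.searchsorted(t, x, side="right")
        if nxt >= len(t):
            return t[-1]
        if nxt + 1 >= len(t):
            return t[-1]
        return 0.5 * (t[nxt] + t[nxt + 1])

    t_end = None
    i = 1
    while i < len(grid):
        if vals[i] <= 0 < vals[i - 1]:
            root = brentq(excess, grid[i - 1], grid[i])
            horizon = hold_horizon(root)
            check = np.linspace(root, horizon, 50)
            if np.all(excess(check) <= tol):
                t_end = float(root)
                break
        i += 1
    if t_end is None:
        duration = float(t[-1] - t[0])
        epoc = float(f.integrate(t[0], t[-1]) - rmr * duration)
        return EPOCResult(max(epoc, 0.0), duration, True)
    duration = t_end - float(t[0])
    epoc = float(f.integrate(t[0], t_end) - rmr * duration)
    return EPOCResult(max(epoc, 0.0), duration, False)


def summarize_fish(
    trace: O2Trace,
    fish: FishRecord,
    protocol: RespirometryProtocol | None = None,
    r2_min_cycles: float = 0.90,
    r2_min_mmr: float = 0.95,
    window_min: float = 180.0,
    window_step: float = 1.0,
    rmr_quantile: float = 0.10,
    min_cycles: int = 60,
    overnight_start_h: float | None = None,
) -> MetabolicSummary:
    """Full per-fish pipeline: cycles -> MMR, RMR, scope, EPOC.

    ``overnight_start_h`` optionally restricts the RMR sample to cycles
    starting after that many hours (resting uptake occurs overnight); the
    default uses all validated cycles and relies on the low quantile to
    ignore the elevated recovery cycles.
    """
    flags: list[str] = []
    slices = segment_cycles(trace, protocol)
    if not slices:
        return MetabolicSummary(fish_id=fish.fish_id, flags=("no measurement phases",))
    cycles = process_trace(trace, fish, protocol, r2_min=r2_min_cycles)
    validated = [c for c in cycles if c.valid]

    mmr = float("nan")
    mmr_res = None
    t0, y0 = slices[0]
    if t0[-1] - t0[0] >= window_min:
        mmr_res = estimate_mmr(
            t0, y0, fish, window_min=window_min, step=window_step, r2_min=r2_min_mmr
        )
    else:
        flags.append("first measurement shorter than minimum window")
    if mmr_res is None:
        flags.append("mmr undetermined")
    else:
        mmr = mmr_res.mmr

    rmr_pool = validated
    if overnight_start_h is not None:
        rmr_pool = [c for c in validated if c.t_start >= overnight_start_h * 3600.0]
    rmr_res = estimate_rmr(
        [c.mdot for c in rmr_pool], quantile=rmr_quantile, min_cycles=min_cycles
    )
    if not rmr_res.ok:
        flags.append(f"rmr undefined: only {rmr_res.n_cycles} validated cycles")
    rmr = rmr_res.value

    aas = fas = float("nan")
    if np.isfinite(mmr) and np.isfinite(rmr) and rmr > 0:
        aas, fas = aerobic_scope(mmr, rmr)

    epoc = epoc_duration = float("nan")
    if mmr_res is not None and rmr_res.ok:
        pts_t = [0.5 * (mmr_res.window_start + mmr_res.window_end) / 60.0]
        pts_y = [mmr]
        for c in validated:
            if c.cycle_index >= 1:
                pts_t.append(c.t_mid / 60.0)
                pts_y.append(c.mdot)
        if len(pts_t) >= 2:
            res = estimate_epoc(np.array(pts_t), np.array(pts_y), rmr)
            epoc, epoc_duration = res.epoc, res.duration
            if res.censored:
                flags.append("epoc censored: uptake never returned to rmr")

    return MetabolicSummary(
        fish_id=fish.fish_id,
        rmr=rmr,
        mmr=mmr,
        aas=aas,
        fas=fas,
        epoc=epoc,
        epoc_duration=epoc_duration,
        n_valid_cycles=rmr_res.n_cycles,
        flags=tuple(flags),
    )
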