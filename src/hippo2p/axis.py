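"""Position of cells along the DG-to-CA1 transverse axis and statistics of
spatial information along it.

The curved cell-body layer imaged in the transverse plane is summarized by
a rotated parabola fit to the cell centroids: the field of view is rotated
over a grid of angles, ``y = a(x-b)^2 + c`` is fit at each angle, and the
rotation maximizing R^2 is kept. The parabola's peak is the axis
inflection point; each cell is assigned the signed arc length along the
curve from the inflection to its nearest point on the curve. Non-uniform
structure of spatial information along the axis is assessed with a sliding
window (bootstrap s.e.m. plus a permutation envelope) and a general linear
F-test against a flat model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "AxisGeometry",
    "AxisProfile",
    "fit_axis_curve",
    "cell_axis_distance",
    "sliding_window_profile",
    "flat_f_test",
]


@dataclass
class AxisGeometry:
    rotation_deg: float
    parabola: tuple  # (a, b, c) in rotated coordinates
    inflection_xy_px: np.ndarray  # original coordinates
    fit_r2: float
    per_cell_distance_um: np.ndarray | None = None


@dataclass
class AxisProfile:
    window_centers_um: np.ndarray
    window_means: np.ndarray
    boot_sem: np.ndarray
    shuffle_band: np.ndarray = field(repr=False)  # (2, n_windows) lo/hi
    shuffle_mean: np.ndarray = field(repr=False)
    flagged: np.ndarray = field(repr=False)


def _rotate(xy: np.ndarray, deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return xy @ rot.T


def _parabola_fit(xy: np.ndarray) -> tuple[tuple, float]:
    x, y = xy[:, 0], xy[:, 1]
    if np.ptp(x) == 0:
        return (np.nan, np.nan, np.nan), -np.inf
    coef = np.polyfit(x, y, 2)
    pred = np.polyval(coef, x)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    a = coef[0]
    if a == 0:
        return (np.nan, np.nan, np.nan), -np.inf
    b = -coef[1] / (2 * a)
    c = np.polyval(coef, b)
    return (float(a), float(b), float(c)), r2


def fit_axis_curve(
    centroids_px: np.ndarray, rotation_step_deg: float = 1.0
) -> AxisGeometry:
    """Fit a rotated parabola to cell centroids.

    Scans rotations on [0, 180) at ``rotation_step_deg``, fits
    ``y = a(x-b)^2 + c`` at each, keeps the rotation with maximal R^2,
    and de-rotates the peak (b, c) to original coordinates as the
    inflection point.
    """
    xy = np.asarray(centroids_px, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 20:
        raise ValueError("need >= 20 centroids as an (n, 2) array")
    best = (None, -np.inf, None)
    for deg in np.arange(0.0, 180.0, rotation_step_deg):
        params, r2 = _parabola_fit(_rotate(xy, deg))
        if r2 > best[1]:
            best = (deg, r2, params)
    deg, r2, params = best
    if params is None or not np.isfinite(r2):
        raise ValueError("degenerate centroid configuration: no parabola fit")
    a, b, c = params
    inflection = _rotate(np.array([[b, c]]), -deg)[0]
    return AxisGeometry(
        rotation_deg=float(deg),
        parabola=(a, b, c),
        inflection_xy_px=inflection,
        fit_r2=float(r2),
    )


def _arc_length(a: float, b: float, x0: float, x1: float) -> float:
    """Arc length of y = a(x-b)^2 + c between x0 and x1 (sign of x1-x0)."""
    f = lambda x: np.sqrt(1.0 + (2.0 * a * (x - b)) ** 2)
    val, _ = integrate.quad(f, x0, x1)
    return val


def cell_axis_distance(
    geometry: AxisGeometry,
    centroid_px: np.ndarray,
    um_per_px: float = 1.0,
    positive_direction: int = +1,
) -> float:
    """Signed arc distance (um) from the inflection to a cell.

    The cell is projected to its nearest point on the fitted curve (in
    rotated coordinates); the distance is the arc length along the curve
    from the inflection to that point, signed by the rotated-x direction
    (``positive_direction`` flips the convention so CA1 can be positive).
    """
    a, b, c = geometry.parabola
    p = _rotate(np.atleast_2d(np.asarray(centroid_px, dtype=float)), geometry.rotation_deg)[0]

    def sqdist(x):
        y = a * (x - b) ** 2 + c
        return (x - p[0]) ** 2 + (y - p[1]) ** 2

    span = max(abs(p[0] - b) * 2.0 + 1.0, 100.0)
    xs = np.linspace(b - span, b + span, 501)
    x0 = xs[np.argmin(sqdist(xs))]
    res = optimize.minimize_scalar(
        sqdist, bracket=(x0 - span / 250, x0, x0 + span / 250)
    )
    x_near = float(res.x)
    s = _arc_length(a, b, b, x_near)
    return float(np.sign(positive_direction) * s * um_per_px)


def sliding_window_profile(
    distances_um: np.ndarray,
    si_values: np.ndarray,
    window_um: float = 200.0,
    step_um: float = 50.0,
    n_boot: int = 1000,
    n_shuffle: int = 1000,
    range_um: float = 600.0,
    seed: int | np.random.Generator = 0,
) -> AxisProfile:
    """Sliding-window mean SI along the axis with bootstrap and shuffle.

    Windows of width ``window_um`` step by ``step_um`` across
    [-range, +range]. Per window: mean SI of cells inside, bootstrap
    s.e.m. (cells resampled with replacement), and a control built by
    permuting SI across cells while keeping positions; windows whose real
    mean falls outside the shuffle 2.5–97.5 percentile band are flagged.
    """
    d = np.asarray(distances_um, dtype=float)
    si = np.asarray(si_values, dtype=float)
    inside = np.abs(d) <= range_um
    d, si = d[inside], si[inside]
    if d.size < 50:
        raise ValueError("need >= 50 cells within the distance range")
    rng = np.random.default_rng(seed)
    centers = np.arange(-range_um, range_um + 1e-9, step_um)
    half = window_um / 2.0
    n_w = centers.size
    means = np.full(n_w, np.nan)
    sems = np.full(n_w, np.nan)
    band = np.full((2, n_w), np.nan)
    shuf_mean = np.full(n_w, np.nan)
    masks = [np.abs(d - cc) <= half for cc in centers]
    # shuffle control: permute SI over cells, recompute all window means
    shuf_stats = np.full((n_shuffle, n_w), np.nan)
    for s_i in range(n_shuffle):
        perm = rng.permutation(si)
        for w, m in enumerate(masks):
            if m.any():
                shuf_stats[s_i, w] = perm[m].mean()
    for w, m in enumerate(masks):
        vals = si[m]
        if vals.size == 0:
            continue
        means[w] = vals.mean()
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        sems[w] = vals[idx].mean(axis=1).std(ddof=1)
        band[0, w], band[1, w] = np.nanpercentile(shuf_stats[:, w], [2.5, 97.5])
        shuf_mean[w] = np.nanmean(shuf_stats[:, w])
    flagged = (means < band[0]) | (means > band[1])
    return AxisProfile(
        window_centers_um=centers,
        window_means=means,
        boot_sem=sems,
        shuffle_band=band,
        shuffle_mean=shuf_mean,
        flagged=flagged,
    )


def flat_f_test(
    distances_um: np.ndarray,
    si_values: np.ndarray,
    n_bins: int = 5,
    range_um: float = 600.0,
) -> tuple[float, int, int, float]:
    """General linear F-test of a binned-means model against a flat model.

    Cells within [-range, +range] are split into ``n_bins`` equal-width
    distance bins; the full model fits one mean per bin, the reduced model
    the grand mean. F = ((RSS_r - RSS_f)/(k-1)) / (RSS_f/(N-k)) with
    df = (k-1, N-k). Returns (F, df1, df2, p).
    """
    d = np.asarray(distances_um, dtype=float)
    si = np.asarray(si_values, dtype=float)
    inside = np.abs(d) <= range_um
    d, si = d[inside], si[inside]
    edges = np.linspace(-range_um, range_um, n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("empty distance bin; adjust n_bins or range")
    grand = si.mean()
    rss_r = float(((si - grand) ** 2).sum())
    bin_means = np.bincount(which, weights=si, minlength=n_bins) / counts
    rss_f = float(((si - bin_means[which]) ** 2).sum())
    df1 = n_bins - 1
    df2 = si.size - n_bins
    tol = 1e-10 * si.size * max(1.0, float(np.mean(si**2)))
    if rss_f <= tol:
        if rss_r <= tol:
            # perfectly flat data: the binned model adds nothing
            return 0.0, df1, df2, 1.0
        # binned means fit exactly while the flat model does not
        return float("inf"), df1, df2, 0.0
    # the binned model nests the flat one, so RSS_r >= RSS_f up to
    # floating error; clamp at zero
    f = max(0.0, ((rss_r - rss_f) / df1) / (rss_f / df2))
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p
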