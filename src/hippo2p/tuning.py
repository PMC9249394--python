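"""Place-cell and speed-cell classification on the 72-bin circular track.

A cell is a place cell (PC) when it passes two independent gates:

* **consistency** — 500 random half-splits of the kept laps give split-half
  tuning-curve correlations that separate from a null built by circularly
  permuting each lap's curve (two-sample KS test at alpha = 0.01 AND
  Cohen's D > 0.5);
* **Gaussian field** — the mean tuning curve is well fit by
  ``R = A0 + A*exp(-((x-B)/C)^2)`` with adjusted R^2 > 0.375,
  2.5 cm < FWHM < 30.6 cm (half the track), A > 0 and A/A0 > 0.5,
  where FWHM = 2*C*sqrt(ln 2).

Speed cells (SCs) are cells whose Pearson correlation between dF/F and
running speed falls outside the 1st–99th percentile band of a circular-
shift null (100 shifts of more than 10 frames).

Spatial information is the occupancy-weighted information rate per
inferred spike: SI = (1/a) * sum_k p(k) a(k) log2(a(k)/a).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .behavior import TrackGeometry

__all__ = [
    "TuningResult",
    "spatial_tuning_curves",
    "consistency_test",
    "fit_gaussian_field",
    "classify_place_cell",
    "speed_score",
    "spatial_information",
    "classify_cell",
    "lap_time_shuffle",
]


def lap_time_shuffle(
    activity: np.ndarray,
    lap_id: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Circularly shift each lap's activity in time by a random offset.

    The false-positive control for the PC classifier: within-lap temporal
    structure is destroyed while each lap's activity content (and the
    behavior) is preserved.
    """
    act = np.asarray(activity, dtype=float).copy()
    lap = np.asarray(lap_id)
    rng = np.random.default_rng(seed)
    for k in np.unique(lap[lap >= 0]):
        sel = np.flatnonzero(lap == k)
        if sel.size > 1:
            act[sel] = np.roll(act[sel], int(rng.integers(1, sel.size)))
    return act


@dataclass
class TuningResult:
    """Everything the classifier computes for one cell."""

    per_lap_curves: np.ndarray  # (n_laps, n_bins), NaN where unoccupied
    mean_curve: np.ndarray
    real_split_corrs: np.ndarray = field(default=None, repr=False)
    shuffle_split_corrs: np.ndarray = field(default=None, repr=False)
    ks_p: float = np.nan
    cohens_d: float = np.nan
    consistent: bool = False
    fit_params: tuple = ()  # (A0, A, B, C)
    adj_r2: float = np.nan
    fwhm_cm: float = np.nan
    criteria_pass: bool = False
    fit_flags: list = field(default_factory=list)
    place_cell: bool = False
    field_center_cm: float = np.nan
    speed_score: float = np.nan
    shuffle_scores: np.ndarray = field(default=None, repr=False)
    speed_cell: bool = False
    speed_sign: str = "none"
    si_bits_per_spike: float = np.nan


def spatial_tuning_curves(
    activity: np.ndarray,
    position_cm: np.ndarray,
    moving: np.ndarray,
    lap_id: np.ndarray,
    track: TrackGeometry,
    lap_kept: np.ndarray | None = None,
    dt_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy-normalized activity-by-position curves, one per kept lap.

    Only moving frames contribute. Per lap, activity is summed in each of
    the track's bins and divided by the occupancy time of that bin; bins
    never occupied on a lap are NaN. The mean curve averages across laps
    ignoring NaNs.
    """
    act = np.asarray(activity, dtype=float)
    pos = np.asarray(position_cm, dtype=float)
    mov = np.asarray(moving, dtype=bool)
    lap = np.asarray(lap_id)
    n_bins = track.n_bins
    lap_ids = np.unique(lap[lap >= 0])
    if lap_kept is not None:
        lap_ids = lap_ids[[bool(lap_kept[k]) for k in lap_ids]]
    bins = track.bin_index(pos)
    curves = np.full((lap_ids.size, n_bins), np.nan)
    for row, k in enumerate(lap_ids):
        sel = (lap == k) & mov
        if not sel.any():
            continue
        occ = np.bincount(bins[sel], minlength=n_bins) * dt_s
        tot = np.bincount(bins[sel], weights=act[sel], minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves[row] = np.where(occ > 0, tot / occ, np.nan)
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(curves, axis=0) if curves.size else np.full(n_bins, np.nan)
    return curves, mean_curve


def _nan_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _split_corrs(
    curves: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Correlations between mean curves of random half-splits of laps."""
    n_laps = curves.shape[0]
    half = n_laps // 2
    out = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(n_laps)
        a = np.nanmean(curves[perm[:half]], axis=0)
        b = np.nanmean(curves[perm[half:]], axis=0)
        out[i] = _nan_corr(a, b)
    return out


def consistency_test(
    per_lap_curves: np.ndarray,
    n_iter: int = 500,
    alpha: float = 0.01,
    d_min: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Split-half consistency against a per-lap circular-permutation null.

    Real distribution: ``n_iter`` random equal splits of the laps, each
    scored by the correlation of the two split-mean curves. Null: the same
    procedure, but each lap's curve is first independently circularly
    permuted by a random number of bins (1..n_bins-1), with a fresh split
    per iteration. The cell is consistent when the two distributions
    differ (two-sample KS p < alpha) with Cohen's D > d_min.
    """
    curves = np.asarray(per_lap_curves, dtype=float)
    n_laps, n_bins = curves.shape
    if n_laps < 6:
        raise ValueError(f"need >= 6 kept laps, got {n_laps}")
    rng = np.random.default_rng(seed)
    split_rng = np.random.default_rng(rng.integers(2**31))
    shuf_rng = np.random.default_rng(rng.integers(2**31))

    real = _split_corrs(curves, n_iter, split_rng)
    shuf = np.empty(n_iter)
    half = n_laps // 2
    col = np.arange(n_bins)
    for i in range(n_iter):
        shifts = shuf_rng.integers(1, n_bins, size=n_laps)
        rolled = curves[np.arange(n_laps)[:, None], (col[None, :] - shifts[:, None]) % n_bins]
        perm = shuf_rng.permutation(n_laps)
        a = np.nanmean(rolled[perm[:half]], axis=0)
        b = np.nanmean(rolled[perm[half:]], axis=0)
        shuf[i] = _nan_corr(a, b)
    real_v = real[np.isfinite(real)]
    shuf_v = shuf[np.isfinite(shuf)]
    if real_v.size < 10 or shuf_v.size < 10:
        return real, shuf, np.nan, np.nan, False
    ks_p = float(stats.ks_2samp(real_v, shuf_v).pvalue)
    pooled = np.sqrt((real_v.var(ddof=1) + shuf_v.var(ddof=1)) / 2.0)
    d = float((real_v.mean() - shuf_v.mean()) / pooled) if pooled > 0 else 0.0
    consistent = (ks_p < alpha) and (d > d_min)
    return real, shuf, ks_p, d, consistent


def fit_gaussian_field(
    mean_curve: np.ndarray,
    track: TrackGeometry,
    adj_r2_min: float = 0.375,
    fwhm_min_cm: float = 2.5,
    fwhm_max_cm: float | None = None,
    amp_ratio_min: float = 0.50,
) -> tuple[tuple, float, float, bool, list]:
    """Least-squares Gaussian fit of the mean tuning curve.

    The curve is circularly recentered on its maximum before fitting (the
    field may straddle the track origin), then fit with
    ``R = A0 + A*exp(-((x-B)/C)^2)``. Criteria: adjusted R^2 > 0.375,
    2.5 cm < FWHM < half the track length, A > 0, A/A0 > 0.50.

    Returns ``(params, adj_r2, fwhm_cm, criteria_pass, flags)`` with
    ``params = (A0, A, B, C)`` and B mapped back to track coordinates.
    """
    y_full = np.asarray(mean_curve, dtype=float)
    n_bins = track.n_bins
    circ = track.midline_circumference_cm
    if fwhm_max_cm is None:
        fwhm_max_cm = circ / 2.0
    ok = np.isfinite(y_full)
    if ok.sum() < max(10, int(0.8 * n_bins)):
        return (), np.nan, np.nan, False, ["too_few_bins"]
    peak_bin = int(np.nanargmax(y_full))
    center_bin = n_bins // 2
    shift = center_bin - peak_bin
    y = np.roll(y_full, shift)
    x = (np.arange(n_bins) + 0.5) * track.bin_length_cm
    m = np.isfinite(y)
    x_fit, y_fit = x[m], y[m]

    def gauss(x, a0, a, b, c):
        return a0 + a * np.exp(-(((x - b) / c) ** 2))

    a0_0 = float(np.nanpercentile(y_fit, 10))
    a_0 = float(np.nanmax(y_fit) - a0_0)
    p0 = [a0_0, max(a_0, 1e-6), x[center_bin], 10.0]
    flags: list[str] = []
    try:
        popt, _ = optimize.curve_fit(
            gauss,
            x_fit,
            y_fit,
            p0=p0,
            bounds=([-np.inf, -np.inf, 0.0, 1e-3], [np.inf, np.inf, circ, circ]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return (), np.nan, np.nan, False, ["fit_failed"]
    a0, a, b, c = (float(v) for v in popt)
    resid = y_fit - gauss(x_fit, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y_fit - y_fit.mean()) ** 2).sum())
    n = y_fit.size
    p = 4
    if ss_tot == 0 or n <= p + 1:
        adj_r2 = np.nan
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    fwhm = 2.0 * abs(c) * np.sqrt(np.log(2.0))
    a0_eff = a0
    if a0 <= 0:
        a0_eff = 1e-6
        flags.append("a0_clamped")
    crits = (
        np.isfinite(adj_r2)
        and adj_r2 > adj_r2_min
        and fwhm_min_cm < fwhm < fwhm_max_cm
        and a > 0
        and a / a0_eff > amp_ratio_min
    )
    b_track = float(np.mod(b - shift * track.bin_length_cm, circ))
    return (a0, a, b_track, c), float(adj_r2), float(fwhm), bool(crits), flags


def classify_place_cell(result: TuningResult, track: TrackGeometry) -> TuningResult:
    """Combine the consistency and Gaussian-fit gates into the PC label.

    The field center is the fitted Gaussian's center B (sub-bin accurate
    on a broad field, where the raw argmax jitters); the argmax bin is
    the fallback when no fit is available. Width is the fit FWHM.
    """
    result.place_cell = bool(result.consistent and result.criteria_pass)
    if result.place_cell:
        if result.fit_params:
            result.field_center_cm = float(result.fit_params[2])
        elif np.any(np.isfinite(result.mean_curve)):
            peak_bin = int(np.nanargmax(result.mean_curve))
            result.field_center_cm = (peak_bin + 0.5) * track.bin_length_cm
    return result


def speed_score(
    dff: np.ndarray,
    speed_mm_s: np.ndarray,
    n_shuffles: int = 100,
    min_shift_frames: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray, bool, str]:
    """Speed score with a circular-shift null.

    Score = Pearson r between dF/F and speed over the whole experiment.
    The null circularly shifts dF/F by amounts uniform on
    [min_shift, N - min_shift] (shifts of more than 10 frames, so the
    null cannot retain trivially high correlations). SC if the score
    exceeds the 99th or falls below the 1st percentile of the null.
    """
    y = np.asarray(dff, dtype=float)
    v = np.asarray(speed_mm_s, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("dff and speed must be equal-length 1-D")
    n = y.size
    if n <= 2 * min_shift_frames:
        raise ValueError("series too short for the shift null")
    if y.std() == 0 or v.std() == 0:
        raise ValueError("constant series: correlation undefined")
    score = float(np.corrcoef(y, v)[0, 1])
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift_frames, n - min_shift_frames, size=n_shuffles, endpoint=True)
    shuf = np.array([np.corrcoef(np.roll(y, int(s)), v)[0, 1] for s in shifts])
    hi, lo = np.percentile(shuf, [99, 1])
    if score > hi:
        return score, shuf, True, "+"
    if score < lo:
        return score, shuf, True, "-"
    return score, shuf, False, "none"


def spatial_information(
    rates: np.ndarray,
    position_cm: np.ndarray,
    moving: np.ndarray,
    track: TrackGeometry,
) -> float:
    """Spatial information in bits per inferred spike.

    SI = (1/abar) * sum_k p(k) * a(k) * log2(a(k)/abar) over the track
    bins, where p(k) is the occupancy probability of bin k during moving
    frames, a(k) the mean inferred rate in bin k, and abar the overall
    mean rate. Zero-rate bins contribute 0.
    """
    r = np.asarray(rates, dtype=float)
    mov = np.asarray(moving, dtype=bool)
    bins = track.bin_index(np.asarray(position_cm, dtype=float))
    r_m, b_m = r[mov], bins[mov]
    if r_m.size == 0 or r_m.sum() <= 0:
        raise ValueError("zero total rate during moving frames: SI undefined")
    occ = np.bincount(b_m, minlength=track.n_bins).astype(float)
    p = occ / occ.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(occ > 0, np.bincount(b_m, weights=r_m, minlength=track.n_bins) / occ, 0.0)
    abar = float((p * a).sum())
    pos = (a > 0) & (p > 0)
    si = float(np.sum(p[pos] * a[pos] * np.log2(a[pos] / abar)) / abar)
    return si


def classify_cell(
    dff: np.ndarray,
    rates: np.ndarray,
    position_cm: np.ndarray,
    speed_mm_s: np.ndarray,
    moving: np.ndarray,
    lap_id: np.ndarray,
    lap_kept: np.ndarray,
    track: TrackGeometry,
    seed: int | np.random.Generator = 0,
    n_consistency: int = 500,
    n_speed_shuffles: int = 100,
) -> TuningResult:
    """Full per-cell pipeline: tuning, consistency, fit, PC/SC labels, SI.

    Spatial tuning (and hence the PC gates and SI) uses the deconvolved
    rates: the slow transient kernel would otherwise smear dF/F several
    bins past the true field in the running direction. The speed score
    uses the dF/F trace itself.
    """
    rng = np.random.default_rng(seed)
    curves, mean_curve = spatial_tuning_curves(
        rates, position_cm, moving, lap_id, track, lap_kept=lap_kept
    )
    res = TuningResult(per_lap_curves=curves, mean_curve=mean_curve)
    if curves.shape[0] >= 6:
        (
            res.real_split_corrs,
            res.shuffle_split_corrs,
            res.ks_p,
            res.cohens_d,
            res.consistent,
        ) = consistency_test(curves, n_iter=n_consistency, seed=rng.integers(2**31))
    fit = fit_gaussian_field(mean_curve, track)
    res.fit_params, res.adj_r2, res.fwhm_cm, res.criteria_pass, res.fit_flags = fit
    classify_place_cell(res, track)
    try:
        res.speed_score, res.shuffle_scores, res.speed_cell, res.speed_sign = speed_score(
            dff, speed_mm_s, n_shuffles=n_speed_shuffles, seed=rng.integers(2**31)
        )
    except ValueError:
        pass
    try:
        res.si_bits_per_spike = spatial_information(rates, position_cm, moving, track)
    except ValueError:
        pass
    return res
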