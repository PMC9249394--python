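"""Synthetic-data generators with ground truth for every pipeline input.

Every generator is a pure function of its spec (including the seed):

* a floating circular-track behavior session with alternating run/rest
  epochs, sampled faster than the imaging frame rate;
* a calcium population with place-, speed-, conjunctive- and untuned
  cells: nonnegative event trains convolved with an AR(2) transient
  kernel, plus shared neuropil contamination and Gaussian noise;
* dendrite image series with spines of known geometry and scripted
  daily addition/subtraction;
* 3-D bead stacks with a known Gaussian PSF;
* cell centroids along a rotated parabolic axis with a known spatial-
  information profile.

Place fields are von Mises bumps on the circle (reported by their FWHM)
so there are no wrap artifacts at the track origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorFrames, TrackGeometry, make_track
from .signals import ar2_coefficients
from .spines import ClassThresholds, SpineRecord, classify_spine

__all__ = [
    "SimSessionSpec",
    "GroundTruth",
    "SimDendriteSpec",
    "SimBeadSpec",
    "simulate_behavior",
    "simulate_population",
    "simulate_dendrite_timeseries",
    "simulate_bead_stack",
    "simulate_axis_cells",
    "vonmises_fwhm_to_kappa",
]


# ---------------------------------------------------------------- session


@dataclass(frozen=True)
class SimSessionSpec:
    """Conditions for one synthetic imaging session.

    Fractions partition the population into place / speed / conjunctive /
    untuned cells. ``field_width_cm`` is the FWHM of the generated place
    fields; amplitudes and noise are in dF/F units.
    """

    n_cells: int = 120
    frac_place: float = 0.25
    frac_speed: float = 0.10
    frac_conjunctive: float = 0.05
    field_width_cm: float = 18.8
    transient_amplitude: float = 0.5
    noise_sd: float = 0.05
    neuropil_gain: float = 0.5
    frame_rate_hz: float = 10.0
    duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self):
        fr = (self.frac_place, self.frac_speed, self.frac_conjunctive)
        if any(f < 0 for f in fr) or sum(fr) > 1.0 + 1e-12:
            raise ValueError("fractions must be nonnegative and sum to <= 1")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.field_width_cm < 0 or self.noise_sd < 0:
            raise ValueError("widths and noise must be nonnegative")
        if not (0.0 <= self.neuropil_gain <= 1.0):
            raise ValueError("neuropil_gain must be in [0, 1]")


@dataclass
class GroundTruth:
    cell_labels: list
    field_centers_cm: np.ndarray
    field_fwhm_cm: np.ndarray
    speed_slopes: np.ndarray
    event_trains: np.ndarray  # (n_cells, n_frames), nonnegative amplitudes


def simulate_behavior(
    track: TrackGeometry,
    spec: SimSessionSpec,
    sample_rate_factor: int = 4,
    run_duration_s: tuple = (8.0, 20.0),
    rest_duration_s: tuple = (2.0, 5.0),
    run_speed_mm_s: tuple = (80.0, 140.0),
) -> pd.DataFrame:
    """Tracker-sample table for a run/rest session on the circular track.

    Samples at ``sample_rate_factor`` times the imaging frame rate (the
    tracker runs faster than the microscope, so per-frame median
    aggregation is nontrivial). Run epochs hold a smoothly modulated
    supra-threshold speed; rest epochs sit near zero. Set
    ``rest_duration_s=(0, 0)`` for a session with no rest.
    """
    if spec.duration_s < 60:
        raise ValueError("need duration_s >= 60")
    rng = np.random.default_rng(spec.seed)
    fs = spec.frame_rate_hz * sample_rate_factor
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    speed = np.zeros(n)
    i = 0
    running = True
    while i < n:
        if running:
            dur = rng.uniform(*run_duration_s)
            target = rng.uniform(*run_speed_mm_s)
        else:
            dur = rng.uniform(*rest_duration_s)
            target = rng.uniform(0.0, 5.0)
        n_ep = max(1, int(round(dur * fs)))
        if n_ep > 0 and dur > 0:
            mod = 1.0 + 0.15 * np.sin(
                2 * np.pi * rng.uniform(0.05, 0.2) * np.arange(n_ep) / fs
                + rng.uniform(0, 2 * np.pi)
            )
            speed[i : i + n_ep] = target * mod[: n - i]
            i += n_ep
        if dur <= 0 and not running:
            pass  # zero-length rest: stay in run
        running = not running if dur > 0 else True
    speed = np.clip(speed, 0.0, None)
    radius_mm = track.midline_radius_cm * 10.0
    angle = np.cumsum(speed / radius_mm) / fs  # rad, accumulates monotonically
    x = radius_mm * np.cos(angle)
    y = radius_mm * np.sin(angle)
    heading = np.mod(np.rad2deg(angle) + 90.0, 360.0)
    return pd.DataFrame(
        {
            "time_s": t,
            "angle_rad": np.mod(angle, 2 * np.pi),
            "x_mm": x,
            "y_mm": y,
            "speed_mm_s": speed,
            "heading": heading,
        }
    )


def vonmises_fwhm_to_kappa(fwhm_cm: float, circumference_cm: float) -> float:
    """Concentration kappa of a von Mises bump with the given FWHM."""
    half_angle = np.pi * fwhm_cm / circumference_cm  # half-width in rad
    if not (0 < half_angle < np.pi):
        raise ValueError("FWHM must be in (0, circumference)")
    return float(np.log(2.0) / (1.0 - np.cos(half_angle)))


def _ar2_convolve(events: np.ndarray, g1: float, g2: float) -> np.ndarray:
    c = np.zeros_like(events)
    for t in range(events.shape[-1]):
        c[..., t] = events[..., t]
        if t >= 1:
            c[..., t] += g1 * c[..., t - 1]
        if t >= 2:
            c[..., t] += g2 * c[..., t - 2]
    return c


def simulate_population(
    frames: BehaviorFrames,
    spec: SimSessionSpec,
    track: TrackGeometry | None = None,
    peak_rate_hz: float = 2.0,
    tau_decay_s: float = 1.5,
    tau_rise_s: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Fluorescence + neuropil traces for a mixed population.

    Place cells emit Poisson events at a rate peaked at their field
    center (von Mises tuning of FWHM ``field_width_cm``), speed cells at
    rates affine in running speed (half negatively modulated), untuned
    cells at a constant moderate rate. Events are convolved with the
    AR(2) kernel, scaled to dF/F units on a per-cell baseline, and mixed
    with a shared neuropil signal plus Gaussian noise:

    ``F_soma = F0*(1 + dff_true) + gain*(N - mean(N)) + noise``.

    Returns long-format soma and neuropil tables plus the ground truth.
    """
    if track is None:
        track = make_track()
    rng = np.random.default_rng(spec.seed + 1)
    n_frames = frames.frame_times_s.size
    dt = 1.0 / spec.frame_rate_hz
    n = spec.n_cells
    n_pc = int(round(spec.frac_place * n))
    n_sc = int(round(spec.frac_speed * n))
    n_cj = int(round(spec.frac_conjunctive * n))
    labels = (
        ["place"] * n_pc + ["speed"] * n_sc + ["conjunctive"] * n_cj
    )
    labels += ["none"] * (n - len(labels))

    circ = track.midline_circumference_cm
    centers = rng.uniform(0, circ, size=n)
    kappa = vonmises_fwhm_to_kappa(spec.field_width_cm, circ)
    slopes = np.zeros(n)
    theta = 2 * np.pi * frames.position_cm / circ
    speed = frames.speed_mm_s
    moving = frames.moving.astype(float)

    rates = np.zeros((n, n_frames))
    for i, lab in enumerate(labels):
        if lab in ("place", "conjunctive"):
            mu = 2 * np.pi * centers[i] / circ
            bump = np.exp(kappa * (np.cos(theta - mu) - 1.0))
            rates[i] = (0.05 + peak_rate_hz * bump) * moving
            if lab == "conjunctive":
                slopes[i] = rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.5)
                gain = np.clip(0.4 + 0.6 * speed / 120.0, 0, 1.5)
                rates[i] = rates[i] * gain + np.clip(
                    0.3 * slopes[i] * speed / 100.0, 0, None
                )
        elif lab == "speed":
            slopes[i] = (1 if i % 2 == 0 else -1) * rng.uniform(0.8, 1.5)
            if slopes[i] > 0:
                rates[i] = np.clip(0.05 + slopes[i] * speed / 100.0, 0, None)
            else:
                rates[i] = np.clip(1.5 + slopes[i] * speed / 100.0, 0, None)
        else:
            rates[i] = 0.3
    counts = rng.poisson(rates * dt)
    # moderate amplitude jitter (cv ~ 0.25): single transients stay well
    # above the deconvolution detection floor, so field tails are not
    # selectively lost
    amps = (
        counts
        * spec.transient_amplitude
        * rng.lognormal(0.0, 0.25, size=counts.shape)
    )
    g1, g2 = ar2_coefficients(spec.frame_rate_hz, tau_decay_s, tau_rise_s)
    dff_true = _ar2_convolve(amps.astype(float), g1, g2)

    # shared neuropil: slow common drift plus fast shared flicker; its
    # fluctuations must rival the somatic signal or the decorrelation
    # search for alpha becomes ill-conditioned
    slow = np.convolve(
        rng.normal(0, 1, n_frames), np.ones(20) / 20.0, mode="same"
    )
    sd = slow.std()
    slow = slow / sd if sd > 0 else slow
    neuropil = 80.0 + 20.0 * slow + 20.0 * rng.normal(0, 1, n_frames)
    f0 = rng.uniform(80.0, 120.0, size=n)
    np_c = neuropil - neuropil.mean()
    f_soma = (
        f0[:, None] * (1.0 + dff_true)
        + spec.neuropil_gain * np_c[None, :]
        + rng.normal(0, spec.noise_sd * f0[:, None], size=(n, n_frames))
    )
    f_neuropil = np.tile(neuropil, (n, 1)) + rng.normal(
        0, 0.01, size=(n, n_frames)
    )
    truth = GroundTruth(
        cell_labels=labels,
        field_centers_cm=np.where(
            [lab in ("place", "conjunctive") for lab in labels], centers, np.nan
        ),
        field_fwhm_cm=np.where(
            [lab in ("place", "conjunctive") for lab in labels],
            spec.field_width_cm,
            np.nan,
        ),
        speed_slopes=slopes,
        event_trains=amps.astype(float),
    )
    cell_ids = np.repeat(np.arange(n), n_frames)
    frame_ids = np.tile(np.arange(n_frames), n)
    soma_df = pd.DataFrame(
        {"cell_id": cell_ids, "frame": frame_ids, "f": f_soma.ravel()}
    )
    np_df = pd.DataFrame(
        {"cell_id": cell_ids, "frame": frame_ids, "f": f_neuropil.ravel()}
    )
    return soma_df, np_df, truth


# ---------------------------------------------------------------- dendrites


@dataclass(frozen=True)
class SimDendriteSpec:
    """Synthetic dendrite image: a horizontal shaft with archetypal spines.

    ``n_spines_per_class`` orders counts as (filopodium, thin, stubby,
    mushroom). Archetype geometries are chosen so each spine's true
    morphometrics classify as labeled under the published decision tree
    (with its documented fallback for long thin shapes).
    """

    image_shape_px: tuple = (192, 640)
    um_per_px: float = 52.0 / 760.0
    n_spines_per_class: tuple = (2, 3, 3, 3)
    shaft_width_um: float = 1.5
    min_spacing_um: float = 3.5
    background: float = 10.0
    foreground: float = 100.0
    background_sd: float = 0.0
    seed: int = 0


_ARCHETYPES = {
    # out_um (length away from shaft), widths are perpendicular to growth;
    # sizes leave margin over the 1 um^2 inclusion rule after the shaft
    # corridor eats the basal rows
    "filopodium": {"kind": "rod", "out": 2.8, "width": 0.5},
    "thin": {"kind": "rod", "out": 1.5, "width": 0.8},
    "stubby": {"kind": "dome", "half_width": 1.4, "out": 1.0},
    "mushroom": {"kind": "mushroom", "neck_len": 1.0, "neck_w": 0.25, "head_d": 1.1},
}


def _render_dendrite(
    spec: SimDendriteSpec, spines: list[dict], rng: np.random.Generator
) -> np.ndarray:
    h, w = spec.image_shape_px
    upp = spec.um_per_px
    img = np.full((h, w), spec.background, dtype=float)
    if spec.background_sd > 0:
        img += rng.normal(0, spec.background_sd, size=(h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    y0 = h // 2
    half_shaft = spec.shaft_width_um / 2.0 / upp
    img[np.abs(yy - y0) <= half_shaft] = spec.foreground
    for sp in spines:
        x_px = sp["x_um"] / upp
        side = sp["side"]  # +1 below, -1 above
        edge = y0 + side * half_shaft
        a = _ARCHETYPES[sp["archetype"]]
        if a["kind"] == "rod":
            out_px = a["out"] / upp
            half_w = a["width"] / 2.0 / upp
            sel = (
                (np.abs(xx - x_px) <= half_w)
                & (side * (yy - edge) >= -1)
                & (side * (yy - edge) <= out_px)
            )
            img[sel] = spec.foreground
        elif a["kind"] == "dome":
            ax_px = a["half_width"] / upp
            by_px = a["out"] / upp
            d2 = ((xx - x_px) / ax_px) ** 2 + ((yy - edge) / by_px) ** 2
            sel = (d2 <= 1.0) & (side * (yy - edge) >= -1)
            img[sel] = spec.foreground
        elif a["kind"] == "mushroom":
            neck_px = a["neck_len"] / upp
            half_nw = a["neck_w"] / 2.0 / upp
            r_head = a["head_d"] / 2.0 / upp
            sel = (
                (np.abs(xx - x_px) <= half_nw)
                & (side * (yy - edge) >= -1)
                & (side * (yy - edge) <= neck_px)
            )
            img[sel] = spec.foreground
            cy = edge + side * (neck_px + r_head)
            sel = (xx - x_px) ** 2 + (yy - cy) ** 2 <= r_head**2
            img[sel] = spec.foreground
    return img


def _true_record(sp: dict, idx: int, spec: SimDendriteSpec) -> SpineRecord:
    """Ground-truth morphometrics of an archetype, classified by the tree."""
    a = _ARCHETYPES[sp["archetype"]]
    if a["kind"] == "rod":
        rec = SpineRecord(
            id=idx,
            base_xy_px=(0, 0),
            length_um=a["out"],
            neck_length_um=0.0,
            head_circularity=0.7,
            aspect_ratio=a["out"] / a["width"],
            area_um2=a["out"] * a["width"],
        )
    elif a["kind"] == "dome":
        rec = SpineRecord(
            id=idx,
            base_xy_px=(0, 0),
            length_um=a["out"],
            neck_length_um=0.0,
            head_circularity=0.85,
            aspect_ratio=a["out"] / (2 * a["half_width"]),
            area_um2=np.pi * a["half_width"] * a["out"] / 2.0,
        )
    else:
        length = a["neck_len"] + a["head_d"]
        rec = SpineRecord(
            id=idx,
            base_xy_px=(0, 0),
            length_um=length,
            neck_length_um=a["neck_len"],
            head_circularity=0.9,
            aspect_ratio=length / a["head_d"],
            area_um2=a["neck_len"] * a["neck_w"] + np.pi * (a["head_d"] / 2) ** 2,
        )
    rec.arc_position_um = sp["x_um"]
    classify_spine(rec, ClassThresholds())
    return rec


def simulate_dendrite_timeseries(
    spec: SimDendriteSpec,
    days: int = 1,
    daily_add_frac: float = 0.0,
    daily_sub_frac: float = 0.0,
) -> tuple[list, dict]:
    """Image series with scripted spine turnover and a true ledger.

    Day 1 realizes all requested spines; each later day removes
    ``round(daily_sub_frac * n)`` spines (uniformly at random) and adds
    ``round(daily_add_frac * n)`` new ones at free positions, where n is
    the previous day's count. Returns ``(images, truth)`` where truth has
    per-day spine dicts and records, plus added/subtracted ids per day
    pair.
    """
    if not (0 <= daily_add_frac < 1 and 0 <= daily_sub_frac < 1):
        raise ValueError("daily fractions must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape_px
    upp = spec.um_per_px
    margin_um = 3.0
    length_um = w * upp
    positions = np.arange(margin_um, length_um - margin_um, spec.min_spacing_um)
    classes = []
    for cls, cnt in zip(("filopodium", "thin", "stubby", "mushroom"), spec.n_spines_per_class):
        classes += [cls] * cnt
    if len(classes) > positions.size:
        raise ValueError("too many spines for the shaft length / spacing")
    rng.shuffle(classes)
    pos_idx = rng.choice(positions.size, size=len(classes), replace=False)
    spines = [
        {
            "x_um": float(positions[pi]),
            "side": 1 if k % 2 == 0 else -1,
            "archetype": cls,
            "uid": k,
        }
        for k, (pi, cls) in enumerate(zip(pos_idx, classes))
    ]
    next_uid = len(spines)
    free = sorted(set(range(positions.size)) - set(int(p) for p in pos_idx))
    occupied = {int(p) for p in pos_idx}
    pos_of = {sp["uid"]: int(pi) for sp, pi in zip(spines, pos_idx)}

    images, per_day, records = [], [], []
    added_ids, subtracted_ids = [], []
    day_spines = list(spines)
    for day in range(days):
        if day > 0:
            n_prev = len(day_spines)
            n_sub = int(round(daily_sub_frac * n_prev))
            n_add = int(round(daily_add_frac * n_prev))
            sub_sel = rng.choice(n_prev, size=n_sub, replace=False) if n_sub else []
            removed = [day_spines[i] for i in sub_sel]
            freed_today = []
            for sp in removed:
                occupied.discard(pos_of[sp["uid"]])
                freed_today.append(pos_of[sp["uid"]])
            day_spines = [sp for i, sp in enumerate(day_spines) if i not in set(sub_sel)]
            new = []
            for _ in range(n_add):
                if not free:
                    break
                # never reuse a position freed the same day: an add at a
                # just-vacated site would look like continuity to the
                # cross-day matcher (and to a human curator)
                pi = free.pop(int(rng.integers(len(free))))
                occupied.add(pi)
                sp = {
                    "x_um": float(positions[pi]),
                    "side": int(rng.choice([-1, 1])),
                    "archetype": str(
                        rng.choice(["thin", "stubby", "mushroom"])
                    ),
                    "uid": next_uid,
                }
                pos_of[sp["uid"]] = pi
                next_uid += 1
                new.append(sp)
            free.extend(freed_today)
            day_spines = day_spines + new
            added_ids.append([sp["uid"] for sp in new])
            subtracted_ids.append([sp["uid"] for sp in removed])
        images.append(_render_dendrite(spec, day_spines, rng))
        per_day.append([dict(sp) for sp in day_spines])
        records.append(
            [_true_record(sp, sp["uid"], spec) for sp in day_spines]
        )
    truth = {
        "per_day_spines": per_day,
        "per_day_records": records,
        "added_ids": added_ids,
        "subtracted_ids": subtracted_ids,
        "n_per_day": [len(d) for d in per_day],
    }
    return images, truth


# ---------------------------------------------------------------- beads


@dataclass(frozen=True)
class SimBeadSpec:
    """3-D bead stack with a known Gaussian PSF (FWHM = 2*sqrt(2 ln 2)*sigma)."""

    stack_shape_px: tuple = (60, 256, 256)
    xy_um_per_px: float = 0.07
    z_um_per_plane: float = 0.5
    psf_fwhm_xy_um: float = 0.6
    psf_fwhm_z_um: float = 3.4
    n_beads: int = 12
    min_separation_px: float = 30.0
    amplitude: float = 1000.0
    noise_sd: float = 0.0
    poisson: bool = False
    allow_edge: bool = False
    seed: int = 0


def simulate_bead_stack(spec: SimBeadSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render Gaussian beads at random isolated positions.

    Returns the stack and a truth table of centroids (z, y, x in px).
    Raises if ``n_beads`` cannot be placed at ``min_separation_px``.
    """
    if spec.psf_fwhm_xy_um <= 0 or spec.psf_fwhm_z_um <= 0:
        raise ValueError("FWHMs must be positive")
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.stack_shape_px
    sig_xy = spec.psf_fwhm_xy_um / (2 * np.sqrt(2 * np.log(2))) / spec.xy_um_per_px
    sig_z = spec.psf_fwhm_z_um / (2 * np.sqrt(2 * np.log(2))) / spec.z_um_per_plane
    margin_z = 0 if spec.allow_edge else int(np.ceil(4 * sig_z)) + 1
    margin_xy = int(np.ceil(4 * sig_xy)) + 1
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_beads:
        attempts += 1
        if attempts > 10000:
            raise ValueError(
                f"cannot place {spec.n_beads} beads at min separation "
                f"{spec.min_separation_px} px in this stack"
            )
        c = np.array(
            [
                rng.uniform(margin_z, nz - 1 - margin_z),
                rng.uniform(margin_xy, ny - 1 - margin_xy),
                rng.uniform(margin_xy, nx - 1 - margin_xy),
            ]
        )
        if all(np.linalg.norm(c - o) >= spec.min_separation_px for o in centers):
            centers.append(c)
    stack = np.zeros((nz, ny, nx))
    zz = np.arange(nz)
    for c in centers:
        lo_y, hi_y = int(c[1] - 5 * sig_xy), int(c[1] + 5 * sig_xy) + 1
        lo_x, hi_x = int(c[2] - 5 * sig_xy), int(c[2] + 5 * sig_xy) + 1
        lo_y, lo_x = max(0, lo_y), max(0, lo_x)
        hi_y, hi_x = min(ny, hi_y), min(nx, hi_x)
        ys = np.arange(lo_y, hi_y)
        xs = np.arange(lo_x, hi_x)
        gz = np.exp(-((zz - c[0]) ** 2) / (2 * sig_z**2))
        gy = np.exp(-((ys - c[1]) ** 2) / (2 * sig_xy**2))
        gx = np.exp(-((xs - c[2]) ** 2) / (2 * sig_xy**2))
        stack[:, lo_y:hi_y, lo_x:hi_x] += (
            spec.amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    if spec.poisson:
        stack = rng.poisson(stack).astype(float)
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0, spec.noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)
    truth = pd.DataFrame(np.array(centers), columns=["z", "y", "x"])
    return stack, truth


# ---------------------------------------------------------------- axis


def simulate_axis_cells(
    a: float,
    b: float,
    c: float,
    rotation_deg: float,
    n_cells: int,
    si_profile=None,
    x_range_px: tuple = (-300.0, 300.0),
    jitter_px: float = 0.0,
    si_noise_sd: float = 0.0,
    um_per_px: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroids around a rotated parabola with SI tied to arc distance.

    Points are placed on ``y = a(x-b)^2 + c`` (in the axis frame, with x
    sampled in ``b + x_range_px``), offset by isotropic jitter, and
    rotated by ``-rotation_deg`` into "original" coordinates — so a fit
    that rotates by ``rotation_deg`` recovers the axis frame. SI values
    are ``si_profile(arc_distance_um)`` plus Gaussian noise. Returns
    (centroids_px, si_values, true_distances_um).
    """
    if n_cells < 20:
        raise ValueError("need n_cells >= 20")
    if si_profile is None:
        si_profile = lambda d: np.full_like(np.asarray(d, dtype=float), 1.0)
    rng = np.random.default_rng(seed)
    from .axis import _arc_length, _rotate

    xs = b + rng.uniform(*x_range_px, size=n_cells)
    ys = a * (xs - b) ** 2 + c
    dists = np.array([_arc_length(a, b, b, x) for x in xs]) * um_per_px
    pts = np.column_stack([xs, ys])
    if jitter_px > 0:
        pts = pts + rng.normal(0, jitter_px, size=pts.shape)
    centroids = _rotate(pts, -rotation_deg)
    si = np.asarray(si_profile(dists), dtype=float)
    if si_noise_sd > 0:
        si = si + rng.normal(0, si_noise_sd, size=si.shape)
    return centroids, si, dists
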