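"""Dendritic-spine extraction, classification, and cross-day tracking.

A dendrite z-stack is collapsed to a Gaussian-weighted composite, high-pass
filtered and binarized (Otsu, with optional manual "rescue" thresholds for
faint spines), and the shaft is skeletonized to one pixel. Spines are the
connected components left after removing a shaft corridor; each spine gets
morphometrics (length, neck length, head circularity, aspect ratio, area)
and one of four classes:

* stubby:     neck < 0.2 um and aspect ratio < 1.3
* mushroom:   neck > 0.2 um and head circularity > 0.8
* filopodium: neck > 0.2 um, length < 0.8 um, aspect ratio > 1.3
* thin:       neck > 0.2 um, length < 0.7 um, head circularity < 0.8
  (records matching no rule fall back to thin and are flagged)

Cross-day bookkeeping matches spines by arc position along the shaft and
yields per-day-pair addition/subtraction percentages, class-normalized
turnover, and the survival fraction S(t) of day-1 spines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, registration

__all__ = [
    "SpineRecord",
    "DendriteSession",
    "TurnoverLedger",
    "ClassThresholds",
    "composite_projection",
    "enhance_and_binarize",
    "extract_spines",
    "classify_spine",
    "spine_density",
    "match_spines_across_days",
    "turnover_stats",
    "survival_fraction",
    "analyze_session",
    "build_ledger",
]

SPINE_CLASSES = ("filopodium", "thin", "stubby", "mushroom")


@dataclass
class SpineRecord:
    """Morphometrics of a single extracted spine."""

    id: int
    base_xy_px: tuple
    length_um: float
    neck_length_um: float
    head_circularity: float
    aspect_ratio: float
    area_um2: float
    spine_class: str = ""
    class_fallback: bool = False
    arc_position_um: float = np.nan
    session_day: int = 0


@dataclass(frozen=True)
class ClassThresholds:
    """Published classification thresholds (config-overridable)."""

    neck_um: float = 0.2
    stubby_aspect_max: float = 1.3
    thin_length_max_um: float = 0.7
    mushroom_circularity_min: float = 0.8
    filopodium_length_max_um: float = 0.8
    filopodium_aspect_min: float = 1.3


@dataclass
class DendriteSession:
    composite_image: np.ndarray = field(repr=False)
    binary_mask: np.ndarray = field(repr=False)
    skeleton_px: np.ndarray = field(repr=False)
    um_per_px: float = 52.0 / 760.0
    spines: list = field(default_factory=list)
    session_day: int = 0

    @property
    def dendrite_length_um(self) -> float:
        return float(self.skeleton_px.sum()) * self.um_per_px


@dataclass
class TurnoverLedger:
    """Added/subtracted spine bookkeeping across a day series."""

    day_pairs: list  # [(day_a, day_b), ...]
    added: list  # list of lists of SpineRecord (in day_b)
    subtracted: list  # list of lists of SpineRecord (in day_a)
    n_per_day: list  # total spine count per day
    days: list


def composite_projection(
    z_stack: np.ndarray, center_plane: int | None = None, sigma_planes: float = 1.5
) -> np.ndarray:
    """Gaussian-weighted average of registered z-planes.

    Each plane is translation-registered to the center plane (phase
    correlation with sub-pixel upsampling), then averaged with Gaussian
    weights over plane index, normalized to sum to one.
    """
    s = np.asarray(z_stack, dtype=float)
    if s.ndim == 2:
        return s.copy()
    if s.ndim != 3 or s.shape[0] == 0:
        raise ValueError("z_stack must have >= 1 plane")
    n = s.shape[0]
    if center_plane is None:
        center_plane = n // 2
    ref = s[center_plane]
    w = np.exp(-((np.arange(n) - center_plane) ** 2) / (2.0 * sigma_planes**2))
    w /= w.sum()
    # mean-subtract and Hann-window before cross-correlation: raw phase
    # normalization is unreliable on smooth, low-texture planes and edge
    # discontinuities bias the sub-pixel peak
    win = filters.window("hann", ref.shape)
    ref_w = (ref - ref.mean()) * win
    out = np.zeros_like(ref)
    for i in range(n):
        plane = s[i]
        if i != center_plane and plane.std() > 0 and ref.std() > 0:
            shift, _, _ = registration.phase_cross_correlation(
                ref_w,
                (plane - plane.mean()) * win,
                upsample_factor=20,
                normalization=None,
            )
            plane = ndimage.shift(plane, shift, order=1, mode="nearest")
        out += w[i] * plane
    return out


def enhance_and_binarize(
    composite_image: np.ndarray,
    rescue_thresholds: list | None = None,
    rescue_rois: list | None = None,
    highpass_sigma_px: float = 20.0,
    min_area_um2: float = 1.0,
    um_per_px: float = 52.0 / 760.0,
) -> np.ndarray:
    """High-pass filter then Otsu-binarize a composite image.

    Background is estimated by a large-kernel Gaussian blur and
    subtracted, and Otsu's global threshold binarizes the result. Each
    entry of ``rescue_thresholds`` (a fraction of the Otsu threshold)
    unions in components above that lower threshold, restricted to the
    matching ROI slice in ``rescue_rois`` when given — the automated
    stand-in for manually rescuing faint spines. Objects smaller than
    ``min_area_um2`` are removed.
    """
    img = np.asarray(composite_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("composite image must be 2-D")
    if np.ptp(img) == 0:
        import warnings

        warnings.warn("constant image: empty mask")
        return np.zeros_like(img, dtype=bool)
    hp = img - ndimage.gaussian_filter(img, highpass_sigma_px)
    # the high-pass halo is negative; clip it so the histogram Otsu sees
    # is background-at-zero vs structure, not halo vs background
    hp = np.clip(hp, 0.0, None)
    thr = filters.threshold_otsu(hp)
    mask = hp > thr
    if rescue_thresholds:
        for i, frac in enumerate(rescue_thresholds):
            sub = hp > frac * thr
            if rescue_rois is not None and i < len(rescue_rois):
                roi_mask = np.zeros_like(mask)
                roi_mask[rescue_rois[i]] = True
                sub &= roi_mask
            mask |= sub
    min_px = max(1, int(round(min_area_um2 / um_per_px**2)))
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def _shaft_corridor(binary_mask: np.ndarray, skeleton: np.ndarray) -> np.ndarray:
    """Skeleton dilated to the shaft's median local width."""
    dist = ndimage.distance_transform_edt(binary_mask)
    on_skel = dist[skeleton.astype(bool)]
    if on_skel.size == 0:
        raise ValueError("empty skeleton")
    radius = max(1, int(round(np.median(on_skel))))
    return ndimage.binary_dilation(
        skeleton.astype(bool), structure=morphology.disk(radius)
    )


def _region_circularity(region_mask: np.ndarray) -> float:
    area = float(region_mask.sum())
    if area == 0:
        return 0.0
    perim = measure.perimeter(region_mask)
    if perim == 0:
        return 1.0
    return float(min(4.0 * np.pi * area / perim**2, 1.0))


def _skeleton_arc_positions(skeleton: np.ndarray, um_per_px: float) -> tuple:
    """Order skeleton pixels along the shaft; returns (coords, arc_um)."""
    pts = np.argwhere(skeleton.astype(bool))
    if pts.shape[0] == 0:
        raise ValueError("empty skeleton")
    # order by walking from an endpoint via nearest-neighbor chaining
    remaining = {tuple(p) for p in map(tuple, pts)}
    # endpoint: pixel with fewest neighbors
    def n_neighbors(p):
        return sum(
            (p[0] + dy, p[1] + dx) in remaining
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dy, dx) != (0, 0)
        )

    start = min(remaining, key=n_neighbors)
    order = [start]
    remaining.discard(start)
    cur = start
    while remaining:
        neigh = [
            p
            for p in remaining
            if abs(p[0] - cur[0]) <= 1 and abs(p[1] - cur[1]) <= 1
        ]
        if not neigh:
            nxt = min(remaining, key=lambda p: (p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2)
        else:
            nxt = neigh[0]
        order.append(nxt)
        remaining.discard(nxt)
        cur = nxt
    coords = np.array(order, dtype=float)
    steps = np.sqrt((np.diff(coords, axis=0) ** 2).sum(axis=1))
    arc = np.concatenate([[0.0], np.cumsum(steps)]) * um_per_px
    return coords, arc


def extract_spines(
    binary_mask: np.ndarray,
    skeleton: np.ndarray,
    um_per_px: float = 52.0 / 760.0,
    min_area_um2: float = 1.0,
    neck_mode: str = "width",
) -> list:
    """Extract laterally projecting spines as individual objects.

    The shaft corridor (skeleton dilated to the shaft's median width) is
    subtracted from the mask; remaining connected components with area
    above ``min_area_um2`` are candidate spines. Per spine:

    * base = pixels adjacent to the shaft corridor;
    * length = Euclidean distance from the base midpoint to the most
      distant spine pixel;
    * the base->tip axis is divided into three equal segments (base,
      neck, head thirds);
    * head circularity = 4*pi*A/P^2 of the distal third; aspect ratio =
      length / max width perpendicular to the axis;
    * neck length: with ``neck_mode="width"`` (default) the along-axis
      extent where the profile width is below half the head width; with
      ``neck_mode="thirds"`` the literal middle third (= length/3).
    """
    mask = np.asarray(binary_mask).astype(bool)
    skel = np.asarray(skeleton).astype(bool)
    if not skel.any():
        raise ValueError("skeleton required")
    corridor = _shaft_corridor(mask, skel)
    spine_area = mask & ~corridor
    labels = measure.label(spine_area, connectivity=2)
    corridor_grown = ndimage.binary_dilation(corridor, structure=morphology.disk(1))
    skel_coords, skel_arc = _skeleton_arc_positions(skel, um_per_px)
    records: list[SpineRecord] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * um_per_px**2
        if area_um2 <= min_area_um2:
            continue
        comp = labels == region.label
        base = comp & corridor_grown
        if not base.any():
            continue
        base_pts = np.argwhere(base)
        base_mid = base_pts.mean(axis=0)
        pts = np.argwhere(comp)
        rel = pts - base_mid
        dists = np.sqrt((rel**2).sum(axis=1))
        tip_i = int(np.argmax(dists))
        length_um = float(dists[tip_i] * um_per_px)
        axis_vec = rel[tip_i]
        norm = np.linalg.norm(axis_vec)
        if norm == 0:
            continue
        u = axis_vec / norm
        along = rel @ u  # px, in [~0, length]
        perp = rel @ np.array([-u[1], u[0]])
        along_um = along * um_per_px
        # distal third = head
        head_sel = along_um >= 2.0 * length_um / 3.0
        head_mask = np.zeros_like(comp)
        hp_pts = pts[head_sel]
        head_mask[hp_pts[:, 0], hp_pts[:, 1]] = True
        head_circ = _region_circularity(head_mask)
        # widths along the axis in ~1 px slabs
        n_slabs = max(3, int(np.ceil(along.max() - along.min())) + 1)
        slab = np.clip(
            ((along - along.min()) / max(along.max() - along.min(), 1e-9) * (n_slabs - 1)).astype(int),
            0,
            n_slabs - 1,
        )
        width_px = np.zeros(n_slabs)
        for s_i in range(n_slabs):
            sel = slab == s_i
            if sel.any():
                width_px[s_i] = perp[sel].max() - perp[sel].min() + 1.0
        # aspect uses the component's full perpendicular extent (the
        # per-slab widths underestimate it when the tip-defined axis runs
        # oblique to a wide, flat spine)
        max_width_um = float((perp.max() - perp.min() + 1.0) * um_per_px)
        aspect = length_um / max_width_um if max_width_um > 0 else np.inf
        head_width_um = float(
            width_px[int(2 * n_slabs / 3) :].max() * um_per_px
            if n_slabs >= 3
            else max_width_um
        )
        if neck_mode == "thirds":
            neck_um = length_um / 3.0
        else:
            # neck = longest contiguous run of narrow slabs proximal to the
            # head third (narrow = width below half the head width); taper
            # at the very tip or base corners is thereby not counted
            slab_len_um = (along.max() - along.min()) * um_per_px / n_slabs
            head_slab0 = int(2 * n_slabs / 3)
            narrow = (width_px[:head_slab0] * um_per_px < 0.5 * head_width_um) & (
                width_px[:head_slab0] > 0
            )
            best_run = run = 0
            for flag in narrow:
                run = run + 1 if flag else 0
                best_run = max(best_run, run)
            neck_um = float(best_run * slab_len_um)
        records.append(
            SpineRecord(
                id=len(records),
                base_xy_px=tuple(np.round(base_mid).astype(int)),
                length_um=length_um,
                neck_length_um=neck_um,
                head_circularity=head_circ,
                aspect_ratio=float(aspect),
                area_um2=float(area_um2),
                arc_position_um=float(
                    skel_arc[
                        np.argmin(
                            ((skel_coords - base_mid) ** 2).sum(axis=1)
                        )
                    ]
                ),
            )
        )
    return records


def classify_spine(
    record: SpineRecord, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Assign one of the four morphological classes.

    Decision tree in precedence order stubby -> mushroom -> filopodium ->
    thin; records matching none of the published rules fall back to thin
    with ``class_fallback = True``.
    """
    t = thresholds
    neck, length = record.neck_length_um, record.length_um
    circ, aspect = record.head_circularity, record.aspect_ratio
    record.class_fallback = False
    if neck < t.neck_um and aspect < t.stubby_aspect_max:
        cls = "stubby"
    elif neck > t.neck_um and circ > t.mushroom_circularity_min:
        cls = "mushroom"
    elif neck > t.neck_um and length < t.filopodium_length_max_um and aspect > t.filopodium_aspect_min:
        cls = "filopodium"
    elif neck > t.neck_um and length < t.thin_length_max_um and circ < t.mushroom_circularity_min:
        cls = "thin"
    else:
        cls = "thin"
        record.class_fallback = True
    record.spine_class = cls
    return cls


def spine_density(session: DendriteSession) -> dict:
    """Spines per 10 um of dendrite, total and per class.

    S_section = S_total / (D_length_px * um_per_px) * 10, with D_length_px
    the 1-px skeleton pixel count.
    """
    d_len_um = session.dendrite_length_um
    if d_len_um <= 0:
        raise ValueError("zero-length skeleton")
    out = {"total": len(session.spines) / d_len_um * 10.0}
    for cls in SPINE_CLASSES:
        out[cls] = sum(1 for s in session.spines if s.spine_class == cls) / d_len_um * 10.0
    return out


def match_spines_across_days(
    session_a: DendriteSession,
    session_b: DendriteSession,
    max_offset_um: float = 1.0,
    curation: dict | None = None,
) -> tuple[list, list, list]:
    """Greedy arc-position matching of spines between two sessions.

    Spines are matched by position along the shared shaft, closest pairs
    first, within ``max_offset_um``. Returns ``(matches, added,
    subtracted)`` where matches is a list of (spine_a, spine_b) pairs,
    added the session-b spines with no partner, subtracted the session-a
    spines with no partner. ``curation`` maps a-spine id -> b-spine id
    (or None to force an unmatch) and overrides the automatic pairing.
    """
    a_list, b_list = list(session_a.spines), list(session_b.spines)
    pairs = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    if curation:
        for aid, bid in curation.items():
            matched_a.add(aid)
            if bid is not None:
                matched_b.add(bid)
                sa = next(s for s in a_list if s.id == aid)
                sb = next(s for s in b_list if s.id == bid)
                pairs.append((sa, sb))
    cands = sorted(
        (
            (abs(sa.arc_position_um - sb.arc_position_um), sa, sb)
            for sa in a_list
            for sb in b_list
            if abs(sa.arc_position_um - sb.arc_position_um) <= max_offset_um
        ),
        key=lambda t: t[0],
    )
    for _, sa, sb in cands:
        if sa.id in matched_a or sb.id in matched_b:
            continue
        matched_a.add(sa.id)
        matched_b.add(sb.id)
        pairs.append((sa, sb))
    added = [s for s in b_list if s.id not in matched_b]
    subtracted = [s for s in a_list if s.id not in matched_a]
    return pairs, added, subtracted


def build_ledger(sessions: list, max_offset_um: float = 1.0) -> TurnoverLedger:
    """Match consecutive sessions into a turnover ledger."""
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    day_pairs, added, subtracted = [], [], []
    for a, b in zip(sessions[:-1], sessions[1:]):
        _, add, sub = match_spines_across_days(a, b, max_offset_um)
        day_pairs.append((a.session_day, b.session_day))
        added.append(add)
        subtracted.append(sub)
    return TurnoverLedger(
        day_pairs=day_pairs,
        added=added,
        subtracted=subtracted,
        n_per_day=[len(s.spines) for s in sessions],
        days=[s.session_day for s in sessions],
    )


def turnover_stats(ledger: TurnoverLedger) -> dict:
    """Percent added/subtracted per day pair, plus class-normalized shares.

    S_a/s = N_a/s(t) / N(t) * 100 with N(t) the mean total spine count of
    the day pair; per-class turnover is each class's share of the total
    cumulative turnover (added + subtracted) that day.
    """
    pct_added, pct_subtracted, per_class = [], [], []
    for i, _pair in enumerate(ledger.day_pairs):
        n_mean = (ledger.n_per_day[i] + ledger.n_per_day[i + 1]) / 2.0
        n_a, n_s = len(ledger.added[i]), len(ledger.subtracted[i])
        pct_added.append(100.0 * n_a / n_mean if n_mean > 0 else 0.0)
        pct_subtracted.append(100.0 * n_s / n_mean if n_mean > 0 else 0.0)
        total_turn = n_a + n_s
        shares = {}
        for cls in SPINE_CLASSES:
            cnt = sum(1 for s in ledger.added[i] + ledger.subtracted[i] if s.spine_class == cls)
            shares[cls] = 100.0 * cnt / total_turn if total_turn > 0 else 0.0
        per_class.append(shares)
    return {
        "pct_added": pct_added,
        "pct_subtracted": pct_subtracted,
        "per_class_share": per_class,
    }


def survival_fraction(
    sessions: list, max_offset_um: float = 1.0
) -> np.ndarray:
    """Survival curve S(t): percent of day-1 spines still present each day.

    Day-1 spines are tracked forward by arc-position matching; a spine
    lost on any day stays lost (re-appearances count as new spines), so
    the curve is monotone non-increasing. S(0) = 100.
    """
    if not sessions:
        raise ValueError("need >= 1 session")
    n0 = len(sessions[0].spines)
    if n0 == 0:
        raise ValueError("no spines on day 1")
    alive = {s.id for s in sessions[0].spines}
    arc_of = {s.id: s.arc_position_um for s in sessions[0].spines}
    curve = [100.0]
    for sess in sessions[1:]:
        b_arcs = [s.arc_position_um for s in sess.spines]
        still = set()
        used_b: set[int] = set()
        cands = sorted(
            (abs(arc_of[aid] - ba), aid, j)
            for aid in alive
            for j, ba in enumerate(b_arcs)
            if abs(arc_of[aid] - ba) <= max_offset_um
        )
        for _, aid, j in cands:
            if aid in still or j in used_b:
                continue
            still.add(aid)
            used_b.add(j)
        alive = still
        curve.append(100.0 * len(alive) / n0)
    return np.array(curve)


def analyze_session(
    z_stack: np.ndarray,
    um_per_px: float = 52.0 / 760.0,
    session_day: int = 0,
    rescue_thresholds: list | None = None,
    thresholds: ClassThresholds = ClassThresholds(),
    shaft_opening_px: int = 10,
) -> DendriteSession:
    """Full single-session spine pipeline: composite -> mask -> spines.

    ``shaft_opening_px`` is the opening radius used to strip spines off
    the mask before skeletonizing the shaft; it must exceed the half-width
    of the widest spine head but not the shaft's half-width.
    """
    composite = composite_projection(z_stack)
    mask = enhance_and_binarize(
        composite, rescue_thresholds=rescue_thresholds, um_per_px=um_per_px
    )
    # keep the largest connected component (the dendrite of interest)
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 0:
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
    # shaft = opening that survives only the thick central structure
    shaft = ndimage.binary_opening(mask, structure=morphology.disk(shaft_opening_px))
    labels_s = measure.label(shaft, connectivity=2)
    if labels_s.max() > 1:
        largest = np.argmax(np.bincount(labels_s.ravel())[1:]) + 1
        shaft = labels_s == largest
    if not shaft.any():
        shaft = mask
    skel = morphology.skeletonize(shaft)
    session = DendriteSession(
        composite_image=composite,
        binary_mask=mask,
        skeleton_px=skel,
        um_per_px=um_per_px,
        session_day=session_day,
    )
    spines = extract_spines(mask, skel, um_per_px)
    for s in spines:
        s.session_day = session_day
        classify_spine(s, thresholds)
    session.spines = spines
    return session
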