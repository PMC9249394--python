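"""Spine morphometrics, classification, density, turnover, survival."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippo2p.spines import (
    ClassThresholds,
    DendriteSession,
    SpineRecord,
    TurnoverLedger,
    analyze_session,
    build_ledger,
    classify_spine,
    composite_projection,
    enhance_and_binarize,
    match_spines_across_days,
    spine_density,
    survival_fraction,
    turnover_stats,
)
from hippo2p.synthetic import SimDendriteSpec, simulate_dendrite_timeseries


def _record(neck, length, circ, aspect, area=1.5):
    return SpineRecord(
        id=0,
        base_xy_px=(0, 0),
        length_um=length,
        neck_length_um=neck,
        head_circularity=circ,
        aspect_ratio=aspect,
        area_um2=area,
    )


class TestClassifySpine:
    @pytest.mark.parametrize(
        "neck,length,circ,aspect,expected",
        [
            (0.1, 0.5, 0.5, 1.2, "stubby"),  # short neck, compact
            (0.3, 1.5, 0.9, 2.0, "mushroom"),  # necked, round head
            (0.3, 0.75, 0.5, 1.5, "filopodium"),  # necked, short, elongated
            (0.3, 0.65, 0.5, 1.2, "thin"),  # necked, short, irregular head
        ],
    )
    def test_published_threshold_table(self, neck, length, circ, aspect, expected):
        rec = _record(neck, length, circ, aspect)
        assert classify_spine(rec) == expected
        assert not rec.class_fallback

    def test_precedence_stubby_before_others(self):
        # short neck + compact wins even with a round head
        rec = _record(0.1, 0.5, 0.95, 1.0)
        assert classify_spine(rec) == "stubby"

    def test_mushroom_before_filopodium(self):
        rec = _record(0.3, 0.75, 0.9, 1.5)  # satisfies both rule sets
        assert classify_spine(rec) == "mushroom"

    def test_unmatched_falls_back_to_thin_flagged(self):
        rec = _record(0.3, 1.5, 0.5, 1.1)  # long, irregular: no rule fires
        assert classify_spine(rec) == "thin"
        assert rec.class_fallback

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(0.0, 1.0),
        st.floats(0.1, 3.0),
        st.floats(0.01, 1.0),
        st.floats(0.1, 6.0),
    )
    def test_every_record_gets_exactly_one_class(self, neck, length, circ, aspect):
        rec = _record(neck, length, circ, aspect)
        assert classify_spine(rec) in ("stubby", "mushroom", "filopodium", "thin")

    def test_thresholds_configurable(self):
        rec = _record(0.15, 0.5, 0.5, 1.2)
        assert classify_spine(rec, ClassThresholds(neck_um=0.1)) != "stubby"


class TestDensity:
    def _session(self, n_spines, skel_px, um_per_px):
        skel = np.zeros((10, skel_px), dtype=bool)
        skel[5, :] = True
        spines = [
            _record(0.1, 0.5, 0.5, 1.0) for _ in range(n_spines)
        ]
        for i, s in enumerate(spines):
            s.id = i
            s.spine_class = "stubby"
        return DendriteSession(
            composite_image=np.zeros((10, skel_px)),
            binary_mask=np.ones((10, skel_px), dtype=bool),
            skeleton_px=skel,
            um_per_px=um_per_px,
            spines=spines,
        )

    def test_ten_spines_on_ten_microns(self):
        # 100 skeleton px at 0.1 um/px = 10 um
        sess = self._session(10, 100, 0.1)
        assert spine_density(sess)["total"] == pytest.approx(10.0)

    def test_formula_arithmetic(self):
        # 21 spines, 2000 px skeleton at 52/760 um/px -> 21/136.8*10
        sess = self._session(21, 2000, 52.0 / 760.0)
        assert spine_density(sess)["total"] == pytest.approx(
            21.0 / (2000 * 52.0 / 760.0) * 10.0, rel=1e-9
        )
        assert spine_density(sess)["total"] == pytest.approx(1.535, abs=0.001)

    def test_linearity_in_count(self):
        d1 = spine_density(self._session(7, 500, 0.1))["total"]
        d2 = spine_density(self._session(14, 500, 0.1))["total"]
        assert d2 == pytest.approx(2 * d1)

    def test_zero_length_skeleton_rejected(self):
        sess = self._session(1, 10, 0.1)
        sess.skeleton_px = np.zeros_like(sess.skeleton_px)
        with pytest.raises(ValueError):
            spine_density(sess)


def _arc_session(arcs, day=0):
    spines = []
    for i, a in enumerate(arcs):
        r = _record(0.1, 0.5, 0.5, 1.0)
        r.id = i
        r.arc_position_um = a
        r.spine_class = "stubby"
        r.session_day = day
        spines.append(r)
    skel = np.zeros((4, 100), dtype=bool)
    skel[2, :] = True
    return DendriteSession(
        composite_image=np.zeros((4, 100)),
        binary_mask=np.ones((4, 100), dtype=bool),
        skeleton_px=skel,
        um_per_px=1.0,
        spines=spines,
        session_day=day,
    )


class TestMatching:
    def test_identical_sessions_no_turnover(self):
        a = _arc_session([3.0, 10.0, 20.0])
        b = _arc_session([3.0, 10.0, 20.0], day=1)
        _, added, subtracted = match_spines_across_days(a, b)
        assert added == [] and subtracted == []

    def test_removed_spines_detected(self):
        a = _arc_session([3.0, 10.0, 20.0, 30.0, 40.0])
        b = _arc_session([10.0, 40.0], day=1)
        _, added, subtracted = match_spines_across_days(a, b)
        assert len(added) == 0 and len(subtracted) == 3
        assert sorted(s.arc_position_um for s in subtracted) == [3.0, 20.0, 30.0]

    def test_curation_overrides_automatic_match(self):
        a = _arc_session([3.0, 10.0])
        b = _arc_session([3.0, 10.0], day=1)
        _, added, subtracted = match_spines_across_days(a, b, curation={0: None})
        assert len(subtracted) == 0  # spine 0 consumed by curation
        assert len(added) == 1  # b's spine at 3.0 left unmatched


class TestTurnoverArithmetic:
    def _ledger(self, added_n, subtracted_n, n0, n1):
        def recs(n, cls="stubby"):
            out = []
            for i in range(n):
                r = _record(0.1, 0.5, 0.5, 1.0)
                r.spine_class = cls
                out.append(r)
            return out

        return TurnoverLedger(
            day_pairs=[(0, 1)],
            added=[recs(added_n)],
            subtracted=[recs(subtracted_n)],
            n_per_day=[n0, n1],
            days=[0, 1],
        )

    def test_three_added_of_mean_twenty(self):
        stats = turnover_stats(self._ledger(3, 0, 20, 20))
        assert stats["pct_added"][0] == pytest.approx(15.0)

    def test_no_turnover_zero_percent_with_guard(self):
        stats = turnover_stats(self._ledger(0, 0, 20, 20))
        assert stats["pct_added"][0] == 0.0
        assert stats["pct_subtracted"][0] == 0.0
        assert all(v == 0.0 for v in stats["per_class_share"][0].values())

    def test_survival_20_to_15_is_75pct(self):
        a = _arc_session(np.arange(20) * 3.0)
        b = _arc_session(np.arange(15) * 3.0, day=1)
        curve = survival_fraction([a, b])
        assert curve[0] == 100.0
        assert curve[1] == pytest.approx(75.0)

    def test_survival_monotone_nonincreasing(self):
        rng = np.random.default_rng(0)
        sessions = [_arc_session(np.arange(20) * 3.0)]
        arcs = list(np.arange(20) * 3.0)
        for day in range(1, 6):
            arcs = [a for a in arcs if rng.random() > 0.2]
            sessions.append(_arc_session(arcs, day=day))
        curve = survival_fraction(sessions)
        assert (np.diff(curve) <= 1e-9).all()


class TestComposite:
    def test_single_plane_identity(self):
        img = np.random.default_rng(0).random((32, 32))
        assert np.allclose(composite_projection(img[None, :, :]), img)

    def test_identical_planes_identity(self):
        img = np.random.default_rng(1).random((32, 32))
        stack = np.tile(img, (5, 1, 1))
        assert np.allclose(composite_projection(stack), img)

    def test_registration_recovers_subpixel_shift(self):
        from scipy import ndimage

        rng = np.random.default_rng(2)
        base = ndimage.gaussian_filter(rng.random((96, 96)), 3)
        shifted = ndimage.shift(base, (1.5, -0.75), order=3, mode="nearest")
        stack = np.stack([base, shifted])
        out = composite_projection(stack, center_plane=0, sigma_planes=10.0)
        # the shifted plane is re-registered onto the base: the composite
        # stays substantially closer to the base than a raw average
        err = np.abs(out - base)[10:-10, 10:-10].mean()
        raw_err = np.abs(0.5 * (base + shifted) - base)[10:-10, 10:-10].mean()
        assert err < 0.5 * raw_err


class TestBinarize:
    def test_two_level_image_separates_exactly(self):
        img = np.full((64, 64), 10.0)
        img[20:40, 20:44] = 100.0
        mask = enhance_and_binarize(img, highpass_sigma_px=30.0, um_per_px=0.1)
        assert mask[25, 30]
        assert mask[20:40, 20:44].mean() > 0.95
        assert mask[~np.zeros((64, 64), dtype=bool)].sum() == mask.sum()
        assert mask[:15].sum() == 0 and mask[45:].sum() == 0

    def test_rescue_threshold_recovers_faint_object(self):
        img = np.full((64, 128), 10.0)
        img[20:40, 10:50] = 100.0  # bright structure
        img[25:35, 80:100] = 25.0  # faint structure below Otsu
        m0 = enhance_and_binarize(img, highpass_sigma_px=30.0, um_per_px=0.1)
        assert m0[28, 90] == False  # noqa: E712
        m1 = enhance_and_binarize(
            img,
            rescue_thresholds=[0.1],
            rescue_rois=[(slice(20, 45), slice(70, 110))],
            highpass_sigma_px=30.0,
            um_per_px=0.1,
        )
        assert m1[28, 90]

    def test_constant_image_warns_empty(self):
        with pytest.warns(UserWarning):
            mask = enhance_and_binarize(np.full((32, 32), 5.0))
        assert not mask.any()


class TestPipelineVsTruth:
    def test_day1_counts_and_classes_match_truth(self, dendrite_day1):
        spec, images, truth = dendrite_day1
        sess = analyze_session(images[0], um_per_px=spec.um_per_px)
        assert len(sess.spines) == truth["n_per_day"][0]
        from collections import Counter

        true_classes = Counter(r.spine_class for r in truth["per_day_records"][0])
        rec_classes = Counter(s.spine_class for s in sess.spines)
        assert rec_classes == true_classes

    def test_generator_labels_self_consistent(self, dendrite_day1):
        """Every true record's geometry classifies as its own label."""
        _, _, truth = dendrite_day1
        for rec in truth["per_day_records"][0]:
            copy = _record(
                rec.neck_length_um,
                rec.length_um,
                rec.head_circularity,
                rec.aspect_ratio,
            )
            assert classify_spine(copy) == rec.spine_class

    def test_ledger_conservation(self):
        spec = SimDendriteSpec(seed=9, n_spines_per_class=(0, 3, 2, 3))
        images, truth = simulate_dendrite_timeseries(
            spec, days=4, daily_add_frac=0.2, daily_sub_frac=0.2
        )
        sessions = [
            analyze_session(im, um_per_px=spec.um_per_px, session_day=d)
            for d, im in enumerate(images)
        ]
        ledger = build_ledger(sessions)
        for i in range(len(ledger.day_pairs)):
            assert ledger.n_per_day[i + 1] == ledger.n_per_day[i] + len(
                ledger.added[i]
            ) - len(ledger.subtracted[i])
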