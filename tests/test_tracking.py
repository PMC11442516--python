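import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonoservo import (
    PhantomConfig,
    RedRegion,
    Template,
    TrackerNotInitializedError,
    TrackerState,
    TrackingParams,
    VesselCandidate,
    canonical_probe_pose,
    extract_red_regions,
    generate_geometry,
    match_template,
    merge_clusters,
    rank_template_candidates,
    render_doppler,
    track_frame,
    update_vessel_position,
)
from sonoservo.tracking import hsv_in_red_range


def ncc_double_loop(image, template):
    """Independent brute-force evaluation of the correlation coefficient."""
    image = np.asarray(image, dtype=float)
    template = np.asarray(template, dtype=float)
    th, tw = template.shape
    out = np.zeros((image.shape[0] - th + 1, image.shape[1] - tw + 1))
    t_energy = np.sum(template**2)
    for y in range(out.shape[0]):
        for x in range(out.shape[1]):
            patch = image[y : y + th, x : x + tw]
            denom = np.sqrt(t_energy * np.sum(patch**2))
            out[y, x] = np.sum(template * patch) / denom if denom > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# template matching
# ---------------------------------------------------------------------------
def test_self_match_peaks_at_one_at_cut_origin(rng):
    image = rng.integers(1, 255, size=(40, 50)).astype(float)
    tpl = image[12:20, 30:41]
    cmap = match_template(image, tpl)
    assert cmap.values.max() == pytest.approx(1.0, abs=1e-12)
    assert np.unravel_index(np.argmax(cmap.values), cmap.values.shape) == (12, 30)


def test_proportional_patch_also_scores_one(rng):
    tpl = rng.integers(1, 100, size=(6, 6)).astype(float)
    image = np.ones((20, 20))
    image[5:11, 7:13] = 2.0 * tpl  # scaled copy
    cmap = match_template(image, tpl)
    assert cmap.values[5, 7] == pytest.approx(1.0, abs=1e-12)


def test_matches_double_loop_oracle_on_small_integer_images(rng):
    for _ in range(60):
        h, w = rng.integers(4, 17, size=2)
        th, tw = rng.integers(2, h + 1), rng.integers(2, w + 1)
        image = rng.integers(0, 256, size=(h, w)).astype(float)
        tpl = rng.integers(1, 256, size=(th, tw)).astype(float)
        cmap = match_template(image, tpl)
        assert np.max(np.abs(cmap.values - ncc_double_loop(image, tpl))) < 1e-12


def test_correlation_bounded_by_one_on_nonnegative_images(rng):
    image = rng.random((80, 90)) * 255
    tpl = rng.random((13, 9)) * 255 + 1
    cmap = match_template(image, tpl)
    assert np.all(cmap.values <= 1.0 + 1e-9)


def test_zero_energy_placements_score_zero():
    image = np.zeros((10, 10))
    image[6:, 6:] = 5.0
    cmap = match_template(image, np.full((3, 3), 2.0))
    assert cmap.values[0, 0] == 0.0


def test_template_validation_errors():
    with pytest.raises(ValueError, match="larger than image"):
        match_template(np.ones((4, 4)), np.ones((5, 5)))
    with pytest.raises(ValueError, match="all-zero"):
        Template(pixels=np.zeros((3, 3)))


def test_rank_candidates_empty_for_zero_map():
    cmap = match_template(np.zeros((12, 12)), np.ones((3, 3)))
    assert rank_template_candidates(cmap, n=5) == []


def test_rank_candidates_single_peak_is_best_match(rng):
    image = rng.random((30, 30)) * 10
    tpl = rng.integers(1, 255, size=(5, 5)).astype(float)
    image[10:15, 20:25] = tpl
    cmap = match_template(image, tpl)
    best = rank_template_candidates(cmap, n=3)[0]
    assert best.rank == 1
    assert best.position_px == (22, 12)  # template center of the planted copy
    assert best.score == pytest.approx(1.0, abs=1e-12)


def test_rank_candidates_ties_broken_row_major():
    tpl = np.full((3, 3), 2.0)
    image = np.zeros((9, 21))
    image[1:4, 2:5] = tpl  # exact copies -> two equal maxima of 1.0
    image[1:4, 12:15] = tpl
    cmap = match_template(image, tpl)
    cands = rank_template_candidates(cmap, n=5)
    perfect = [c for c in cands if c.score > 1 - 1e-9]
    assert len(perfect) == 2
    assert perfect[0].position_px[0] < perfect[1].position_px[0]


# ---------------------------------------------------------------------------
# HSV red extraction
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "h, s, v, expected",
    [
        (5, 100, 100, True),  # red, low hue branch
        (175, 200, 200, True),  # red, wrapped hue branch
        (60, 255, 255, False),  # green
        (5, 255, 10, False),  # value below the floor
        (5, 30, 100, False),  # too desaturated
        (90, 100, 100, False),  # cyan
    ],
)
def test_hsv_red_gate_examples(h, s, v, expected):
    assert bool(hsv_in_red_range(h, s, v)) is expected


def test_extract_red_regions_finds_painted_disks():
    from skimage.color import hsv2rgb

    img = np.zeros((100, 120, 3), dtype=np.uint8)
    red = (hsv2rgb(np.array([[[5 / 180, 200 / 255, 220 / 255]]])) * 255).astype(np.uint8)[0, 0]
    yy, xx = np.mgrid[:100, :120]
    big = (xx - 40) ** 2 + (yy - 50) ** 2 <= 15**2
    small = (xx - 100) ** 2 + (yy - 20) ** 2 <= 6**2
    img[big] = red
    img[small] = red
    regions = extract_red_regions(img)
    assert len(regions) == 2
    assert regions[0].area_px > regions[1].area_px  # sorted by size
    assert regions[0].centroid_px == pytest.approx((40, 50), abs=0.1)


def test_extraction_ignores_non_red_recoloring():
    from skimage.color import hsv2rgb

    rng = np.random.default_rng(7)
    img = np.zeros((60, 60, 3), dtype=np.uint8)
    red = (hsv2rgb(np.array([[[4 / 180, 220 / 255, 200 / 255]]])) * 255).astype(np.uint8)[0, 0]
    yy, xx = np.mgrid[:60, :60]
    disk = (xx - 30) ** 2 + (yy - 30) ** 2 <= 8**2
    img[disk] = red
    ref = extract_red_regions(img)
    # recolor the outside with random non-red hues (green..blue)
    outside = ~disk
    hues = rng.uniform(60 / 180, 150 / 180, size=outside.sum())
    hsv = np.stack([hues, np.full_like(hues, 0.9), np.full_like(hues, 0.9)], axis=-1)
    img[outside] = (hsv2rgb(hsv[None]) * 255).astype(np.uint8)[0]
    recolored = extract_red_regions(img)
    assert len(recolored) == len(ref) == 1
    assert recolored[0].centroid_px == pytest.approx(ref[0].centroid_px)


def test_small_regions_filtered_as_noise():
    from skimage.color import hsv2rgb

    img = np.zeros((20, 20, 3), dtype=np.uint8)
    red = (hsv2rgb(np.array([[[5 / 180, 0.8, 0.8]]])) * 255).astype(np.uint8)[0, 0]
    img[3, 3] = red  # single-pixel speck
    assert extract_red_regions(img, min_area_px=5) == []
    assert len(extract_red_regions(img, min_area_px=1)) == 1


# ---------------------------------------------------------------------------
# cluster merging
# ---------------------------------------------------------------------------
def test_merge_two_nearby_regions_area_weighted():
    regions = [
        RedRegion(centroid_px=(100.0, 100.0), area_px=50),
        RedRegion(centroid_px=(130.0, 100.0), area_px=10),
    ]
    cands = merge_clusters(regions, T_cl=50)
    assert len(cands) == 1
    assert cands[0].position_px == pytest.approx((105.0, 100.0))  # (100*50+130*10)/60
    assert cands[0].score == 60


def test_distant_regions_stay_separate():
    regions = [
        RedRegion(centroid_px=(100.0, 100.0), area_px=50),
        RedRegion(centroid_px=(160.0, 100.0), area_px=10),  # distance 60 > 50
    ]
    cands = merge_clusters(regions, T_cl=50)
    assert len(cands) == 2
    assert cands[0].position_px == (100.0, 100.0)


def test_single_region_passes_through():
    cands = merge_clusters([RedRegion(centroid_px=(42.0, 7.0), area_px=33)], T_cl=50)
    assert len(cands) == 1
    assert cands[0].position_px == (42.0, 7.0)
    assert cands[0].score == 33


def test_merge_empty_input():
    assert merge_clusters([], T_cl=50) == []


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 300, allow_nan=False),
            st.floats(0, 300, allow_nan=False),
            st.integers(1, 500),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_merging_conserves_area_and_stays_in_hull(raw):
    regions = [RedRegion(centroid_px=(x, y), area_px=a) for x, y, a in raw]
    cands = merge_clusters(regions, T_cl=50)
    assert sum(c.score for c in cands) == sum(r.area_px for r in regions)
    xs = [r.centroid_px[0] for r in regions]
    ys = [r.centroid_px[1] for r in regions]
    for c in cands:  # centroid in the bounding box of members (hull superset)
        assert min(xs) - 1e-9 <= c.position_px[0] <= max(xs) + 1e-9
        assert min(ys) - 1e-9 <= c.position_px[1] <= max(ys) + 1e-9


# ---------------------------------------------------------------------------
# plausibility tracker
# ---------------------------------------------------------------------------
def cand(x, y, score=1.0):
    return VesselCandidate(position_px=(x, y), score=score)


def test_nearest_candidate_within_gate_accepted():
    state = TrackerState.seeded((200, 150))
    update_vessel_position([cand(210, 150), cand(400, 300)], state, T_d=50)
    assert state.position_px == (210.0, 150.0)
    assert state.history[-1][2] is True


def test_far_candidate_retains_previous_center():
    state = TrackerState.seeded((200, 150))
    update_vessel_position([cand(260, 150)], state, T_d=50)  # distance 60
    assert state.position_px == (200.0, 150.0)
    assert state.history[-1][2] is False


def test_no_candidates_retains_previous_center():
    state = TrackerState.seeded((200, 150))
    update_vessel_position([], state, T_d=50)
    assert state.position_px == (200.0, 150.0)


def test_uninitialized_tracker_demands_operator_seed():
    with pytest.raises(TrackerNotInitializedError):
        update_vessel_position([cand(1, 1)], TrackerState(), T_d=50)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.data())
def test_accepted_steps_bounded_and_retained_steps_exact(data):
    state = TrackerState.seeded((256.0, 256.0))
    for _ in range(data.draw(st.integers(1, 8))):
        cands = [
            cand(data.draw(st.floats(0, 512)), data.draw(st.floats(0, 512)))
            for _ in range(data.draw(st.integers(0, 4)))
        ]
        prev = state.position_px
        update_vessel_position(cands, state, T_d=50)
        dist = np.hypot(state.position_px[0] - prev[0], state.position_px[1] - prev[1])
        if state.history[-1][2]:
            assert dist <= 50.0
        else:
            assert state.position_px == prev


# ---------------------------------------------------------------------------
# frame-level glue
# ---------------------------------------------------------------------------
def test_doppler_frame_tracks_rendered_disk(config, geometry, centered_pose):
    frame = render_doppler(geometry, centered_pose, 0.2, config)
    cx, cy = frame.true_center_px
    state = TrackerState.seeded((cx - 5, cy + 3))
    track_frame(frame, "doppler", state)
    assert state.history[-1][2] is True
    assert np.hypot(state.position_px[0] - cx, state.position_px[1] - cy) <= 1.0


def test_blank_frame_leaves_state_unchanged():
    blank = np.zeros((64, 64, 3), dtype=np.uint8)
    state = TrackerState.seeded((30, 30))
    track_frame(blank, "doppler", state)
    assert state.position_px == (30.0, 30.0)
    assert state.history[-1][2] is False


def test_windowed_template_search_equals_full_search(config, geometry):
    import sonoservo as ss

    cfg = dataclasses.replace(config, speckle_noise_level=0.2)
    pose = canonical_probe_pose(cfg, u_mm=20.0)
    frame0 = ss.render_bmode(geometry, pose, cfg, time_s=0.0)
    cx, cy = (int(round(v)) for v in frame0.true_center_px)
    tpl = Template(frame0.pixels[cy - 40 : cy + 41, cx - 40 : cx + 41])
    pose1 = canonical_probe_pose(cfg, u_mm=21.0, lateral_mm=1.0)
    frame1 = ss.render_bmode(geometry, pose1, cfg, time_s=0.04)
    full = TrackerState.seeded((cx, cy))
    track_frame(frame1, "template", full, template=tpl)
    windowed = TrackerState.seeded((cx, cy))
    track_frame(frame1, "template", windowed, template=tpl, search_halfwidth_px=60.0)
    assert windowed.position_px == full.position_px


def test_drifting_vessel_followed_with_fragmented_doppler(config):
    # sequence with lateral drift up to ~3 px/frame and heavy fragmentation
    cfg = dataclasses.replace(config, fragment_probability=0.5, rng_seed=11)
    geometry = generate_geometry(cfg)
    r_px = cfg.vessel_radius_mm / cfg.spacing_mm_per_px
    state = None
    errors = []
    params = TrackingParams()
    for i in range(40):
        t = i / cfg.doppler_rate_hz
        pose = canonical_probe_pose(cfg, u_mm=3.0 * t * cfg.doppler_rate_hz * 0.1 + 5.0)
        frame = render_doppler(geometry, pose, t, cfg)
        if state is None:
            state = TrackerState.seeded(frame.true_center_px)
        else:
            track_frame(frame, "doppler", state, params=params, frame_index=i)
        errors.append(
            np.hypot(
                state.position_px[0] - frame.true_center_px[0],
                state.position_px[1] - frame.true_center_px[1],
            )
        )
    assert np.mean(errors) <= 0.25 * r_px


def test_tracker_history_csv_export(tmp_path):
    import csv

    from sonoservo.tracking import write_history_csv

    state = TrackerState.seeded((100.0, 120.0))
    update_vessel_position([cand(105, 120)], state, T_d=50)
    path = tmp_path / "history.csv"
    write_history_csv(state, path, method="doppler")
    with open(path) as fh:
        rows = list(csv.reader(fh))
    assert rows[0] == ["frame", "method", "x_px", "y_px", "accepted"]
    assert len(rows) == 3
    assert rows[2][2] == "105.0"
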