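"""Behavioral model: sampling-area geometry, decision rule, crossings."""

import numpy as np
import pytest

from cuttlecamo.arena import ArenaSpec, ReflectanceField, build_arena
from cuttlecamo.camo_model import (
    CSAGeometry,
    ConfigurationError,
    Decision,
    ModelParams,
    ModelState,
    _filter_path,
    camo_decision,
    csa_mean,
    estimate_patch_size,
    make_csa_mask,
    model_overlay,
    simulate_crossing,
)
from cuttlecamo.transition_analysis import detect_transitions


def brute_force_oval_count(a, b, deadzone=None, skew=0):
    """Independent rasterization oracle: loop over the bounding box with
    half-integer row offsets (corner-centered across the tank)."""
    count = 0
    fa = int(np.floor(a))
    nh = int(np.floor(b + 0.5))
    for dxi in range(-fa, fa + 1):
        for j in range(-nh, nh):
            dy = j + 0.5
            if (dxi / a) ** 2 + (dy / b) ** 2 <= 1.0:
                if deadzone is not None:
                    da, db = deadzone
                    if ((dxi + skew) / da) ** 2 + (dy / db) ** 2 <= 1.0:
                        continue
                count += 1
    return count


class TestMask:
    def test_default_mask_has_4530_pixels(self, default_mask):
        assert default_mask.area_px == 4530

    def test_default_mask_matches_brute_force(self, default_mask):
        g = CSAGeometry()
        assert default_mask.area_px == brute_force_oval_count(
            g.semi_axis_along_px, g.semi_axis_across_px
        )

    def test_unskewed_mask_symmetric_both_axes(self):
        m = make_csa_mask(CSAGeometry(forward_skew_px=0, target_area_px=None))
        assert np.array_equal(m.mask, m.mask[::-1, :])
        assert np.array_equal(m.mask, m.mask[:, ::-1])

    def test_arbitrary_axes_match_brute_force(self):
        g = CSAGeometry(
            semi_axis_along_px=40, semi_axis_across_px=36, target_area_px=None
        )
        m = make_csa_mask(g)
        assert m.area_px == brute_force_oval_count(40, 36)

    def test_deadzone_removed(self):
        g = CSAGeometry(
            deadzone_semi_axis_along_px=10,
            deadzone_semi_axis_across_px=8,
            target_area_px=None,
        )
        m = make_csa_mask(g)
        full = make_csa_mask(CSAGeometry(target_area_px=None))
        expected = brute_force_oval_count(
            g.semi_axis_along_px, g.semi_axis_across_px, deadzone=(10, 8), skew=20
        )
        assert m.area_px == expected < full.area_px

    def test_wrong_target_area_raises(self):
        with pytest.raises(ConfigurationError):
            make_csa_mask(CSAGeometry(semi_axis_along_px=10, semi_axis_across_px=10))


class TestCsaMean:
    def test_uniform_field_gives_18(self, default_mask):
        fld = build_arena(ArenaSpec(patch_width_cm=0))
        assert csa_mean(fld, default_mask, (200, 1000)) == pytest.approx(18.0)

    def test_inside_black_band_gives_3(self, default_mask):
        fld = build_arena(ArenaSpec(patch_width_cm=60))
        # oval center at col 1000+20, band spans cols 700..1299
        assert csa_mean(fld, default_mask, (200, 980)) == pytest.approx(3.0)

    def test_straddling_edge_unskewed_gives_midpoint(self):
        m = make_csa_mask(CSAGeometry(forward_skew_px=0, target_area_px=None))
        fld = build_arena(ArenaSpec(patch_width_cm=60))
        # gray/black boundary between cols 699 and 700: center the oval on it
        vals = fld.values.copy()
        f2 = ReflectanceField(vals, fld.px_per_cm)
        left = csa_mean(f2, m, (200, 699))   # oval cols 660..738, 39 black
        right = csa_mean(f2, m, (200, 700))  # oval cols 661..739, 40 black
        # average of the two placements brackets the exact half split
        assert (left + right) / 2 == pytest.approx((18 + 3) / 2, abs=0.2)

    def test_matches_brute_force_on_random_fields(self, default_mask, rng):
        vals = rng.uniform(0, 100, (90, 240))
        fld = ReflectanceField(vals, 10.0)
        m = default_mask
        for _ in range(100):
            r = int(rng.integers(-20, 110))
            c = int(rng.integers(-60, 300))
            rows = r + m.row0 + np.arange(m.mask.shape[0])
            cols = c + m.col0 + np.arange(m.mask.shape[1])
            tot = n = 0
            for j, rr in enumerate(rows):
                for k, cc in enumerate(cols):
                    if m.mask[j, k] and 0 <= rr < 90 and 0 <= cc < 240:
                        tot += vals[rr, cc]
                        n += 1
            if n == 0:
                with pytest.raises(ValueError):
                    csa_mean(fld, m, (r, c))
            else:
                assert csa_mean(fld, m, (r, c)) == pytest.approx(
                    tot / n, rel=1e-12
                )

    def test_entirely_outside_raises(self, default_mask):
        fld = build_arena(ArenaSpec(patch_width_cm=0))
        with pytest.raises(ValueError):
            csa_mean(fld, default_mask, (200, -5000))


class TestEstimatePatchSize:
    def test_control_returns_none(self):
        assert estimate_patch_size(ArenaSpec(), 50.0) is None

    def test_patch_ahead_within_lookahead(self):
        spec = ArenaSpec(patch_width_cm=19)  # band [90.5, 109.5)
        assert estimate_patch_size(spec, 80.5, 30.0) == 19

    def test_patch_beyond_lookahead_returns_none(self):
        spec = ArenaSpec(patch_width_cm=19)
        assert estimate_patch_size(spec, 10.0, 30.0) is None

    def test_patch_behind_returns_none(self):
        spec = ArenaSpec(patch_width_cm=19)
        assert estimate_patch_size(spec, 110.0, 30.0) is None

    def test_rear_margin_keeps_patch_visible(self):
        spec = ArenaSpec(patch_width_cm=19)
        assert estimate_patch_size(spec, 110.0, 30.0, rear_margin_cm=2.0) == 19

    def test_position_outside_tank_rejected(self):
        with pytest.raises(ValueError):
            estimate_patch_size(ArenaSpec(), 250.0)


class TestDecision:
    @pytest.mark.parametrize(
        "pse,sr,csa,expected",
        [
            (3.0, 18.0, 18.0, Decision.NO_CHANGE_SMALL_PATCH),
            (19.0, 18.0, 3.0, Decision.UPDATE),
            (19.0, 18.0, 18.0, Decision.NO_CHANGE_MATCHED),
            (None, 18.0, 3.0, Decision.UPDATE),
            (None, 18.0, 18.2, Decision.NO_CHANGE_MATCHED),
            (10.2, 18.0, 3.0, Decision.UPDATE),  # tie opens the gate
        ],
    )
    def test_decision_table(self, pse, sr, csa, expected):
        state = ModelState(position_cm=50.0, sr_pct=sr)
        params = ModelParams(ceps_threshold_cm=10.2, delta_threshold_pct=0.5)
        assert camo_decision(state, params, pse, csa) == expected


def _noise_free(**kw):
    defaults = dict(
        ceps_threshold_cm=10.2,
        delta_threshold_pct=0.0,
        noise_halfrange_pct=0.0,
        baseline_noise_halfrange_pct=0.0,
        gain=1.0,
    )
    defaults.update(kw)
    return ModelParams(**defaults)


class TestSimulateCrossing:
    def test_control_noise_free_constant(self, default_mask):
        spec = ArenaSpec(patch_width_cm=0)
        fld = build_arena(spec)
        tr = simulate_crossing(fld, spec, _noise_free(), csamask=default_mask)
        assert np.all(tr.sr_pct == 18.0)

    def test_point_csa_yields_step_function(self):
        m = make_csa_mask(
            CSAGeometry(
                semi_axis_along_px=0.4, semi_axis_across_px=0.9,
                forward_skew_px=0, target_area_px=None,
            )
        )
        # corner-centered rows come in pairs: the narrowest mask is one
        # column (the point-sampling limit along the swimming axis)
        assert m.along_extent_px == 1 and m.area_px == 2
        spec = ArenaSpec(patch_width_cm=60)
        fld = build_arena(spec)
        tr = simulate_crossing(fld, spec, _noise_free(), csamask=m)
        assert set(np.unique(tr.sr_pct)) == {3.0, 18.0}
        # exactly two jumps: down at entry, up at exit
        jumps = np.flatnonzero(np.diff(tr.sr_pct) != 0)
        assert len(jumps) == 2

    def test_ramp_support_equals_oval_along_extent(self, default_mask):
        # with gain 1 the trace equals the CSA profile: the entry ramp
        # spans exactly the oval's along-axis extent
        spec = ArenaSpec(patch_width_cm=60)
        fld = build_arena(spec)
        tr = simulate_crossing(fld, spec, _noise_free(gain=1.0), csamask=default_mask)
        changing = np.flatnonzero(np.diff(tr.sr_pct) < 0)
        ramp_px = changing[-1] - changing[0] + 1  # spatial span in pixels
        assert ramp_px == default_mask.along_extent_px

    def test_matches_straight_loop_oracle(self, default_mask):
        """Independent re-simulation: direct loop over positions calling
        csa_mean and applying the update rule step by step."""
        spec = ArenaSpec(length_cm=60, width_cm=10, patch_width_cm=10,
                         patch_center_cm=30)
        fld = build_arena(spec)
        params = _noise_free(gain=0.05, ceps_threshold_cm=5.0)
        tr = simulate_crossing(fld, spec, params, csamask=default_mask)
        sr = 18.0
        expected = []
        for pos in range(fld.n_cols):
            c = csa_mean(fld, default_mask, (fld.n_rows // 2, pos))
            sr = sr + params.gain * (c - sr)
            expected.append(sr)
        assert np.allclose(tr.sr_pct, expected, atol=1e-10)

    def test_same_seed_bitwise_identical(self, default_mask, field_60, arena_60):
        params = ModelParams(rng_seed=77, gain=0.01, noise_halfrange_pct=3.0,
                             baseline_noise_halfrange_pct=0.05,
                             ceps_threshold_cm=10.2)
        a = simulate_crossing(field_60, arena_60, params, csamask=default_mask)
        b = simulate_crossing(field_60, arena_60, params, csamask=default_mask)
        assert np.array_equal(a.sr_pct, b.sr_pct)
        assert np.array_equal(a.decisions, b.decisions)

    def test_noise_free_symmetry_zero_skew(self):
        """Entry and exit slope magnitudes agree to 1e-9 for a symmetric
        (zero-skew) sampling area over a centered patch."""
        m = make_csa_mask(CSAGeometry(forward_skew_px=0, target_area_px=None))
        spec = ArenaSpec(patch_width_cm=60)
        fld = build_arena(spec)
        tr = simulate_crossing(fld, spec, _noise_free(gain=0.1), csamask=m)
        segs = detect_transitions(tr.sr_pct, tr.x_cm, eps_pct=1e-7)
        assert len(segs) == 2
        s_in = [s for s in segs if s.direction == "into_patch"][0]
        s_out = [s for s in segs if s.direction == "out_of_patch"][0]
        assert abs(abs(s_in.slope_pct_per_cm) - abs(s_out.slope_pct_per_cm)) < 1e-9

    def test_amplitude_monotone_in_width_and_zero_below_gate(self, default_mask):
        params = _noise_free(gain=0.01, ceps_threshold_cm=10.2)
        amps = {}
        for w in [3, 7, 10, 19, 29, 60]:
            spec = ArenaSpec(patch_width_cm=w)
            fld = build_arena(spec)
            tr = simulate_crossing(fld, spec, params, csamask=default_mask)
            amps[w] = tr.sr_pct.max() - tr.sr_pct.min()
        assert amps[3] == 0.0 and amps[7] == 0.0 and amps[10] == 0.0
        assert 0 < amps[19] <= amps[29] <= amps[60]

    def test_loop_and_filter_paths_agree(self, default_mask, field_60, arena_60):
        from cuttlecamo.camo_model import _csa_column_profile

        params = _noise_free(gain=0.07)
        tr = simulate_crossing(field_60, arena_60, params, csamask=default_mask)
        prof = _csa_column_profile(field_60.column_values(), default_mask)
        assert np.allclose(tr.sr_pct, _filter_path(prof, 0.07, 18.0), atol=1e-12)

    def test_reverse_direction_same_amplitude(self, default_mask, field_60, arena_60):
        params = _noise_free(gain=0.05)
        f = simulate_crossing(field_60, arena_60, params, direction="forward",
                              csamask=default_mask)
        r = simulate_crossing(field_60, arena_60, params, direction="reverse",
                              csamask=default_mask)
        assert f.sr_pct.min() == pytest.approx(r.sr_pct.min(), abs=1e-9)

    def test_recentered_axis_zero_at_boundary(self, default_mask, field_60, arena_60):
        tr = simulate_crossing(field_60, arena_60, _noise_free(), csamask=default_mask)
        left = arena_60.patch_interval_cm[0]
        i0 = np.argmin(np.abs(tr.x_cm))
        assert tr.s_cm[i0] == pytest.approx(left, abs=0.1)


class TestModelOverlay:
    def test_identity_on_uniform_grid(self, default_mask, field_60, arena_60):
        tr = simulate_crossing(field_60, arena_60, _noise_free(), csamask=default_mask)
        df = model_overlay([tr], grid_cm=tr.x_cm)
        assert np.allclose(df["trace_0"], tr.sr_pct)

    def test_midpoint_is_mean(self):
        from cuttlecamo.camo_model import ReflectanceTrace

        tr = ReflectanceTrace(
            s_cm=np.array([0.0, 1.0]),
            x_cm=np.array([0.0, 1.0]),
            sr_pct=np.array([10.0, 20.0]),
            decisions=np.zeros(2, dtype=np.int8),
        )
        df = model_overlay([tr], grid_cm=np.array([0.5]))
        assert df["trace_0"].iloc[0] == pytest.approx(15.0)

    def test_matches_interpolation_oracle(self, rng):
        from cuttlecamo.camo_model import ReflectanceTrace

        x = np.sort(rng.uniform(0, 10, 40))
        y = rng.uniform(0, 100, 40)
        tr = ReflectanceTrace(
            s_cm=x, x_cm=x, sr_pct=y, decisions=np.zeros(40, dtype=np.int8)
        )
        grid = np.linspace(x[0], x[-1], 17)
        df = model_overlay([tr], grid_cm=grid)
        for g, v in zip(grid, df["trace_0"]):
            j = np.searchsorted(x, g)
            if x[j] == g:
                expected = y[j]
            else:
                t = (g - x[j - 1]) / (x[j] - x[j - 1])
                expected = y[j - 1] * (1 - t) + y[j] * t
            assert v == pytest.approx(expected, rel=1e-10)
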