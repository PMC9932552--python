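"""Model stages: pooling, templates, matching, dynamics, decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from headingflow.flow import SceneConfig, TrialSpec, render_sequence
from headingflow.model import (
    ModelParams,
    MSTdState,
    TemplateBank,
    UndefinedEstimateError,
    _gaussian_kernel_1d,
    _gaussian_kernel_2d,
    _radial_field,
    build_templates,
    decode_heading,
    mt_pool,
    run_trial,
    smooth_activations,
    step_dynamics,
    template_match,
)


def brute_convolve_2d(field, kernel):
    """Direct double-loop convolution with zero padding (oracle)."""
    r = kernel.shape[0] // 2
    out = np.zeros_like(field)
    H, W = field.shape
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W:
                        acc += field[ii, jj] * kernel[r - di, r - dj]
            out[i, j] = acc
    return out


class TestMTPool:
    def test_uniform_field_preserved_in_interior(self):
        params = ModelParams()
        field = np.ones((64, 64, 2)) * 0.37
        pooled = mt_pool(field, params)
        r = int(params.r_mt)
        np.testing.assert_allclose(pooled[r:-r, r:-r], 0.37, rtol=1e-12)

    def test_impulse_response_is_truncated_gaussian(self):
        params = ModelParams()
        field = np.zeros((41, 41, 2))
        field[20, 20, 0] = 1.0
        pooled = mt_pool(field, params)
        kernel = _gaussian_kernel_2d(params.sigma_mt, int(params.r_mt))
        np.testing.assert_allclose(pooled[14:27, 14:27, 0], kernel, atol=1e-12)
        assert pooled[..., 1].max() == 0.0
        assert np.argmax(pooled[..., 0]) == 20 * 41 + 20

    def test_matches_brute_force_on_crops(self):
        rng = np.random.default_rng(1)
        params = ModelParams(r_mt=3, sigma_mt=2.0)
        field = np.zeros((16, 16, 2))
        idx = rng.integers(0, 16, size=(12, 2))
        field[idx[:, 0], idx[:, 1]] = rng.normal(size=(12, 2))
        pooled = mt_pool(field, params)
        kernel = _gaussian_kernel_2d(2.0, 3)
        for comp in range(2):
            expected = brute_convolve_2d(field[..., comp], kernel)
            np.testing.assert_allclose(pooled[..., comp], expected, atol=1e-9)


class TestTemplates:
    def test_one_template_per_column(self, bank):
        assert bank.n_templates == 128
        assert bank.templates.shape == (128, 128, 128, 2)

    def test_headings_span_fov_linearly(self, bank, scene):
        np.testing.assert_allclose(np.diff(bank.headings), scene.deg_per_px)
        assert bank.headings[64] + bank.headings[63] == pytest.approx(0.0)

    def test_vectors_parallel_to_foe_ray(self, bank):
        # center-ish template: vector at each pixel is parallel to the ray
        # from the FoE to the pixel (upward-positive vertical component)
        k = 64
        mid = (128 - 1) / 2.0
        t = bank.templates[k]
        for row, col in [(10, 100), (90, 20), (63, 64)]:
            vec = t[row, col]
            ray = np.array([col - k, mid - row])
            cross = vec[0] * ray[1] - vec[1] * ray[0]
            assert cross == pytest.approx(0.0, abs=1e-9)
            assert vec @ ray > 0

    def test_inverse_distance_weighting(self, bank):
        # on the midline, weight at distance 2d is half the weight at d
        k = 30
        mid_rows = (63, 64)  # midline straddles rows 63/64 (FoE row 63.5)
        w_d = np.hypot(*bank.templates[k, 63, k + 8])
        w_2d = np.hypot(*bank.templates[k, 63, k + 16])
        assert w_d / w_2d == pytest.approx(2.0, rel=0.02)

    def test_weight_capped_at_one(self, bank):
        mags = np.hypot(bank.templates[64, ..., 0], bank.templates[64, ..., 1])
        assert mags.max() <= 1.0 + 1e-12

    def test_match_argmax_at_foe_column(self, bank):
        # noise-free analytic expansion with FoE at column 64 drives the
        # bank's activation peak to template 64 (brute-force argmax oracle)
        mid = (128 - 1) / 2.0
        field = _radial_field(128, mid, 64.0, weighted=False)
        acts = template_match(field, bank)
        assert abs(int(np.argmax(acts)) - 64) <= 1

    def test_contraction_rectified_to_zero(self, bank):
        mid = (128 - 1) / 2.0
        contraction = -_radial_field(128, mid, 64.0, weighted=False)
        acts = template_match(contraction, bank)
        assert acts.min() == 0.0 and acts[50:80].max() == 0.0

    def test_zero_frame_gives_zero_activations(self, bank):
        acts = template_match(np.zeros((128, 128, 2)), bank)
        assert np.all(acts == 0.0)


class TestSmoothing:
    def test_uniform_vector_unchanged(self):
        params = ModelParams()
        out = smooth_activations(np.full(128, 3.3), params)
        np.testing.assert_allclose(out, 3.3, rtol=1e-12)

    def test_impulse_gives_gaussian_profile(self):
        params = ModelParams()
        x = np.zeros(128)
        x[64] = 1.0
        out = smooth_activations(x, params)
        kernel = _gaussian_kernel_1d(params.sigma_mst, int(params.r_mst))
        np.testing.assert_allclose(out[64 - 19 : 64 + 20], kernel, atol=1e-12)

    def test_matches_brute_force_with_edge_renormalization(self):
        rng = np.random.default_rng(3)
        params = ModelParams(r_mst=5, sigma_mst=2.5)
        x = rng.normal(size=20)
        out = smooth_activations(x, params)
        kernel = _gaussian_kernel_1d(2.5, 5)
        expected = np.empty(20)
        for i in range(20):
            num = den = 0.0
            for d in range(-5, 6):
                if 0 <= i + d < 20:
                    num += x[i + d] * kernel[5 + d]
                    den += kernel[5 + d]
            expected[i] = num / den
        np.testing.assert_allclose(out, expected, atol=1e-9)


class TestDynamics:
    def test_zero_drive_decays_monotonically_without_feedback(self):
        # passive decay only: f == 0 removes recurrent feedback
        params = ModelParams(signal_fn=lambda x: np.zeros_like(x))
        state = MSTdState(x=np.full(8, 5.0), input_trace=np.zeros(8))
        prev = state.x.sum()
        for _ in range(5):
            state = step_dynamics(state, np.zeros(8), params)
            assert state.x.sum() < prev
            prev = state.x.sum()
        np.testing.assert_allclose(state.x, state.x[0])

    def test_zero_drive_total_activation_non_increasing(self):
        # with the full recurrent dynamics, total activation cannot grow
        # once the input is removed
        params = ModelParams()
        rng = np.random.default_rng(5)
        state = MSTdState(x=rng.uniform(0, 10, 32), input_trace=rng.uniform(0, 1, 32))
        prev = state.x.sum()
        for _ in range(10):
            state = step_dynamics(state, np.zeros(32), params)
            assert state.x.sum() <= prev + 1e-9
            prev = state.x.sum()

    def test_mirror_symmetric_drive_preserves_symmetry(self):
        params = ModelParams()
        drive = np.zeros(32)
        drive[10] = drive[21] = 2.0
        state = MSTdState.zeros(32)
        for _ in range(6):
            state = step_dynamics(state, drive, params)
        np.testing.assert_allclose(state.x, state.x[::-1], rtol=1e-10)

    def test_sustained_drive_bounded_by_ceiling_and_suppresses_rest(self):
        params = ModelParams()
        drive = np.zeros(16)
        drive[4] = 50.0
        state = MSTdState(x=np.full(16, 1.0), input_trace=np.zeros(16))
        for _ in range(30):
            state = step_dynamics(state, drive, params)
        assert state.x[4] < params.b_ceiling
        assert state.x[4] > 0.9 * params.b_ceiling
        others = np.delete(state.x, 4)
        assert others.max() < 1e-3

    def test_nonfinite_drive_rejected(self):
        with pytest.raises(FloatingPointError):
            step_dynamics(MSTdState.zeros(4), np.array([1.0, np.nan, 0, 0]), ModelParams())

    @given(
        hnp.arrays(np.float64, 16, elements=st.floats(0, 100)),
        hnp.arrays(np.float64, (5, 16), elements=st.floats(0, 1e3)),
    )
    @settings(max_examples=30, deadline=None)
    def test_boundedness_for_arbitrary_drive(self, x0, drives):
        """Shunting bounds: activations stay in [0, B] for any input."""
        params = ModelParams()
        state = MSTdState(x=np.clip(x0, 0, params.b_ceiling), input_trace=np.zeros(16))
        for d in drives:
            state = step_dynamics(state, d, params)
            assert np.all(state.x >= 0.0)
            assert np.all(state.x <= params.b_ceiling)


class TestDecode:
    def _bank_stub(self, headings):
        h = np.asarray(headings, float)
        return TemplateBank(
            templates=np.zeros((len(h), 1, 1, 2)), headings=h, reference_gain=1.0
        )

    def test_all_mass_on_one_unit(self):
        bank = self._bank_stub([-6.0, 0.0, 12.0])
        state = MSTdState(x=np.array([0.0, 0.0, 3.0]), input_trace=np.zeros(3))
        assert decode_heading(state, bank).value == pytest.approx(12.0)

    def test_symmetric_mass_decodes_to_center(self):
        bank = self._bank_stub([-6.0, 6.0])
        state = MSTdState(x=np.array([0.4, 0.4]), input_trace=np.zeros(2))
        assert decode_heading(state, bank).value == pytest.approx(0.0)

    def test_weighted_average_arithmetic(self):
        # x = {0.2 at 0 deg, 0.6 at 9 deg} -> (0.2*0 + 0.6*9) / 0.8 = 6.75
        bank = self._bank_stub([0.0, 9.0])
        state = MSTdState(x=np.array([0.2, 0.6]), input_trace=np.zeros(2))
        assert decode_heading(state, bank).value == pytest.approx(6.75)

    def test_zero_activation_raises(self):
        bank = self._bank_stub([0.0, 9.0])
        with pytest.raises(UndefinedEstimateError):
            decode_heading(MSTdState.zeros(2), bank)

    @given(hnp.arrays(np.float64, 8, elements=st.floats(0.001, 10)))
    @settings(max_examples=25, deadline=None)
    def test_estimate_within_bank_range(self, x):
        bank = self._bank_stub(np.linspace(-45, 45, 8))
        est = decode_heading(MSTdState(x=x, input_trace=np.zeros(8)), bank)
        assert bank.headings.min() <= est.value <= bank.headings.max()


class TestTranslationEquivariance:
    def test_shifted_field_shifts_activation_profile(self, bank, scene):
        # shifting a flow field by k columns shifts the smoothed profile by
        # k templates (interior region), hence the decoded heading by
        # k * deg_per_px
        params = ModelParams()
        mid = (128 - 1) / 2.0
        field = _radial_field(128, mid, 54.0, weighted=False)
        # localize the pattern so the shift does not wrap content at edges
        rows, cols = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        field[np.hypot(cols - 54.0, rows - mid) > 35.0] = 0.0
        shifted = np.roll(field, 10, axis=1)  # pattern now centered at column 64
        a1 = smooth_activations(template_match(mt_pool(field, params), bank, params), params)
        a2 = smooth_activations(template_match(mt_pool(shifted, params), bank, params), params)
        interior = slice(30, 98)
        np.testing.assert_allclose(
            a2[interior], np.roll(a1, 10)[interior], rtol=0.02, atol=1e-6 * a1.max()
        )
        # the decoded heading therefore shifts by 10 * deg_per_px
        from headingflow.model import MSTdState, decode_heading

        d1 = decode_heading(MSTdState(x=a1, input_trace=a1), bank).value
        d2 = decode_heading(MSTdState(x=a2, input_trace=a2), bank).value
        assert d2 - d1 == pytest.approx(10 * scene.deg_per_px, abs=0.15)


class TestRunTrial:
    def test_straight_ahead_estimate_near_zero(self, scene, bank):
        spec = TrialSpec(
            preswitch_heading=0.0, switch_angle=0.0, n_frames=34, switch_frame=30, seed=21,
            condition_label="noswitch",
        )
        sample = render_sequence(spec, scene)
        result = run_trial(sample, ModelParams(), readout_frames=[34], bank=bank)
        assert abs(result.estimates[0].value) < 1.0

    def test_deterministic(self, scene, bank):
        spec = TrialSpec(
            preswitch_heading=-6.0, switch_angle=6.0, n_frames=12, switch_frame=10, seed=8
        )
        sample = render_sequence(spec, scene)
        r1 = run_trial(sample, ModelParams(), readout_frames=[10, 12], bank=bank)
        r2 = run_trial(sample, ModelParams(), readout_frames=[10, 12], bank=bank)
        assert [e.value for e in r1.estimates] == [e.value for e in r2.estimates]

    def test_estimate_moves_toward_postswitch_heading(self, scene, bank):
        spec = TrialSpec(
            preswitch_heading=-6.0, switch_angle=12.0, n_frames=34, switch_frame=30, seed=13
        )
        sample = render_sequence(spec, scene)
        result = run_trial(sample, ModelParams(), readout_frames=[30, 34], bank=bank)
        at30, at34 = (e.value for e in result.estimates)
        assert abs(at34 - 6.0) < abs(at30 - 6.0)

    def test_invalid_readout_rejected(self, scene, bank):
        spec = TrialSpec(
            preswitch_heading=0.0, switch_angle=0.0, n_frames=6, switch_frame=3, seed=1
        )
        sample = render_sequence(spec, scene)
        with pytest.raises(ValueError):
            run_trial(sample, ModelParams(), readout_frames=[7], bank=bank)


class TestParams:
    def test_defaults_are_reference_values(self):
        p = ModelParams()
        assert (p.r_mt, p.sigma_mt, p.r_mst, p.sigma_mst) == (6.0, 9.51, 19.0, 10.08)
        assert (p.a_decay, p.b_ceiling, p.c_avg) == (0.81, 146.0, 0.7)

    def test_short_name_round_trip(self):
        p = ModelParams.from_dict({"rMT": 4, "sigmaMT": 5.0, "A": 0.5, "B": 100, "c": 0.3})
        assert p.r_mt == 4 and p.a_decay == 0.5 and p.c_avg == 0.3
        assert ModelParams.from_dict(p.to_dict()) == p

    @pytest.mark.parametrize("kwargs", [dict(c_avg=1.5), dict(a_decay=-1), dict(dt=0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
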