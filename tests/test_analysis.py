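"""Size tuning, suppression index, DoG-area fits, weight decomposition,
sensitivities and activity maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares

from v1surround import (
    GratingStimulus,
    SizeTuningCurve,
    activity_map,
    assemble_system,
    background_state,
    fit_dog_area,
    lgn_response,
    sensitivity,
    size_tuning_all,
    solve_linear,
    suppression_index,
    weight_analysis,
)
from v1surround.analysis import (
    UndefinedSIError,
    dog_area_model,
    sensitivity_linear_analytic,
)
from v1surround.geometry import center_group
from v1surround.lgn import DEFAULT_RADIUS_GRID
from v1surround.params import POPULATIONS

RADII_SHORT = np.round(np.arange(1, 9) * 0.05, 10)


def _curve(responses, radii=None):
    responses = np.asarray(responses, dtype=float)
    radii = np.arange(1, len(responses) + 1) * 0.05 if radii is None else radii
    return SizeTuningCurve(radii=np.asarray(radii, float), responses=responses,
                           population="4E", location=(0, 0))


class TestSuppressionIndex:
    def test_constant_curve_gives_zero(self):
        assert suppression_index(_curve([2.0] * 10)) == 0.0

    def test_half_decline_gives_half(self):
        assert suppression_index(_curve([1.0, 2.0, 1.5, 1.0])) == pytest.approx(0.5)

    def test_monotone_increasing_gives_zero(self):
        assert suppression_index(_curve([0.1, 0.5, 0.9, 1.3])) == 0.0

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(UndefinedSIError):
            suppression_index(_curve([-1.0, -0.5, -2.0]))

    def test_tail_averaging_variant(self):
        c = _curve([1.0, 2.0, 1.0, 0.5])
        assert suppression_index(c, tail=2) == pytest.approx(1 - 0.75 / 2.0)

    @given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_si_always_within_unit_interval(self, values):
        assert 0.0 <= suppression_index(_curve(values)) <= 1.0


class TestDoGAreaFit:
    def test_parameter_recovery_noiseless(self):
        radii = DEFAULT_RADIUS_GRID
        truth = (0.9, 0.18, 0.5, 0.55)
        y = dog_area_model(radii, *truth)
        fit = fit_dog_area(_curve(y, radii))
        assert fit.k_e == pytest.approx(truth[0], rel=0.01)
        assert fit.sigma_e == pytest.approx(truth[1], rel=0.01)
        assert fit.k_i == pytest.approx(truth[2], rel=0.01)
        assert fit.sigma_i == pytest.approx(truth[3], rel=0.01)
        assert fit.sigma_i > fit.sigma_e

    def test_pure_excitatory_curve_recovers_zero_inhibition(self):
        radii = DEFAULT_RADIUS_GRID
        y = dog_area_model(radii, 1.2, 0.25, 0.0, 1.0)
        fit = fit_dog_area(_curve(y, radii))
        assert abs(fit.k_i * fit.sigma_i) < 1e-3 * fit.k_e * fit.sigma_e
        assert fit.k_e == pytest.approx(1.2, rel=0.01)
        assert fit.sigma_e == pytest.approx(0.25, rel=0.01)

    def test_beats_single_gaussian_on_suppressed_curve(self):
        """Nested-model check: on a curve with genuine suppression the DoG
        model must fit at least as well as the best pure-Gaussian-area model
        (found by brute-force least squares)."""
        radii = DEFAULT_RADIUS_GRID
        y = dog_area_model(radii, 1.0, 0.2, 0.6, 0.6)
        fit = fit_dog_area(_curve(y, radii))

        def single_resid(x):
            return dog_area_model(radii, x[0], x[1], 0.0, 1.0) - y

        best_single = min(
            float(np.linalg.norm(
                least_squares(single_resid, [k0, s0],
                              bounds=([1e-12, 1e-3], [np.inf, np.inf])).fun
            ))
            for k0 in (0.1, 1.0) for s0 in (0.1, 0.3, 0.6)
        )
        assert fit.residual <= best_single

    def test_too_few_radii_rejected(self):
        with pytest.raises(Exception):
            fit_dog_area(_curve([1, 2, 1.5], [0.1, 0.2, 0.3]))


class TestSizeTuning:
    def test_default_grid_has_32_radii(self):
        np.testing.assert_allclose(DEFAULT_RADIUS_GRID[0], 0.05)
        np.testing.assert_allclose(DEFAULT_RADIUS_GRID[-1], 1.6)
        assert len(DEFAULT_RADIUS_GRID) == 32
        np.testing.assert_allclose(np.diff(DEFAULT_RADIUS_GRID), 0.05)

    def test_zero_contrast_gives_identically_zero_curve(
        self, lattice_3x3, omap_3x3, default_params
    ):
        """With the LGN silenced the background-subtracted response vanishes."""
        bg = background_state(default_params, lattice_3x3, omap_3x3, tol=1e-12)
        zero = np.zeros((lattice_3x3.n_side,) * 2)
        st = solve_linear(
            assemble_system(lattice_3x3, omap_3x3, default_params, zero), tol=1e-12
        )
        cg = center_group(lattice_3x3)
        for pop in POPULATIONS:
            assert st.output(pop, cg) - bg.output(pop, cg) == pytest.approx(0.0, abs=1e-12)

    def test_curves_deterministic_and_background_subtracted(
        self, lattice_3x3, omap_3x3, default_params
    ):
        a = size_tuning_all(default_params, lattice_3x3, omap_3x3, radii=RADII_SHORT)
        b = size_tuning_all(default_params, lattice_3x3, omap_3x3, radii=RADII_SHORT)
        for pop in POPULATIONS:
            np.testing.assert_array_equal(a[pop].responses, b[pop].responses)
        # at R -> 0 the stimulus vanishes and so does the response
        assert abs(a["4E"].responses[0]) < a["4E"].responses.max()


@pytest.fixture(scope="module")
def solved(lattice_3x3, omap_3x3, default_params):
    lgn = lgn_response(lattice_3x3, GratingStimulus(radius=0.4))
    system = assemble_system(lattice_3x3, omap_3x3, default_params, lgn)
    state = solve_linear(system, tol=1e-11)
    return system, state


class TestWeightAnalysis:
    @pytest.mark.parametrize("population", POPULATIONS)
    def test_components_sum_to_output(self, solved, population):
        system, state = solved
        cg = center_group(system.lattice)
        b = weight_analysis(state, system, population, cg)
        assert b.total == pytest.approx(state.output(population, cg), abs=1e-9)

    def test_component_sign_structure(self, solved):
        system, state = solved
        b = weight_analysis(state, system, "4E")
        assert b.components["4I"] <= 0
        for src in ("LGN", "4E", "6E", "Ambient"):
            assert b.components[src] >= 0
        b6 = weight_analysis(state, system, "6E")
        assert b6.components["6I"] <= 0

    def test_local_recurrence_dominates_center_4e_input(self, solved):
        """The 4E->4E recurrent component is the largest single excitatory
        contribution to the center 4E group."""
        system, state = solved
        comps = weight_analysis(state, system, "4E").components
        assert comps["4E"] == max(
            comps[src] for src in ("LGN", "4E", "6E", "Ambient")
        )


class TestSensitivity:
    def test_analytic_matches_central_difference(self, lattice_3x3, omap_3x3, default_params):
        lgn = lgn_response(lattice_3x3, GratingStimulus(radius=0.3))
        cg = center_group(lattice_3x3)

        for name in ("weight.6E->4E", "ambient.4E", "longrange.pe.1"):
            analytic = sensitivity_linear_analytic(
                default_params, name, lattice_3x3, omap_3x3, lgn, 90.0, "4E", cg
            )

            def functional(p):
                system = assemble_system(lattice_3x3, omap_3x3, p, lgn, 90.0)
                return solve_linear(system, tol=1e-12).output("4E", cg)

            rep = sensitivity(default_params, name, functional, step=1e-4)
            assert rep.derivative == pytest.approx(analytic, rel=1e-4), name

    def test_disconnected_parameter_has_zero_derivative(
        self, lattice_3x3, omap_3x3, default_params
    ):
        """A long-range knot beyond the small lattice's diameter cannot reach
        any pair of groups."""
        lgn = lgn_response(lattice_3x3, GratingStimulus(radius=0.3))
        cg = center_group(lattice_3x3)
        # 3x3-HC lattice has diameter ~1.06 deg; the d = 1.4 knot is unused
        analytic = sensitivity_linear_analytic(
            default_params, "longrange.pe.7", lattice_3x3, omap_3x3, lgn, 90.0, "4E", cg
        )
        assert analytic == 0.0

    def test_stronger_l6_feedback_excites_center(self, lattice_3x3, omap_3x3, default_params):
        """Raising the 6E->4E weight increases the center 4E output (the
        L4-L6 loop is mutually excitatory)."""
        lgn = lgn_response(lattice_3x3, GratingStimulus(radius=0.4))
        cg = center_group(lattice_3x3)
        analytic = sensitivity_linear_analytic(
            default_params, "weight.6E->4E", lattice_3x3, omap_3x3, lgn, 90.0, "4E", cg
        )
        assert analytic > 0


class TestActivityMap:
    def test_background_against_itself_is_zero(self, lattice_3x3, omap_3x3, default_params):
        bg = background_state(default_params, lattice_3x3, omap_3x3)
        amap = activity_map(bg, bg, "L4", "E")
        np.testing.assert_array_equal(amap, 0.0)

    def test_center_pixel_equals_tuning_point(self, lattice_3x3, omap_3x3, default_params):
        R = 0.3
        curves = size_tuning_all(default_params, lattice_3x3, omap_3x3, radii=[R])
        bg = background_state(default_params, lattice_3x3, omap_3x3, tol=1e-9)
        lgn = lgn_response(lattice_3x3, GratingStimulus(radius=R))
        st = solve_linear(
            assemble_system(lattice_3x3, omap_3x3, default_params, lgn), tol=1e-9
        )
        amap = activity_map(st, bg, "L4", "E")
        cg = center_group(lattice_3x3)
        assert amap[cg] == pytest.approx(curves["4E"].responses[0], abs=1e-10)

    def test_optimally_driven_domains_respond_most(
        self, lattice_3x3, omap_3x3, default_params
    ):
        """Under a vertical grating the mean L4-E response over 90-degree
        domains exceeds the mean over 0-degree (orthogonal) domains."""
        lgn = lgn_response(lattice_3x3, GratingStimulus(theta0=90.0, radius=0.3))
        bg = background_state(default_params, lattice_3x3, omap_3x3)
        st = solve_linear(
            assemble_system(lattice_3x3, omap_3x3, default_params, lgn, 90.0)
        )
        amap = activity_map(st, bg, "L4", "E")
        assert amap[omap_3x3.theta == 90.0].mean() > amap[omap_3x3.theta == 0.0].mean()

    def test_invalid_layer_rejected(self, lattice_3x3, omap_3x3, default_params):
        bg = background_state(default_params, lattice_3x3, omap_3x3)
        with pytest.raises(ValueError):
            activity_map(bg, bg, "L5", "E")
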