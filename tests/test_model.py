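"""Piecewise model construction, evaluation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sinteroct import (
    ARCHETYPES,
    AnchorSet,
    build_model,
    curvature,
    evaluate,
    fit_best,
    fit_model,
    gradient,
    parabola_point_vertex,
    select_archetype,
)
from sinteroct.model import model_from_dict, model_to_dict

from conftest import X_MAX, build_random, dense_samples


class TestParabolaPointVertex:
    @pytest.mark.parametrize(
        "point, vertex, expected",
        [
            # pressed-ceramic under-fired graph: dip from 60 to 35 at 1.5 mm
            ((0, 60), (1.5, 35), (11.11, -33.33, 60.0)),
            # degenerate flat parabola
            ((0, 5), (1, 5), (0.0, 0.0, 5.0)),
        ],
    )
    def test_coefficients(self, point, vertex, expected):
        a, b, c = parabola_point_vertex(point, vertex)
        assert (round(a, 2), round(b, 2), round(c, 2)) == expected

    def test_rise_segment_quadratic_coefficient(self):
        a, _, _ = parabola_point_vertex((3.25, 82), (1.5, 35))
        assert round(a, 2) == 15.35

    def test_coincident_abscissae_rejected(self):
        with pytest.raises(ValueError):
            parabola_point_vertex((1.0, 10.0), (1.0, 20.0))

    @given(
        x=st.floats(-5, 5),
        xv=st.floats(-5, 5),
        rho=st.floats(0, 255),
        rv=st.floats(0, 255),
    )
    @settings(derandomize=True, max_examples=100)
    def test_interpolates_point_and_vertex(self, x, xv, rho, rv):
        """The parabola passes through its defining point, takes the
        vertex value at the vertex, and is stationary there."""
        if abs(x - xv) < 1e-3:
            return
        a, b, c = parabola_point_vertex((x, rho), (xv, rv))
        assert (a * x + b) * x + c == pytest.approx(rho, rel=1e-9, abs=1e-7)
        assert (a * xv + b) * xv + c == pytest.approx(rv, rel=1e-9, abs=1e-7)
        assert 2 * a * xv + b == pytest.approx(0.0, abs=1e-7 * max(1, abs(a)))


class TestBuildModel:
    def test_valley_intervals(self, group_models):
        m = group_models["L"]
        assert len(m.segments) == 2
        assert (m.segments[0].x_lo, m.segments[0].x_hi) == (0.0, 1.5)
        assert (m.segments[1].x_lo, m.segments[1].x_hi) == (1.5, 3.25)

    def test_flat_single_constant_segment(self):
        m = build_model("flat", AnchorSet(rho0=25))
        assert len(m.segments) == 1
        assert evaluate(m, 2.0) == 25

    def test_degenerate_linear_ramp_is_constant(self):
        m = build_model("linear_ramp", AnchorSet(rho0=40, rho_max=40))
        x = np.linspace(0, X_MAX, 7)
        assert np.allclose(m.evaluate(x), 40)

    def test_missing_anchor_named_in_error(self):
        with pytest.raises(ValueError, match="rho_min"):
            build_model("valley", AnchorSet(rho0=60, rho_max=82, x_m=1.5))

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            build_model("spline", AnchorSet(rho0=10))

    def test_discontinuous_anchors_rejected(self):
        bad = AnchorSet(
            rho0=60, x_M=1.0, rho_max=80, x_i=1.5, rho_i=30, x_m=2.5,
            rho_min=20, x_max=X_MAX,
        )
        with pytest.raises(ValueError, match="discontinuous"):
            build_model("hump_valley", bad)

    def test_degenerate_valley_collapses_to_flat(self):
        v = build_model(
            "valley", AnchorSet(rho0=50, rho_min=50, rho_max=50, x_m=1.5)
        )
        f = build_model("flat", AnchorSet(rho0=50))
        x = np.linspace(0, X_MAX, 33)
        assert np.allclose(v.evaluate(x), f.evaluate(x))

    @pytest.mark.parametrize("archetype", ARCHETYPES)
    def test_anchor_interpolation_and_vertex_property(self, archetype, dense_grid):
        """Built segments pass through their anchors and are stationary
        at every designated vertex."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            anchors, m = build_random(archetype, rng, dense_grid)
            assert evaluate(m, 0.0) == pytest.approx(anchors.rho0, rel=1e-9)
            for seg in m.segments:
                v = seg.vertex()
                if v is not None and seg.x_lo <= v <= seg.x_hi:
                    assert gradient(m, v) == pytest.approx(0.0, abs=1e-9)
            # interior continuity within half a gray level
            for left, right in zip(m.segments, m.segments[1:]):
                xb = left.x_hi
                assert abs(left.value(xb) - right.value(xb)) <= 0.5 + 1e-9


class TestEvaluateAndDerivatives:
    def test_group_l_values(self, group_models):
        m = group_models["L"]
        assert evaluate(m, 0.0) == pytest.approx(60.0)
        assert evaluate(m, 1.5) == pytest.approx(35.0)

    def test_group_l_gradient(self, group_models):
        m = group_models["L"]
        assert round(gradient(m, 0.0), 2) == -33.33
        assert gradient(m, 1.5) == pytest.approx(0.0)

    def test_group_n_first_segment_curvature(self, group_models):
        assert curvature(group_models["N"], 0.5) == pytest.approx(-19.2)

    def test_outside_domain_rejected(self, group_models):
        with pytest.raises(ValueError):
            evaluate(group_models["L"], 4.0)
        with pytest.raises(ValueError):
            gradient(group_models["L"], -0.1)


class TestFitModel:
    def test_noiseless_valley_recovery(self, group_models, dense_grid):
        # the generating vertex must be a grid point for exact recovery
        grid = np.unique(np.append(dense_grid, 1.5))
        prof = dense_samples(group_models["L"], grid)
        model, anchors, sse = fit_model(prof, "valley", x_max=X_MAX)
        assert sse < 1e-12
        assert anchors.rho0 == pytest.approx(60, abs=1e-6)
        assert anchors.rho_min == pytest.approx(35, abs=1e-6)
        assert anchors.x_m == pytest.approx(1.5, abs=1e-9)
        assert anchors.rho_max == pytest.approx(82, abs=1e-6)

    def test_constant_profile_flat_fit(self, dense_grid):
        prof = (dense_grid, np.full_like(dense_grid, 42.0))
        model, anchors, sse = fit_model(prof, "flat")
        assert sse == pytest.approx(0.0, abs=1e-18)
        assert anchors.rho0 == pytest.approx(42.0)

    def test_flat_fit_of_structured_profile_is_mean_fit(self, group_models, dense_grid):
        rho = np.asarray(group_models["L"].evaluate(dense_grid))
        _, _, sse = fit_model((dense_grid, rho), "flat")
        assert sse == pytest.approx(float(np.sum((rho - rho.mean()) ** 2)), rel=1e-12)

    def test_too_few_points_rejected(self):
        x = np.linspace(0, X_MAX, 5)
        with pytest.raises(ValueError):
            fit_model((x, np.zeros(5)), "flat")


class TestSelectArchetype:
    def test_constant_selects_flat(self, dense_grid):
        prof = (dense_grid, np.full_like(dense_grid, 30.0))
        assert select_archetype(prof) == "flat"

    def test_valley_samples_select_valley(self, group_models, dense_grid):
        grid = np.unique(np.append(dense_grid, 1.5))
        assert select_archetype(dense_samples(group_models["L"], grid)) == "valley"

    def test_ramp_samples_select_linear(self, dense_grid):
        rho = 20.0 + 3.0 * dense_grid
        assert select_archetype((dense_grid, rho)) == "linear_ramp"


def test_model_json_round_trip(group_models):
    for label, m in group_models.items():
        payload = model_to_dict(m, None)
        m2, _ = model_from_dict(payload)
        x = np.linspace(0, X_MAX, 17)
        assert np.allclose(m.evaluate(x), m2.evaluate(x))
        assert m2.archetype == m.archetype
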