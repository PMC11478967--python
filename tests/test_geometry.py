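"""Quadrangle model: symmetrization, derived traits and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikequad as sq
from spikequad.geometry import polygon_area

from conftest import random_models


def shoelace(vertices):
    """Independent shoelace oracle (plain Python loop)."""
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestSymmetrize:
    def test_parameterwise_mean(self):
        fit = sq.AsymmetricQuadrangleFit(
            x_u1=12, x_u2=20, x_u3=5, y_u1=3, y_u2=4,
            x_b1=8, x_b2=20, x_b3=5, y_b1=3, y_b2=4,
        )
        m = sq.symmetrize(fit)
        assert m.q_x1s == pytest.approx(10.0)
        assert m.q_x2s == pytest.approx(20.0)

    def test_equal_sides_pass_through(self):
        fit = sq.AsymmetricQuadrangleFit(10, 20, 5, 2, 4, 10, 20, 5, 2, 4)
        m = sq.symmetrize(fit)
        assert (m.q_x1s, m.q_x2s, m.q_x3s, m.q_y1s, m.q_y2s) == (10, 20, 5, 2, 4)

    def test_average_of_sums_equals_sum_of_averages(self):
        fit = sq.AsymmetricQuadrangleFit(10, 20, 5, 1, 1, 14, 16, 9, 1, 1)
        assert sq.symmetrize(fit).q_L == pytest.approx((35 + 39) / 2)

    def test_negative_parameter_rejected(self):
        with pytest.raises(sq.InvalidModelError):
            sq.AsymmetricQuadrangleFit(-1, 20, 5, 2, 4, 10, 20, 5, 2, 4)


class TestDeriveTraits:
    def test_length_is_sum(self):
        m = sq.SymmetricQuadrangleModel(30, 50, 10, 1, 1)
        assert sq.derive_traits(m).q_L == pytest.approx(90.0)

    def test_areas_match_shoelace_oracle(self):
        # half-spike polygon (0,0),(10,2),(30,4),(35,0)
        m = sq.SymmetricQuadrangleModel(10, 20, 5, 2, 4)
        d = sq.derive_traits(m)
        assert d.q_S1 == pytest.approx(10.0)
        assert d.q_S2 == pytest.approx(60.0)
        assert d.q_S3 == pytest.approx(10.0)
        assert d.q_S == pytest.approx(shoelace([(0, 0), (10, 2), (30, 4), (35, 0)]))
        assert d.q_ym == pytest.approx(80.0 / 35.0)

    def test_zero_height_model(self):
        d = sq.derive_traits(sq.SymmetricQuadrangleModel(10, 20, 5, 0, 0))
        assert d.q_S == 0.0 and d.q_ym == 0.0
        assert np.isnan(d.q_S1S) and np.isnan(d.q_S2S) and np.isnan(d.q_S3S)

    def test_normalized_triplets_sum_to_one(self):
        for m in random_models(50, seed=1):
            d = sq.derive_traits(m)
            assert d.q_x1ns + d.q_x2ns + d.q_x3ns == pytest.approx(1.0, rel=1e-9)
            if d.q_S > 0:
                assert d.q_S1S + d.q_S2S + d.q_S3S == pytest.approx(1.0, rel=1e-9)


class TestSpikeDensityIndex:
    @pytest.mark.parametrize(
        "ssc, sl, expected", [(21, 100, 20.0), (1, 50, 0.0), (16, 75, 20.0)]
    )
    def test_values(self, ssc, sl, expected):
        assert sq.spike_density_index(ssc, sl) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sq.spike_density_index(10, 0.0)
        with pytest.raises(ValueError):
            sq.spike_density_index(0, 50.0)


class TestModelPolyline:
    def test_construction_extremes(self):
        poly = sq.model_polyline(sq.SymmetricQuadrangleModel(10, 20, 5, 2, 4))
        assert poly.shape == (7, 2)
        assert np.allclose(poly[0], poly[-1])
        assert poly[:, 0].min() == 0 and poly[:, 0].max() == 35
        assert poly[:, 1].min() == -4 and poly[:, 1].max() == 4

    def test_degenerate_collapses_to_axis(self):
        poly = sq.model_polyline(sq.SymmetricQuadrangleModel(10, 20, 5, 0, 0))
        assert np.all(poly[:, 1] == 0)

    def test_shoelace_area_is_twice_half_spike_area(self):
        for m in random_models(200, seed=2):
            d = sq.derive_traits(m)
            assert shoelace(sq.model_polyline(m)[:-1]) == pytest.approx(
                2.0 * d.q_S, rel=1e-9, abs=1e-9
            )


# Hypothesis property tests on randomized valid models ----------------------

model_strategy = st.builds(
    sq.SymmetricQuadrangleModel,
    st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100),
    st.floats(0.0, 20), st.floats(0.0, 20),
)


@settings(max_examples=200, derandomize=True)
@given(model_strategy)
def test_additivity_invariants(m):
    d = sq.derive_traits(m)
    assert d.q_S1 + d.q_S2 + d.q_S3 == pytest.approx(d.q_S, rel=1e-9, abs=1e-12)
    assert m.q_x1s + m.q_x2s + m.q_x3s == pytest.approx(d.q_L, rel=1e-9)


@settings(max_examples=200, derandomize=True)
@given(model_strategy, st.floats(0.01, 50))
def test_scale_equivariance(m, k):
    d, dk = sq.derive_traits(m), sq.derive_traits(m.scaled(k))
    assert dk.q_L == pytest.approx(k * d.q_L, rel=1e-9)
    assert dk.q_S == pytest.approx(k * k * d.q_S, rel=1e-6)
    assert dk.q_x2ns == pytest.approx(d.q_x2ns, rel=1e-9)
    if d.q_S > 0:
        assert dk.q_S2S == pytest.approx(d.q_S2S, rel=1e-6)


@settings(max_examples=100, derandomize=True)
@given(model_strategy, st.floats(0.1, 10))
def test_symmetrize_idempotent_and_commutes_with_scaling(m, k):
    fit = sq.AsymmetricQuadrangleFit(
        m.q_x1s, m.q_x2s, m.q_x3s, m.q_y1s, m.q_y2s,
        m.q_x1s, m.q_x2s, m.q_x3s, m.q_y1s, m.q_y2s,
    )
    assert sq.symmetrize(fit) == m  # symmetrizing a symmetric fit is identity
    scaled_fit = sq.AsymmetricQuadrangleFit(
        *(k * v for v in (m.q_x1s, m.q_x2s, m.q_x3s, m.q_y1s, m.q_y2s) * 2)
    )
    assert sq.symmetrize(scaled_fit) == m.scaled(k)


def test_trait_record_roundtrip(basic_model):
    rec = sq.TraitRecord(
        plant="p1", species="TAE", accession="a", spike_type="normal",
        manual=sq.ManualTraits(SL=80, SFW=9, SSW=7, SSC=16),
        model=basic_model,
        derived=sq.derive_traits(basic_model),
    )
    row = rec.to_dict()
    assert row["SDI"] == pytest.approx((16 - 1) * 100 / 80)
    back = sq.TraitRecord.from_dict(row)
    assert back.model == basic_model
    assert back.manual.SL == 80
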