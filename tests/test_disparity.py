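"""e-dagger, the sensitivity curves, the threshold age, and the REC
decomposition, checked against closed forms, refined-grid quadrature and a
direct perturbation experiment."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifedisparity import (
    DisparityResult,
    FixtureSpec,
    HazardSchedule,
    InvalidArgumentError,
    NoThresholdError,
    UndefinedValueError,
    decompose,
    e_dagger,
    e_dagger_above,
    entropy,
    lifetable_from_hazard,
    make_fixture,
    make_grid,
    sensitivity_curves,
    threshold_age,
)
from conftest import FAMILIES, build_lifetable


def refined(family, factor=10):
    return build_lifetable(family, omega=120, step=0.1 / factor)


def truncated_exponential_phi(x, mu=0.1, omega=120.0):
    """Exact phi for a constant hazard truncated at omega (deaths surviving
    to omega are closed out there): e(x) = (1-exp(-mu s))/mu with s = omega-x,
    edag(x) = e(x) - s exp(-mu s), phi = edag(x) + e(x)(mu x - 1)."""
    s = omega - x
    e = (1 - np.exp(-mu * s)) / mu
    edag = e - s * np.exp(-mu * s)
    return edag + e * (mu * x - 1.0)


class TestEDagger:
    def test_exponential_edag_equals_e0(self, lt_constant):
        assert abs(e_dagger(lt_constant) - lt_constant.e0) < 0.02

    def test_gompertz_edag_vs_refined_grid(self, lt_gompertz):
        assert e_dagger(lt_gompertz) == pytest.approx(e_dagger(refined("gompertz")), abs=1e-3)

    def test_conditional_at_zero_is_total(self, lt_gompertz):
        assert e_dagger_above(lt_gompertz, 0.0) == e_dagger(lt_gompertz)

    def test_conditional_memoryless_with_truncation(self, lt_constant):
        # exact truncated form: edag(x) = e(x) - (omega-x) exp(-mu(omega-x));
        # the correction is negligible at young ages and ~0.17 years at x=60
        mu, omega = 0.1, 120.0
        for x in (10.0, 30.0, 60.0):
            s = omega - x
            closed = (1 - np.exp(-mu * s)) / mu - s * np.exp(-mu * s)
            assert e_dagger_above(lt_constant, x) == pytest.approx(closed, abs=2e-3)
        assert abs(e_dagger_above(lt_constant, 30.0) - 10.0) < 0.05

    def test_conditional_vs_refined_grid(self, lt_gompertz):
        assert e_dagger_above(lt_gompertz, 70.0) == pytest.approx(
            e_dagger_above(refined("gompertz"), 70.0), abs=1e-3
        )

    def test_conditional_undefined_when_extinct(self, lt_nearrect):
        with pytest.raises(UndefinedValueError):
            e_dagger_above(lt_nearrect, 119.0)


class TestSensitivityCurves:
    def test_g_is_d_times_phi(self, lt_gompertz):
        sc = sensitivity_curves(lt_gompertz)
        assert np.allclose(sc.g, lt_gompertz.d * sc.phi)

    def test_phi_at_zero_is_edag_minus_e0(self, lt_gompertz):
        sc = sensitivity_curves(lt_gompertz)
        assert sc.phi[0] == pytest.approx(e_dagger(lt_gompertz) - lt_gompertz.e0, abs=1e-9)
        assert sc.phi[0] < 0

    def test_exponential_phi_matches_truncated_closed_form(self, lt_constant):
        x = lt_constant.grid.ages
        sc = sensitivity_curves(lt_constant)
        keep = x <= 100  # avoid the last cells where e and edag are O(step)
        dev = np.abs(sc.phi[keep] - truncated_exponential_phi(x[keep]))
        assert dev.max() < 2e-3
        # far from omega the truncation term dies and phi(x) ~ x
        young = x <= 20
        assert np.abs(sc.phi[young] - x[young]).max() < 1e-2

    @pytest.mark.parametrize("family", ["gompertz", "gompertz_makeham", "near_rectangular"])
    def test_phi_single_sign_change(self, family, all_lifetables):
        lt = all_lifetables[family]
        sc = sensitivity_curves(lt)
        valid = lt.l > 1e-12
        sgn = np.sign(sc.phi[valid])
        sgn = sgn[sgn != 0]
        assert np.count_nonzero(np.diff(sgn)) == 1


class TestThresholdAge:
    def test_exponential_threshold_degenerate(self, lt_constant):
        assert threshold_age(lt_constant) < lt_constant.grid.step

    def test_gompertz_perturbation_sign_flips_across_threshold(self, lt_gompertz):
        """A 1% hazard cut on a 1-year band below a-dagger must lower e-dagger,
        above it must raise it."""
        a_dag = threshold_age(lt_gompertz)
        ages = lt_gompertz.grid.ages
        for x0, expected_sign in [(a_dag - 2.0, -1.0), (a_dag + 1.0, +1.0)]:
            band = (ages >= x0) & (ages < x0 + 1.0)
            mu2 = lt_gompertz.mu.copy()
            mu2[band] *= 0.99
            lt2 = lifetable_from_hazard(HazardSchedule(grid=lt_gompertz.grid, mu=mu2))
            d_edag = e_dagger(lt2) - e_dagger(lt_gompertz)
            assert np.sign(d_edag) == expected_sign

    def test_near_rectangular_threshold_tracks_modal_age(self, lt_nearrect):
        # modal age at death for Gompertz is ln(b/a)/b; the threshold sits
        # just below it, within about one death-distribution scale (1/b)
        modal = np.log(0.5 / 1e-12) / 0.5
        a_dag = threshold_age(lt_nearrect)
        assert modal - 2.0 / 0.5 < a_dag < modal

    def test_no_threshold_error_carries_entropy(self):
        # a hazard that *decreases* strongly with age pushes entropy above 1
        grid = make_grid(120, 0.1)
        mu = 0.2 * np.exp(-0.08 * grid.ages) + 1e-4
        lt = lifetable_from_hazard(HazardSchedule(grid=grid, mu=mu))
        assert entropy(lt) > 1
        with pytest.raises(NoThresholdError):
            threshold_age(lt)


class TestPerturbationOracle:
    def test_first_order_prediction(self, lt_gompertz):
        """Relative hazard cuts of 1e-3 on 1-year bands: the sign of the
        e-dagger response must match g, and the first-order prediction
        eps * int_band g must agree within 5%."""
        sc = sensitivity_curves(lt_gompertz)
        a_dag = threshold_age(lt_gompertz)
        ages = lt_gompertz.grid.ages
        eps = 1e-3
        for x0 in [10.0, 30.0, 50.0, a_dag - 5.0, a_dag + 5.0, 90.0]:
            band = (ages >= x0) & (ages < x0 + 1.0)
            mu2 = lt_gompertz.mu.copy()
            mu2[band] *= 1.0 - eps
            lt2 = lifetable_from_hazard(HazardSchedule(grid=lt_gompertz.grid, mu=mu2))
            d_edag = e_dagger(lt2) - e_dagger(lt_gompertz)
            g_band = np.trapezoid(np.where(band, sc.g, 0.0), ages)
            assert np.sign(d_edag) == np.sign(g_band)
            assert abs(d_edag - eps * g_band) / abs(d_edag) < 0.05


class TestDecompose:
    @pytest.mark.parametrize("family", ["gompertz", "gompertz_makeham", "near_rectangular"])
    def test_conservation_and_invariants(self, family, all_lifetables):
        lt = all_lifetables[family]
        res = decompose(lt)
        assert res.ec + res.ee == pytest.approx(e_dagger(lt), abs=1e-6)
        assert res.ec >= 0 and res.ee >= 0
        assert 0 <= res.a_dag <= lt.grid.omega
        assert res.rec == pytest.approx(res.ee / res.ec)
        assert res.dec == pytest.approx(res.ee - res.ec)
        assert res.entropy == pytest.approx(res.edag / res.e0)

    def test_from_components_identities(self):
        res = DisparityResult.from_components(ec=2.0, ee=2.0)
        assert res.rec == 1.0 and res.dec == 0.0 and res.edag == 4.0

    def test_exponential_rec_blows_up(self, lt_constant):
        res = decompose(lt_constant)
        assert res.a_dag < lt_constant.grid.step
        assert res.rec > 100  # -> +inf as the threshold -> 0

    def test_summary_mentions_all_quantities(self, lt_gompertz):
        text = decompose(lt_gompertz).summary()
        for key in ("e0", "e-dagger", "a-dagger", "REC", "DEC", "entropy"):
            assert key in text


class TestEntropy:
    def test_limits(self, lt_constant, lt_nearrect, lt_gompertz):
        assert entropy(lt_constant) == pytest.approx(1.0, abs=0.01)
        assert entropy(lt_nearrect) < 0.05
        assert entropy(lt_gompertz) == e_dagger(lt_gompertz) / lt_gompertz.e0

    def test_rectangular_limit_drives_edag_to_zero(self):
        """Steeper senescence compresses deaths: e-dagger falls toward 0."""
        edags = []
        for b in (0.5, 1.0, 2.0, 4.0):
            a = b * np.exp(-b * 60.0)  # keep the modal age at 60
            lt = build_lifetable("near_rectangular", {"a": a, "b": b})
            edags.append(e_dagger(lt))
        assert all(x > y for x, y in zip(edags, edags[1:]))
        assert edags[-1] < 0.5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=1e-5, max_value=1e-3),
    b=st.floats(min_value=0.08, max_value=0.14),
    c=st.floats(min_value=0.0, max_value=2e-3),
)
def test_decomposition_properties_over_gompertz_makeham_family(a, b, c):
    """For any senescent schedule with entropy < 1: conservation holds, the
    components are positive, and phi changes sign exactly once."""
    grid = make_grid(120, 0.1)
    mu = a * np.exp(b * grid.ages) + c
    lt = lifetable_from_hazard(HazardSchedule(grid=grid, mu=mu))
    ent = entropy(lt)
    assert 0 < ent < 1
    res = decompose(lt)
    assert res.ec + res.ee == pytest.approx(e_dagger(lt), abs=1e-6)
    assert res.ec > 0 and res.ee > 0
    sc = sensitivity_curves(lt)
    sgn = np.sign(sc.phi[lt.l > 1e-12])
    sgn = sgn[sgn != 0]
    assert np.count_nonzero(np.diff(sgn)) == 1
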