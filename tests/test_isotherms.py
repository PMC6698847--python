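import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memchrom.isotherms import (
    BatchAdsorptionPoint,
    IsothermParams,
    fit_isotherm,
    loading_from_binding,
    loading_from_elution,
    q_equilibrium,
)
from memchrom.fixtures import (
    FixtureSpec,
    HIC_MODIFIER_LEVELS,
    hic_isotherm,
    iex_isotherm,
    make_isotherm_dataset,
)


def _point(c_feed, c_star_b, c_star_e, vt=5.0, va=0.05, cmod=0.1):
    names = tuple(f"c{i}" for i in range(len(c_feed)))
    return BatchAdsorptionPoint(
        names=names,
        c_feed=np.array(c_feed, float),
        c_star_binding=np.array(c_star_b, float),
        c_star_elution=np.array(c_star_e, float),
        v_total=vt,
        v_ads=va,
        c_mod=cmod,
    )


class TestBathMassBalances:
    def test_binding_balance_direct(self):
        p = _point([5.0], [1.0], [0.0])
        assert loading_from_binding(p, 0) == pytest.approx(400.0)

    def test_no_binding_gives_zero(self):
        p = _point([5.0], [5.0], [0.0])
        assert loading_from_binding(p, 0) == 0.0

    def test_elution_balance_direct(self):
        p = _point([5.0], [1.0], [1.0], vt=5.0, va=0.05)
        assert loading_from_elution(p, 0) == pytest.approx(100.0)
        p0 = _point([5.0], [1.0], [0.0])
        assert loading_from_elution(p0, 0) == 0.0

    def test_supernatant_above_feed_rejected(self):
        with pytest.raises(ValueError, match="assignment"):
            _point([1.0], [2.0], [0.0])

    def test_binding_and_elution_agree_on_loss_free_synthetic_data(self):
        ds = make_isotherm_dataset(FixtureSpec(seed=3))
        for p in ds.points:
            for i in range(len(p.names)):
                assert loading_from_elution(p, i) == pytest.approx(
                    loading_from_binding(p, i), rel=1e-8, abs=1e-8
                )


class TestEquilibrium:
    def test_empty_column(self, iex_params):
        q = q_equilibrium(np.zeros(3), 0.05, iex_params)
        assert np.all(q == 0.0)

    def test_single_component_hand_value(self):
        params = IsothermParams(a1=[0.0], a2=[100.0], b1=[10.0], b2=[0.0], l1=0.0)
        q = q_equilibrium(np.array([1.0]), 0.1, params)
        assert q[0] == pytest.approx(10.0 / 1.1, rel=1e-12)

    def test_langmuir_saturation_limit(self):
        params = IsothermParams(a1=[0.0], a2=[100.0], b1=[10.0], b2=[0.0], l1=0.0)
        q = q_equilibrium(np.array([1e7]), 0.1, params)
        assert q[0] == pytest.approx(100.0, rel=1e-4)

    def test_out_of_range_modifier_raises(self, iex_params):
        with pytest.raises(ValueError, match="modifier"):
            q_equilibrium(np.array([1.0, 0.1, 0.1]), 5.0, iex_params)

    @given(
        c=st.floats(min_value=0.0, max_value=20.0),
        dc=st.floats(min_value=1e-6, max_value=5.0),
        cmod=st.floats(min_value=0.02, max_value=0.3),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_own_concentration(self, c, dc, cmod):
        params = iex_isotherm()
        lo = q_equilibrium(np.array([c, 0.2, 0.05]), cmod, params)
        hi = q_equilibrium(np.array([c + dc, 0.2, 0.05]), cmod, params)
        assert hi[0] >= lo[0] - 1e-9

    @given(
        c2=st.floats(min_value=0.0, max_value=5.0),
        dc2=st.floats(min_value=1e-6, max_value=5.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_competitive_displacement_never_raises_other_loadings(self, c2, dc2):
        params = iex_isotherm()
        lo = q_equilibrium(np.array([2.0, c2, 0.05]), 0.05, params)
        hi = q_equilibrium(np.array([2.0, c2 + dc2, 0.05]), 0.05, params)
        assert hi[0] <= lo[0] + 1e-9
        assert hi[2] <= lo[2] + 1e-9


class TestFitting:
    def test_noise_free_parameter_recovery(self):
        true = iex_isotherm()
        ds = make_isotherm_dataset(FixtureSpec(seed=0))
        fit = fit_isotherm(ds, seed=1, n_starts=2)
        for name in ("a1", "a2", "b1", "b2"):
            est, ref = getattr(fit.params, name), getattr(true, name)
            assert np.max(np.abs(est / ref - 1.0)) < 1e-6

    def test_fit_invariant_to_point_ordering(self):
        ds = make_isotherm_dataset(FixtureSpec(seed=0))
        shuffled = type(ds)(points=tuple(reversed(ds.points)), resin_label=ds.resin_label)
        f1 = fit_isotherm(ds, seed=1, n_starts=1)
        f2 = fit_isotherm(shuffled, seed=1, n_starts=1)
        for name in ("a1", "a2", "b1", "b2"):
            assert np.allclose(
                getattr(f1.params, name), getattr(f2.params, name), rtol=1e-6
            )

    def test_single_modifier_level_is_rejected(self):
        ds = make_isotherm_dataset(FixtureSpec(seed=0), modifier_levels=(0.1,))
        with pytest.raises(ValueError, match="modifier levels"):
            fit_isotherm(ds)

    def test_hic_needs_the_linear_term(self):
        # HIC data generated with l1 > 0: forcing l1 = 0 must fit worse
        ds = make_isotherm_dataset(
            FixtureSpec(seed=0), params=hic_isotherm(),
            modifier_levels=HIC_MODIFIER_LEVELS, resin_label="HIC",
        )
        free = fit_isotherm(ds, seed=2, n_starts=2)
        fixed = fit_isotherm(ds, seed=2, n_starts=2, fit_l1=False)
        assert free.residual_norm < fixed.residual_norm
        assert free.params.l1 == pytest.approx(hic_isotherm().l1, rel=1e-4)
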