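import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartmac.model_core import (
    CartTumorParams,
    CytokineParams,
    DoseRegimen,
    InvalidParameterError,
    ModelState,
    UnitContext,
    UnsupportedConversionError,
    activation_rate,
    antigen_binding,
    cart_tumor_rhs,
    convert_units,
    macrophage_rhs,
    zero_limit,
)


class TestAntigenBinding:
    @pytest.mark.parametrize("T_P, A, expected", [
        (0.0, 1e6, 0.0),          # no antigen, no binding
        (1e6, 1e6, 0.5),          # half-saturation
        (9e6, 1e6, 0.9),          # 9A/(A+9A)
    ])
    def test_known_values(self, T_P, A, expected):
        assert antigen_binding(T_P, A) == pytest.approx(expected)

    def test_invalid_half_saturation(self):
        with pytest.raises(InvalidParameterError):
            antigen_binding(1e6, 0.0)

    @given(st.floats(min_value=0, max_value=1e14),
           st.floats(min_value=1e-3, max_value=1e12))
    @settings(max_examples=50, deadline=None)
    def test_fraction_bounded_and_monotone(self, T_P, A):
        f = antigen_binding(T_P, A)
        assert 0.0 <= f <= 1.0
        assert antigen_binding(T_P * 2 + 1, A) >= f


class TestCartTumorRhs:
    def test_pure_injected_decay(self):
        p = CartTumorParams(eta=0.0, mu_I=0.5)
        s = ModelState(C_I=1e6)
        d = cart_tumor_rhs(s, p)
        assert d[0] == pytest.approx(-5e5)
        assert np.allclose(d[1:], 0.0, atol=1e-12)

    def test_expander_net_growth_at_antigen_saturation(self):
        # T_P >> A so F ~ 1; epsilon term vanishes; expect (kappa-mu_E)*C_E
        p = CartTumorParams(eta=0.0, kappa=1.2, mu_E=0.35, epsilon=1e-3,
                            A=1e6, B=1e7)
        C_E = 1e7
        s = ModelState(C_E=C_E, T_P=1e12)
        d = cart_tumor_rhs(s, p)
        expected = (p.kappa - p.mu_E) * C_E
        assert d[1] == pytest.approx(expected, rel=1e-4)

    def test_logistic_tumor_growth_without_cart(self):
        p = CartTumorParams(rho=0.2, K=4.25e12)
        s = ModelState(T_P=1e8)
        d = cart_tumor_rhs(s, p)
        assert d[3] == pytest.approx(0.2 * 1e8 * (1 - 1e8 / 4.25e12))

    def test_negative_state_rejected(self):
        p = CartTumorParams()
        with pytest.raises(ValueError):
            cart_tumor_rhs(np.array([-1.0, 0, 0, 0, 0]), p)

    def test_crowding_shared_between_tumor_compartments(self):
        p = CartTumorParams(rho=0.3, K=1e10, g0=0.1)
        s = ModelState(T_P=4e9, T_N=4e9)
        d = cart_tumor_rhs(s, p)
        crowd = 1 - 8e9 / 1e10
        assert d[3] == pytest.approx(0.3 * 4e9 * crowd)
        assert d[4] == pytest.approx(0.3 * 4e9 * crowd)


class TestZeroLimit:
    def test_subcell_tumor_growth_gated_kill_active(self):
        p = CartTumorParams(rho=0.3, gamma=1.0, B=1e6)
        s = ModelState(C_E=1e8, T_P=0.5)
        d = cart_tumor_rhs(s, p)
        kill = p.gamma * 1e8 / (p.B + 1e8)
        assert d[3] == pytest.approx(-kill * 0.5)   # no growth term

    def test_one_cell_boundary_keeps_growth(self):
        p = CartTumorParams(rho=0.3, gamma=0.0)
        s = ModelState(T_P=1.0)
        d = cart_tumor_rhs(s, p)
        assert d[3] == pytest.approx(0.3 * (1 - 1.0 / p.K))

    def test_gated_equals_ungated_above_one_cell(self):
        p = CartTumorParams(g0=0.05)
        s = ModelState(C_I=1e5, C_E=2e6, C_P=10.0, T_P=1e9, T_N=5.0)
        assert np.allclose(cart_tumor_rhs(s, p, gated=True),
                           cart_tumor_rhs(s, p, gated=False))

    def test_flags(self):
        flags = zero_limit(ModelState(C_E=0.5, C_P=2.0, T_P=0.0, T_N=1.0))
        assert list(flags) == [0.0, 1.0, 0.0, 1.0]


class TestActivationRate:
    def test_all_components_vanish_without_expanders(self):
        q = CytokineParams(beta_B=1e-10, beta_K=1e-11, beta_C=1e-9)
        p = CartTumorParams()
        h = activation_rate(0.0, 1e10, 1e5, 1e9, q, p)
        assert h == (0.0, 0.0, 0.0, 0.0)

    def test_cd40_needs_activated_macrophages(self):
        q = CytokineParams(beta_B=0.0, beta_K=0.0, beta_C=1e-9)
        p = CartTumorParams()
        h_total, *_ = activation_rate(1e9, 1e10, 0.0, 0.0, q, p)
        assert h_total == 0.0

    def test_cd40_saturation_limit(self):
        q = CytokineParams(beta_C=1e-9, C=1e10)
        p = CartTumorParams()
        C_E = 1e9
        _, _, _, h_cd40 = activation_rate(C_E, 0.0, 0.0, 1e16, q, p)
        assert h_cd40 == pytest.approx(q.beta_C * C_E, rel=1e-5)

    def test_component_formulas(self):
        q = CytokineParams(beta_B=2e-11, beta_K=3e-12, beta_C=5e-10, C=1e10)
        p = CartTumorParams(A=1e8, B=1e8, g0=0.1)
        C_E, T_P, T_N, M_a = 2e8, 5e9, 1e6, 3e8
        h, h1, h2, h3 = activation_rate(C_E, T_P, T_N, M_a, q, p)
        assert h1 == pytest.approx(3e-12 * (C_E / (1e8 + C_E)) * (T_P + 0.1 * T_N))
        assert h2 == pytest.approx(2e-11 * (T_P / (1e8 + T_P)) * C_E)
        assert h3 == pytest.approx(5e-10 * (M_a / (1e10 + M_a)) * C_E)
        assert h == pytest.approx(h1 + h2 + h3)


class TestMacrophageRhs:
    def test_naive_steady_state(self):
        q = CytokineParams(sigma_M=3e9, delta_M=0.3)
        s = ModelState(M_i=3e9 / 0.3)
        d = macrophage_rhs(s, q, h=0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-6)

    def test_il6_baseline_steady_state(self):
        q = CytokineParams(sigma_I=10.0, delta_I=2.0)
        s = ModelState(IL6=5.0)          # sigma_I / delta_I
        d = macrophage_rhs(s, q, h=0.0)
        assert d[2] == pytest.approx(0.0)

    def test_pure_il6_decay(self):
        q = CytokineParams(sigma_I=0.0, delta_I=1.0, alpha=0.0)
        d = macrophage_rhs(ModelState(IL6=2.0), q, h=0.0)
        assert d[2] == pytest.approx(-2.0)


class TestUnitConversions:
    def test_copies_per_ug(self):
        assert convert_units(25, "copies/ug", "cells") == pytest.approx(2.5e5)

    def test_cells_per_uL(self):
        assert convert_units(1, "cells/uL_pb", "cells") == pytest.approx(5e6)

    def test_bone_marrow_scaling(self):
        assert convert_units(1, "cells/uL_bm", "cells") == pytest.approx(5e8)

    def test_percent_blasts_uses_mean_wbc(self):
        # 100 %blasts -> the full mean WBC count
        assert convert_units(100, "%blasts", "cells") == pytest.approx(4.25e10)

    def test_zero_maps_to_zero(self):
        for u in ("copies/ug", "cells/uL_pb", "%blasts"):
            assert convert_units(0.0, u, "cells") == 0.0

    def test_unknown_unit(self):
        with pytest.raises(UnsupportedConversionError):
            convert_units(1.0, "furlongs", "cells")

    @given(st.sampled_from(["cells", "copies/ug", "cells/uL_pb",
                            "cells/uL_bm", "%blasts"]),
           st.sampled_from(["cells", "copies/ug", "cells/uL_pb",
                            "cells/uL_bm", "%blasts"]),
           st.floats(min_value=1e-6, max_value=1e12))
    @settings(max_examples=60, deadline=None)
    def test_round_trip(self, u, v, x):
        ctx = UnitContext()
        back = convert_units(convert_units(x, u, v, ctx), v, u, ctx)
        assert back == pytest.approx(x, rel=1e-12)


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            CartTumorParams(mu_I=-0.1)

    def test_g0_range(self):
        with pytest.raises(InvalidParameterError):
            CartTumorParams(g0=1.5)

    def test_cytokine_saturation_positive(self):
        with pytest.raises(InvalidParameterError):
            CytokineParams(C=0.0)

    def test_dose_regimen_ordering(self):
        with pytest.raises(ValueError):
            DoseRegimen([(3.0, 1e7), (1.0, 1e7)])

    def test_split_dose_fractions(self):
        reg = DoseRegimen.split(1e8)
        assert [c for _, c in reg.events] == pytest.approx([1e7, 3e7, 6e7])
        assert reg.total_dose == pytest.approx(1e8)

    def test_negative_state_component(self):
        with pytest.raises(ValueError):
            ModelState(T_P=-1.0)
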