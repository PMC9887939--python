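import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate as sint
from scipy import special

from vegroots import ModelParams, SystemState, build_kernel_approx, find_branch
from vegroots.model_core import (
    cauchy_kernel_ft,
    evaporation_rate,
    gaussian_kernel_ft,
    local_rates_sedge,
    rhs,
    root_kernel_value,
    spectral_laplacian,
    sucker_growth,
    sucker_kernel_value,
)
from vegroots.nonlocal_operators import nonlocal_growth, nonlocal_uptake

from helpers import smooth_field


class TestModelParams:
    def test_default_values(self, params):
        expected = {
            "E1": 16.0, "E2": 5.0, "K1": 0.7, "K2": 0.35, "M1": 7.05,
            "M2": 7.05, "N": 15.0, "Lam1": 0.06, "Lam2": 0.16,
            "Gam1": 15.0, "Gam2": 5.0, "R1": 0.1, "R2": 0.1,
            "Th1": 3.125, "Th2": 3.125, "DW": 0.5, "SG1": 0.5,
            "SD1": 0.5, "SD2": 0.01, "Wstar1": 0.5, "Wstar2": 2.0,
        }
        for name, val in expected.items():
            assert getattr(params, name) == val

    @pytest.mark.parametrize("bad", [
        {"K1": -1.0}, {"N": 0.0}, {"E1": -0.5}, {"R1": 0.6, "R2": 0.5},
        {"SD1": 0.0}, {"M2": -7.0},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_root_width_monotone(self, params):
        b = np.linspace(0, params.K1, 50)
        w = params.root_width(b)
        assert np.all(np.diff(w) > 0)
        assert w[0] == params.SG1


class TestRootKernel:
    def test_origin_value(self, params):
        assert root_kernel_value(0.0, 0.0, params) == pytest.approx(
            1.0 / (2 * np.pi * params.SG1 ** 2))

    def test_plane_integral_bare(self, params):
        val, _ = sint.quad(
            lambda r: 2 * np.pi * r * root_kernel_value(r, 0.0, params),
            0, 10 * params.SG1)
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_plane_integral_grown(self, params):
        # mass (1 + 16*0.5)**2 = 81, by quadrature over a disc of radius 10*S
        B = 0.5
        S = params.root_width(B)
        val, _ = sint.quad(
            lambda r: 2 * np.pi * r * root_kernel_value(r, B, params),
            0, 10 * S)
        assert val == pytest.approx((1 + params.E1 * B) ** 2, rel=1e-6)
        assert val == pytest.approx(81.0, rel=1e-6)

    def test_line_integral_1d(self, params):
        B = 0.3
        val, _ = sint.quad(
            lambda r: root_kernel_value(r, B, params, dim=1),
            0, 12 * params.root_width(B))
        assert 2 * val == pytest.approx((1 + params.E1 * B) ** 2, rel=1e-6)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            root_kernel_value(-1.0, 0.0, params)
        with pytest.raises(ValueError):
            root_kernel_value(1.0, -0.1, params)

    @settings(max_examples=20, deadline=None)
    @given(B=st.floats(0.0, 2.0))
    def test_ft_matches_mass(self, B):
        # transform at k=0 equals the plane integral
        p = ModelParams()
        assert gaussian_kernel_ft(0.0, p.root_width(B), p.root_mass(B)) == \
            pytest.approx(p.root_mass(B))


class TestSuckerKernel:
    def test_origin_value(self):
        SD = 0.5
        assert sucker_kernel_value(0.0, SD) == pytest.approx(1 / (2 * np.pi * SD ** 2))

    @pytest.mark.parametrize("SD", [0.1, 0.5, 2.0])
    def test_unit_mass(self, SD):
        val, _ = sint.quad(
            lambda r: 2 * np.pi * r * sucker_kernel_value(r, SD),
            0, np.inf)
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_unit_mass_1d(self):
        val, _ = sint.quad(lambda r: sucker_kernel_value(r, 0.5, dim=1), 0, np.inf)
        assert 2 * val == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("k", [0.0, 0.5, 2.0, 5.0])
    def test_hankel_transform(self, k):
        # 2D Fourier transform of the radial kernel equals exp(-SD*k),
        # checked against numerical Hankel quadrature (piecewise between
        # Bessel zeros to tame the oscillatory integrand)
        SD = 0.5

        def f(r):
            return 2 * np.pi * r * special.j0(k * r) * sucker_kernel_value(r, SD)

        if k == 0.0:
            val, _ = sint.quad(f, 0, np.inf)
        else:
            edges = np.concatenate([[0.0], special.jn_zeros(0, 300) / k])
            val = sum(sint.quad(f, a, b)[0] for a, b in zip(edges[:-1], edges[1:]))
        assert val == pytest.approx(np.exp(-SD * k), abs=1e-5)
        assert cauchy_kernel_ft(k, SD) == pytest.approx(np.exp(-SD * k))

    def test_heavier_than_gaussian_tail(self, params):
        r = 6.0
        g = root_kernel_value(r, 0.0, params)       # gaussian, width 0.5
        c = sucker_kernel_value(r, 0.5)
        assert c > 100 * g

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sucker_kernel_value(1.0, -0.5)


class TestLocalRates:
    def test_zero_biomass(self, params):
        W = np.full(8, 30.0)
        growth, uptake = local_rates_sedge(np.zeros(8), W, params)
        np.testing.assert_allclose(growth, params.Lam2 * W)
        np.testing.assert_allclose(uptake, 0.0)

    def test_zero_water(self, params):
        growth, _ = local_rates_sedge(np.full(8, 0.2), np.zeros(8), params)
        np.testing.assert_allclose(growth, 0.0)

    def test_closed_form_at_capacity(self, params):
        # B2 = K2 = 0.35, W = 50: aug = (1 + 5*0.35)**2 = 7.5625
        growth, uptake = local_rates_sedge(np.array([0.35]), np.array([50.0]), params)
        aug = (1 + 5 * 0.35) ** 2
        assert growth[0] == pytest.approx(0.16 * 50 * aug)
        assert uptake[0] == pytest.approx(5 * 0.35 * aug)

    def test_shape_mismatch(self, params):
        with pytest.raises(ValueError):
            local_rates_sedge(np.zeros(4), np.zeros(5), params)


class TestSuckerGrowth:
    def test_zero_water(self, params, grid1d):
        out = sucker_growth(np.full(grid1d.shape, 0.3), np.zeros(grid1d.shape),
                            1, params, grid1d)
        np.testing.assert_allclose(out, 0.0)

    def test_uniform_fields(self, params, grid2d):
        b, w = 0.4, 20.0
        out = sucker_growth(np.full(grid2d.shape, b), np.full(grid2d.shape, w),
                            1, params, grid2d)
        expected = params.Th1 * w / (w + params.Wstar1) * b
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_localized_spike_brute_force(self, params, grid1d):
        # nonzero response far from the spike; matches direct O(n^2) quadrature
        B1 = np.zeros(grid1d.shape)
        B1[grid1d.nx // 2] = 1.0
        W = np.full(grid1d.shape, 10.0)
        out = sucker_growth(B1, W, 1, params, grid1d)

        x = grid1d.axes()[0]
        d = np.abs(x[:, None] - x[None, :])
        d = np.minimum(d, grid1d.Lx - d)
        # periodic images of the heavy tail matter: sum a few copies
        kern = sum(
            sucker_kernel_value(np.abs(d + s * grid1d.Lx), params.SD1, dim=1)
            for s in range(-40, 41)
        )
        direct = params.Th1 * W / (W + params.Wstar1) * (kern @ B1) * grid1d.dx
        np.testing.assert_allclose(out, direct, rtol=1e-2, atol=1e-12)
        far = np.abs(x - x[grid1d.nx // 2]) > 20 * params.SD1
        assert np.all(out[far] > 0)

    def test_negative_water_rejected(self, params, grid1d):
        with pytest.raises(ValueError):
            sucker_growth(np.zeros(grid1d.shape), np.full(grid1d.shape, -1.0),
                          1, params, grid1d)


class TestEvaporation:
    def test_bare_soil(self, params):
        assert evaporation_rate(np.zeros(3), np.zeros(3), params)[0] == 15.0

    def test_full_shading_species1(self, params):
        L = evaporation_rate(np.full(3, params.K1), np.zeros(3), params)
        np.testing.assert_allclose(L, 0.9 * params.N)

    @settings(max_examples=25, deadline=None)
    @given(b1=st.floats(0, 0.7), b2=st.floats(0, 0.35))
    def test_pointwise_formula(self, b1, b2):
        p = ModelParams()
        L = evaporation_rate(np.array([b1]), np.array([b2]), p)
        assert L[0] == pytest.approx(15.0 * (1 - 0.1 * b1 / 0.7 - 0.1 * b2 / 0.35))
        assert L[0] >= p.N * (1 - p.R1 - p.R2) - 1e-12


class TestRhs:
    def test_bare_soil_equilibrium(self, params, grid1d, approx1d):
        state = SystemState.uniform(grid1d, 0.0, 0.0, params.P / params.N)
        dB1, dB2, dW = rhs(state, params, grid1d, approx1d)
        np.testing.assert_allclose(dB1, 0.0, atol=1e-12)
        np.testing.assert_allclose(dB2, 0.0, atol=1e-12)
        np.testing.assert_allclose(dW, 0.0, atol=1e-10)

    def test_uniform_equilibria_are_fixed_points(self, params, grid1d, approx1d):
        for label in ("GU", "CU"):
            eq = find_branch(params, label)
            assert eq is not None
            d = rhs(eq.as_state(grid1d), params, grid1d, approx1d)
            for term in d:
                np.testing.assert_allclose(term, 0.0, atol=1e-8)

    def test_water_budget_closes(self, params, grid2d, approx2d):
        # spatial mean of dW equals mean source minus sink terms: the
        # periodic spectral Laplacian integrates to zero
        B1 = smooth_field(grid2d, 1, 0, params.K1)
        B2 = smooth_field(grid2d, 2, 0, params.K2)
        W = smooth_field(grid2d, 3, 1.0, 30.0)
        state = SystemState(B1, B2, W)
        _, _, dW = rhs(state, params, grid2d, approx2d)
        uptake1 = nonlocal_uptake(B1, approx2d, params)
        _, uptake2 = local_rates_sedge(B2, W, params)
        L = evaporation_rate(B1, B2, params)
        expected = params.P - (L * W).mean() - (W * (uptake1 + uptake2)).mean()
        assert dW.mean() == pytest.approx(expected, rel=1e-12, abs=1e-10)

    def test_no_negative_biomass_generation(self, params, grid1d, approx1d):
        # where B_i = 0, dB_i reduces to the (nonnegative) recruitment term
        B1 = np.zeros(grid1d.shape)
        B1[:10] = 0.5
        B2 = np.zeros(grid1d.shape)
        B2[50:60] = 0.3
        W = np.full(grid1d.shape, 10.0)
        dB1, dB2, _ = rhs(SystemState(B1, B2, W), params, grid1d, approx1d)
        assert np.all(dB1[B1 == 0] >= 0)
        assert np.all(dB2[B2 == 0] >= 0)

    def test_local_limit_matches_algebraic_rates(self, grid1d):
        # narrow root kernel: nonlocal rates collapse to the local closed
        # forms on nonuniform fields to < 1%
        p = ModelParams(SG1=0.01)
        ap = build_kernel_approx(p, grid1d)
        B1 = smooth_field(grid1d, 4, 0, p.K1, corr=4.0)
        W = smooth_field(grid1d, 5, 1.0, 20.0, corr=4.0)
        growth = nonlocal_growth(W, B1, ap, p)
        uptake = nonlocal_uptake(B1, ap, p)
        growth_local = p.Lam1 * W * (1 + p.E1 * B1) ** 2
        uptake_local = p.Gam1 * B1 * (1 + p.E1 * B1) ** 2
        assert np.linalg.norm(growth - growth_local) < 0.01 * np.linalg.norm(growth_local)
        assert np.linalg.norm(uptake - uptake_local) < 0.01 * np.linalg.norm(uptake_local)

    def test_nan_diagnostic(self, params, grid1d, approx1d):
        state = SystemState.uniform(grid1d, 0.1, 0.1, 10.0)
        state.W[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(state, params, grid1d, approx1d)


class TestSpectralLaplacian:
    def test_single_mode(self, grid1d):
        x = grid1d.axes()[0]
        k = 2 * np.pi * 3 / grid1d.Lx
        f = np.cos(k * x)
        np.testing.assert_allclose(spectral_laplacian(f, grid1d), -k * k * f,
                                   atol=1e-10)
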