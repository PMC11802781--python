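"""Steady-state solver: closed forms, linear-algebra and dynamical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendrocost as dc
from dendrocost.params import spine_capacity_density
from dendrocost.steady_state import mrna_profile_shape, solve_protein_bvp
from dendrocost.transport import normalised_cosh_profile

from conftest import dense_linear_protein_solve, time_integrate_protein


class TestSpineOccupancy:
    def test_zero_shaft_gives_empty_spines(self, camkii, geom250):
        assert dc.spine_occupancy(0.0, camkii, geom250) == 0.0

    def test_saturates_at_capacity(self, camkii, geom250):
        E = spine_capacity_density(camkii, geom250)
        s = dc.spine_occupancy(1e12, camkii, geom250)
        assert s < E
        assert s == pytest.approx(E, rel=1e-3)

    @given(st.floats(min_value=0.0, max_value=1e9))
    @settings(derandomize=True, max_examples=60)
    def test_bounded_and_monotone(self, p):
        sp = dc.camkii_preset()
        geom = dc.DendriteGeometry(L=100.0)
        E = spine_capacity_density(sp, geom)
        s = dc.spine_occupancy(p, sp, geom)
        assert 0.0 <= s < E
        assert dc.spine_occupancy(p + 1.0, sp, geom) >= s


class TestMrnaProfile:
    def test_dendritic_mrna_is_cosh_closed_form(self, fast_species, geom250):
        """The solved dendritic mRNA profile equals
        A*cosh((L-x)/ell)/cosh(L/ell) with ell = sqrt(D_eff/lambda_m)."""
        prof = dc.solve_steady(fast_species, geom250, dc.Scenario.dendritic(0.3))
        D_eff = prof.diagnostics["D_eff"]
        ell = np.sqrt(D_eff / fast_species.lambda_m)
        expected = prof.m[0] * normalised_cosh_profile(prof.x, geom250.L, ell)
        assert np.max(np.abs(prof.m - expected)) <= 1e-6 * prof.m[0]

    def test_bias_profile_reduces_to_cosh_at_zero_drift(self):
        x = np.linspace(0, 200, 201)
        a = mrna_profile_shape(x, 200.0, 0.1, 1e-4, v_bias=0.0)
        b = mrna_profile_shape(x, 200.0, 0.1, 1e-4, v_bias=1e-12)
        assert np.allclose(a, b, rtol=1e-6)

    def test_anterograde_bias_flattens_profile(self):
        x = np.linspace(0, 200, 201)
        unbiased = mrna_profile_shape(x, 200.0, 0.1, 1e-4, v_bias=0.0)
        biased = mrna_profile_shape(x, 200.0, 0.1, 1e-4, v_bias=0.001)
        assert biased[-1] > unbiased[-1]


class TestSolveSteady:
    def test_somatic_scenario_keeps_dendrite_mrna_free(self, camkii, geom500):
        prof = dc.solve_steady(camkii, geom500, dc.Scenario.somatic())
        assert np.all(prof.m == 0.0)
        assert prof.m_soma > 0

    def test_r_soma_share_definition(self, fast_species, geom250):
        """r_soma = m_soma / (m_soma + integral m)."""
        for r in (0.2, 0.5, 0.8):
            prof = dc.solve_steady(fast_species, geom250, dc.Scenario.dendritic(r))
            share = prof.m_soma / prof.m_total
            assert share == pytest.approx(r, rel=1e-9)

    def test_profiles_nonnegative_and_distal_spine_filled(
        self, fast_species, geom250
    ):
        for sc in (dc.Scenario.somatic(), dc.Scenario.dendritic(0.5)):
            prof = dc.solve_steady(fast_species, geom250, sc)
            E = spine_capacity_density(fast_species, geom250)
            assert np.all(prof.p >= 0)
            assert np.all(prof.p_spine >= 0)
            assert np.all(prof.p_spine <= E)
            assert np.min(prof.p_spine) == pytest.approx(
                geom250.phi * E, rel=1e-6
            )

    def test_flux_balance_synthesis_equals_degradation(
        self, fast_species, camkii, geom250
    ):
        """Total protein synthesis tau*(m_soma + int m) balances total
        degradation lambda_p*(int p + int p_spine) within 0.1%."""
        for sp in (fast_species, camkii):
            for sc in (dc.Scenario.somatic(), dc.Scenario.dendritic(0.4)):
                prof = dc.solve_steady(sp, geom250, sc)
                synth = sp.tau * prof.m_total
                degr = sp.lambda_p * np.trapezoid(
                    prof.p + prof.p_spine, prof.x
                )
                assert degr == pytest.approx(synth, rel=1e-3)
                assert prof.diagnostics["flux_imbalance"] < 1e-6

    def test_linear_limit_matches_dense_solve(self, geom250):
        """With negligible spine exchange the protein BVP is linear and
        must match an independent dense finite-difference solve."""
        sp = dc.camkii_preset().with_(u_p=1e-12, nu_p=3e-4)
        x = np.linspace(0, geom250.L, geom250.n_nodes)
        m = 50.0 * normalised_cosh_profile(x, geom250.L, 120.0)
        m_soma = 2000.0
        p, s = solve_protein_bvp(sp, geom250, m, m_soma)
        p_ref, _ = dense_linear_protein_solve(sp, geom250, m, m_soma)
        assert np.max(np.abs(p - p_ref)) <= 1e-8 * np.max(p_ref)
        assert np.max(s) <= 1e-6 * np.max(p)

    def test_converged_profile_is_dynamical_fixed_point(
        self, fast_species, geom250
    ):
        """Time-integrating the protein/spine dynamics from the returned
        profile for 1e5 s changes no density beyond solver tolerance."""
        prof = dc.solve_steady(fast_species, geom250, dc.Scenario.dendritic(0.3))
        p_end, s_end = time_integrate_protein(
            fast_species, geom250, prof.m, prof.diagnostics["J0"],
            prof.p, prof.p_spine, t_end=1e5, dt=50.0,
        )
        assert np.max(np.abs(p_end - prof.p)) <= 1e-6 * np.max(prof.p)
        assert np.max(np.abs(s_end - prof.p_spine)) <= 1e-6 * np.max(prof.p_spine)

    def test_grid_refinement_converged(self, fast_species):
        """Richardson check: halving dx changes integrated counts by less
        than 0.1%."""
        g1 = dc.DendriteGeometry(L=250.0, grid_dx=1.0)
        g2 = dc.DendriteGeometry(L=250.0, grid_dx=0.5)
        c1 = dc.total_counts(
            dc.solve_steady(fast_species, g1, dc.Scenario.dendritic(0.5)), g1
        )
        c2 = dc.total_counts(
            dc.solve_steady(fast_species, g2, dc.Scenario.dendritic(0.5)), g2
        )
        assert c1["P_total"] == pytest.approx(c2["P_total"], rel=1e-3)
        assert c1["M_total"] == pytest.approx(c2["M_total"], rel=1e-3)

    def test_u_p_zero_raises_configuration_error(self, camkii, geom250):
        no_entry = _without_validation(camkii)
        with pytest.raises(dc.ConfigurationError):
            dc.solve_steady(no_entry, geom250, dc.Scenario.somatic())

    def test_invalid_r_soma_rejected(self):
        with pytest.raises(dc.ConfigurationError):
            dc.Scenario.dendritic(0.0)
        with pytest.raises(dc.ConfigurationError):
            dc.Scenario.dendritic(1.0)


def _without_validation(species):
    """Clone a species with u_p = 0, bypassing dataclass validation."""
    import copy
    clone = copy.copy(species)
    object.__setattr__(clone, "u_p", 0.0)
    return clone


class TestTotalCounts:
    def _profile(self, x, m, p, s, geom):
        return dc.SpatialProfile(
            x=x, m=m, p=p, p_spine=s, m_soma=0.0, p_soma=0.0, r_soma=1.0,
            scenario=dc.Scenario.somatic(),
        )

    def test_all_zero_profile(self, geom250):
        x = np.linspace(0, geom250.L, geom250.n_nodes)
        z = np.zeros_like(x)
        counts = dc.total_counts(self._profile(x, z, z, z, geom250), geom250)
        assert counts == {"M_total": 0.0, "P_total": 0.0}

    def test_uniform_density_integrates_to_c_times_L(self, geom250):
        x = np.linspace(0, geom250.L, geom250.n_nodes)
        z = np.zeros_like(x)
        p = np.full_like(x, 7.5)
        counts = dc.total_counts(self._profile(x, z, p, z, geom250), geom250)
        assert counts["P_total"] == pytest.approx(7.5 * geom250.L)

    def test_doubling_eta_doubles_totals(self, fast_species, geom250):
        """The solved system is homogeneous in the spine capacity."""
        sc = dc.Scenario.dendritic(0.5)
        c1 = dc.total_counts(dc.solve_steady(fast_species, geom250, sc), geom250)
        doubled = fast_species.with_(eta_p=2 * fast_species.eta_p)
        c2 = dc.total_counts(dc.solve_steady(doubled, geom250, sc), geom250)
        assert c2["P_total"] == pytest.approx(2 * c1["P_total"], rel=1e-6)
        assert c2["M_total"] == pytest.approx(2 * c1["M_total"], rel=1e-6)
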