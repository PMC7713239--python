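import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solvmut.constants import K_E
from solvmut.solvation_core import (
    ChargingPath,
    LowDensityProvider,
    SoluteSite,
    SolventModel,
    SolventSite,
    ThermodynamicState,
    born_delta_g,
    charging_decomposition,
    delta_g_solv,
    group_by_residue,
    load_solvent_model,
    mayer_free_energy,
    pair_potential,
    solute_sites_from_structure,
    water_model,
    with_salt,
)


@pytest.fixture
def lj_atom():
    return SoluteSite(position=[0.0, 0.0, 0.0], charge=0.0, sigma=3.4,
                      epsilon=0.109, residue_index=0)


@pytest.fixture
def charged_atom():
    return SoluteSite(position=[0.0, 0.0, 0.0], charge=0.5, sigma=3.0,
                      epsilon=0.15, residue_index=0)


class TestPairPotential:
    def test_zero_coupling_is_zero(self, charged_atom, mild):
        for sv in mild.sites:
            for r in (1.0, 3.0, 10.0):
                assert pair_potential(charged_atom, sv, r, (0.0, 0.0)) == 0.0

    def test_lj_zero_crossing_at_sigma(self, lj_atom):
        sv = SolventSite("X", 0.0, 0.0334, 3.0, 0.2)
        sigma_comb = 0.5 * (3.4 + 3.0)
        u = pair_potential(lj_atom, sv, sigma_comb, (1.0, 1.0))
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_term_value(self):
        # +1 against the water oxygen charge at 3 A
        site = SoluteSite(position=[0, 0, 0], charge=1.0, sigma=3.0,
                          epsilon=0.0)
        sv = SolventSite("O", -0.8476, 0.0334, 3.166, 1e-12)
        u = pair_potential(site, sv, 3.0, (1.0, 1.0))
        assert u == pytest.approx(K_E * -0.8476 / 3.0, rel=1e-6)
        assert u == pytest.approx(-93.78, abs=0.05)

    def test_r_zero_rejected(self, lj_atom, mild):
        with pytest.raises(ValueError):
            pair_potential(lj_atom, mild.sites[0], 0.0, (1.0, 1.0))


class TestChargingDecomposition:
    def test_noninteracting_solute_gives_zero(self, mild, state):
        solute = [SoluteSite(position=[0, 0, 0], charge=0.0, sigma=3.0,
                             epsilon=0.0, residue_index=0)]
        prov = LowDensityProvider(solute, mild, state)
        dr = charging_decomposition(solute, mild, prov, state=state)
        np.testing.assert_allclose(dr.per_atom, 0.0, atol=1e-12)

    def test_single_atom_matches_closed_form(self, charged_atom, mild,
                                             state):
        """8+8-node charging total vs the ideal-dilute closed form
        -kT sum_g rho_g int (e^{-beta u} - 1) dV."""
        solute = [charged_atom]
        prov = LowDensityProvider(solute, mild, state)
        exact = mayer_free_energy(solute, mild, state,
                                  support=(prov.points, prov.volumes))
        dr = charging_decomposition(solute, mild, prov,
                                    ChargingPath.two_stage(8, 8), state)
        assert dr.total == pytest.approx(exact, rel=1e-3)

    def test_two_atom_closed_form_and_dense_lambda(self, mild, state):
        solute = [
            SoluteSite(position=[0, 0, 0], charge=0.3, sigma=3.2,
                       epsilon=0.12, residue_index=0),
            SoluteSite(position=[3.5, 0, 0], charge=-0.3, sigma=3.0,
                       epsilon=0.15, residue_index=1),
        ]
        prov = LowDensityProvider(solute, mild, state, spacing=0.3,
                                  padding=7.0)
        exact = mayer_free_energy(solute, mild, state,
                                  support=(prov.points, prov.volumes))
        dr = charging_decomposition(solute, mild, prov,
                                    ChargingPath.two_stage(8, 8), state)
        assert dr.total == pytest.approx(exact, rel=5e-3)
        dense = charging_decomposition(solute, mild, prov,
                                       ChargingPath.two_stage(64, 64),
                                       state)
        np.testing.assert_allclose(dr.per_atom, dense.per_atom, rtol=5e-3)

    def test_conservation_identity(self, charged_atom, mild, state):
        solute = [charged_atom,
                  SoluteSite(position=[4, 0, 0], charge=-0.2, sigma=3.1,
                             epsilon=0.1, residue_index=1)]
        prov = LowDensityProvider(solute, mild, state, spacing=0.4,
                                  padding=6.0)
        dr = charging_decomposition(solute, mild, prov, state=state)
        assert sum(dr.per_residue().values()) == pytest.approx(
            dr.total, rel=1e-10)

    def test_path_independence_of_total(self, charged_atom, mild, state):
        """Proportional one-stage path and the default two-stage path give
        the same total with the ideal-dilute provider (per-atom values may
        differ between paths)."""
        solute = [charged_atom]
        prov = LowDensityProvider(solute, mild, state)
        two = charging_decomposition(solute, mild, prov,
                                     ChargingPath.two_stage(8, 8), state)
        prop = charging_decomposition(solute, mild, prov,
                                      ChargingPath.proportional(32), state)
        assert prop.total == pytest.approx(two.total, rel=5e-3)

    def test_quadrature_convergence(self, charged_atom, mild, state):
        solute = [charged_atom]
        prov = LowDensityProvider(solute, mild, state)
        t8 = charging_decomposition(solute, mild, prov,
                                    ChargingPath.two_stage(8, 8), state)
        t16 = charging_decomposition(solute, mild, prov,
                                     ChargingPath.two_stage(16, 16), state)
        assert abs(t16.total - t8.total) / abs(t16.total) < 1e-3


class TestLowDensityProvider:
    def test_zero_coupling_unity(self, charged_atom, mild, state):
        prov = LowDensityProvider([charged_atom], mild, state)
        fields = prov.fields((0.0, 0.0))
        for g in fields.g.values():
            np.testing.assert_allclose(g, 1.0)

    def test_core_exclusion(self, lj_atom, mild, state):
        prov = LowDensityProvider([lj_atom], mild, state)
        fields = prov.fields((1.0, 1.0))
        r = np.linalg.norm(fields.points - lj_atom.position, axis=1)
        assert np.all(fields.g["A"][r < 2.0] < 1e-6)


class TestGrouping:
    def test_one_residue_solute(self, charged_atom, mild, state):
        prov = LowDensityProvider([charged_atom], mild, state)
        dr = charging_decomposition([charged_atom], mild, prov, state=state)
        assert dr.per_residue() == {0: pytest.approx(dr.total)}

    def test_permutation_invariance_and_sums(self, mild, state):
        rng = np.random.default_rng(3)
        solute = [SoluteSite(position=rng.normal(scale=2, size=3),
                             charge=0.1 * (-1) ** i, sigma=3.2,
                             epsilon=0.12, residue_index=i % 3)
                  for i in range(6)]
        prov = LowDensityProvider(solute, mild, state, spacing=0.5,
                                  padding=5.0)
        dr = charging_decomposition(solute, mild, prov, state=state)
        perm = [3, 1, 5, 0, 2, 4]
        prov2 = LowDensityProvider([solute[i] for i in perm], mild, state,
                                   spacing=0.5, padding=5.0)
        dr2 = charging_decomposition([solute[i] for i in perm], mild, prov2,
                                     state=state)
        for k, v in dr.per_residue().items():
            assert dr2.per_residue()[k] == pytest.approx(v, rel=1e-6)
        assert sum(dr.per_residue().values()) == pytest.approx(dr.total)

    def test_orphan_atom_rejected(self, mild, state):
        orphan = SoluteSite(position=[0, 0, 0], charge=0.0, sigma=3.0,
                            epsilon=0.1)  # residue_index defaults to -1
        prov = LowDensityProvider([orphan], mild, state)
        dr = charging_decomposition([orphan], mild, prov, state=state)
        with pytest.raises(ValueError, match="not mapped"):
            dr.per_residue()


class TestSoluteParameterisation:
    def test_charges_on_charged_group_atoms(self, benches):
        cs = benches["salt_bridge"]["structure"]
        sites = solute_sites_from_structure(cs)
        by_label = {s.label: s.charge for s in sites}
        assert by_label["A:1:NZ"] == +1.0
        assert by_label["A:2:OD1"] == -1.0
        assert by_label["A:1:CA"] == 0.0
        assert sum(s.charge for s in sites) == pytest.approx(
            cs.total_charge)


class TestBorn:
    def test_zero_increment(self):
        assert born_delta_g(1.0, 0.0) == 0.0

    def test_ratio_three(self):
        for radius, eps in [(2.0, 78.4), (5.0, 30.0)]:
            ratio = (born_delta_g(1, 1, radius, eps)
                     / born_delta_g(0, 1, radius, eps))
            assert ratio == pytest.approx(3.0, rel=1e-12)

    def test_sign_rules(self):
        # removing positive charge from a positive sphere costs energy
        assert born_delta_g(1.0, -1.0) > 0
        # adding positive charge to a positive sphere is favourable
        assert born_delta_g(1.0, 1.0) < 0
        # sign is set by -(2 Q dQ + dQ^2)
        assert born_delta_g(-3.0, 1.0) > 0

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-5, 5), st.floats(-3, 3),
           st.floats(0.5, 10), st.floats(1.5, 100))
    def test_round_trip(self, q, dq, radius, eps):
        total = (born_delta_g(q, dq, radius, eps)
                 + born_delta_g(q + dq, -dq, radius, eps))
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            born_delta_g(1, 1, radius=-1.0)
        with pytest.raises(ValueError):
            born_delta_g(1, 1, dielectric=0.5)


class TestDeltaGStats:
    def test_identical_ensembles(self):
        stats = delta_g_solv([[1.0, 2.0]], [[1.0, 2.0]])
        assert stats.mean == 0.0
        assert stats.se is None  # single run: no between-run error

    def test_hand_computed_two_runs(self):
        stats = delta_g_solv([[0.0, 0.0], [0.0, 0.0]],
                             [[-10.0, -10.0], [-20.0, -20.0]])
        assert stats.mean == -15.0
        assert stats.se == 5.0
        assert stats.per_run_delta == [-10.0, -20.0]
        assert stats.per_run_sd == [0.0, 0.0]

    def test_per_frame_fluctuation(self):
        stats = delta_g_solv([[0.0, 0.0, 0.0]], [[-5.0, 5.0, 0.0]])
        assert stats.per_run_sd[0] == pytest.approx(5.0)
        np.testing.assert_allclose(stats.traces[0], [-5.0, 5.0, 0.0])

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            delta_g_solv([[]], [[1.0]])
        with pytest.raises(ValueError):
            delta_g_solv([], [])


class TestSolventModels:
    def test_salt_densities(self, water):
        salty = with_salt(water, 0.150)
        names = [s.name for s in salty.sites]
        assert names == ["O", "H1", "H2", "NA", "CL"]
        na = salty.site("NA")
        assert na.density == pytest.approx(0.150 * 6.022e-4, rel=1e-3)

    def test_yaml_round_trip(self, tmp_path, water):
        cfg = tmp_path / "solvent.yaml"
        cfg.write_text(
            "sites:\n"
            + "".join(
                f"  - {{name: {s.name}, charge: {s.charge}, "
                f"density: {s.density}, sigma: {s.sigma}, "
                f"epsilon: {s.epsilon}}}\n" for s in water.sites)
            + "bonds:\n"
            + "".join(f"  - {{i: {i}, j: {j}, distance: {d}}}\n"
                      for (i, j), d in water.bonds.items()))
        back = load_solvent_model(cfg)
        assert [s.name for s in back.sites] == ["O", "H1", "H2"]
        assert back.bond_distance("H1", "H2") == pytest.approx(1.633)
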