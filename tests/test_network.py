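"""Mass-action core: rate law, RHS assembly, conservation, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from fvmapk.network import (
    Species, Reaction, ReactionNetwork, mass_action_rate, assemble_rhs,
    conserved_moieties, network_to_dict, network_from_dict, to_sbml,
    NetworkConfigError,
)


class TestMassActionRate:
    def test_vegfr2_binding_example(self):
        """kf*[VEGF][VEGFR2] - kr*[pVEGFR2] with the stated numbers gives 6."""
        rx = Reaction("R", [("VEGF", 1), ("VEGFR2", 1)], [("pVEGFR2", 1)],
                      3.0, 5.0)
        idx = {"VEGF": 0, "VEGFR2": 1, "pVEGFR2": 2}
        flux = mass_action_rate(rx, np.array([1.0, 2.0, 0.0]), idx)
        assert flux == pytest.approx(6.0)

    def test_all_zero_state_has_zero_flux(self):
        rx = Reaction("R", [("A", 2), ("B", 1)], [("C", 1)], 7.0, 2.0)
        idx = {"A": 0, "B": 1, "C": 2}
        assert mass_action_rate(rx, np.zeros(3), idx) == 0.0

    def test_unknown_species_raises(self):
        rx = Reaction("R", [("X", 1)], [], 1.0)
        with pytest.raises(NetworkConfigError):
            mass_action_rate(rx, np.zeros(1), {"A": 0})

    @given(
        coeffs=st.lists(st.integers(1, 3), min_size=1, max_size=3),
        kf=st.floats(0, 10), kr=st.floats(0, 10),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_product_of_powers_oracle(self, coeffs, kf, kr, data):
        """Random reactions agree with a hand-accumulated product of powers."""
        names = [f"S{i}" for i in range(len(coeffs) + 1)]
        state = np.array([
            data.draw(st.floats(0, 5)) for _ in names])
        rx = Reaction("R", [(n, c) for n, c in zip(names[:-1], coeffs)],
                      [(names[-1], 1)], kf, kr)
        idx = {n: i for i, n in enumerate(names)}
        expected = kf
        for n, c in zip(names, coeffs):
            for _ in range(c):
                expected *= state[idx[n]]
        expected -= kr * state[-1]
        got = mass_action_rate(rx, state, idx)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestAssembleRHS:
    def test_reversible_isomerization_matches_closed_form(self, toy_network):
        """A<->B with kf=kr=1, A0=2 relaxes as A(t) = 1 + exp(-2t)."""
        rhs = assemble_rhs(toy_network)
        sol = solve_ivp(rhs, (0, 5), toy_network.initial_state(),
                        rtol=1e-10, atol=1e-12, dense_output=True)
        t = np.linspace(0, 5, 20)
        a = sol.sol(t)[0]
        assert np.allclose(a, 1 + np.exp(-2 * t), atol=1e-7)
        # equilibrium A = B = 1 (up to the residual exp(-2t) transient)
        assert sol.sol(5.0)[0] == pytest.approx(1.0 + np.exp(-10.0), abs=1e-7)

    def test_clamped_species_has_zero_derivative(self):
        net = ReactionNetwork(
            species=[Species("L", "extracellular", 5.0, clamped=True),
                     Species("R", "surface", 10.0), Species("C", "surface")],
            reactions=[Reaction("R1", [("L", 1), ("R", 1)], [("C", 1)], 2.0)],
        )
        rhs = assemble_rhs(net)
        dy = rhs(0.0, net.initial_state())
        assert dy[0] == 0.0
        assert dy[1] == pytest.approx(-100.0)

    def test_jacobian_matches_finite_differences(self, main_model):
        rhs = assemble_rhs(main_model.network)
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 1000, size=rhs.n_species)
        J = rhs.jacobian(0.0, y)
        f0 = rhs(0.0, y)
        eps = 1e-6
        for j in rng.integers(0, rhs.n_species, size=10):
            yp = y.copy()
            h = eps * max(1.0, abs(y[j]))
            yp[j] += h
            col = (rhs(0.0, yp) - f0) / h
            assert np.allclose(J[:, j], col, rtol=1e-4,
                               atol=1e-4 * max(1, np.abs(col).max()))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_random_small_networks_match_symbolic_oracle(self, seed):
        """RHS equals a per-reaction hand-expanded sum at random states."""
        rng = np.random.default_rng(seed)
        n_sp = rng.integers(2, 6)
        n_rx = rng.integers(1, 6)
        names = [f"S{i}" for i in range(n_sp)]
        reactions = []
        for r in range(n_rx):
            nr = rng.integers(1, 3)
            np_ = rng.integers(1, 3)
            reactants = [(names[i], int(rng.integers(1, 3)))
                         for i in rng.choice(n_sp, nr, replace=False)]
            products = [(names[i], int(rng.integers(1, 3)))
                        for i in rng.choice(n_sp, np_, replace=False)]
            reactions.append(Reaction(
                f"R{r}", reactants, products,
                float(rng.uniform(0, 2)), float(rng.uniform(0, 2))))
        net = ReactionNetwork(
            species=[Species(n, initial_amount=1.0) for n in names],
            reactions=reactions)
        rhs = assemble_rhs(net)
        y = rng.uniform(0, 3, size=n_sp)
        idx = net.species_index()
        expected = np.zeros(n_sp)
        for rx in reactions:
            flux = mass_action_rate(rx, y, idx)
            for nm, c in rx.reactants:
                expected[idx[nm]] -= c * flux
            for nm, c in rx.products:
                expected[idx[nm]] += c * flux
        got = rhs(0.0, y)
        scale = max(1.0, np.abs(expected).max())
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12 * scale)


class TestConservedMoieties:
    def test_linear_chain_total_mass(self):
        net = ReactionNetwork(
            species=[Species("A", initial_amount=1.0), Species("B"),
                     Species("C")],
            reactions=[Reaction("R1", [("A", 1)], [("B", 1)], 1.0),
                       Reaction("R2", [("B", 1)], [("C", 1)], 0.5)],
        )
        mo = conserved_moieties(net)
        assert len(mo) == 1
        w = mo[0]
        assert set(w) == {"A", "B", "C"}
        assert len(set(w.values())) == 1  # equal weights

    def test_clamped_species_excluded(self):
        net = ReactionNetwork(
            species=[Species("L", "extracellular", 1.0, clamped=True),
                     Species("R", initial_amount=1.0), Species("C")],
            reactions=[Reaction("R1", [("L", 1), ("R", 1)], [("C", 1)],
                                1.0, 0.1)],
        )
        for w in conserved_moieties(net):
            assert "L" not in w

    def test_moieties_constant_on_signaling_trajectory(self, main_model,
                                                       fgf_trajectory):
        """Every left-null-space vector is constant along a stimulated
        trajectory to 1e-6 relative."""
        mo = conserved_moieties(main_model.network)
        assert mo, "signaling model should have conserved moieties"
        idx = {s: i for i, s in enumerate(fgf_trajectory.species_names)}
        for w in mo:
            tot = sum(wt * fgf_trajectory.amounts[:, idx[sp]]
                      for sp, wt in w.items())
            scale = np.abs(tot[0]) if tot[0] != 0 else 1.0
            assert np.max(np.abs(tot - tot[0])) <= 1e-6 * max(scale, 1.0)


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self, main_model):
        d = network_to_dict(main_model.network)
        back = network_from_dict(d)
        assert network_to_dict(back) == d

    def test_sbml_export_is_valid_xml_with_declared_sizes(self, main_model):
        from lxml import etree

        xml = to_sbml(main_model.network)
        root = etree.fromstring(xml.encode())
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        assert len(root.findall(".//s:species", ns)) == 72
        assert len(root.findall(".//s:reaction", ns)) == 70
        assert len(root.findall(".//s:parameter", ns)) == 75

    def test_validation_rejects_unknown_species(self):
        net = ReactionNetwork(
            species=[Species("A")],
            reactions=[Reaction("R1", [("Z", 1)], [("A", 1)], 1.0)],
        )
        with pytest.raises(NetworkConfigError):
            net.validate()
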