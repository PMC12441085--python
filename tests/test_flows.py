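"""Infection-path enumeration, expected times, the matrix of flows."""

import pytest
import sympy

from epipetri._symbols import symbolic_equal
from epipetri.flows import (
    FlowsNotApplicable,
    check_assumption7,
    enumerate_paths,
    expected_time,
    matrix_of_flows,
    susceptible_flow,
    verify_corollary9,
)


class TestExitClockStructure:
    def test_siwr_shedding_flagged(self, load):
        """The waterborne model's shedding transition returns the infectious
        individual (I -> shed -> I), breaking the exponential exit clock."""
        fx = load("siwr")
        issues = check_assumption7(fx.net, fx.partition)
        assert any("shed" in msg for msg in issues)

    @pytest.mark.parametrize("name", ["sir", "seair", "malaria", "quarantine"])
    def test_clean_models(self, load, name):
        fx = load(name)
        assert check_assumption7(fx.net, fx.partition) == []

    def test_enumeration_refuses_on_violation(self, load):
        fx = load("siwr")
        with pytest.raises(FlowsNotApplicable):
            enumerate_paths(fx.net, fx.partition, dst="I", src="I")


class TestPathEnumeration:
    def test_seair_e_to_e_has_two_loops(self, load):
        """E -> (eta, p) -> I -> (beta) -> E and E -> (eta, 1-p) -> A ->
        (q beta) -> E."""
        fx = load("seair")
        paths = enumerate_paths(fx.net, fx.partition, dst="E", src="E")
        routes = {p.compartments[1:-1] + (p.contact_transition,) for p in paths}
        assert routes == {("I", "infect"), ("A", "infect_a")}
        assert len(paths) == 2

    def test_seair_no_paths_into_a_from_e(self, load):
        """New infections only land in E, so the (A, E) entry is empty."""
        fx = load("seair")
        assert enumerate_paths(fx.net, fx.partition, dst="A", src="E") == []

    def test_malaria_cross_species_path(self, load):
        fx = load("malaria")
        paths = enumerate_paths(fx.net, fx.partition, dst="I_H", src="I_M")
        assert len(paths) == 1
        assert paths[0].contact_transition == "infect_H"
        assert paths[0].compartments == ("I_M", "I_H")

    def test_order_independence(self, load):
        """Enumeration is a set: querying twice gives the same paths."""
        fx = load("scir")
        a = {p for p in enumerate_paths(fx.net, fx.partition, dst="C", src="C")}
        b = {p for p in enumerate_paths(fx.net, fx.partition, dst="C", src="C")}
        assert a == b and len(a) == 2


class TestExpectedTimeAndFlow:
    def test_seair_exposed_to_infectious_loop(self, load):
        """E -> I -> (beta) -> E: E(gamma) = p*eta/((eta+mu)(alpha+mu))."""
        fx = load("seair")
        n = fx.net
        paths = enumerate_paths(fx.net, fx.partition, dst="E", src="E")
        via_i = next(p for p in paths if "I" in p.compartments)
        E = expected_time(fx.net, fx.partition, via_i)
        assert symbolic_equal(E, n.parse("p*eta/((eta+mu)*(alpha+mu))"))

    def test_seair_asymptomatic_entry(self, load):
        """A -> (q beta) -> E waits only in A: E(gamma) = 1/(gamma+mu)."""
        fx = load("seair")
        (p,) = enumerate_paths(fx.net, fx.partition, dst="E", src="A")
        E = expected_time(fx.net, fx.partition, p)
        assert symbolic_equal(E, 1 / (fx.net.var("gamma") + fx.net.var("mu")))

    def test_sir_loop_time_is_infectious_period(self, load):
        fx = load("sir")
        (p,) = enumerate_paths(fx.net, fx.partition, dst="I", src="I")
        assert symbolic_equal(
            expected_time(fx.net, fx.partition, p), 1 / fx.net.var("alpha")
        )

    def test_susceptible_flows_at_dfe(self, load):
        """SEAIR: beta*S through the symptomatic contact, q*beta*S through the
        asymptomatic one; the vaccination model routes beta*S/N and
        beta*delta*V/N through its two valves."""
        fx = load("seair")
        dfe = fx.dfe()
        paths = enumerate_paths(fx.net, fx.partition, dst="E", src="E")
        flows = {
            p.contact_transition: susceptible_flow(fx.net, fx.partition, p, dfe)
            for p in paths
        }
        n = fx.net
        assert symbolic_equal(flows["infect"], n.parse("beta*S"))
        assert symbolic_equal(flows["infect_a"], n.parse("q*beta*S"))

        fx2 = load("vaccination2")
        dfe2 = fx2.dfe()
        paths2 = enumerate_paths(fx2.net, fx2.partition, dst="I", src="I")
        flows2 = {
            p.contact_transition: susceptible_flow(fx2.net, fx2.partition, p, dfe2)
            for p in paths2
        }
        n2 = fx2.net
        assert symbolic_equal(flows2["infect_s"], n2.parse("beta*mu/(mu+psi)"))
        assert symbolic_equal(
            flows2["infect_v"], n2.parse("beta*delta*psi/(mu+psi)")
        )

    def test_every_expected_time_is_positive(self, load):
        """E(gamma) is a ratio of positive parameter products."""
        for name in ("seair", "scir", "table6_seir_variant"):
            fx = load(name)
            reg = fx.net.registry()
            for dst in fx.partition.s_i:
                for src in fx.partition.s_i:
                    for p in enumerate_paths(fx.net, fx.partition, dst=dst, src=src):
                        E = expected_time(fx.net, fx.partition, p)
                        assert reg.is_nonnegative(E) is True


class TestMatrixOfFlows:
    def test_seair_flow_matrix_equals_printed_ngm(self, load):
        fx = load("seair")
        flow = matrix_of_flows(fx.net, fx.partition, fx.dfe())
        K = fx.golden_K
        assert all(
            symbolic_equal(flow.M[i, j], K[i, j])
            for i in range(K.rows) for j in range(K.cols)
        )

    def test_malaria_zero_diagonal(self, load):
        fx = load("malaria")
        flow = matrix_of_flows(fx.net, fx.partition, fx.dfe())
        assert flow.M[0, 0] == 0 and flow.M[1, 1] == 0
        K = fx.golden_K
        assert symbolic_equal(flow.M[0, 1], K[0, 1])
        assert symbolic_equal(flow.M[1, 0], K[1, 0])

    def test_vaccination1_single_entry(self, load):
        """With the solved equilibrium S = qN the unique loop carries
        beta*q*N/(mu+alpha)."""
        fx = load("vaccination1")
        flow = matrix_of_flows(fx.net, fx.partition, fx.dfe())
        assert flow.M.shape == (1, 1)
        assert symbolic_equal(flow.M[0, 0], fx.net.parse("beta*q*N/(mu+alpha)"))

    def test_entry_decomposition_sums_to_entry(self, load):
        fx = load("seair")
        flow = matrix_of_flows(fx.net, fx.partition, fx.dfe())
        for (dst, src), entries in flow.decomposition.items():
            i = flow.order.index(dst)
            j = flow.order.index(src)
            total = sum((S * E for _, S, E in entries), sympy.Integer(0))
            assert symbolic_equal(flow.M[i, j], total)

    def test_flow_matrix_equals_ngm_on_clean_fixtures(self, partitioned_fixtures):
        """The path-sum reconstruction agrees with F V^{-1} symbolically on
        every model with clean exit clocks; the waterborne model refuses."""
        for fx in partitioned_fixtures:
            if fx.flags.get("assumption7_clean"):
                ok, residual = verify_corollary9(fx.net, fx.partition, fx.dfe())
                assert ok, (fx.name, residual)
            else:
                with pytest.raises(FlowsNotApplicable):
                    matrix_of_flows(fx.net, fx.partition, fx.dfe())
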