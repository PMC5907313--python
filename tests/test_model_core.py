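"""Core object model: normalization, rate laws, branch perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liversim import (
    FluxSource,
    ModelDocument,
    Reaction,
    RegulatoryEdge,
    Species,
    compile_model,
    mass_balance_residual,
    reaction_rate,
    set_branch_fraction,
)
from liversim.errors import ModelValidationError, NonNormalizableError

from conftest import make_branch_doc, make_chain_doc


class TestCompile:
    def test_linear_chain_normalizes_to_unit_fluxes(self, chain_model):
        assert chain_model.v0 == pytest.approx([1.0, 1.0])
        res = mass_balance_residual(chain_model, {"A": 1, "B": 1, "sink": 1})
        assert max(abs(v) for v in res.values()) <= 1e-12

    def test_branch_fluxes_follow_fractions(self, branch_doc):
        m = compile_model(branch_doc)
        fluxes = dict(zip(m.reaction_ids, m.v0))
        assert fluxes["rB"] == pytest.approx(0.5)
        assert fluxes["rC"] == pytest.approx(0.5)
        assert fluxes["dB"] == pytest.approx(0.5)

    def test_unresolved_reference_names_offender(self):
        doc = make_chain_doc()
        doc.reactions.append(
            Reaction(id="bad", substrates=[("Xmissing", 1)], products=[])
        )
        with pytest.raises(ModelValidationError, match="Xmissing"):
            compile_model(doc)

    def test_species_without_outflow_is_non_normalizable(self):
        doc = make_chain_doc()
        doc.reactions = [r for r in doc.reactions if r.id != "r2"]  # B accumulates
        with pytest.raises(NonNormalizableError) as err:
            compile_model(doc)
        assert "B" in err.value.species

    def test_branch_fraction_sum_is_checked(self):
        doc = make_branch_doc(f=(0.5, 0.4))
        with pytest.raises(ModelValidationError, match="bp"):
            compile_model(doc)


class TestReactionRate:
    def test_all_ones_state_gives_nominal_flux(self, branch_doc):
        m = compile_model(branch_doc)
        state = {s.id: 1.0 for s in branch_doc.species}
        for rid, v0 in zip(m.reaction_ids, m.v0):
            assert reaction_rate(m, rid, state) == pytest.approx(v0)

    def test_first_order_in_substrate(self, branch_doc):
        # v0 = 0.5 for the branch arm, doubling the substrate doubles the rate
        m = compile_model(branch_doc)
        assert reaction_rate(m, "rB", {"A": 2.0}) == pytest.approx(1.0)

    def test_linear_activator_multiplier(self, chain_doc):
        chain_doc.species.append(Species(id="Act", compartment="liver", role="regulator"))
        chain_doc.flux_sources.append(
            FluxSource(id="syn_Act", target_species="Act", basal_rate=1.0)
        )
        chain_doc.reactions.append(
            Reaction(id="d_act", substrates=[("Act", 1)], products=[])
        )
        chain_doc.regulatory_edges.append(
            RegulatoryEdge(id="e", regulator="Act", target="r1", sign=1, weight=1.0)
        )
        m = compile_model(chain_doc)
        assert reaction_rate(m, "r1", {"A": 1.0, "Act": 2.0}) == pytest.approx(2.0)

    def test_negative_concentration_rejected(self, chain_model):
        with pytest.raises(ValueError, match="negative"):
            reaction_rate(chain_model, "r1", {"A": -0.1})

    def test_removing_neutral_edge_changes_no_nominal_flux(self, chain_doc):
        with_edge = chain_doc.copy()
        with_edge.species.append(Species(id="Act", compartment="liver", role="regulator"))
        with_edge.flux_sources.append(
            FluxSource(id="syn_Act", target_species="Act", basal_rate=1.0)
        )
        with_edge.reactions.append(
            Reaction(id="d_act", substrates=[("Act", 1)], products=[])
        )
        with_edge.regulatory_edges.append(
            RegulatoryEdge(id="e", regulator="Act", target="r1", sign=-1, weight=0.7)
        )
        m_plain = compile_model(chain_doc)
        m_edge = compile_model(with_edge)
        ones = {s.id: 1.0 for s in with_edge.species}
        for rid in m_plain.reaction_ids:
            assert reaction_rate(m_edge, rid, ones) == pytest.approx(
                reaction_rate(m_plain, rid, {k: 1.0 for k in ("A", "B", "sink")})
            )


class TestSetBranchFraction:
    def test_two_way_proportional_rescale(self, branch_doc):
        m = compile_model(branch_doc)
        m2 = set_branch_fraction(m, "bp", "rB", 0.525)
        assert m2.fractions["bp"]["rB"] == pytest.approx(0.525)
        assert m2.fractions["bp"]["rC"] == pytest.approx(0.475)
        # original untouched
        assert m.fractions["bp"]["rB"] == pytest.approx(0.5)

    def test_three_way_proportional_rescale(self):
        doc = make_branch_doc()
        doc.species.append(Species(id="D", compartment="liver"))
        doc.reactions += [
            Reaction(id="rD", substrates=[("A", 1)], products=[("D", 1)]),
            Reaction(id="dD", substrates=[("D", 1)], products=[("sink", 1)]),
        ]
        doc.branch_points[0].fractions = {"rB": 0.2, "rC": 0.3, "rD": 0.5}
        m = compile_model(doc)
        m2 = set_branch_fraction(m, "bp", "rB", 0.24)
        assert m2.fractions["bp"]["rB"] == pytest.approx(0.24)
        assert m2.fractions["bp"]["rC"] == pytest.approx(0.285)
        assert m2.fractions["bp"]["rD"] == pytest.approx(0.475)

    def test_identity_perturbation_is_noop(self, branch_doc):
        m = compile_model(branch_doc)
        m2 = set_branch_fraction(m, "bp", "rB", 0.5)
        assert m2.fractions == m.fractions

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_fraction_domain_enforced(self, branch_doc, bad):
        m = compile_model(branch_doc)
        with pytest.raises(ValueError):
            set_branch_fraction(m, "bp", "rB", bad)

    def test_unknown_ids_raise_key_error(self, branch_doc):
        m = compile_model(branch_doc)
        with pytest.raises(KeyError):
            set_branch_fraction(m, "nope", "rB", 0.4)
        with pytest.raises(KeyError):
            set_branch_fraction(m, "bp", "nope", 0.4)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["rB", "rC"]),
                              st.floats(0.05, 0.95)), min_size=1, max_size=8))
    def test_branch_closure_under_any_perturbation_sequence(self, moves):
        m = compile_model(make_branch_doc())
        for rid, f in moves:
            m = set_branch_fraction(m, "bp", rid, f)
            assert abs(sum(m.fractions["bp"].values()) - 1.0) <= 1e-12


class TestMassBalance:
    def test_doubled_intermediate_drains(self, chain_model):
        res = mass_balance_residual(chain_model, {"A": 1, "B": 2, "sink": 1})
        assert res["B"] < 0  # outflow exceeds inflow
        assert res["A"] == pytest.approx(0.0, abs=1e-12)

    def test_boundary_species_excluded(self, chain_model):
        res = mass_balance_residual(chain_model, {"A": 1, "B": 1, "sink": 1})
        assert "sink" not in res

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_source_scaling_scales_nominal_fluxes(self, c):
        base = compile_model(make_branch_doc())
        scaled_doc = make_branch_doc()
        for src in scaled_doc.flux_sources:
            src.basal_rate *= c
        scaled = compile_model(scaled_doc)
        assert np.allclose(scaled.v0, c * base.v0, rtol=1e-12)
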