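"""Control coefficients: difference quotient, scans, rankings, sex comparison."""

import logging

import pytest

from liversim import (
    SensitivityAnalysis,
    SexConfiguration,
    classify_high_sensitivity,
    compare_sexes,
    configure_sex,
    control_coefficient,
    generate_toy_branch_network,
    scan_parameter,
)
from liversim.document import HormoneProfile, RegulatoryEdge
from liversim.errors import EmptyScanError, ModelValidationError


class TestControlCoefficient:
    @pytest.mark.parametrize(
        "x_star,x,f_star,f,expected",
        [
            (1.2, 1.0, 1.1, 1.0, 2.0),
            (1.0, 1.0, 1.3, 1.0, 0.0),
            (0.9, 1.0, 1.05, 1.0, -2.0),
        ],
    )
    def test_difference_quotient(self, x_star, x, f_star, f, expected):
        assert control_coefficient(x_star, x, f_star, f) == pytest.approx(expected)

    def test_equal_fractions_rejected(self):
        with pytest.raises(ZeroDivisionError):
            control_coefficient(1.2, 1.0, 0.5, 0.5)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            control_coefficient(1.2, 0.0, 0.6, 0.5)


class TestToyOracle:
    @pytest.mark.parametrize("fractions", [(0.5, 0.5), (0.2, 0.8), (0.2, 0.3, 0.5)])
    def test_scan_matches_analytic_coefficients(self, fractions):
        doc, analytic = generate_toy_branch_network(list(fractions), chain_depth=2)
        engine = SensitivityAnalysis(doc, sex=None, challenge=None)
        for (bid, terminal), expected in analytic.items():
            rec = engine.record(bid, terminal)
            assert rec.headline == pytest.approx(expected, abs=1e-3)
            # exactness at every increment implies first-order convergence
            for c in rec.per_increment.values():
                assert c == pytest.approx(expected, abs=1e-3)

    def test_same_branch_positive_cross_branch_negative(self):
        doc, _ = generate_toy_branch_network([0.4, 0.6], chain_depth=1)
        engine = SensitivityAnalysis(doc, None, None)
        same = engine.record("b0", "chain0_s1")
        cross = engine.record("b0", "chain1_s1")
        assert all(c > 0 for c in same.per_increment.values())
        assert all(c < 0 for c in cross.per_increment.values())

    def test_oversized_increment_skipped_with_warning(self, caplog):
        doc, _ = generate_toy_branch_network([0.8, 0.2], chain_depth=1)
        with caplog.at_level(logging.WARNING, logger="liversim.mca"):
            rec = scan_parameter(doc, None, "b0", "chain0_s1", challenge=None)
        # 0.8 * 1.30 > 1: the 30% increment must be absent
        assert 30.0 not in rec.per_increment
        assert 25.0 not in rec.per_increment  # 0.8*1.25 = 1.0 also invalid
        assert 20.0 in rec.per_increment
        assert any("skipping" in r.message for r in caplog.records)

    def test_all_increments_skipped_raises(self):
        doc, _ = generate_toy_branch_network([0.96, 0.04], chain_depth=1)
        with pytest.raises(EmptyScanError):
            scan_parameter(doc, None, "b0", "chain0_s1", challenge=None)

    def test_headline_is_smallest_increment(self):
        doc, _ = generate_toy_branch_network([0.3, 0.7], chain_depth=1)
        rec = scan_parameter(doc, None, "b0", "chain0_s1", challenge=None)
        assert rec.headline == rec.per_increment[5.0]


class TestClassifyAndCompare:
    def _recs(self, headlines, sex="male"):
        from liversim.mca import SensitivityRecord

        return [
            SensitivityRecord(pid, "X", sex, {5.0: c}) for pid, c in headlines.items()
        ]

    def test_threshold_uses_absolute_value(self):
        table = self._recs({"a": 2.0, "b": 0.5, "c": -1.5})
        assert classify_high_sensitivity(table) == {"a", "c"}

    def test_no_exceedance_gives_empty_set(self):
        assert classify_high_sensitivity(self._recs({"a": 0.2})) == set()

    def test_identical_tables_rank_lexicographically(self):
        m = self._recs({"b": 1.0, "a": 2.0})
        f = self._recs({"b": 1.0, "a": 2.0}, sex="female")
        table = compare_sexes(m, f)
        assert [row[0] for row in table.rows] == ["a", "b"]
        assert all(row[3] == 0.0 for row in table.rows)

    def test_largest_difference_ranks_first(self):
        m = self._recs({"p": 1.0, "q": 3.0})
        f = self._recs({"p": 2.0, "q": 3.0}, sex="female")
        table = compare_sexes(m, f)
        assert table.rows[0][0] == "p"
        assert table.rows[0][3] == pytest.approx(1.0)

    def test_parameter_mismatch_reports_difference(self):
        m = self._recs({"p": 1.0})
        f = self._recs({"q": 1.0}, sex="female")
        with pytest.raises(ModelValidationError, match="q"):
            compare_sexes(m, f)


class TestRegulatorRanking:
    def test_stronger_edge_weight_ranks_higher(self):
        from liversim.document import FluxSource, Reaction, Species

        doc, _ = generate_toy_branch_network([0.5, 0.5], chain_depth=1)
        for rid, weight in (("R1", 0.8), ("R2", 0.4)):
            doc.species.append(Species(id=rid, compartment="liver", role="regulator"))
            doc.flux_sources.append(
                FluxSource(id=f"syn_{rid}", target_species=rid, basal_rate=0.5)
            )
            doc.reactions.append(
                Reaction(id=f"d_{rid}", substrates=[(rid, 1)], products=[])
            )
            doc.regulatory_edges.append(
                RegulatoryEdge(id=f"e_{rid}", regulator="chain0_s1",
                               target=f"syn_{rid}", sign=1, weight=weight)
            )
        doc.validate()
        engine = SensitivityAnalysis(doc, None, None)
        assert engine.top_regulators("b0", 2) == ["R1", "R2"]
        # k capped at the number of declared regulators
        assert engine.top_regulators("b0", 5) == ["R1", "R2"]


class TestSexSymmetryNull:
    def test_identical_configurations_give_identical_tables(self, hormone_doc):
        cfg = SexConfiguration(
            sex="null",
            profiles={
                "growth_hormone": HormoneProfile("growth_hormone", "constant", 1.0),
                "androgen": HormoneProfile("androgen", "constant", 1.0),
                "estrogen": HormoneProfile("estrogen", "constant", 1.0),
            },
        )
        tables = {}
        for label in ("male", "female"):
            doc = configure_sex(hormone_doc, label, config=cfg)
            engine = SensitivityAnalysis(doc, sex=None, challenge=None)
            tables[label] = engine.table("LipidA")
        for rm, rf in zip(tables["male"], tables["female"]):
            assert rm.parameter_id == rf.parameter_id
            assert abs(rm.headline - rf.headline) <= 1e-9


class TestReferenceFiniteDifference:
    def test_headline_consistent_with_centered_difference(self, reference_doc):
        """The 5% one-sided protocol coefficient should agree within 5% with a
        +-1% centered-difference derivative estimate on the reference network."""
        engine = SensitivityAnalysis(reference_doc, "male",
                                     increments=(1.0, 5.0))
        rec = engine.record("k159", "TG_hepatic_droplet")
        bid = engine.model.branch_of["k159"]
        f0 = engine.model.fractions[bid]["k159"]
        x0 = engine.baseline.concentrations["TG_hepatic_droplet"]
        up = engine.perturbed("k159", 1.0).concentrations["TG_hepatic_droplet"]
        down_model = engine.model.with_branch_fraction(bid, "k159", f0 * 0.99)
        from liversim import solve_steady_state

        down = solve_steady_state(
            down_model, initial_state=engine.baseline.concentrations
        ).concentrations["TG_hepatic_droplet"]
        centered = (up - down) / (0.02 * f0) * (f0 / x0)
        assert rec.headline == pytest.approx(centered, rel=0.05)
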