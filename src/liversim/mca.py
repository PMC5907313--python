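"""Metabolic control analysis of branch-point flux-distribution parameters.

The concentration control coefficient of a flux-distribution parameter ``f``
with respect to an observed concentration ``X`` is the normalized difference
quotient

    C_f^X = ((X* - X) / (f* - f)) * (f / X),

evaluated between the nominal steady state and the steady state after the
fraction is perturbed to ``f* = f (1 + delta)`` (siblings rescaled
proportionally).  The scan protocol raises the triglyceride influx 10-fold to
imitate a high-fat diet, then varies each branch fraction incrementally by 5%
up to 30%.  With hepatic triglycerides as the output the coefficient is
written CfTG; with a regulatory factor R as the output, CfR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .document import ModelDocument
from .errors import EmptyScanError, ModelValidationError
from .hormones import configure_sex
from .model import compile_model, set_branch_fraction
from .simulate import DietSpec, apply_diet, solve_steady_state

log = logging.getLogger(__name__)

DEFAULT_INCREMENTS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

__all__ = [
    "SensitivityRecord",
    "SexComparisonTable",
    "SensitivityAnalysis",
    "control_coefficient",
    "scan_parameter",
    "mca_table",
    "classify_high_sensitivity",
    "compare_sexes",
    "top_regulators",
]


def control_coefficient(x_star: float, x: float, f_star: float, f: float) -> float:
    """Normalized concentration control coefficient (difference-quotient form)."""
    if f_star == f:
        raise ZeroDivisionError("f_star must differ from f")
    if x <= 0 or f <= 0:
        raise ValueError("nominal concentration and fraction must be positive")
    return (x_star - x) / (f_star - f) * (f / x)


@dataclass
class SensitivityRecord:
    parameter_id: str
    output_id: str
    sex: str
    per_increment: dict  # percent increment -> coefficient
    headline: float = field(init=False)
    aggregate_mean: float = field(init=False)
    aggregate_max: float = field(init=False)

    def __post_init__(self):
        if not self.per_increment:
            raise EmptyScanError(
                f"no usable increments for parameter {self.parameter_id!r}"
            )
        smallest = min(self.per_increment)
        self.headline = self.per_increment[smallest]
        vals = list(self.per_increment.values())
        self.aggregate_mean = sum(vals) / len(vals)
        self.aggregate_max = max(vals, key=abs)


@dataclass
class SexComparisonTable:
    """Rows (parameter, C_male, C_female, |difference|), largest difference first."""

    rows: list  # (parameter_id, c_male, c_female, abs_difference)


class SensitivityAnalysis:
    """Shared engine for coefficient scans on one (document, sex, challenge).

    Solving the perturbed steady states dominates the cost, and the same
    states serve any number of output species, so the engine caches them:
    a full CfTG table and a CfR regulator query reuse each other's solves.
    """

    def __init__(self, doc: ModelDocument, sex=None,
                 challenge: DietSpec | None = DietSpec.tg_challenge(10.0),
                 increments=DEFAULT_INCREMENTS):
        d = configure_sex(doc, sex) if sex is not None else doc.copy()
        if challenge is not None:
            d = apply_diet(d, challenge)
        self.sex = sex or "unspecified"
        self.increments = tuple(increments)
        self.model = compile_model(d)
        self.baseline = solve_steady_state(self.model)
        self._states = {}  # (reaction_id, percent) -> SteadyStateResult or None

    # -- internals -----------------------------------------------------
    def _branch_for(self, reaction_id):
        bid = self.model.branch_of.get(reaction_id)
        if bid is None:
            raise ModelValidationError(
                f"reaction {reaction_id!r} is not a branch-point member"
            )
        return bid

    def perturbed(self, reaction_id, percent):
        """Steady state with f* = f (1 + percent/100); None if f* >= 1."""
        key = (reaction_id, float(percent))
        if key in self._states:
            return self._states[key]
        bid = self._branch_for(reaction_id)
        f0 = self.model.fractions[bid][reaction_id]
        f_star = f0 * (1.0 + percent / 100.0)
        if f_star >= 1.0:
            log.warning(
                "skipping %s%% increment of %s: f* = %.6f >= 1",
                percent, reaction_id, f_star,
            )
            self._states[key] = None
            return None
        m = set_branch_fraction(self.model, bid, reaction_id, f_star)
        res = solve_steady_state(m, initial_state=self.baseline.concentrations)
        self._states[key] = res
        return res

    # -- spec operations -------------------------------------------------
    def record(self, reaction_id, output_id) -> SensitivityRecord:
        if output_id not in self.model.sidx:
            raise ModelValidationError(f"unknown output species {output_id!r}")
        bid = self._branch_for(reaction_id)
        f0 = self.model.fractions[bid][reaction_id]
        x0 = self.baseline.concentrations[output_id]
        per = {}
        for pct in self.increments:
            res = self.perturbed(reaction_id, pct)
            if res is None:
                continue
            f_star = f0 * (1.0 + pct / 100.0)
            per[pct] = control_coefficient(
                res.concentrations[output_id], x0, f_star, f0
            )
        if not per:
            raise EmptyScanError(
                f"every increment of {reaction_id!r} was skipped (f too close to 1)"
            )
        return SensitivityRecord(reaction_id, output_id, self.sex, per)

    def branch_parameters(self):
        out = []
        for b in self.model.doc.branch_points:
            out.extend(b.fractions)
        return sorted(out)

    def table(self, output_id) -> list:
        records = [self.record(rid, output_id) for rid in self.branch_parameters()]
        records.sort(key=lambda r: (-abs(r.headline), r.parameter_id))
        return records

    def top_regulators(self, reaction_id, k=5) -> list:
        regulators = sorted(
            s.id for s in self.model.doc.species if s.role == "regulator"
        )
        if len(regulators) < k:
            log.warning(
                "only %d regulator species declared; returning all", len(regulators)
            )
        recs = [self.record(reaction_id, rid) for rid in regulators]
        recs.sort(key=lambda r: (-abs(r.headline), r.output_id))
        return [r.output_id for r in recs[: min(k, len(recs))]]


# -- functional wrappers ---------------------------------------------------

def scan_parameter(doc, sex, reaction_id, output_id,
                   increments=DEFAULT_INCREMENTS,
                   challenge: DietSpec | None = DietSpec.tg_challenge(10.0),
                   engine: SensitivityAnalysis | None = None) -> SensitivityRecord:
    """Incremental perturbation scan of one branch parameter for one output."""
    if engine is None:
        engine = SensitivityAnalysis(doc, sex, challenge, increments)
    return engine.record(reaction_id, output_id)


def mca_table(doc, sex, output_id,
              challenge: DietSpec | None = DietSpec.tg_challenge(10.0),
              increments=DEFAULT_INCREMENTS,
              engine: SensitivityAnalysis | None = None) -> list:
    """One record per branch-member reaction, sorted by |headline| descending."""
    if engine is None:
        engine = SensitivityAnalysis(doc, sex, challenge, increments)
    return engine.table(output_id)


def classify_high_sensitivity(table, threshold: float = 1.0) -> set:
    """Parameters with |headline coefficient| above the threshold.

    The absolute value is used so that a sign convention (e.g. coefficients
    of export branches are negative for an accumulating output) cannot
    silently drop a highly sensitive reaction.
    """
    return {r.parameter_id for r in table if abs(r.headline) > threshold}


def compare_sexes(male_table, female_table) -> SexComparisonTable:
    """Join per-sex tables and rank by |C_male - C_female| descending."""
    male = {r.parameter_id: r.headline for r in male_table}
    female = {r.parameter_id: r.headline for r in female_table}
    if set(male) != set(female):
        only_m = sorted(set(male) - set(female))
        only_f = sorted(set(female) - set(male))
        raise ModelValidationError(
            f"parameter sets differ between sexes (male only: {only_m}, "
            f"female only: {only_f})"
        )
    rows = [
        (pid, male[pid], female[pid], abs(male[pid] - female[pid]))
        for pid in male
    ]
    rows.sort(key=lambda row: (-row[3], row[0]))
    return SexComparisonTable(rows=rows)


def top_regulators(doc, sex, reaction_id, k: int = 5,
                   challenge: DietSpec | None = DietSpec.tg_challenge(10.0),
                   engine: SensitivityAnalysis | None = None) -> list:
    """The k regulators whose CfR responds most to the branch perturbation."""
    if engine is None:
        engine = SensitivityAnalysis(doc, sex, challenge)
    return engine.top_regulators(reaction_id, k)
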