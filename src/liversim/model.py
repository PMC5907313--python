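"""Compilation of a model document into an executable normalized network.

The central construction is steady-state normalization: nominal fluxes
``v0_j`` are solved from linear flux balance at the all-ones state given the
source strengths and branch-point fractions, and every rate law is anchored so
that the all-ones state is a steady state.  The rate of reaction ``j`` is

    v_j = (f_j / f0_j) * v0_j * prod_s x_s^n_s * prod_m g(x_m)

with ``g(x) = 1 + w (x - 1)`` for activators and ``g(x) = 1 / (1 + w (x - 1))``
for inhibitors (``g`` clipped to ``[G_MIN, 1/G_MIN]``), and ``f_j / f0_j = 1``
for reactions that are not branch members.  All kinetic constants are lumped
into ``v0_j`` by the normalization, so branch fractions, regulation weights
and source strengths are the only free dynamical parameters.
"""

from __future__ import annotations

import copy

import numpy as np

from .document import ModelDocument
from .errors import ModelValidationError, NonNormalizableError

G_MIN = 1e-6

__all__ = [
    "Model",
    "compile_model",
    "reaction_rate",
    "set_branch_fraction",
    "mass_balance_residual",
    "G_MIN",
]


def _g_scalar(x, sign, weight):
    d = 1.0 + weight * (x - 1.0)
    if sign > 0:
        g = d
    else:
        g = 1.0 / d if d > G_MIN else 1.0 / G_MIN
    return min(max(g, G_MIN), 1.0 / G_MIN)


def _g_array(x, sign, weight):
    d = 1.0 + weight * (x - 1.0)
    g = np.where(sign > 0, d, 1.0 / np.maximum(d, G_MIN))
    return np.minimum(np.maximum(g, G_MIN), 1.0 / G_MIN)


class Model:
    """Executable model produced by :func:`compile_model`.

    Holds the validated document, the solved nominal fluxes, the current
    branch fractions and vectorized index structures for fast rate/RHS
    evaluation.  Instances are treated as immutable; branch perturbations
    return modified copies.
    """

    def __init__(self, doc: ModelDocument):
        self.doc = doc
        self.species_ids = [s.id for s in doc.species]
        self.sidx = {sid: i for i, sid in enumerate(self.species_ids)}
        self.reaction_ids = [r.id for r in doc.reactions]
        self.ridx = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.ns = len(self.species_ids)
        self.nr = len(self.reaction_ids)

        roles = {s.id: s.role for s in doc.species}
        self.boundary = np.array([s.is_boundary for s in doc.species], dtype=bool)
        self.algebraic = np.array(
            [roles[sid] in ("receptor_active", "receptor_inactive") for sid in self.species_ids],
            dtype=bool,
        )
        receptor_species = {
            p.active_species for p in doc.receptor_pairs
        } | {p.inactive_species for p in doc.receptor_pairs}
        for sid in self.species_ids:
            if roles[sid].startswith("receptor") and sid not in receptor_species:
                raise ModelValidationError(
                    f"receptor species {sid!r} is not part of any receptor pair"
                )
        self.dynamic = ~(self.boundary | self.algebraic)
        self.dynamic_idx = np.flatnonzero(self.dynamic)

        # stoichiometry matrix (ns x nr)
        S = np.zeros((self.ns, self.nr))
        for j, r in enumerate(doc.reactions):
            for sid, st in r.substrates:
                S[self.sidx[sid], j] -= st
            for sid, st in r.products:
                S[self.sidx[sid], j] += st
        self.S = S

        # substrate factors as flat arrays for vectorized products
        sub_r, sub_s, sub_e = [], [], []
        for j, r in enumerate(doc.reactions):
            for sid, st in r.substrates:
                sub_r.append(j)
                sub_s.append(self.sidx[sid])
                sub_e.append(float(st))
        self._sub_r = np.asarray(sub_r, dtype=np.intp)
        self._sub_s = np.asarray(sub_s, dtype=np.intp)
        self._sub_e = np.asarray(sub_e)

        # regulatory edges on reactions
        edges = doc.edges_by_id()
        mod_r, mod_s, mod_sign, mod_w = [], [], [], []
        for j, r in enumerate(doc.reactions):
            for eid in r.modifiers:
                e = edges[eid]
                mod_r.append(j)
                mod_s.append(self.sidx[e.regulator])
                mod_sign.append(e.sign)
                mod_w.append(e.weight)
        self._mod_r = np.asarray(mod_r, dtype=np.intp)
        self._mod_s = np.asarray(mod_s, dtype=np.intp)
        self._mod_sign = np.asarray(mod_sign)
        self._mod_w = np.asarray(mod_w)

        # sources: mean strengths plus optional hormone waveforms and edges
        profiles = {p.hormone: p for p in doc.hormone_profiles}
        hormone_species = {
            s.id for s in doc.species if s.role == "hormone"
        }
        source_edges = {}
        sources_by_id = doc.sources_by_id()
        rx_ids = set(self.ridx)
        for e in doc.regulatory_edges:
            if e.target in sources_by_id:
                source_edges.setdefault(e.target, []).append(e)
            elif e.target not in rx_ids and e.target in self.sidx:
                # species-target edges also act on sources feeding the species
                for src in doc.flux_sources:
                    if src.target_species == e.target:
                        source_edges.setdefault(src.id, []).append(e)
        # Normalization is anchored at the basal (chow, mean-waveform) state:
        # multipliers (diets, challenges) act as post-normalization forcing and
        # are NOT absorbed into the nominal fluxes.
        self.sources = []  # (sp_idx, basal, multiplier, profile, [(reg_idx, sign, w)])
        for src in doc.flux_sources:
            prof = None
            if src.target_species in hormone_species:
                prof = profiles.get(src.target_species)
            eds = [
                (self.sidx[e.regulator], e.sign, e.weight)
                for e in source_edges.get(src.id, [])
            ]
            self.sources.append(
                (self.sidx[src.target_species], src.basal_rate, src.multiplier, prof, eds)
            )
        # vectorized source evaluation structures
        self._src_rows = np.asarray([s[0] for s in self.sources], dtype=np.intp)
        self._src_base = np.asarray([s[1] * s[2] for s in self.sources])
        self._src_prof = [
            (k, s[3]) for k, s in enumerate(self.sources) if s[3] is not None
        ]
        se_pos, se_reg, se_sign, se_w = [], [], [], []
        for k, (_i, _b, _m, _p, eds) in enumerate(self.sources):
            for reg_i, sign, w in eds:
                se_pos.append(k)
                se_reg.append(reg_i)
                se_sign.append(sign)
                se_w.append(w)
        self._se_pos = np.asarray(se_pos, dtype=np.intp)
        self._se_reg = np.asarray(se_reg, dtype=np.intp)
        self._se_sign = np.asarray(se_sign)
        self._se_w = np.asarray(se_w)

        # receptor algebra (normalized so the nominal active level is 1)
        self.receptors = []  # (hormone_idx, active_idx, inactive_idx, K, total)
        for p in doc.receptor_pairs:
            h_sid = p.hormone  # hormone species id equals the hormone name
            if h_sid not in self.sidx:
                raise ModelValidationError(
                    f"receptor pair for {p.hormone!r}: hormone species "
                    f"{h_sid!r} missing from the document"
                )
            self.receptors.append(
                (
                    self.sidx[h_sid],
                    self.sidx[p.active_species],
                    self.sidx[p.inactive_species],
                    p.half_saturation,
                    p.total,
                )
            )

        # branch bookkeeping: current fractions and nominal fractions
        self.branch_of = {}  # reaction id -> branch id
        self.fractions = {}  # branch id -> {reaction id: f}
        for b in doc.branch_points:
            self.fractions[b.id] = dict(b.fractions)
            for rid in b.fractions:
                self.branch_of[rid] = b.id
        self.f0 = {bid: dict(fr) for bid, fr in self.fractions.items()}

        self.v0 = self._solve_nominal_fluxes()
        for r, v in zip(doc.reactions, self.v0):
            r.nominal_flux = float(v)
        self._update_f_ratio()

        active = [
            p
            for p in doc.hormone_profiles
            if p.kind != "constant" and p.amplitude > 0
        ]
        #: longest period among active (oscillating) hormone profiles
        self.forcing_period = max((p.period_hours for p in active), default=None)

    # ------------------------------------------------------------------
    def _update_f_ratio(self):
        ratio = np.ones(self.nr)
        for bid, fr in self.fractions.items():
            for rid, f in fr.items():
                ratio[self.ridx[rid]] = f / self.f0[bid][rid]
        self._f_ratio = ratio

    def _solve_nominal_fluxes(self):
        """Linear flux balance at the all-ones state.

        Unknowns are one total outflow per branch point plus one flux per
        non-branch reaction; branch members are tied to the total by their
        fractions.  The solution must balance every dynamic species and be
        strictly positive, otherwise the model is not normalizable.
        """
        doc = self.doc
        branch_ids = [b.id for b in doc.branch_points]
        bpos = {bid: k for k, bid in enumerate(branch_ids)}
        free = [r.id for r in doc.reactions if r.id not in self.branch_of]
        fpos = {rid: len(branch_ids) + k for k, rid in enumerate(free)}
        nunk = len(branch_ids) + len(free)

        balance_rows = self.dynamic_idx
        A = np.zeros((len(balance_rows), nunk))
        b = np.zeros(len(balance_rows))
        rowpos = {int(i): k for k, i in enumerate(balance_rows)}

        for j, rid in enumerate(self.reaction_ids):
            if rid in self.branch_of:
                bid = self.branch_of[rid]
                col = bpos[bid]
                coef = self.f0[bid][rid]
            else:
                col = fpos[rid]
                coef = 1.0
            for i in np.flatnonzero(self.S[:, j]):
                if int(i) in rowpos:
                    A[rowpos[int(i)], col] += coef * self.S[i, j]
        for sp_i, basal, _mult, _prof, _eds in self.sources:
            if sp_i in rowpos:
                b[rowpos[sp_i]] -= basal

        if nunk == 0:
            resid = -b
        else:
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            resid = A @ sol - b
        bad = [
            self.species_ids[int(balance_rows[k])]
            for k in np.flatnonzero(np.abs(resid) > 1e-9)
        ]
        if bad:
            raise NonNormalizableError(
                "non-normalizable model: no flux balance at the all-ones state "
                f"for species {bad}",
                species=bad,
            )
        v0 = np.empty(self.nr)
        for j, rid in enumerate(self.reaction_ids):
            if rid in self.branch_of:
                bid = self.branch_of[rid]
                v0[j] = self.f0[bid][rid] * sol[bpos[bid]]
            else:
                v0[j] = sol[fpos[rid]]
        if np.any(v0 <= MIN_POSITIVE_FLUX):
            bad = [self.reaction_ids[j] for j in np.flatnonzero(v0 <= MIN_POSITIVE_FLUX)]
            raise NonNormalizableError(
                f"non-normalizable model: non-positive nominal flux for {bad}",
                species=bad,
            )
        return v0

    # ------------------------------------------------------------------
    def state_array(self, state=None):
        """Full concentration vector from a mapping (defaults to all ones)."""
        x = np.ones(self.ns)
        if state is not None:
            for sid, val in state.items():
                x[self.sidx[sid]] = val
        return x

    def apply_receptor_algebra(self, x):
        """Overwrite receptor entries with their quasi-steady-state values.

        Species values are normalized, so the active form is scaled by its
        nominal level ``K_ratio = total * 1 / (K + 1)``; conservation of the
        raw pool (active + inactive = total) is exact by construction.
        """
        for h_i, a_i, i_i, K, _total in self.receptors:
            H = max(x[h_i], 0.0)
            x[a_i] = H * (1.0 + K) / (K + H)
            x[i_i] = (1.0 + K) / (K + H)
        return x

    def receptor_raw(self, x):
        """Raw (unnormalized) active/inactive levels per hormone."""
        out = {}
        for h_i, a_i, i_i, K, total in self.receptors:
            H = max(x[h_i], 0.0)
            active = total * H / (K + H)
            out[self.species_ids[a_i]] = active
            out[self.species_ids[i_i]] = total - active
        return out

    def rates(self, x):
        """Vector of reaction rates at the (full) concentration vector x."""
        v = self.v0 * self._f_ratio
        if self._sub_r.size:
            factors = np.power(np.maximum(x[self._sub_s], 0.0), self._sub_e)
            np.multiply.at(v, self._sub_r, factors)
        if self._mod_r.size:
            g = _g_array(x[self._mod_s], self._mod_sign, self._mod_w)
            np.multiply.at(v, self._mod_r, g)
        return v

    def source_vector(self, t=None, x=None):
        """Species influx vector; ``t=None`` uses period-mean source strengths."""
        from .hormones import _scalar_level  # local import to avoid a cycle

        vals = self._src_base.copy()
        if t is not None:
            for k, prof in self._src_prof:
                vals[k] *= _scalar_level(prof, t) / prof.mean_level
        if x is not None and self._se_pos.size:
            g = _g_array(x[self._se_reg], self._se_sign, self._se_w)
            np.multiply.at(vals, self._se_pos, g)
        src = np.zeros(self.ns)
        np.add.at(src, self._src_rows, vals)
        return src

    def rhs(self, t, y, clip_counter=None):
        """Time derivative of the dynamic species (receptors are algebraic)."""
        x = np.ones(self.ns)
        if clip_counter is not None and np.any(y < -1e-9):
            clip_counter[0] += int(np.sum(y < -1e-9))
        x[self.dynamic_idx] = np.maximum(y, 0.0)
        self.apply_receptor_algebra(x)
        v = self.rates(x)
        dx = self.S @ v + self.source_vector(t, x)
        return dx[self.dynamic_idx]

    def full_state(self, y, t=0.0):
        x = np.ones(self.ns)
        x[self.dynamic_idx] = np.maximum(y, 0.0)
        self.apply_receptor_algebra(x)
        return x

    # ------------------------------------------------------------------
    def with_branch_fraction(self, branch_id, reaction_id, f_new):
        """Copy of the model with one branch fraction changed.

        The remaining fractions of the branch are rescaled proportionally so
        the branch still sums to 1, preserving total outflow: a branch
        fraction is a flux *distribution* parameter.
        """
        if branch_id not in self.fractions:
            raise KeyError(branch_id)
        fr = self.fractions[branch_id]
        if reaction_id not in fr:
            raise KeyError(reaction_id)
        if not (0.0 < f_new < 1.0):
            raise ValueError(f"fraction must lie in (0, 1), got {f_new!r}")
        f_old = fr[reaction_id]
        new = copy.copy(self)
        new.fractions = {bid: dict(f) for bid, f in self.fractions.items()}
        scale = (1.0 - f_new) / (1.0 - f_old)
        for rid in new.fractions[branch_id]:
            if rid == reaction_id:
                new.fractions[branch_id][rid] = f_new
            else:
                new.fractions[branch_id][rid] *= scale
        new._update_f_ratio()
        return new


MIN_POSITIVE_FLUX = 1e-9


def compile_model(doc: ModelDocument) -> Model:
    """Validate and normalize a document into an executable :class:`Model`."""
    doc = doc.copy()
    doc.validate()
    return Model(doc)


def reaction_rate(model: Model, reaction_id: str, state) -> float:
    """Rate of one reaction at an explicit concentration mapping."""
    r = model.doc.reactions_by_id()[reaction_id]
    needed = {sid for sid, _ in r.substrates}
    edges = model.doc.edges_by_id()
    needed |= {edges[eid].regulator for eid in r.modifiers}
    for sid in needed:
        if sid not in state:
            raise KeyError(f"state is missing species {sid!r}")
        if state[sid] < 0:
            raise ValueError(f"negative concentration for species {sid!r}")
    j = model.ridx[reaction_id]
    v = model.v0[j] * model._f_ratio[j]
    for sid, st in r.substrates:
        v *= state[sid] ** st
    for eid in r.modifiers:
        e = edges[eid]
        v *= _g_scalar(state[e.regulator], e.sign, e.weight)
    return float(v)


def set_branch_fraction(model: Model, branch_id: str, reaction_id: str, f_new: float) -> Model:
    return model.with_branch_fraction(branch_id, reaction_id, f_new)


def mass_balance_residual(model: Model, state) -> dict:
    """Net production minus consumption per non-boundary dynamic species.

    Sources enter with their period-mean strength, matching the normalization
    contract (oscillatory sources are mean-preserving).  Boundary species and
    algebraic receptor forms are excluded.
    """
    x = model.state_array(state)
    v = model.rates(x)
    net = model.S @ v + model.source_vector(t=None, x=x)
    return {
        model.species_ids[int(i)]: float(net[int(i)])
        for i in model.dynamic_idx
    }
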