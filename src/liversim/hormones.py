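"""Sex-specific hormone sources, receptor activation and sex configuration.

Hormones are grouped into growth hormone, androgens and estrogens, each with
its own source of flux.  The male growth-hormone source is a daily (~24 h)
oscillator while the female source is constant; the female estrogen source
follows the ~monthly (720 h) estrous cycle with a single peak per cycle.  The
male androgen source is 10-fold the estrogen source; in females the androgen
source is three-fold lower than the estrogen source.  Oscillations are
mean-preserving, so the sexes differ in waveform, ratios and the wiring of
active receptors into the liver, not in period-averaged source strength of
growth hormone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks
from scipy.special import i0

from .document import (
    HormoneProfile,
    ModelDocument,
    RegulatoryEdge,
)
from .errors import InsufficientDataError, ModelValidationError

#: concentration shape parameter of the estrous (monthly) bump
ESTROUS_KAPPA = 4.0

__all__ = [
    "SexConfiguration",
    "hormone_level",
    "receptor_activation",
    "configure_sex",
    "dominant_period",
    "default_sex_configuration",
]


def _scalar_level(profile: HormoneProfile, t: float) -> float:
    """Fast scalar waveform evaluation used inside the integrator RHS."""
    if profile.kind == "constant":
        return profile.mean_level
    theta = 2.0 * math.pi * (t - profile.phase_hours) / profile.period_hours
    if profile.kind == "daily_oscillation":
        return profile.mean_level + profile.amplitude * math.cos(theta)
    kappa = ESTROUS_KAPPA
    i0k = _I0_KAPPA
    w = math.exp(kappa * math.cos(theta)) / i0k
    w_max = math.exp(kappa) / i0k
    return profile.mean_level + profile.amplitude * (w - 1.0) / (w_max - 1.0)


_I0_KAPPA = float(i0(ESTROUS_KAPPA))


def hormone_level(profile: HormoneProfile, t_hours: float):
    """Source level at time ``t_hours`` (vectorized over ``t_hours``).

    ``constant`` profiles return the mean; ``daily_oscillation`` is a raised
    cosine; ``monthly_cycle`` is a mean-preserving von-Mises-shaped bump with
    exactly one maximum per period.  The signal is non-negative whenever
    ``amplitude <= mean_level``.
    """
    t = np.asarray(t_hours, dtype=float)
    if profile.kind == "constant":
        out = np.full_like(t, profile.mean_level)
    else:
        theta = 2.0 * math.pi * (t - profile.phase_hours) / profile.period_hours
        if profile.kind == "daily_oscillation":
            out = profile.mean_level + profile.amplitude * np.cos(theta)
        else:  # monthly_cycle
            kappa = ESTROUS_KAPPA
            w = np.exp(kappa * np.cos(theta)) / i0(kappa)  # periodic, mean 1
            w_max = math.exp(kappa) / i0(kappa)
            out = profile.mean_level + profile.amplitude * (w - 1.0) / (w_max - 1.0)
    return float(out) if np.isscalar(t_hours) else out


def receptor_activation(hormone_level_value: float, pair) -> float:
    """Active receptor amount under saturable (quasi-steady-state) binding.

    active = total * H / (K + H); the inactive form is total - active.
    """
    if hormone_level_value < 0:
        raise ValueError("hormone level must be non-negative")
    H = hormone_level_value
    return pair.total * H / (pair.half_saturation + H)


@dataclass
class SexConfiguration:
    """Hormone profiles and receptor wiring for one sex.

    ``edges`` lists the regulatory edges the configuration installs
    (replacing any document edge with the same id): the active-receptor links
    into the liver, the sex-modulated metabolic/gene-regulatory weights, and
    - for females - the estrogen-receptor feedback on the growth-hormone
    source.
    """

    sex: str
    profiles: dict = field(default_factory=dict)  # hormone -> HormoneProfile
    edges: list = field(default_factory=list)  # RegulatoryEdge objects
    er_gh_feedback: bool = False

    def validate(self):
        a = self.profiles["androgen"].mean_level
        e = self.profiles["estrogen"].mean_level
        gh = self.profiles["growth_hormone"]
        if self.sex == "male":
            if abs(a / e - 10.0) > 1e-9:
                raise ModelValidationError("male androgen:estrogen source ratio must be 10")
            if gh.kind != "daily_oscillation":
                raise ModelValidationError("male growth hormone must oscillate daily")
        elif self.sex == "female":
            if abs(e / a - 3.0) > 1e-9:
                raise ModelValidationError("female estrogen:androgen source ratio must be 3")
            if gh.kind != "constant":
                raise ModelValidationError("female growth hormone must be constant")
            if not self.er_gh_feedback:
                raise ModelValidationError(
                    "female configuration requires the ER -> growth hormone feedback"
                )
        else:
            raise ModelValidationError(f"unknown sex {self.sex!r}")
        return self


def default_sex_configuration(sex: str) -> SexConfiguration:
    """Built-in profile set (normalized units: the larger sex-hormone mean is 1)."""
    if sex == "male":
        return SexConfiguration(
            sex="male",
            profiles={
                "growth_hormone": HormoneProfile(
                    "growth_hormone", "daily_oscillation", 1.0, 0.8, 24.0, 0.0
                ),
                "androgen": HormoneProfile("androgen", "constant", 1.0),
                "estrogen": HormoneProfile("estrogen", "constant", 0.1),
            },
        )
    if sex == "female":
        return SexConfiguration(
            sex="female",
            profiles={
                "growth_hormone": HormoneProfile("growth_hormone", "constant", 1.0),
                "androgen": HormoneProfile("androgen", "constant", 1.0 / 3.0),
                "estrogen": HormoneProfile(
                    "estrogen", "monthly_cycle", 1.0, 0.9, 720.0, 360.0
                ),
            },
            er_gh_feedback=True,
        )
    raise ModelValidationError(f"unknown sex {sex!r}")


def _load_metadata_config(doc: ModelDocument, sex: str) -> Optional[SexConfiguration]:
    raw = doc.metadata.get("sex_configurations", {}).get(sex)
    if raw is None:
        return None
    cfg = default_sex_configuration(sex)
    for item in raw.get("edges", []):
        cfg.edges.append(RegulatoryEdge(**item))
    return cfg


def configure_sex(doc: ModelDocument, sex: str, config: Optional[SexConfiguration] = None) -> ModelDocument:
    """Return a new document configured for ``sex``.

    Installs the sex's hormone profiles, sets the hormone source strengths to
    the profile means, installs the configuration's regulatory edges, and for
    females adds the estrogen-receptor feedback on the growth-hormone source.
    The operation is idempotent.
    """
    if config is None:
        # packaged configurations must satisfy the per-sex invariants; an
        # explicitly supplied configuration is a researcher override (e.g. a
        # receptor-dysfunction or symmetry-null experiment) and is used as-is
        config = _load_metadata_config(doc, sex) or default_sex_configuration(sex)
        config.validate()

    new = doc.copy()
    species = new.species_by_id()
    hormone_species = [s for s in new.species if s.role == "hormone"]
    have = {s.id for s in hormone_species}
    missing = [h for h in ("growth_hormone", "androgen", "estrogen") if h not in have]
    if missing:
        raise ModelValidationError(
            f"document lacks hormone species {missing}; cannot configure sex"
        )
    pair_hormones = {p.hormone for p in new.receptor_pairs}
    missing_pairs = [
        h for h in ("growth_hormone", "androgen", "estrogen") if h not in pair_hormones
    ]
    if missing_pairs:
        raise ModelValidationError(
            f"document lacks receptor pairs for {missing_pairs}; cannot configure sex"
        )

    new.hormone_profiles = [
        config.profiles[h] for h in ("growth_hormone", "androgen", "estrogen")
    ]
    gh_source_id = None
    for src in new.flux_sources:
        if src.target_species in have:
            src.basal_rate = config.profiles[src.target_species].mean_level
            if src.target_species == "growth_hormone":
                gh_source_id = src.id

    install = {e.id: e for e in config.edges}
    if config.er_gh_feedback and "er_gh_feedback" not in install:
        er_active = next(
            p.active_species for p in new.receptor_pairs if p.hormone == "estrogen"
        )
        if gh_source_id is None:
            raise ModelValidationError("no growth-hormone source to attach ER feedback")
        install["er_gh_feedback"] = RegulatoryEdge(
            id="er_gh_feedback",
            regulator=er_active,
            target=gh_source_id,
            sign=-1,
            weight=0.5,
        )
    for e in install.values():
        if e.regulator not in species:
            raise ModelValidationError(
                f"sex configuration edge {e.id!r}: unknown regulator {e.regulator!r}"
            )
    kept = [e for e in new.regulatory_edges if e.id not in install]
    new.regulatory_edges = kept + [install[k] for k in sorted(install)]
    new.metadata = dict(new.metadata)
    new.metadata["sex"] = sex
    new.validate()
    return new


def dominant_period(signal, dt_hours: float):
    """Mean spacing of successive local maxima of a sampled signal, in hours.

    Returns ``None`` for (numerically) constant signals.  Raises
    :class:`InsufficientDataError` when fewer than three maxima are present,
    i.e. fewer than ~3 full periods were sampled.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InsufficientDataError("need a 1-d signal with at least 3 samples")
    scale = max(np.max(np.abs(y)), 1.0)
    if np.ptp(y) <= 1e-9 * scale:
        return None
    peaks, _ = find_peaks(y)
    if len(peaks) < 3:
        raise InsufficientDataError(
            f"found {len(peaks)} maxima; need >= 3 full periods in the series"
        )
    return float(np.mean(np.diff(peaks)) * dt_hours)
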