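"""Hormone waveforms, receptor activation, sex configuration, period estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liversim import (
    HormoneProfile,
    ReceptorPair,
    compile_model,
    configure_sex,
    dominant_period,
    hormone_level,
    receptor_activation,
    simulate_timecourse,
)
from liversim.errors import InsufficientDataError, ModelValidationError


class TestWaveforms:
    def test_constant_profile_is_flat(self):
        p = HormoneProfile("growth_hormone", "constant", 1.0)
        assert hormone_level(p, 0.0) == 1.0
        assert hormone_level(p, 137.3) == 1.0

    def test_daily_profile_has_24h_period(self):
        p = HormoneProfile("growth_hormone", "daily_oscillation", 1.0, 0.8, 24.0)
        t = np.arange(0, 96, 0.37)
        assert np.allclose(hormone_level(p, t), hormone_level(p, t + 24.0))

    @pytest.mark.parametrize("phase", [0.0, 123.4, 360.0])
    def test_monthly_profile_single_peak_per_cycle(self, phase):
        p = HormoneProfile("estrogen", "monthly_cycle", 1.0, 0.9, 720.0, phase)
        t = np.arange(0.0, 720.0, 0.1)
        y = hormone_level(p, t)
        # circular maximum count over one full cycle
        maxima = np.flatnonzero((y > np.roll(y, 1)) & (y >= np.roll(y, -1)))
        assert len(maxima) == 1

    @settings(max_examples=25, deadline=None)
    @given(
        kind=st.sampled_from(["daily_oscillation", "monthly_cycle"]),
        mean=st.floats(0.2, 3.0),
        frac=st.floats(0.0, 1.0),
        phase=st.floats(-30.0, 30.0),
    )
    def test_oscillations_are_mean_preserving_and_nonnegative(self, kind, mean, frac, phase):
        period = 24.0 if kind == "daily_oscillation" else 720.0
        p = HormoneProfile("estrogen", kind, mean, frac * mean, period, phase)
        t = np.linspace(0.0, period, 20001)
        y = hormone_level(p, t)
        assert np.all(y >= -1e-12)
        avg = np.trapezoid(y, t) / period
        assert avg == pytest.approx(mean, abs=1e-6)


class TestReceptorActivation:
    pair = ReceptorPair("estrogen", "ER_inactive", "ER_active",
                        half_saturation=2.0, total=1.0)

    def test_zero_hormone_no_activation(self):
        assert receptor_activation(0.0, self.pair) == 0.0

    def test_half_saturation_point(self):
        assert receptor_activation(2.0, self.pair) == pytest.approx(0.5)

    def test_nine_k_gives_ninety_percent(self):
        assert receptor_activation(18.0, self.pair) == pytest.approx(0.9)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            receptor_activation(-1.0, self.pair)

    def test_conservation_along_trajectory(self, hormone_doc):
        model = compile_model(configure_sex(hormone_doc, "male"))
        traj = simulate_timecourse(model, duration_hours=48.0, dt_hours=0.5)
        for k in range(len(traj.t)):
            x = np.array([traj.species[sid][k] for sid in model.species_ids])
            raw = model.receptor_raw(x)
            for pair in model.doc.receptor_pairs:
                total = raw[pair.active_species] + raw[pair.inactive_species]
                assert total == pytest.approx(pair.total, abs=1e-12)
                # normalized forms recombine to the conserved raw pool
                K = pair.half_saturation
                act = traj.species[pair.active_species][k] / (1.0 + K)
                inact = traj.species[pair.inactive_species][k] * K / (1.0 + K)
                assert act + inact == pytest.approx(pair.total, abs=1e-9)


class TestConfigureSex:
    def test_male_androgen_to_estrogen_source_ratio_is_ten(self, hormone_doc):
        doc = configure_sex(hormone_doc, "male")
        src = doc.sources_by_id()
        ratio = src["androgen_source"].effective_rate / src["estrogen_source"].effective_rate
        assert ratio == pytest.approx(10.0)

    def test_female_estrogen_to_androgen_source_ratio_is_three(self, hormone_doc):
        doc = configure_sex(hormone_doc, "female")
        src = doc.sources_by_id()
        ratio = src["estrogen_source"].effective_rate / src["androgen_source"].effective_rate
        assert ratio == pytest.approx(3.0)

    def test_female_installs_er_gh_feedback(self, hormone_doc):
        doc = configure_sex(hormone_doc, "female")
        edges = doc.edges_by_id()
        assert "er_gh_feedback" in edges
        assert edges["er_gh_feedback"].sign == -1

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_idempotent(self, hormone_doc, sex):
        once = configure_sex(hormone_doc, sex)
        twice = configure_sex(once, sex)
        assert once.to_dict() == twice.to_dict()

    def test_missing_hormone_species_rejected(self, chain_doc):
        with pytest.raises(ModelValidationError, match="hormone"):
            configure_sex(chain_doc, "male")


class TestDominantPeriod:
    def test_male_growth_hormone_source_period(self):
        p = HormoneProfile("growth_hormone", "daily_oscillation", 1.0, 0.8, 24.0)
        t = np.arange(0.0, 7 * 24.0, 0.1)
        period = dominant_period(hormone_level(p, t), 0.1)
        assert period == pytest.approx(24.0, abs=0.2)

    def test_constant_signal_flagged_aperiodic(self):
        assert dominant_period(np.ones(5000), 0.1) is None

    def test_synthetic_cosine_period_recovered(self):
        t = np.arange(0.0, 5 * 36.0, 0.1)
        y = 2.0 + np.cos(2 * np.pi * t / 36.0)
        assert dominant_period(y, 0.1) == pytest.approx(36.0, abs=0.2)

    def test_short_series_raises(self):
        t = np.arange(0.0, 30.0, 0.1)  # barely over one period
        y = 2.0 + np.cos(2 * np.pi * t / 24.0)
        with pytest.raises(InsufficientDataError):
            dominant_period(y, 0.1)
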