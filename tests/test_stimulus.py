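"""Input-trajectory generator: amplitudes, timing convention, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msnsig.stimulus import (
    CalciumTrain,
    DopamineTransient,
    StimulusProtocol,
    TrialSchedule,
    build_traces,
    frequency_variant,
)


def default_protocol(delta_t=1.0, ca_onset=10.0, total=60.0):
    return StimulusProtocol(
        calcium=CalciumTrain(onset=ca_onset),
        dopamine=DopamineTransient(),
        schedule=TrialSchedule(n_trials=1, delta_t=delta_t),
        total_duration=total,
    )


def test_dopamine_onset_follows_dt_convention():
    """Dt = +1 s: dopamine starts 1 s after the calcium train start."""
    p = default_protocol(delta_t=1.0, ca_onset=10.0)
    assert p.dopamine_onsets()[0] == pytest.approx(11.0)
    assert np.allclose(p.all_pulse_onsets(), 10.0 + np.arange(10) / 10.0)


def test_calcium_train_peaks_at_5uM_over_60nM_basal():
    p = default_protocol()
    t = np.arange(0.0, 30.0, 0.001)
    ca, _ = build_traces(p, t)
    assert ca.max() == pytest.approx(5.0, rel=0.01)
    assert ca[t < 10.0].max() == pytest.approx(0.060, abs=1e-9)


def test_protocol_without_dopamine_stays_at_da_basal():
    p = default_protocol()
    p = StimulusProtocol(
        calcium=p.calcium, dopamine=None, schedule=p.schedule,
        total_duration=p.total_duration,
    )
    t = np.arange(0.0, 30.0, 0.01)
    _, da = build_traces(p, t)
    assert np.allclose(da, 0.020)


def test_dopamine_amplitude_and_duration():
    p = default_protocol(delta_t=0.0)
    t = np.arange(0.0, 30.0, 0.001)
    _, da = build_traces(p, t)
    assert da.max() == pytest.approx(1.5, rel=0.01)
    above_half = t[da > 0.75]
    assert above_half[-1] - above_half[0] == pytest.approx(1.0, abs=0.1)


def test_grid_too_short_fails():
    p = default_protocol(ca_onset=50.0)
    with pytest.raises(ValueError, match="onset"):
        build_traces(p, np.arange(0.0, 10.0, 0.01))


@given(offset=st.floats(0.5, 50.0))
@settings(max_examples=20, deadline=None)
def test_translation_equivariance(offset):
    p = default_protocol()
    t = np.arange(10.0, 25.0, 0.01)
    ca0, da0 = build_traces(p, t)
    ca1, da1 = build_traces(p.shifted(offset), t + offset)
    assert np.allclose(ca0, ca1, atol=1e-12)
    assert np.allclose(da0, da1, atol=1e-12)


@given(n=st.integers(1, 10))
@settings(max_examples=10, deadline=None)
def test_calcium_integral_proportional_to_pulse_count(n):
    """For non-overlapping pulses the integral above basal scales with n."""
    cal = CalciumTrain(n_pulses=n, frequency=1.0, onset=1.0)  # 1 Hz: no overlap
    p = StimulusProtocol(
        calcium=cal, dopamine=None, schedule=TrialSchedule(),
        total_duration=n + 20.0,
    )
    t = np.arange(0.0, n + 15.0, 0.001)
    ca, _ = build_traces(p, t)
    integral = np.trapezoid(ca - cal.basal, t)
    per_pulse = cal.pulse_amplitude() * (cal.decay_tau - cal.rise_tau)
    assert integral == pytest.approx(n * per_pulse, rel=0.02)


def test_dt_sign_swap_mirrors_onset_order():
    pos = default_protocol(delta_t=2.0)
    neg = default_protocol(delta_t=-2.0)
    assert pos.dopamine_onsets()[0] - pos.calcium_onsets()[0] == pytest.approx(2.0)
    assert neg.dopamine_onsets()[0] - neg.calcium_onsets()[0] == pytest.approx(-2.0)
    # calcium timing itself is unchanged
    assert np.allclose(pos.all_pulse_onsets(), neg.all_pulse_onsets())


class TestFrequencyVariant:
    def test_respacing(self):
        p = default_protocol()
        q = frequency_variant(p, 20.0)
        on = q.all_pulse_onsets()
        assert len(on) == 10
        assert np.allclose(np.diff(on), 0.05)

    def test_identity(self):
        p = default_protocol()
        q = frequency_variant(p, p.calcium.frequency)
        assert q.calcium.peak == pytest.approx(p.calcium.peak, rel=1e-9)

    def test_amplitude_preserved_so_overlap_raises_peak(self):
        p = default_protocol()
        hi = frequency_variant(p, 40.0)
        lo = frequency_variant(p, 5.0)
        assert hi.calcium.pulse_amplitude() == pytest.approx(
            p.calcium.pulse_amplitude(), rel=1e-6
        )
        t = np.arange(0.0, 40.0, 0.001)
        ca_hi, _ = build_traces(hi, t)
        ca_lo, _ = build_traces(lo, t)
        assert ca_hi.max() > ca_lo.max()


class TestValidation:
    def test_peak_not_above_basal_rejected(self):
        with pytest.raises(ValueError):
            CalciumTrain(peak=0.05, basal=0.06)

    def test_multi_trial_needs_positive_iti(self):
        with pytest.raises(ValueError):
            TrialSchedule(n_trials=2, iti=0.0)

    def test_overlapping_trials_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusProtocol(
                calcium=CalciumTrain(onset=0.0),
                dopamine=DopamineTransient(),
                schedule=TrialSchedule(n_trials=3, iti=0.5, delta_t=1.0),
                total_duration=30.0,
            )
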