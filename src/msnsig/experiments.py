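"""In-silico experiments on the calibrated striatal model.

All experiments read out the *activation area*: the time integral of an
observable's excursion above its pre-stimulus basal over a fixed window
(calcium onset to onset + 100 s by default), normalized to a matched
calcium-alone baseline.  On top of that:

* ``dt_sweep`` -- normalized pSubstrate area as a function of the input
  interval Dt = t_dopamine - t_calcium, for any model variant.
* ``camkii_amplitude_curve`` -- peak active CaMKII vs Dt (the threshold-like
  input-order read-out).
* ``refractoriness`` -- two-trial protocols; REF(t) = 1 - A2(ITI=t)/A2(ITI=100).
* ``multi_trial`` -- per-trial areas in an n-trial train.
* ``robustness_grid`` -- Dt sweeps across dopamine amplitudes or calcium
  frequencies.
* ``sensitivity_scan`` -- one-at-a-time parameter perturbations of the Dt
  response, summarized per Dt-sign regime.

Simulations start from the variant's basal steady state.  Everything is
deterministic: no randomness enters any experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, simulate
from .model import (
    VariantSpec,
    apply_scaling,
    basal_state,
    build_model,
    observable_trace,
)
from .network import NetworkModel
from .stimulus import CalciumTrain, DopamineTransient, StimulusProtocol, TrialSchedule

log = logging.getLogger(__name__)

__all__ = [
    "DtResponseCurve",
    "RefractorinessCurve",
    "SensitivityReport",
    "activation_area",
    "run_trial",
    "dt_sweep",
    "camkii_amplitude_curve",
    "refractoriness",
    "multi_trial",
    "robustness_grid",
    "sensitivity_scan",
]

#: default integration window after each trial's calcium onset (s)
WINDOW = 100.0
#: default calcium onset within a single-trial protocol (s); leaves room for
#: dopamine-first (negative Dt) protocols and a pre-stimulus baseline
CA_ONSET = 8.0
#: default Dt grid (s)
DT_GRID = tuple(np.round(np.arange(-6.0, 8.01, 0.5), 3))
#: solver max step used for the experiment suites; inputs are evaluated in
#: closed form and onsets are integration breakpoints, so the pulse train is
#: resolved by the stiff error control (grid-refinement checked in tests)
MAX_STEP = 0.05


@dataclass
class DtResponseCurve:
    delta_t_values: np.ndarray
    normalized_area: np.ndarray
    baseline_area: float
    variant: VariantSpec
    integration_window: tuple[float, float]
    amplitude: np.ndarray | None = None  # per-Dt normalized CaMKII amplitude

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"delta_t": self.delta_t_values, "normalized_area": self.normalized_area}
        )
        if self.amplitude is not None:
            df["camkii_amplitude"] = self.amplitude
        df["variant"] = self.variant.name
        return df


@dataclass
class RefractorinessCurve:
    iti_values: np.ndarray
    ref_values: np.ndarray
    reference_iti: float = 100.0
    variant: VariantSpec | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iti": self.iti_values,
                "ref": self.ref_values,
                "variant": self.variant.name if self.variant else "WT",
            }
        )


@dataclass
class SensitivityReport:
    per_parameter: pd.DataFrame  # parameter, direction, per-Dt fractional change
    delta_t_values: np.ndarray
    perturbation: float

    def regime_means(self) -> pd.DataFrame:
        dts = self.delta_t_values
        pos = [f"dt_{v}" for v in dts if v >= 0]
        neg = [f"dt_{v}" for v in dts if v < 0]
        df = self.per_parameter.copy()
        df["mean_pos"] = df[pos].mean(axis=1)
        df["mean_neg"] = df[neg].mean(axis=1) if neg else np.nan
        return df[["parameter", "direction", "mean_pos", "mean_neg"]]

    def top_parameters(self, regime: str, k: int = 15) -> list[str]:
        """Top-k parameters ranked by |mean fractional change|, maximized
        over the up/down perturbation pair."""
        col = "mean_pos" if regime == "pos" else "mean_neg"
        m = self.regime_means()
        ranked = (
            m.assign(mag=m[col].abs())
            .groupby("parameter")["mag"]
            .max()
            .sort_values(ascending=False)
        )
        return list(ranked.index[:k])


# ---------------------------------------------------------------------------


def activation_area(
    result: SimulationResult,
    observable: str,
    window: tuple[float, float],
    model: NetworkModel | None = None,
    basal: float | None = None,
) -> float:
    """Trapezoidal integral of (observable - pre-stimulus basal), floored at 0.

    ``basal`` defaults to the observable's value at the window start's
    pre-stimulus trace start (t = 0).
    """
    trace = observable_trace(result, observable, model)
    t = result.time
    a, b = window
    if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside simulated span [{t[0]}, {t[-1]}]")
    if basal is None:
        basal = float(trace[0])
    m = (t >= a) & (t <= b)
    exc = np.clip(trace[m] - basal, 0.0, None)
    return float(np.trapezoid(exc, t[m]))


def _protocol(
    delta_t: float | None,
    n_trials: int = 1,
    iti: float = 100.0,
    ca_onset: float = CA_ONSET,
    window: float = WINDOW,
    dopamine: DopamineTransient | None = None,
    calcium: CalciumTrain | None = None,
) -> StimulusProtocol:
    cal = calcium if calcium is not None else CalciumTrain()
    cal = replace(cal, onset=ca_onset)
    if delta_t is None:
        da = None
        delta_t_val = 0.0
    else:
        da = dopamine if dopamine is not None else DopamineTransient()
        delta_t_val = delta_t
    total = ca_onset + (n_trials - 1) * iti + window + 5.0
    return StimulusProtocol(
        calcium=cal,
        dopamine=da,
        schedule=TrialSchedule(n_trials=n_trials, iti=iti, delta_t=delta_t_val),
        total_duration=total,
    )


def run_trial(
    model: NetworkModel,
    delta_t: float | None,
    window: float = WINDOW,
    ca_onset: float = CA_ONSET,
    dopamine: DopamineTransient | None = None,
    calcium: CalciumTrain | None = None,
    max_step: float = MAX_STEP,
) -> SimulationResult:
    """One single-trial simulation from the basal steady state.

    ``delta_t=None`` means calcium alone (no dopamine transient).
    """
    onset = ca_onset
    if delta_t is not None and onset + delta_t < 1.0:
        onset = 1.0 - delta_t  # keep the dopamine onset inside the simulation
    proto = _protocol(delta_t, ca_onset=onset, window=window,
                      dopamine=dopamine, calcium=calcium)
    t_end = onset + window + 1.0
    init = basal_state(model)
    return simulate(model, proto, t_end=t_end, max_step=max_step, grid_dt=0.02,
                    initial_state=init)


def _resolve(variant) -> tuple[NetworkModel, VariantSpec]:
    if isinstance(variant, NetworkModel):
        return variant, VariantSpec("WT")
    spec = VariantSpec(variant) if isinstance(variant, str) else variant
    return build_model(spec), spec


def dt_sweep(
    variant,
    delta_t_values: Sequence[float] = DT_GRID,
    window: float = WINDOW,
    dopamine: DopamineTransient | None = None,
    calcium: CalciumTrain | None = None,
    max_step: float = MAX_STEP,
) -> DtResponseCurve:
    """Normalized pSubstrate area (and CaMKII amplitude) as a function of Dt."""
    model, spec = _resolve(variant)
    base = run_trial(model, None, window, dopamine=dopamine, calcium=calcium,
                     max_step=max_step)
    onset = base.input_trace["Ca"].to_numpy()
    ca_on = CA_ONSET
    win = (ca_on, ca_on + window)
    base_area = activation_area(base, "pSubstrate", win, model)
    base_amp = float(np.max(observable_trace(base, "active_CaMKII", model)))
    if base_area <= 0:
        raise RuntimeError("calcium-alone baseline area is zero")
    areas, amps = [], []
    for dt in delta_t_values:
        res = run_trial(model, float(dt), window, dopamine=dopamine,
                        calcium=calcium, max_step=max_step)
        onset_dt = CA_ONSET if CA_ONSET + dt >= 1.0 else 1.0 - dt
        w = (onset_dt, onset_dt + window)
        areas.append(activation_area(res, "pSubstrate", w, model) / base_area)
        amps.append(
            float(np.max(observable_trace(res, "active_CaMKII", model))) / base_amp
        )
        log.debug("dt=%.2f area=%.3f", dt, areas[-1])
    return DtResponseCurve(
        delta_t_values=np.asarray(delta_t_values, float),
        normalized_area=np.asarray(areas),
        baseline_area=base_area,
        variant=spec,
        integration_window=win,
        amplitude=np.asarray(amps),
    )


def camkii_amplitude_curve(
    variants: Sequence = ("WT", "NO_ARPP21"),
    delta_t_values: Sequence[float] = DT_GRID,
    **kw,
) -> dict[str, DtResponseCurve]:
    """Per-variant max active CaMKII vs Dt, normalized to calcium alone."""
    return {
        (v if isinstance(v, str) else v.name): dt_sweep(v, delta_t_values, **kw)
        for v in variants
    }


def refractoriness(
    variant,
    iti_values: Sequence[float] = (10.0, 20.0, 30.0, 50.0, 100.0),
    delta_t: float = 1.0,
    window: float = WINDOW,
    reference_iti: float = 100.0,
    max_step: float = MAX_STEP,
) -> RefractorinessCurve:
    """REF(t) = 1 - A2(ITI=t)/A2(ITI=reference) for two-trial protocols.

    The second trial's activation area is the excursion of the two-trial
    trajectory above the matching *single-trial* trajectory, integrated over a
    window anchored at the second trial's calcium onset; this attributes a
    decaying first-trial tail to the first trial, not the second.
    """
    model, spec = _resolve(variant)
    itis = sorted(set(float(v) for v in iti_values) | {float(reference_iti)})
    init = basal_state(model)
    # one-trial reference trajectory spanning the longest protocol
    t_max = CA_ONSET + max(itis) + window + 1.0
    proto1 = _protocol(delta_t, n_trials=1, window=t_max - CA_ONSET)
    one = simulate(model, proto1, t_end=t_max, max_step=max_step, grid_dt=0.02,
                   initial_state=init)
    one_trace = observable_trace(one, "pSubstrate", model)
    second_areas = {}
    for iti in itis:
        proto = _protocol(delta_t, n_trials=2, iti=iti, window=window)
        t_end = CA_ONSET + iti + window + 1.0
        res = simulate(model, proto, t_end=t_end, max_step=max_step,
                       grid_dt=0.02, initial_state=init)
        trace = observable_trace(res, "pSubstrate", model)
        tail = np.interp(res.time, one.time, one_trace)
        on2 = CA_ONSET + iti
        m = (res.time >= on2) & (res.time <= on2 + window)
        exc = np.clip(trace[m] - tail[m], 0.0, None)
        second_areas[iti] = float(np.trapezoid(exc, res.time[m]))
    ref_area = second_areas[float(reference_iti)]
    if ref_area <= 0:
        raise RuntimeError("reference second-trial area is zero")
    out_itis = np.asarray([v for v in iti_values], float)
    refs = np.asarray([1.0 - second_areas[float(v)] / ref_area for v in out_itis])
    return RefractorinessCurve(out_itis, refs, reference_iti, spec)


def multi_trial(
    variant,
    n_trials: int = 10,
    iti: float = 10.0,
    delta_t: float = 1.0,
    window: float = WINDOW,
    max_step: float = MAX_STEP,
) -> np.ndarray:
    """Per-trial pSubstrate areas normalized to trial 1.

    Trial k's area is the excursion of the k-trial trajectory above the
    (k-1)-trial trajectory over [onset_k, onset_k + window], so overlapping
    response tails are attributed to the trial that produced them.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    model, spec = _resolve(variant)
    init = basal_state(model)
    t_max = CA_ONSET + (n_trials - 1) * iti + window + 1.0
    traces = []
    times = None
    for k in range(1, n_trials + 1):
        if k == 1:
            proto = _protocol(delta_t, n_trials=1, window=t_max - CA_ONSET)
        else:
            proto = _protocol(delta_t, n_trials=k, iti=iti,
                              window=t_max - (CA_ONSET + (k - 1) * iti))
        res = simulate(model, proto, t_end=t_max, max_step=max_step,
                       grid_dt=0.02, initial_state=init)
        traces.append(observable_trace(res, "pSubstrate", model))
        times = res.time
    zero = np.full_like(traces[0], traces[0][0])
    areas = []
    for k in range(n_trials):
        prev = traces[k - 1] if k > 0 else zero
        on = CA_ONSET + k * iti
        m = (times >= on) & (times <= on + window)
        exc = np.clip(traces[k][m] - prev[m], 0.0, None)
        areas.append(float(np.trapezoid(exc, times[m])))
    areas = np.asarray(areas)
    if areas[0] <= 0:
        raise RuntimeError("first-trial area is zero")
    return areas / areas[0]


def robustness_grid(
    axis: str,
    values: Sequence[float] | None = None,
    delta_t_values: Sequence[float] = (-4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0),
    variant="WT",
    window: float = WINDOW,
    max_step: float = MAX_STEP,
) -> pd.DataFrame:
    """Dt response across input strengths.

    ``axis`` is ``dopamine_amplitude`` (uM, log-spaced 10 nM - 3 uM by
    default) or ``calcium_frequency`` (Hz).  Each row is normalized by its
    own calcium-alone baseline (identical calcium input, no dopamine).
    """
    if axis == "dopamine_amplitude":
        vals = np.geomspace(0.01, 3.0, 6) if values is None else np.asarray(values, float)
    elif axis == "calcium_frequency":
        vals = np.asarray([5.0, 10.0, 20.0, 40.0]) if values is None else np.asarray(values, float)
    else:
        raise ValueError("axis must be 'dopamine_amplitude' or 'calcium_frequency'")
    if np.any(vals <= 0):
        raise ValueError("axis values must be positive")
    model, spec = _resolve(variant)
    rows = []
    for v in vals:
        if axis == "dopamine_amplitude":
            from .stimulus import DA_BASAL

            if v > DA_BASAL:
                da = DopamineTransient(amplitude=float(v))
            else:
                # an amplitude at or below the dopamine background is no
                # transient at all; the trace stays flat at basal
                da = DopamineTransient(amplitude=DA_BASAL + 1e-12, basal=DA_BASAL)
            cal = None
        else:
            da = None
            from .stimulus import StimulusProtocol as _SP, frequency_variant

            ref = _protocol(1.0)
            cal = frequency_variant(ref, float(v)).calcium
        curve = dt_sweep(model, delta_t_values, window=window, dopamine=da,
                         calcium=cal, max_step=max_step)
        for dt, area in zip(curve.delta_t_values, curve.normalized_area):
            rows.append({"axis": axis, "value": float(v), "delta_t": float(dt),
                         "normalized_area": float(area)})
    df = pd.DataFrame(rows)
    df.attrs["variant"] = spec.name
    return df


def sensitivity_scan(
    perturbation: float = 0.2,
    delta_t_values: Sequence[float] = (-4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0),
    variant="WT",
    parameters: Sequence[str] | None = None,
    window: float = WINDOW,
    max_step: float = MAX_STEP,
    factor_mode: bool = False,
) -> SensitivityReport:
    """One-at-a-time parameter perturbation of the Dt response.

    ``perturbation=0.2`` scales each parameter by 1 +- 20%; ``factor_mode``
    instead scales by x2 / x0.5 (the coarse robustness screen).  Fractional
    response change = (area_perturbed - area_base)/area_base per Dt.  A
    perturbed run that fails to integrate is recorded as NaN, not fatal.
    """
    model, spec = _resolve(variant)
    base_curve = dt_sweep(model, delta_t_values, window=window, max_step=max_step)
    base_areas = base_curve.normalized_area * base_curve.baseline_area
    params = list(parameters) if parameters is not None else model.parameter_names()
    if factor_mode:
        factors = {"up": 2.0, "down": 0.5}
    else:
        factors = {"up": 1.0 + perturbation, "down": 1.0 - perturbation}
    rows = []
    for p in params:
        for direction, f in factors.items():
            pert = apply_scaling(model, {p: f})
            pert.name = f"{model.name}__{p}_{direction}"
            row = {"parameter": p, "direction": direction}
            try:
                curve = dt_sweep(pert, delta_t_values, window=window,
                                 max_step=max_step)
                areas = curve.normalized_area * curve.baseline_area
                # compare raw areas against the base model's raw areas so a
                # perturbation of the baseline normalization also registers
                frac = (curve.normalized_area - base_curve.normalized_area) / base_curve.normalized_area
                for dt, fr in zip(delta_t_values, frac):
                    row[f"dt_{dt}"] = float(fr)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                log.warning("perturbed run failed for %s %s: %s", p, direction, exc)
                for dt in delta_t_values:
                    row[f"dt_{dt}"] = np.nan
            rows.append(row)
    return SensitivityReport(
        per_parameter=pd.DataFrame(rows),
        delta_t_values=np.asarray(delta_t_values, float),
        perturbation=perturbation if not factor_mode else 2.0,
    )
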