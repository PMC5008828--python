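"""Executable molecular phenotypes: treatments, curve fits and divergence.

Each phenotype is an in-silico surrogate of a published experiment used to
constrain the model:

* ``Basal`` -- steady state under 60 nM calcium / 20 nM dopamine.
* ``ReceptorGProtein`` -- G-protein activation rate under saturating ligand
  (monoexponential fit; the experimental constraint is the band 10-100 1/s).
* ``SliceDA`` -- sustained 10 uM dopamine, markers sampled at 5 min,
  expressed as fold over basal.
* ``SliceCa`` -- sustained elevated calcium (NMDA-bath surrogate, 1 uM),
  sampled at 10 min, fold over basal.
* ``SlicePKADynamics`` -- steady cAMP under saturating dopamine (~10 uM), and
  the difference-of-two-exponentials shape of the PKA/PP1 reporter response
  to a single transient dopamine input.
* ``SlicePDE10Inhibition`` -- PDE10 catalysis off, Thr-34 fold over basal.
* ``PDEKinetics`` -- cAMP decay from 50 uM with synthesis off
  (monoexponential rate).
* ``CaMKIIDynamics`` -- active-CaMKII deactivation after the standard
  calcium train (monoexponential rate).
* ``DoseResponse`` -- Hill fits of isolated-protein activation curves: PKA
  vs clamped cAMP, fully loaded calmodulin vs clamped calcium.

Simulated values are compared with the experimental targets as log2 ratios
and classified into +-30% / +-80% divergence bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .engine import simulate, steady_state
from .model import basal_state, extract_subnetwork, observables
from .stimulus import (
    CalciumTrain,
    DopamineTransient,
    StimulusProtocol,
    TrialSchedule,
    basal_protocol,
)

__all__ = [
    "PhenotypeTarget",
    "PhenotypeReport",
    "fit_monoexponential",
    "fit_diff_exponentials",
    "fit_hill",
    "evaluate_phenotype",
    "divergence_table",
    "band_of",
    "PHENOTYPE_TARGETS",
]

WITHIN30 = math.log2(1.3)
WITHIN80 = math.log2(1.8)


# ---------------------------------------------------------------------------
# curve fits


def _multistart(objective, starts, param_builder):
    best = None
    for s in starts:
        try:
            res = minimize(objective, param_builder(s), method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")
    return best


def fit_monoexponential(t, y) -> tuple[float, float]:
    """Fit y = a*exp(-k*t) + c from the trace maximum onward; returns (k, residual).

    The trace must decay toward a plateau after its maximum.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    i0 = int(np.argmax(y))
    if i0 >= len(y) - 5:
        raise ValueError("trace does not decay (maximum at the end)")
    tt = t[i0:] - t[i0]
    yy = y[i0:]
    drop = yy[0] - yy[-1]
    if drop <= 0 or drop < 0.02 * max(abs(yy[0]), 1e-12):
        raise ValueError("trace does not decay after its maximum")

    def obj(p):
        return p["a"] * np.exp(-p["k"] * tt) + p["c"] - yy

    span = tt[-1]
    starts = np.geomspace(0.2 / span, 200.0 / span, 7)

    def build(k0):
        p = Parameters()
        p.add("a", value=drop, min=0)
        p.add("k", value=k0, min=1e-6)
        p.add("c", value=yy[-1])
        return p

    best = _multistart(obj, starts, build)
    return float(best.params["k"].value), float(np.sqrt(best.chisqr / len(yy)))


def fit_diff_exponentials(t, y) -> tuple[float, float]:
    """Fit y = A*(exp(-k1 t) - exp(-k2 t)) + c with k2 > k1; returns (k1, k2).

    The trace must rise and then decay (a transient).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    i0 = int(np.argmax(y))
    if i0 <= 2 or i0 >= len(y) - 5:
        raise ValueError("trace is not rise-then-decay")
    tt = t - t[0]
    amp = y[i0] - y[0]
    if amp <= 0:
        raise ValueError("trace is not rise-then-decay")

    def obj(p):
        k1 = p["k1"].value
        k2 = k1 + p["dk"].value
        return p["A"] * (np.exp(-k1 * tt) - np.exp(-k2 * tt)) + p["c"] - y

    tpk = tt[i0]
    starts = [
        (0.3 / tt[-1], 1.0 / tpk),
        (0.1 / tt[-1], 3.0 / tpk),
        (1.0 / tt[-1], 0.5 / tpk),
        (0.05 / tt[-1], 1.0 / tpk),
        (0.5 / tt[-1], 5.0 / tpk),
    ]

    def build(s):
        k1, k2 = s
        p = Parameters()
        p.add("A", value=2 * amp, min=0)
        p.add("k1", value=k1, min=1e-6)
        p.add("dk", value=max(k2 - k1, 1e-3), min=1e-6)
        p.add("c", value=y[0])
        return p

    best = _multistart(obj, starts, build)
    k1 = float(best.params["k1"].value)
    k2 = k1 + float(best.params["dk"].value)
    if k2 / k1 < 1.05:
        raise RuntimeError("degenerate fit: k1 ~ k2")
    return k1, k2


def fit_hill(dose, response) -> tuple[float, float]:
    """Fit r = rmax * d^h / (K^h + d^h); returns (h, K)."""
    d = np.asarray(dose, float)
    r = np.asarray(response, float)
    if len(d) < 5:
        raise ValueError("need at least 5 doses")
    order = np.argsort(d)
    d, r = d[order], r[order]
    if np.any(np.diff(r) < -0.02 * (r.max() - r.min()) - 1e-15):
        raise ValueError("response is not monotone in dose")

    def obj(p):
        return p["rmax"] * d ** p["h"] / (p["K"] ** p["h"] + d ** p["h"]) - r

    starts = np.geomspace(d[0], d[-1], 5)

    def build(K0):
        p = Parameters()
        p.add("rmax", value=r.max(), min=0)
        p.add("h", value=1.2, min=0.2, max=6)
        p.add("K", value=K0, min=d[0] / 100, max=d[-1] * 100)
        return p

    best = _multistart(obj, starts, build)
    return float(best.params["h"].value), float(best.params["K"].value)


# ---------------------------------------------------------------------------
# phenotype targets


@dataclass
class PhenotypeTarget:
    """One phenotypic variable: its treatment, marker and experimental value."""

    phenotype: str
    variable: str
    exp_value: float | tuple[float, float]  # point target or accepted range
    kind: str  # 'abs' (uM), 'fold', 'rate' (1/s), 'hill_h', 'hill_K'
    needs_arpp21: bool = False


PHENOTYPE_TARGETS: list[PhenotypeTarget] = [
    PhenotypeTarget("Basal", "cAMP", (0.03, 0.09), "abs"),
    PhenotypeTarget("Basal", "DARPP32p34", 0.4, "abs"),
    PhenotypeTarget("Basal", "DARPP32p75", 12.0, "abs"),
    PhenotypeTarget("Basal", "ARPP21p55", 0.7, "abs", needs_arpp21=True),
    PhenotypeTarget("ReceptorGProtein", "Golf_activation_k", (10.0, 100.0), "rate"),
    PhenotypeTarget("SliceDA", "DARPP32p34_fold", 11.0, "fold"),
    PhenotypeTarget("SliceDA", "DARPP32p75_fold", 0.5, "fold"),
    PhenotypeTarget("SliceDA", "ARPP21p55_fold", 7.0, "fold", needs_arpp21=True),
    PhenotypeTarget("SliceCa", "DARPP32p34_fold", 0.5, "fold"),
    PhenotypeTarget("SliceCa", "DARPP32p75_fold", 0.5, "fold"),
    PhenotypeTarget("SlicePKADynamics", "cAMP_max", 10.0, "abs"),
    PhenotypeTarget("SlicePKADynamics", "AKAR_k1", 0.043, "rate"),
    PhenotypeTarget("SlicePKADynamics", "AKAR_k2", 0.227, "rate"),
    PhenotypeTarget("SlicePDE10Inhibition", "DARPP32p34_fold", 2.0, "fold"),
    PhenotypeTarget("PDEKinetics", "cAMP_decay_k", 0.508, "rate"),
    PhenotypeTarget("CaMKIIDynamics", "CaMKII_decay_k", 0.166, "rate"),
    PhenotypeTarget("DoseResponse", "PKA_hill_h", 1.4, "hill_h"),
    PhenotypeTarget("DoseResponse", "PKA_hill_K", 0.5278, "hill_K"),
    PhenotypeTarget("DoseResponse", "CaMCa4_hill_h", 1.0, "hill_h"),
    PhenotypeTarget("DoseResponse", "CaMCa4_hill_K", 6.29, "hill_K"),
]


def band_of(log2_ratio: float) -> str:
    a = abs(log2_ratio)
    if a <= WITHIN30:
        return "within30"
    if a <= WITHIN80:
        return "within80"
    return "outside"


def _log2_ratio(sim: float, exp) -> float:
    if isinstance(exp, tuple):
        lo, hi = exp
        if lo <= sim <= hi:
            return 0.0
        edge = lo if sim < lo else hi
        return math.log2(sim / edge)
    return math.log2(sim / exp)


# ---------------------------------------------------------------------------
# treatments


def _obs_sum(state: dict, members: list[str]) -> float:
    return sum(state.get(m, 0.0) for m in members)


def _marker(model, state, name) -> float:
    return _obs_sum(state, observables(model)[name])


def _da_clamp_protocol(level: float, duration: float) -> StimulusProtocol:
    cal = CalciumTrain(n_pulses=1, peak=0.060 + 1e-12)
    da = DopamineTransient(amplitude=level, duration=duration, onset=0.0)
    return StimulusProtocol(
        calcium=cal, dopamine=da, schedule=TrialSchedule(n_trials=1, delta_t=0.0),
        total_duration=duration + 10.0,
    )


def _pde10_off(model):
    m = model.copy()
    m.get_reaction("pde10_cat").kf = 0.0
    m.name = model.name + "_pde10off"
    return m


def _synthesis_off(model):
    m = model.copy()
    m.get_reaction("ac5_basal_cat").kf = 0.0
    m.get_reaction("ac5_golf_cat").kf = 0.0
    m.name = model.name + "_noAC"
    return m


class PhenotypeRunner:
    """Runs all phenotype treatments against one model, caching shared state."""

    def __init__(self, model, params: dict | None = None):
        self.model = model
        if params is None:
            from .model import load_parameters

            params = load_parameters()
        self.treatments = params.get("treatments", {})
        self.basal = basal_state(model)
        self.has_arpp21 = "A21" in model.species_names()

    # -- individual treatments -------------------------------------------
    def basal_markers(self) -> dict[str, float]:
        m, s = self.model, self.basal
        out = {
            "cAMP": _marker(m, s, "cAMP"),
            "DARPP32p34": _marker(m, s, "pDARPP32_T34"),
            "DARPP32p75": _marker(m, s, "pDARPP32_T75"),
        }
        if self.has_arpp21:
            out["ARPP21p55"] = _marker(m, s, "pARPP21_S55")
        return out

    def receptor_gprotein(self) -> float:
        level = float(self.treatments.get("slice_da_clamp", 10.0))
        res = simulate(
            self.model, basal_protocol(2.0), t_end=1.0, grid_dt=0.002,
            initial_state=self.basal, clamp={"DA": level},
        )
        trace = res["Golf_a"]
        plateau = trace[-1]
        k, _ = fit_monoexponential(res.time, plateau - trace)
        return k

    def slice_da(self) -> dict[str, float]:
        level = float(self.treatments.get("slice_da_clamp", 10.0))
        res = simulate(
            self.model, basal_protocol(310.0), t_end=300.0, max_step=np.inf,
            grid_dt=0.5, initial_state=self.basal, clamp={"DA": level},
        )
        end = res.concentrations.iloc[-1].to_dict()
        b = self.basal_markers()
        out = {
            "DARPP32p34_fold": _marker(self.model, end, "pDARPP32_T34") / b["DARPP32p34"],
            "DARPP32p75_fold": _marker(self.model, end, "pDARPP32_T75") / b["DARPP32p75"],
            "cAMP_max": float(np.max(res["cAMP"])),
        }
        if self.has_arpp21:
            out["ARPP21p55_fold"] = (
                _marker(self.model, end, "pARPP21_S55") / b["ARPP21p55"]
            )
        return out

    def slice_ca(self) -> dict[str, float]:
        level = float(self.treatments.get("slice_ca_clamp", 1.0))
        res = simulate(
            self.model, basal_protocol(610.0), t_end=600.0, max_step=np.inf,
            grid_dt=1.0, initial_state=self.basal, clamp={"Ca": level},
        )
        end = res.concentrations.iloc[-1].to_dict()
        b = self.basal_markers()
        return {
            "DARPP32p34_fold": _marker(self.model, end, "pDARPP32_T34") / b["DARPP32p34"],
            "DARPP32p75_fold": _marker(self.model, end, "pDARPP32_T75") / b["DARPP32p75"],
        }

    def akar_dynamics(self) -> tuple[float, float]:
        """Reporter response to one transient dopamine input (no calcium)."""
        cal = CalciumTrain(n_pulses=1, peak=0.060 + 1e-12, onset=0.0)
        da = DopamineTransient(onset=5.0)
        proto = StimulusProtocol(
            calcium=cal, dopamine=da,
            schedule=TrialSchedule(n_trials=1, delta_t=5.0), total_duration=125.0,
        )
        res = simulate(self.model, proto, t_end=120.0, max_step=0.05, grid_dt=0.05,
                       initial_state=self.basal)
        from .model import observable_trace

        trace = observable_trace(res, "pAKAR", self.model)
        mask = res.time >= 5.0
        return fit_diff_exponentials(res.time[mask] - 5.0, trace[mask])

    def pde10_inhibition(self) -> float:
        m = _pde10_off(self.model)
        ss = steady_state(m, initial_state=self.basal)
        return _marker(m, ss.state, "pDARPP32_T34") / self.basal_markers()["DARPP32p34"]

    def pde_kinetics(self) -> float:
        m = _synthesis_off(self.model)
        c0 = float(self.treatments.get("pde_kinetics_camp0", 50.0))
        init = dict(self.basal)
        init["cAMP"] = c0
        res = simulate(m, basal_protocol(30.0), t_end=25.0, max_step=np.inf,
                       grid_dt=0.02, initial_state=init)
        k, _ = fit_monoexponential(res.time, res["cAMP"])
        return k

    def camkii_dynamics(self) -> float:
        proto = StimulusProtocol(
            calcium=CalciumTrain(onset=2.0), dopamine=None,
            schedule=TrialSchedule(n_trials=1), total_duration=65.0,
        )
        res = simulate(self.model, proto, t_end=60.0, initial_state=self.basal)
        from .model import observable_trace

        trace = observable_trace(res, "active_CaMKII", self.model)
        k, _ = fit_monoexponential(res.time, trace)
        return k

    def dose_response_pka(self) -> tuple[float, float]:
        sub = extract_subnetwork(
            self.model, {"PKA", "PKA_cAMP", "PKA_cAMP2", "PKAr", "PKAc"},
            clamp={"cAMP"},
        )
        dmax = float(self.treatments.get("pka_dose_max", 30.0))
        doses = np.geomspace(0.02, dmax, 12)
        resp = []
        for d in doses:
            ss = steady_state(sub, clamp={"cAMP": float(d)}, tol=1e-10)
            resp.append(ss.state["PKAc"])
        return fit_hill(doses, np.asarray(resp))

    def dose_response_cam(self) -> tuple[float, float]:
        sub = extract_subnetwork(self.model, {"CaM", "CaMCa2", "CaMCa4"},
                                 clamp={"Ca"})
        doses = np.geomspace(0.1, 200.0, 12)
        resp = []
        for d in doses:
            ss = steady_state(
                sub,
                basal_stimulus=None,
                clamp={"Ca": float(d)},
                tol=1e-10,
            )
            resp.append(ss.state["CaMCa4"])
        return fit_hill(doses, np.asarray(resp))

    # -- assembly ---------------------------------------------------------
    def run_all(self) -> dict[str, float]:
        out = {}
        for name, v in self.basal_markers().items():
            out[f"Basal/{name}"] = v
        out["ReceptorGProtein/Golf_activation_k"] = self.receptor_gprotein()
        da = self.slice_da()
        for k in ("DARPP32p34_fold", "DARPP32p75_fold"):
            out[f"SliceDA/{k}"] = da[k]
        if self.has_arpp21:
            out["SliceDA/ARPP21p55_fold"] = da["ARPP21p55_fold"]
        ca = self.slice_ca()
        out["SliceCa/DARPP32p34_fold"] = ca["DARPP32p34_fold"]
        out["SliceCa/DARPP32p75_fold"] = ca["DARPP32p75_fold"]
        out["SlicePKADynamics/cAMP_max"] = da["cAMP_max"]
        k1, k2 = self.akar_dynamics()
        out["SlicePKADynamics/AKAR_k1"] = k1
        out["SlicePKADynamics/AKAR_k2"] = k2
        out["SlicePDE10Inhibition/DARPP32p34_fold"] = self.pde10_inhibition()
        out["PDEKinetics/cAMP_decay_k"] = self.pde_kinetics()
        out["CaMKIIDynamics/CaMKII_decay_k"] = self.camkii_dynamics()
        h, K = self.dose_response_pka()
        out["DoseResponse/PKA_hill_h"] = h
        out["DoseResponse/PKA_hill_K"] = K
        h, K = self.dose_response_cam()
        out["DoseResponse/CaMCa4_hill_h"] = h
        out["DoseResponse/CaMCa4_hill_K"] = K
        return out


def evaluate_phenotype(model, target: PhenotypeTarget, runner=None) -> dict:
    """Evaluate one phenotypic variable; returns the report row as a dict."""
    runner = runner or PhenotypeRunner(model)
    sims = runner.run_all()
    key = f"{target.phenotype}/{target.variable}"
    if key not in sims:
        raise KeyError(f"phenotype variable {key!r} not available for this model")
    sim = sims[key]
    r = _log2_ratio(sim, target.exp_value)
    return {
        "phenotype": target.phenotype,
        "variable": target.variable,
        "simulated": sim,
        "experimental": target.exp_value,
        "log2_ratio": r,
        "band": band_of(r),
    }


def divergence_table(model, runner: PhenotypeRunner | None = None) -> pd.DataFrame:
    """The full simulated-vs-experimental phenotype report for one model."""
    runner = runner or PhenotypeRunner(model)
    sims = runner.run_all()
    rows = []
    for tg in PHENOTYPE_TARGETS:
        if tg.needs_arpp21 and not runner.has_arpp21:
            continue
        key = f"{tg.phenotype}/{tg.variable}"
        sim = sims[key]
        r = _log2_ratio(sim, tg.exp_value)
        rows.append(
            {
                "phenotype": tg.phenotype,
                "variable": tg.variable,
                "simulated": sim,
                "experimental": str(tg.exp_value),
                "log2_ratio": r,
                "band": band_of(r),
            }
        )
    return pd.DataFrame(rows)
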