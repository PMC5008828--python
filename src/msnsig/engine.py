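"""Stiff integration of the network ODEs with time-varying clamped inputs.

The solver is SciPy's variable-order BDF with an analytic Jacobian assembled
from the reaction stoichiometry.  The integration is split at every stimulus
onset/offset so the discontinuity-like input edges are never stepped over,
and the maximum step is capped (0.01 s by default) so the pulsed calcium
input is always resolved.  Output is returned on a uniform grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .network import NetworkModel
from .stimulus import StimulusProtocol, basal_protocol

__all__ = ["SimulationResult", "SteadyState", "simulate", "steady_state"]

NEG_TOL = 1e-9  # uM; largest tolerated negative excursion


@dataclass
class SimulationResult:
    """Time grid, per-species trajectories and the applied input traces."""

    time: np.ndarray
    concentrations: pd.DataFrame  # index: time, columns: species (uM)
    input_trace: pd.DataFrame  # columns: Ca, DA (uM)
    solver_stats: dict = field(default_factory=dict)
    model_name: str = "model"

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species].to_numpy()

    def to_tidy(self) -> pd.DataFrame:
        df = self.concentrations.reset_index(names="time")
        return df.melt(id_vars="time", var_name="species", value_name="value")

    def write_csv(self, path, wide: bool = False) -> None:
        """Write the trajectory with a metadata comment header."""
        stats = ", ".join(f"{k}={v}" for k, v in sorted(self.solver_stats.items()))
        header = (
            f"# msnsig trajectory; model={self.model_name}; "
            f"model_hash={self.solver_stats.get('model_hash', 'n/a')}\n"
            f"# {stats}\n"
        )
        df = (
            self.concentrations.reset_index(names="time")
            if wide
            else self.to_tidy()
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)


@dataclass
class SteadyState:
    """Result of relaxing the model under constant basal inputs."""

    state: dict[str, float]
    converged: bool
    residual: float  # max |d[X]/dt| / max([X], 1e-6)  (1/s)
    t_reached: float


def _model_hash(model: NetworkModel) -> str:
    h = hashlib.md5()
    for r in model.reactions:
        h.update(f"{r.id}:{r.kf!r}:{r.kr!r}".encode())
    for s in model.species:
        h.update(f"{s.name}:{s.initial_concentration!r}".encode())
    return h.hexdigest()[:12]


def _clamp_arrays(model, net, clamp):
    clamp = dict(clamp or {})
    missing = [n for n in net.extra_clamped if n not in clamp]
    if missing:
        raise ValueError(
            f"clamped species {missing} need levels via the clamp argument"
        )
    idx = model.species_index()
    cl_idx = np.array([idx[n] for n in clamp], dtype=np.int64)
    cl_val = np.array([float(v) for v in clamp.values()], dtype=float)
    return cl_idx, cl_val


def _kernel_args(net: _kernels.CompiledNetwork, stim: _kernels.StimulusArrays,
                 cl_idx, cl_val):
    return (
        cl_idx,
        cl_val,
        net.ri1,
        net.ri2,
        net.pi1,
        net.pi2,
        net.kf,
        net.kr,
        net.ica,
        net.ida,
        stim.ca_t0,
        stim.ca_amp,
        stim.ca_rise,
        stim.ca_decay,
        stim.ca_basal,
        stim.da_t0,
        stim.da_amp,
        stim.da_dur,
        stim.da_edge,
        stim.da_basal,
    )


def simulate(
    model: NetworkModel,
    stimulus: StimulusProtocol | None,
    t_end: float,
    max_step: float = 0.01,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    grid_dt: float = 0.01,
    initial_state: dict[str, float] | None = None,
    clamp: dict[str, float] | None = None,
) -> SimulationResult:
    """Integrate the model under the given stimulus from t=0 to t_end.

    Clamped input species follow the stimulus exactly on the output grid.
    Raises RuntimeError (with the failure time) if the solver does not
    converge or the state turns non-finite.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if stimulus is None:
        stimulus = basal_protocol(total_duration=t_end)
    net = _kernels.compile_network(model)
    stim = _kernels.pack_stimulus(stimulus)
    cl_idx, cl_val = _clamp_arrays(model, net, clamp)
    args = _kernel_args(net, stim, cl_idx, cl_val)

    y0 = net.y0.copy()
    if initial_state is not None:
        idx = model.species_index()
        for name, v in initial_state.items():
            y0[idx[name]] = v
    if net.ica >= 0:
        y0[net.ica] = stim.ca_basal
    if net.ida >= 0:
        y0[net.ida] = stim.da_basal
    for i, v in zip(cl_idx, cl_val):
        y0[i] = v

    grid = np.round(np.arange(0.0, t_end + grid_dt / 2, grid_dt), 9)
    breaks = [b for b in stimulus.breakpoints() if b < t_end]
    edges = np.concatenate(([0.0], breaks, [t_end]))
    edges = np.unique(edges)

    out_t = [0.0]
    out_y = [y0.copy()]
    nfev = njev = nsteps = 0
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1e-12:
            continue
        t_eval = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
        # always evaluate the exact segment edge so the next segment starts
        # from the true edge state
        if t_eval.size == 0 or abs(t_eval[-1] - b) > 1e-12:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(
            _kernels._rhs,
            (a, b),
            y,
            method="BDF",
            jac=_kernels._jac,
            args=args,
            max_step=max_step,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval if t_eval.size else None,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if sol.t.size else a:.4f}s: "
                f"{sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"non-finite state in segment [{a}, {b}]")
        nfev += sol.nfev
        njev += sol.njev
        nsteps += sol.t.size
        out_t.extend(sol.t.tolist())
        out_y.extend(sol.y.T.copy())
        y = sol.y[:, -1].copy()

    t_arr = np.asarray(out_t)
    y_arr = np.asarray(out_y)

    min_conc = float(y_arr.min())
    if min_conc < -NEG_TOL * 100:
        # large negative excursions indicate a genuinely failed solve
        raise RuntimeError(f"negative concentration {min_conc:.3e} uM in output")
    y_arr = np.clip(y_arr, 0.0, None)

    # clamped species follow the stimulus exactly on the grid
    ca_trace = stimulus.calcium_at(t_arr)
    da_trace = stimulus.dopamine_at(t_arr)
    if net.ica >= 0:
        y_arr[:, net.ica] = ca_trace
    if net.ida >= 0:
        y_arr[:, net.ida] = da_trace
    for i, v in zip(cl_idx, cl_val):
        y_arr[:, i] = v

    conc = pd.DataFrame(y_arr, index=pd.Index(t_arr, name="time"), columns=net.species)
    inputs = pd.DataFrame(
        {"Ca": ca_trace, "DA": da_trace}, index=pd.Index(t_arr, name="time")
    )
    stats = {
        "steps": int(nsteps),
        "nfev": int(nfev),
        "njev": int(njev),
        "min_concentration": min_conc,
        "rtol": rtol,
        "atol": atol,
        "max_step": max_step,
        "model_hash": _model_hash(model),
    }
    return SimulationResult(
        time=t_arr,
        concentrations=conc,
        input_trace=inputs,
        solver_stats=stats,
        model_name=model.name,
    )


def steady_state(
    model: NetworkModel,
    basal_stimulus: StimulusProtocol | None = None,
    tol: float = 1e-8,
    t_max: float = 1e4,
    chunk: float = 250.0,
    initial_state: dict[str, float] | None = None,
    clamp: dict[str, float] | None = None,
) -> SteadyState:
    """Relax the model to its basal steady state by long integration.

    Inputs are held at their basal values (60 nM calcium, 20 nM dopamine by
    default).  Convergence criterion: max over species of
    |d[X]/dt| / max([X], 1e-6 uM) < tol (1/s), checked every ``chunk``
    seconds up to ``t_max``.
    """
    if basal_stimulus is None:
        basal_stimulus = basal_protocol(total_duration=t_max)
    net = _kernels.compile_network(model)
    stim = _kernels.pack_stimulus(basal_stimulus)
    cl_idx, cl_val = _clamp_arrays(model, net, clamp)
    args = _kernel_args(net, stim, cl_idx, cl_val)

    y = net.y0.copy()
    if initial_state is not None:
        idx = model.species_index()
        for name, v in initial_state.items():
            y[idx[name]] = v
    if net.ica >= 0:
        y[net.ica] = stim.ca_basal
    if net.ida >= 0:
        y[net.ida] = stim.da_basal
    for i, v in zip(cl_idx, cl_val):
        y[i] = v

    def residual(t, yv):
        dy = _kernels._rhs(t, yv, *args)
        return float(np.max(np.abs(dy) / np.maximum(np.abs(yv), 1e-6)))

    t = 1e3 * np.finfo(float).eps  # evaluate just past any t=0 input edge
    res = residual(t, y)
    while res >= tol and t < t_max:
        t1 = min(t + chunk, t_max)
        sol = solve_ivp(
            _kernels._rhs,
            (t, t1),
            y,
            method="BDF",
            jac=_kernels._jac,
            args=args,
            rtol=1e-8,
            atol=1e-11,
        )
        if not sol.success:
            raise RuntimeError(f"steady-state relaxation failed at t={t:.1f}s")
        y = np.clip(sol.y[:, -1], 0.0, None)
        t = t1
        res = residual(t, y)
    state = dict(zip(net.species, (float(v) for v in y)))
    return SteadyState(state=state, converged=bool(res < tol), residual=res, t_reached=t)
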