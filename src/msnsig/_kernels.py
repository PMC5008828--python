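"""Array-compiled right-hand side and Jacobian for the mass-action ODEs.

The network is flattened into index arrays (at most two reactant and two
product slots per reaction; a stoichiometry-two species occupies both slots).
Clamped inputs (calcium, dopamine) are evaluated in closed form inside the
RHS from the stimulus parameters, so the integrator sees smooth forcing with
no interpolation error.

If numba is importable the kernels are JIT-compiled; otherwise a pure-numpy
fallback with identical semantics is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class CompiledNetwork:
    """Flattened reaction arrays plus clamped-input metadata."""

    species: list
    ri1: np.ndarray
    ri2: np.ndarray
    pi1: np.ndarray
    pi2: np.ndarray
    kf: np.ndarray
    kr: np.ndarray
    ica: int
    ida: int
    y0: np.ndarray
    extra_clamped: list


@dataclass
class StimulusArrays:
    """Closed-form stimulus parameters packed for the kernels."""

    ca_t0: np.ndarray
    ca_amp: float
    ca_rise: float
    ca_decay: float
    ca_basal: float
    da_t0: np.ndarray
    da_amp: float  # amplitude above basal
    da_dur: float
    da_edge: float
    da_basal: float


def compile_network(model) -> CompiledNetwork:
    model.validate()
    idx = model.species_index()
    nr = len(model.reactions)
    ri1 = np.full(nr, -1, dtype=np.int64)
    ri2 = np.full(nr, -1, dtype=np.int64)
    pi1 = np.full(nr, -1, dtype=np.int64)
    pi2 = np.full(nr, -1, dtype=np.int64)
    kf = np.zeros(nr)
    kr = np.zeros(nr)
    for j, r in enumerate(model.reactions):
        slots = []
        for name, stoich in r.reactants:
            slots.extend([idx[name]] * stoich)
        if len(slots) > 2:
            raise ValueError(f"reaction {r.id!r}: reactant order > 2")
        if slots:
            ri1[j] = slots[0]
        if len(slots) == 2:
            ri2[j] = slots[1]
        slots = []
        for name, stoich in r.products:
            slots.extend([idx[name]] * stoich)
        if len(slots) > 2:
            raise ValueError(f"reaction {r.id!r}: product order > 2")
        if slots:
            pi1[j] = slots[0]
        if len(slots) == 2:
            pi2[j] = slots[1]
        kf[j] = r.kf
        kr[j] = r.kr
    # the engine drives two kinds of stimulus-driven input, named by
    # convention "Ca" and "DA"; any other clamped species must be held at a
    # constant level supplied via the ``clamp`` argument of the engine
    ica = ida = -1
    extra_clamped: list[str] = []
    for s in model.species:
        if s.is_clamped_input:
            if s.name == "Ca":
                ica = idx[s.name]
            elif s.name == "DA":
                ida = idx[s.name]
            else:
                extra_clamped.append(s.name)
    y0 = np.array([s.initial_concentration for s in model.species], dtype=float)
    return CompiledNetwork(
        species=model.species_names(),
        ri1=ri1,
        ri2=ri2,
        pi1=pi1,
        pi2=pi2,
        kf=kf,
        kr=kr,
        ica=ica,
        ida=ida,
        y0=y0,
        extra_clamped=extra_clamped,
    )


def pack_stimulus(protocol) -> StimulusArrays:
    cal = protocol.calcium
    da = protocol.dopamine
    if da is not None:
        da_t0 = np.asarray(protocol.dopamine_onsets(), dtype=float)
        da_amp = da.amplitude - da.basal
        da_dur = da.duration
        da_edge = da.edge_tau
        da_basal = da.basal
    else:
        from .stimulus import DA_BASAL

        da_t0 = np.empty(0)
        da_amp, da_dur, da_edge, da_basal = 0.0, 1.0, 0.01, DA_BASAL
    return StimulusArrays(
        ca_t0=np.asarray(protocol.all_pulse_onsets(), dtype=float),
        ca_amp=cal.pulse_amplitude(),
        ca_rise=cal.rise_tau,
        ca_decay=cal.decay_tau,
        ca_basal=cal.basal,
        da_t0=da_t0,
        da_amp=da_amp,
        da_dur=da_dur,
        da_edge=da_edge,
        da_basal=da_basal,
    )


@njit(cache=False)
def _ca_value(t, ca_t0, ca_amp, ca_rise, ca_decay, ca_basal):
    v = ca_basal
    for k in range(ca_t0.size):
        tau = t - ca_t0[k]
        if tau > 0.0:
            v += ca_amp * (math.exp(-tau / ca_decay) - math.exp(-tau / ca_rise))
    return v


@njit(cache=False)
def _da_value(t, da_t0, da_amp, da_dur, da_edge, da_basal):
    v = da_basal
    for k in range(da_t0.size):
        tau = t - da_t0[k]
        if tau > 0.0:
            if tau <= da_dur:
                v += da_amp * (1.0 - math.exp(-tau / da_edge))
            else:
                level = da_amp * (1.0 - math.exp(-da_dur / da_edge))
                v += level * math.exp(-(tau - da_dur) / da_edge)
    return v


@njit(cache=False)
def _rhs(
    t,
    y,
    cl_idx,
    cl_val,
    ri1,
    ri2,
    pi1,
    pi2,
    kf,
    kr,
    ica,
    ida,
    ca_t0,
    ca_amp,
    ca_rise,
    ca_decay,
    ca_basal,
    da_t0,
    da_amp,
    da_dur,
    da_edge,
    da_basal,
):
    n = y.size
    w = np.empty(n)
    for i in range(n):
        w[i] = y[i] if y[i] > 0.0 else 0.0
    if ica >= 0:
        w[ica] = _ca_value(t, ca_t0, ca_amp, ca_rise, ca_decay, ca_basal)
    if ida >= 0:
        w[ida] = _da_value(t, da_t0, da_amp, da_dur, da_edge, da_basal)
    for k in range(cl_idx.size):
        w[cl_idx[k]] = cl_val[k]
    dy = np.zeros(n)
    for j in range(ri1.size):
        fwd = kf[j]
        if ri1[j] >= 0:
            fwd *= w[ri1[j]]
        if ri2[j] >= 0:
            fwd *= w[ri2[j]]
        bwd = 0.0
        if kr[j] > 0.0:
            bwd = kr[j]
            if pi1[j] >= 0:
                bwd *= w[pi1[j]]
            if pi2[j] >= 0:
                bwd *= w[pi2[j]]
        v = fwd - bwd
        if ri1[j] >= 0:
            dy[ri1[j]] -= v
        if ri2[j] >= 0:
            dy[ri2[j]] -= v
        if pi1[j] >= 0:
            dy[pi1[j]] += v
        if pi2[j] >= 0:
            dy[pi2[j]] += v
    if ica >= 0:
        dy[ica] = 0.0
    if ida >= 0:
        dy[ida] = 0.0
    for k in range(cl_idx.size):
        dy[cl_idx[k]] = 0.0
    return dy


@njit(cache=False)
def _jac(
    t,
    y,
    cl_idx,
    cl_val,
    ri1,
    ri2,
    pi1,
    pi2,
    kf,
    kr,
    ica,
    ida,
    ca_t0,
    ca_amp,
    ca_rise,
    ca_decay,
    ca_basal,
    da_t0,
    da_amp,
    da_dur,
    da_edge,
    da_basal,
):
    n = y.size
    w = np.empty(n)
    for i in range(n):
        w[i] = y[i] if y[i] > 0.0 else 0.0
    if ica >= 0:
        w[ica] = _ca_value(t, ca_t0, ca_amp, ca_rise, ca_decay, ca_basal)
    if ida >= 0:
        w[ida] = _da_value(t, da_t0, da_amp, da_dur, da_edge, da_basal)
    for k in range(cl_idx.size):
        w[cl_idx[k]] = cl_val[k]
    J = np.zeros((n, n))
    for j in range(ri1.size):
        a = ri1[j]
        b = ri2[j]
        p = pi1[j]
        q = pi2[j]
        # forward-flux partials
        if a >= 0:
            dfa = kf[j] * (w[b] if b >= 0 else 1.0)
            _scatter(J, a, b, p, q, a, dfa)
        if b >= 0 and b != a:
            dfb = kf[j] * w[a]
            _scatter(J, a, b, p, q, b, dfb)
        elif b >= 0 and b == a:
            # y^2 term: total derivative is 2*kf*y; the slot above added one
            _scatter(J, a, b, p, q, a, kf[j] * w[a])
        # backward-flux partials (negative contribution to net flux)
        if kr[j] > 0.0:
            if p >= 0:
                dfp = -kr[j] * (w[q] if q >= 0 else 1.0)
                _scatter(J, a, b, p, q, p, dfp)
            if q >= 0 and q != p:
                _scatter(J, a, b, p, q, q, -kr[j] * w[p])
            elif q >= 0 and q == p:
                _scatter(J, a, b, p, q, p, -kr[j] * w[p])
    if ica >= 0:
        J[ica, :] = 0.0
        J[:, ica] = 0.0
    if ida >= 0:
        J[ida, :] = 0.0
        J[:, ida] = 0.0
    for k in range(cl_idx.size):
        J[cl_idx[k], :] = 0.0
        J[:, cl_idx[k]] = 0.0
    return J


@njit(cache=False)
def _scatter(J, a, b, p, q, col, dv):
    if a >= 0:
        J[a, col] -= dv
    if b >= 0:
        J[b, col] -= dv
    if p >= 0:
        J[p, col] += dv
    if q >= 0:
        J[q, col] += dv
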