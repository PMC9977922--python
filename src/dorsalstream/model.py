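"""Deterministic right-hand side of the delayed three-area neural mass model.

The network state collects, for every population channel and every
long-projection channel, the pair (y, x) = (postsynaptic potential,
its derivative).  Every channel obeys the same second-order synaptic
dynamics

    dy/dt = x
    dx/dt = H * a * u(t) - 2 * a * x - a**2 * y

where ``u`` is the channel input: the population firing rate (plus the
exogenous drive p/c_ep for eIN channels), or ``k_ij * z_pj(t - T)`` for a
projection channel.  sIN channels use (H_s, a_s), fIN channels
(H_f, a_f), and all other channels — including the projections, which
are excitatory synapses of the *target* area — use (H_e, a_e).

This module is the plain-numpy reference implementation; the fast
numba kernel in :mod:`dorsalstream._kernel` is validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AREA_IDS, PROJECTIONS, Model, SigmoidParams

__all__ = [
    "STATE_DIM",
    "POPULATIONS",
    "NetworkState",
    "PopulationSignals",
    "sigmoid",
    "membrane_potentials",
    "rhs",
]

#: populations per area, in state order
POPULATIONS = ("p", "e", "s", "f")

#: total state dimension: 12 population + 6 projection channels, (y, x) each
STATE_DIM = 2 * (len(AREA_IDS) * len(POPULATIONS) + len(PROJECTIONS))

_PROJ_NAMES = tuple(p[0] for p in PROJECTIONS)


def _pop_index(area: int, pop: int) -> int:
    return 2 * (area * len(POPULATIONS) + pop)


def _proj_index(chan: int) -> int:
    return 2 * len(AREA_IDS) * len(POPULATIONS) + 2 * chan


class NetworkState:
    """Named view over the flat 36-component state vector.

    Thin convenience wrapper: the integrator works on the raw vector,
    tests and users can address components as ``state.y('v1', 'e')`` or
    ``state.y_proj('k21')``.
    """

    __slots__ = ("vector",)

    def __init__(self, vector: np.ndarray | None = None):
        if vector is None:
            vector = np.zeros(STATE_DIM)
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (STATE_DIM,):
            raise ValueError(f"state vector must have shape ({STATE_DIM},)")
        self.vector = vector

    def _pop(self, area_id: str, pop: str) -> int:
        return _pop_index(AREA_IDS.index(area_id), POPULATIONS.index(pop))

    def y(self, area_id: str, pop: str) -> float:
        return float(self.vector[self._pop(area_id, pop)])

    def x(self, area_id: str, pop: str) -> float:
        return float(self.vector[self._pop(area_id, pop) + 1])

    def set_y(self, area_id: str, pop: str, value: float) -> None:
        self.vector[self._pop(area_id, pop)] = value

    def y_proj(self, name: str) -> float:
        return float(self.vector[_proj_index(_PROJ_NAMES.index(name))])

    def set_y_proj(self, name: str, value: float) -> None:
        self.vector[_proj_index(_PROJ_NAMES.index(name))] = value

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.vector)))


@dataclass(frozen=True)
class PopulationSignals:
    """Membrane potentials v (mV) and firing rates z = S(v) (s^-1).

    Arrays are indexed ``[area, population]`` with areas (v1, v2, v5) and
    populations (PY, eIN, sIN, fIN).  For non-pyramidal populations the
    "membrane potential" is the summed synaptic input that feeds the
    sigmoid, exactly as the model equations prescribe.
    """

    v: np.ndarray
    z: np.ndarray

    def v_p(self, area_id: str) -> float:
        return float(self.v[AREA_IDS.index(area_id), 0])


def sigmoid(v, params: SigmoidParams = SigmoidParams()):
    """Odd firing-rate sigmoid ``2 e0 / (1 + exp(-r v)) - e0``.

    Strictly increasing, bounded in (-e0, e0), zero at zero.  Accepts
    scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    out = 2.0 * params.e0 / (1.0 + np.exp(-params.r * v)) - params.e0
    return out if out.ndim else float(out)


def membrane_potentials(state: NetworkState | np.ndarray, model: Model) -> PopulationSignals:
    """Summed synaptic inputs and firing rates of all twelve populations.

    Projection channels add to their targets as the connectivity rules
    prescribe: descending projections (y_21, y_51 in v1; y_52 in v2) add
    to the pyramidal potential *and* to the fIN input, ascending ones
    (y_12 in v2; y_15, y_25 in v5) add to the eIN input.  Area v5, top of
    the hierarchy here, receives no descending input.
    """
    vec = state.vector if isinstance(state, NetworkState) else np.asarray(state, float)
    v = np.zeros((3, 4))
    yq = [vec[_proj_index(c)] for c in range(6)]  # k21, k51, k52, k12, k15, k25
    desc = (yq[0] + yq[1], yq[2], 0.0)   # descending input per area
    asc = (0.0, yq[3], yq[4] + yq[5])    # ascending input per area
    for a, area in enumerate(model.areas):
        yp = vec[_pop_index(a, 0)]
        ye = vec[_pop_index(a, 1)]
        ys = vec[_pop_index(a, 2)]
        yf = vec[_pop_index(a, 3)]
        v[a, 0] = area.c_ep * ye - area.c_fp * yf - area.c_sp * ys + desc[a]
        v[a, 1] = area.c_pe * yp + asc[a]
        v[a, 2] = area.c_ps * yp - area.c_fs * yf
        v[a, 3] = area.c_pf * yp - area.c_sf * ys + desc[a]
    return PopulationSignals(v=v, z=sigmoid(v, model.sigmoid))


def rhs(
    t: float,
    state: NetworkState | np.ndarray,
    delayed_rates: np.ndarray,
    noise_drive: np.ndarray,
    model: Model,
) -> np.ndarray:
    """Drift of the 36-dimensional delayed system.

    Parameters
    ----------
    t
        Time (s); unused (the system is autonomous) but kept for the
        standard ODE signature.
    delayed_rates
        Pyramidal firing rates ``(z_p1, z_p2, z_p5)`` evaluated at
        ``t - T``; the integrator owns the history buffer.
    noise_drive
        Exogenous drive ``p_i`` per area (firing-rate-like units); the
        term ``p_i / c_epi`` is added to the eIN channel input.
    """
    vec = state.vector if isinstance(state, NetworkState) else np.asarray(state, float)
    sig = membrane_potentials(vec, model)
    dv = np.empty(STATE_DIM)
    for a, area in enumerate(model.areas):
        H = (area.H_e, area.H_e, area.H_s, area.H_f)
        rate = (area.a_e, area.a_e, area.a_s, area.a_f)
        u = sig.z[a].copy()
        u[1] += noise_drive[a] / area.c_ep
        for m in range(4):
            i = _pop_index(a, m)
            y, x = vec[i], vec[i + 1]
            dv[i] = x
            dv[i + 1] = H[m] * rate[m] * u[m] - 2.0 * rate[m] * x - rate[m] ** 2 * y
    src_idx = {"v1": 0, "v2": 1, "v5": 2}
    for c, (name, src, tgt) in enumerate(PROJECTIONS):
        area = model.area(tgt)
        i = _proj_index(c)
        y, x = vec[i], vec[i + 1]
        u = model.conn.k(name) * delayed_rates[src_idx[src]]
        dv[i] = x
        dv[i + 1] = area.H_e * area.a_e * u - 2.0 * area.a_e * x - area.a_e ** 2 * y
    return dv
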