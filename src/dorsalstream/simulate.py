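"""Fixed-step Euler integration of the delayed stochastic network.

The numerical protocol follows the published one: explicit Euler with
dt = 2 ms, 600 s of simulated time of which the first 30 s are discarded
as transient, zero initial state, and a delay history buffer initialized
at the resting rate (zero, since S(0) = 0).  The exogenous drive is one
independent Gaussian sample per step and per area.

Two backends produce identical trajectories for identical inputs: a
numba-compiled kernel (default) and a slow pure-numpy reference built on
:func:`dorsalstream.model.rhs`, retained as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import model as _model
from ._kernel import PROJ_SRC, PROJ_TGT, euler_run
from .params import AREA_IDS, Model

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationError",
    "simulate",
    "simulate_ensemble",
]

CHANNELS = ("v_p1", "v_p2", "v_p5")


class SimulationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical protocol for one run.

    duration, transient are in seconds; ``dt`` must divide the
    conduction delay T exactly (10 ms / 2 ms = 5 steps by default).
    ``noise_scaling='per_step'`` draws N(mean, var) once per step;
    ``'sqrt_dt'`` scales the standard deviation by 1/sqrt(dt) so that
    ``var`` is a white-noise intensity instead.
    """

    duration: float = 600.0
    dt: float = 0.002
    transient: float = 30.0
    seed: int = 0
    record: str = "pyramidal"      # or "full"
    noise_scaling: str = "per_step"  # or "sqrt_dt"
    backend: str = "numba"         # or "reference"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.duration > self.transient >= 0):
            raise ValueError("need duration > transient >= 0")
        if self.record not in ("pyramidal", "full"):
            raise ValueError("record must be 'pyramidal' or 'full'")
        if self.noise_scaling not in ("per_step", "sqrt_dt"):
            raise ValueError("noise_scaling must be 'per_step' or 'sqrt_dt'")
        if self.backend not in ("numba", "reference"):
            raise ValueError("backend must be 'numba' or 'reference'")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_transient(self) -> int:
        return int(round(self.transient / self.dt))

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def delay_steps(self, T: float) -> int:
        d = T / self.dt
        if abs(d - round(d)) > 1e-9 or round(d) < 1:
            raise ValueError(f"delay T={T} s must be a positive integer multiple of dt={self.dt} s")
        return int(round(d))


@dataclass(frozen=True)
class SimulationResult:
    """Sampled pyramidal membrane potentials with full provenance."""

    times: np.ndarray          # (n,) seconds, absolute simulation time
    data: np.ndarray           # (n, 3) v_p1, v_p2, v_p5 in mV
    fs: float                  # sampling rate, Hz
    seed: int
    config: SimulationConfig
    params: dict               # flat parameter snapshot (symbol -> value)
    full_state: np.ndarray | None = None   # (n, 36) if record='full'

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]

    def __len__(self) -> int:
        return self.data.shape[0]

    # -- plain-text round trip ------------------------------------------
    def to_tsv(self, path) -> None:
        """Columnar text (time, v_p1, v_p2, v_p5) with a provenance header."""
        header = [f"fs: {self.fs!r}", f"seed: {self.seed}"]
        header += [f"param {k}: {v!r}" for k, v in sorted(self.params.items())]
        header += [f"config {k}: {getattr(self.config, k)!r}"
                   for k in ("duration", "dt", "transient", "noise_scaling")]
        np.savetxt(path, np.column_stack([self.times, self.data]),
                   fmt="%.10e", delimiter="\t",
                   header="\n".join(header + ["time\t" + "\t".join(CHANNELS)]))

    @staticmethod
    def from_tsv(path) -> "SimulationResult":
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                text = line[1:].strip()
                if ":" in text:
                    key, _, val = text.partition(":")
                    meta[key.strip()] = val.strip()
        arr = np.loadtxt(path, delimiter="\t")
        params = {k[len("param "):]: float(v) for k, v in meta.items()
                  if k.startswith("param ")}
        cfg = SimulationConfig(
            duration=float(meta.get("config duration", 600.0)),
            dt=float(meta.get("config dt", 0.002)),
            transient=float(meta.get("config transient", 30.0)),
            seed=int(meta.get("seed", 0)),
            noise_scaling=meta.get("config noise_scaling", "per_step").strip("'\""),
        )
        return SimulationResult(times=arr[:, 0], data=arr[:, 1:4],
                                fs=float(meta.get("fs", 500.0)),
                                seed=int(meta.get("seed", 0)),
                                config=cfg, params=params)

    def to_npz(self, path) -> None:
        """Binary container with the parameter snapshot."""
        np.savez_compressed(
            path, times=self.times, data=self.data, fs=self.fs, seed=self.seed,
            param_names=np.array(sorted(self.params)),
            param_values=np.array([self.params[k] for k in sorted(self.params)]),
        )


def draw_noise(model: Model, cfg: SimulationConfig) -> np.ndarray:
    """Exogenous drive samples, one independent stream per area.

    Stream ``a`` is seeded deterministically from ``(seed, a)`` so that
    run-to-run and area-to-area streams are independent but reproducible.
    """
    n = cfg.n_steps
    noise = np.empty((n, 3))
    for a, area in enumerate(model.areas):
        std = np.sqrt(area.noise_var)
        if cfg.noise_scaling == "sqrt_dt":
            std /= np.sqrt(cfg.dt)
        rng = np.random.default_rng([int(cfg.seed), a])
        noise[:, a] = rng.normal(area.noise_mean, std, n)
    return noise


def _pack(model: Model):
    H = np.empty((3, 4)); a = np.empty((3, 4)); c = np.empty((3, 8))
    for i, ar in enumerate(model.areas):
        H[i] = (ar.H_e, ar.H_e, ar.H_s, ar.H_f)
        a[i] = (ar.a_e, ar.a_e, ar.a_s, ar.a_f)
        c[i] = (ar.c_pe, ar.c_pf, ar.c_ps, ar.c_ep,
                ar.c_fp, ar.c_fs, ar.c_sp, ar.c_sf)
    k = np.array([model.conn.k(name)
                  for name in ("k21", "k51", "k52", "k12", "k15", "k25")])
    return H, a, c, k


def simulate(model: Model, cfg: SimulationConfig | None = None) -> SimulationResult:
    """Run one stochastic simulation and return the post-transient samples."""
    cfg = cfg or SimulationConfig()
    d = cfg.delay_steps(model.conn.T)
    n = cfg.n_steps
    noise = draw_noise(model, cfg)
    record_full = cfg.record == "full"
    state = np.zeros(_model.STATE_DIM)
    out_vp = np.empty((n, 3))
    out_full = np.empty((n, _model.STATE_DIM)) if record_full else np.empty((1, _model.STATE_DIM))

    if cfg.backend == "numba":
        H, a, c, k = _pack(model)
        bad = euler_run(state, n, cfg.dt, d, model.sigmoid.e0, model.sigmoid.r,
                        H, a, c, k, noise, PROJ_SRC, PROJ_TGT,
                        out_vp, out_full, record_full)
        if bad >= 0:
            raise SimulationError(
                f"state became non-finite at step {bad} (t = {bad * cfg.dt:.3f} s)")
    else:
        _reference_loop(model, cfg, d, noise, state, out_vp,
                        out_full if record_full else None)

    keep = slice(cfg.n_transient, n)
    times = np.arange(n)[keep] * cfg.dt
    return SimulationResult(
        times=times, data=out_vp[keep].copy(), fs=cfg.fs, seed=cfg.seed,
        config=cfg, params=model.to_flat(),
        full_state=out_full[keep].copy() if record_full else None,
    )


def _reference_loop(model, cfg, d, noise, state, out_vp, out_full) -> None:
    """Pure-numpy Euler loop over model.rhs (independent oracle path)."""
    zhist = np.zeros((cfg.n_steps, 3))
    for i in range(cfg.n_steps):
        sig = _model.membrane_potentials(state, model)
        vp = sig.v[:, 0]
        out_vp[i] = vp
        if out_full is not None:
            out_full[i] = state
        if not np.all(np.isfinite(vp)):
            raise SimulationError(
                f"state became non-finite at step {i} (t = {i * cfg.dt:.3f} s)")
        zhist[i] = sig.z[:, 0]
        delayed = zhist[i - d] if i - d >= 0 else np.zeros(3)
        state += cfg.dt * _model.rhs(i * cfg.dt, state, delayed, noise[i], model)


def simulate_ensemble(
    model: Model,
    cfg: SimulationConfig | None = None,
    n_runs: int = 50,
    base_seed: int = 0,
) -> list[SimulationResult]:
    """``n_runs`` independent runs seeded ``base_seed + run_index``.

    The published protocol averages spectra over 50 such runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = cfg or SimulationConfig()
    results = []
    for run_idx in range(n_runs):
        run_cfg = replace(cfg, seed=int(base_seed) + run_idx)
        try:
            results.append(simulate(model, run_cfg))
        except SimulationError as err:
            raise SimulationError(f"run {run_idx} (seed {run_cfg.seed}): {err}") from err
    return results
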