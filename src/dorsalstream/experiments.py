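"""Projection-loss experiments: uncoupled baseline and coherence-vs-k sweeps.

The three canonical experiments lesion one long projection at a time
while holding every other projection at 10, emulating the synaptic-loss
condition: the descending v2->v1 projection (k21, swept 20..0, coherence
read out as the 24.5-25.25 Hz band mean between v_p2 and v_p1), the
descending v5->v2 projection (k52, 25..0, 11.5-12 Hz, v_p5 vs v_p2) and
the ascending v2->v5 projection (k25, 50..0, 25.75-26.25 Hz, v_p2 vs
v_p5).  The uncoupled baseline (all k = 0) exposes each area's intrinsic
rhythm: gamma in v1, beta in v2, alpha in v5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import analysis
from .params import Model, build_default_model
from .simulate import CHANNELS, SimulationConfig, simulate_ensemble

__all__ = [
    "AnalysisProtocol",
    "SweepSpec",
    "SweepResult",
    "BaselineResult",
    "PRESET_SWEEPS",
    "run_condition",
    "run_uncoupled_baseline",
    "run_sweep",
]

PROJECTION_NAMES = ("k12", "k15", "k25", "k21", "k51", "k52")


@dataclass(frozen=True)
class AnalysisProtocol:
    """Filtering and spectral-estimation settings shared by all experiments."""

    f_lo: float = 3.0
    f_hi: float = 60.0
    filter_order: int = 5
    seg_seconds: float = 4.0          # 0.25 Hz resolution at 500 Hz
    overlap_fraction: float = 0.5
    window_name: str = "hamming"
    coherence_method: str = "average"  # per-run curves averaged; or "pooled"

    def seg_len(self, fs: float) -> int:
        return int(round(self.seg_seconds * fs))


@dataclass(frozen=True)
class ConditionResult:
    """Ensemble-averaged spectra and coherence for one parameter setting."""

    overrides: dict
    spectra: dict               # channel -> Spectrum (ensemble averaged)
    coherences: dict            # (chan_x, chan_y) -> CoherenceCurve
    n_runs: int
    base_seed: int
    config: SimulationConfig


def run_condition(
    overrides: dict,
    cfg: SimulationConfig | None = None,
    n_runs: int = 50,
    base_seed: int = 0,
    pairs: Sequence[tuple[str, str]] = (),
    protocol: AnalysisProtocol = AnalysisProtocol(),
    model: Model | None = None,
) -> ConditionResult:
    """Simulate an ensemble for one parameter setting and analyse it.

    ``overrides`` are flat symbol-name overrides applied to the default
    model (or to ``model`` if given).  Every run is band-pass filtered,
    then PSDs are averaged across runs and coherence is computed per run
    and averaged (or pooled, per the protocol).
    """
    cfg = cfg or SimulationConfig()
    model = (model or build_default_model()).replace(**overrides)
    runs = simulate_ensemble(model, cfg, n_runs=n_runs, base_seed=base_seed)
    fs = cfg.fs
    seg = protocol.seg_len(fs)
    filtered = [
        analysis.bandpass(r.data, fs, protocol.f_lo, protocol.f_hi,
                          order=protocol.filter_order)
        for r in runs
    ]
    spectra = {}
    for ci, chan in enumerate(CHANNELS):
        per_run = [analysis.welch_psd(f[:, ci], fs, seg_len=seg,
                                      overlap_fraction=protocol.overlap_fraction,
                                      window_name=protocol.window_name)
                   for f in filtered]
        spectra[chan] = analysis.average_spectra(per_run)
    coherences = {}
    for cx, cy in pairs:
        ix, iy = CHANNELS.index(cx), CHANNELS.index(cy)
        if protocol.coherence_method == "pooled":
            curve = analysis.pooled_coherence(
                [f[:, ix] for f in filtered], [f[:, iy] for f in filtered],
                fs, seg_len=seg, overlap_fraction=protocol.overlap_fraction,
                window_name=protocol.window_name)
        else:
            per_run = [analysis.coherence(f[:, ix], f[:, iy], fs, seg_len=seg,
                                          overlap_fraction=protocol.overlap_fraction,
                                          window_name=protocol.window_name)
                       for f in filtered]
            curve = analysis.average_coherence(per_run)
        coherences[(cx, cy)] = curve
    return ConditionResult(overrides=dict(overrides), spectra=spectra,
                           coherences=coherences, n_runs=n_runs,
                           base_seed=base_seed, config=cfg)


# ---------------------------------------------------------------------------
# Baseline

@dataclass(frozen=True)
class BaselineResult:
    spectra: dict               # channel -> ensemble-averaged Spectrum
    peak_freqs: dict            # channel -> peak frequency over the full band
    n_runs: int
    base_seed: int
    config: SimulationConfig


def run_uncoupled_baseline(
    cfg: SimulationConfig | None = None,
    n_runs: int = 50,
    base_seed: int = 0,
    protocol: AnalysisProtocol = AnalysisProtocol(),
) -> BaselineResult:
    """All projections at zero: each area expresses its intrinsic rhythm."""
    overrides = {name: 0.0 for name in PROJECTION_NAMES}
    cond = run_condition(overrides, cfg=cfg, n_runs=n_runs,
                         base_seed=base_seed, protocol=protocol)
    peaks = {
        chan: analysis.peak_frequency(spec, protocol.f_lo, protocol.f_hi)
        for chan, spec in cond.spectra.items()
    }
    return BaselineResult(spectra=cond.spectra, peak_freqs=peaks,
                          n_runs=n_runs, base_seed=base_seed, config=cond.config)


# ---------------------------------------------------------------------------
# Sweeps

@dataclass(frozen=True)
class SweepSpec:
    """One projection swept over a value grid, the others held fixed."""

    projection: str
    values: tuple[float, ...]
    fixed: float = 10.0
    n_runs: int = 50
    band: tuple[float, float] = (24.5, 25.25)
    pair: tuple[str, str] = ("v_p2", "v_p1")
    compute_phase_metrics: bool = False
    phase_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.projection not in PROJECTION_NAMES:
            raise ValueError(f"unknown projection {self.projection!r}")
        if any(v < 0 for v in self.values):
            raise ValueError("swept values must be non-negative")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("invalid analysis band")
        for chan in self.pair:
            if chan not in CHANNELS:
                raise ValueError(f"unknown channel {chan!r}")

    def overrides_for(self, value: float) -> dict:
        ov = {name: self.fixed for name in PROJECTION_NAMES}
        ov[self.projection] = float(value)
        return ov


def _grid(hi: int) -> tuple[float, ...]:
    return tuple(float(v) for v in range(hi, -1, -1))


#: the three canonical lesion experiments (descending v2->v1, descending
#: v5->v2, ascending v2->v5) with their published read-out bands
PRESET_SWEEPS = {
    "k21": SweepSpec("k21", _grid(20), band=(24.5, 25.25), pair=("v_p2", "v_p1")),
    "k52": SweepSpec("k52", _grid(25), band=(11.5, 12.0), pair=("v_p5", "v_p2")),
    "k25": SweepSpec("k25", _grid(50), band=(25.75, 26.25), pair=("v_p2", "v_p5")),
}


@dataclass(frozen=True)
class SweepResult:
    """Band-mean coherence (and spectra) for every swept projection value."""

    spec: SweepSpec
    values: tuple[float, ...]
    coherence: np.ndarray            # band-mean coherence per value
    curves: list                     # CoherenceCurve per value
    spectra: list                    # dict channel -> Spectrum per value
    plv: np.ndarray | None
    ppc: np.ndarray | None
    base_seed: int
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        header = [
            f"projection: {self.spec.projection}",
            f"fixed others: {self.spec.fixed}",
            f"band Hz: {self.spec.band[0]}-{self.spec.band[1]}",
            f"pair: {self.spec.pair[0]} vs {self.spec.pair[1]}",
            f"n_runs: {self.spec.n_runs}",
            f"base_seed: {self.base_seed}",
            f"duration s: {self.config.duration}", f"dt s: {self.config.dt}",
        ]
        cols = [np.asarray(self.values), self.coherence]
        names = [self.spec.projection, "coherence"]
        if self.plv is not None:
            cols += [self.plv, self.ppc]
            names += ["plv", "ppc"]
        np.savetxt(path, np.column_stack(cols), fmt="%.8g", delimiter="\t",
                   header="\n".join(header + ["\t".join(names)]))


def run_sweep(
    spec: SweepSpec,
    cfg: SimulationConfig | None = None,
    base_seed: int = 0,
    protocol: AnalysisProtocol = AnalysisProtocol(),
) -> SweepResult:
    """Run the ensemble at every swept value and collect coherence curves.

    Seeds advance by ``n_runs`` between values so no two runs in the
    sweep share a noise stream.
    """
    cfg = cfg or SimulationConfig()
    coh, curves, spectra = [], [], []
    plvs, ppcs = [], []
    for vi, value in enumerate(spec.values):
        seed = base_seed + vi * spec.n_runs
        cond = run_condition(spec.overrides_for(value), cfg=cfg,
                             n_runs=spec.n_runs, base_seed=seed,
                             pairs=[spec.pair], protocol=protocol)
        curve = cond.coherences[spec.pair]
        curves.append(curve)
        spectra.append(cond.spectra)
        coh.append(analysis.band_mean_coherence(curve, *spec.band))
        if spec.compute_phase_metrics:
            lo, hi = spec.phase_band or spec.band
            p_vals, q_vals = [], []
            model = build_default_model(spec.overrides_for(value))
            for run in simulate_ensemble(model, cfg, n_runs=min(spec.n_runs, 5),
                                         base_seed=seed):
                x = analysis.bandpass(run.channel(spec.pair[0]), cfg.fs, lo, hi)
                y = analysis.bandpass(run.channel(spec.pair[1]), cfg.fs, lo, hi)
                p_vals.append(analysis.plv(x, y))
                q_vals.append(analysis.ppc(x, y))
            plvs.append(float(np.mean(p_vals)))
            ppcs.append(float(np.mean(q_vals)))
    return SweepResult(
        spec=spec, values=tuple(spec.values), coherence=np.asarray(coh),
        curves=curves, spectra=spectra,
        plv=np.asarray(plvs) if plvs else None,
        ppc=np.asarray(ppcs) if ppcs else None,
        base_seed=base_seed, config=cfg,
    )


def write_manifest(path, **entries) -> None:
    """JSON run manifest with enough provenance to re-run bit-identically."""
    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        return str(obj)
    Path(path).write_text(json.dumps(entries, indent=2, default=default))
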