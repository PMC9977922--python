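"""Model parameters for the three-area dorsal-pathway neural mass model.

Each cortical area (v1, v2, v5) contains four neural populations —
pyramidal cells (PY), excitatory interneurons (eIN), slow inhibitory
interneurons (sIN) and fast inhibitory interneurons (fIN) — each modelled
as a second-order synaptic channel with gain ``H`` (mV) and rate constant
``a`` (s^-1).  The areas are linked by six long cortico-cortical
projections: ascending ones terminate on the target's eIN, descending
ones on the target's PY and fIN, all with a shared conduction delay ``T``.

Defaults reproduce the published parameterization of this pathway model
(intra-area weights expressed as fractions of the PY->eIN weight), with
one documented exception: the exogenous noise mean defaults to zero
because the firing-rate sigmoid used here is odd and centred at zero, so
a symmetric exogenous drive is the operating condition that produces the
intrinsic gamma/beta/alpha rhythms of areas v1/v2/v5 (see
docs/methods.md for the full discussion).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "AREA_IDS",
    "PROJECTIONS",
    "SigmoidParams",
    "AreaParams",
    "ConnectivityParams",
    "Model",
    "build_default_model",
    "load_config",
    "save_config",
]

#: canonical area ordering used everywhere in the package
AREA_IDS = ("v1", "v2", "v5")

#: projection channels as (name, source area, target area); ascending
#: projections (12, 15, 25) run up the hierarchy, descending ones
#: (21, 51, 52) run down.
PROJECTIONS = (
    ("k21", "v2", "v1"),
    ("k51", "v5", "v1"),
    ("k52", "v5", "v2"),
    ("k12", "v1", "v2"),
    ("k15", "v1", "v5"),
    ("k25", "v2", "v5"),
)


class ConfigError(ValueError):
    """Raised for unknown parameter names or invalid parameter values."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the odd firing-rate sigmoid S(v) = 2 e0 / (1 + exp(-r v)) - e0.

    ``2 * e0`` is the maximum population firing rate (s^-1) and ``r`` the
    steepness (mV^-1).  ``s0`` (mV) is carried along for config fidelity
    but does not enter the transfer function as printed; see
    docs/methods.md.
    """

    e0: float = 2.5
    r: float = 0.56
    s0: float = 6.0

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.r <= 0:
            raise ConfigError("sigmoid requires e0 > 0 and r > 0")


@dataclass(frozen=True)
class AreaParams:
    """Per-area synaptic gains, rate constants, intra-area weights and noise.

    Gains ``H_*`` are in mV, rate constants ``a_*`` in s^-1, the
    connection weights ``c_*`` are dimensionless, and the exogenous
    Gaussian drive has mean ``noise_mean`` and variance ``noise_var``
    (firing-rate-like units, entering the eIN input as p/c_ep).
    """

    area_id: str
    H_e: float
    H_s: float
    H_f: float
    a_e: float
    a_s: float
    a_f: float
    c_pe: float
    c_pf: float
    c_ps: float
    c_ep: float
    c_fp: float
    c_fs: float
    c_sp: float
    c_sf: float
    noise_mean: float = 0.0
    noise_var: float = 60.0

    def __post_init__(self) -> None:
        if self.area_id not in AREA_IDS:
            raise ConfigError(f"unknown area_id {self.area_id!r}")
        for name in ("H_e", "H_s", "H_f", "a_e", "a_s", "a_f"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0 for area {self.area_id}")
        for name in ("c_pe", "c_pf", "c_ps", "c_ep", "c_fp", "c_fs", "c_sp", "c_sf"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0 for area {self.area_id}")
        if self.noise_var < 0:
            raise ConfigError("noise_var must be >= 0")


@dataclass(frozen=True)
class ConnectivityParams:
    """Long-projection strengths k_ij (dimensionless) and shared delay T (s)."""

    k21: float = 0.0
    k51: float = 0.0
    k52: float = 0.0
    k12: float = 0.0
    k15: float = 0.0
    k25: float = 0.0
    T: float = 0.010

    def __post_init__(self) -> None:
        for name in ("k21", "k51", "k52", "k12", "k15", "k25"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.T <= 0:
            raise ConfigError("delay T must be > 0")

    def k(self, name: str) -> float:
        if name not in ("k21", "k51", "k52", "k12", "k15", "k25"):
            raise ConfigError(f"unknown projection {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class Model:
    """Full parameterization: three areas, connectivity and the sigmoid."""

    areas: tuple[AreaParams, AreaParams, AreaParams]
    conn: ConnectivityParams
    sigmoid: SigmoidParams

    def __post_init__(self) -> None:
        if tuple(a.area_id for a in self.areas) != AREA_IDS:
            raise ConfigError("areas must be (v1, v2, v5) in order")

    def area(self, area_id: str) -> AreaParams:
        return self.areas[AREA_IDS.index(area_id)]

    def replace(self, **overrides: float) -> "Model":
        """Return a copy with flat symbol-name overrides applied (e.g. k21=20)."""
        return _apply_overrides(self, overrides)

    def to_flat(self) -> dict[str, float]:
        """Flat mapping keyed by the printed symbol names (He1, Cpe2, k21, ...)."""
        flat: dict[str, float] = {}
        for key, getter, _ in _flat_fields():
            flat[key] = getter(self)
        return flat


# ---------------------------------------------------------------------------
# Default values (intra-area weights and basal constants)

_TABLE_WEIGHTS = {
    # area: (c_pe, c_pf, c_ps, c_ep, c_fp, c_fs, c_sp, c_sf)
    "v1": (65.0, 19.5, 19.5, 52.0, 52.0, 6.5, 19.5, 6.5),
    "v2": (80.0, 24.0, 24.0, 64.0, 64.0, 8.0, 24.0, 8.0),
    "v5": (59.0, 17.7, 17.7, 47.2, 47.2, 5.9, 17.7, 5.9),
}

_TABLE_GAINS = {
    # area: (H_e, H_s, H_f, a_e, a_s, a_f)
    "v1": (5.6, 3.8, 173.1, 110.0, 40.0, 790.0),
    "v2": (5.2, 4.5, 57.1, 85.0, 30.0, 350.0),
    "v5": (2.7, 3.2, 39.0, 40.0, 20.0, 300.0),
}

#: exogenous drive: variance as published; mean 0 by design (see module docstring)
_DEFAULT_NOISE = {"mean": 0.0, "var": 60.0}


def _default_area(area_id: str) -> AreaParams:
    He, Hs, Hf, ae, as_, af = _TABLE_GAINS[area_id]
    cpe, cpf, cps, cep, cfp, cfs, csp, csf = _TABLE_WEIGHTS[area_id]
    return AreaParams(
        area_id=area_id,
        H_e=He, H_s=Hs, H_f=Hf, a_e=ae, a_s=as_, a_f=af,
        c_pe=cpe, c_pf=cpf, c_ps=cps, c_ep=cep, c_fp=cfp,
        c_fs=cfs, c_sp=csp, c_sf=csf,
        noise_mean=_DEFAULT_NOISE["mean"], noise_var=_DEFAULT_NOISE["var"],
    )


def build_default_model(overrides: Mapping[str, float] | None = None) -> Model:
    """Build the default three-area model, then apply flat overrides.

    Overrides are keyed by printed symbol name, e.g. ``{"k21": 20}`` or
    ``{"He1": 5.0}``.  Unknown names raise :class:`ConfigError`.
    """
    model = Model(
        areas=tuple(_default_area(a) for a in AREA_IDS),  # type: ignore[arg-type]
        conn=ConnectivityParams(),
        sigmoid=SigmoidParams(),
    )
    if overrides:
        model = _apply_overrides(model, overrides)
    return model


# ---------------------------------------------------------------------------
# Flat symbol-name view (config file schema)

def _flat_fields() -> Iterator[tuple[str, object, object]]:
    """Yield (symbol, getter, setter-key) triples for the flat config schema."""
    def sig(name):
        return (name, lambda m, n=name: getattr(m.sigmoid, n),
                ("sigmoid", name))
    yield sig("e0")
    yield sig("r")
    yield sig("s0")
    suffix = {"v1": "1", "v2": "2", "v5": "5"}
    per_area = [
        ("He", "H_e"), ("Hs", "H_s"), ("Hf", "H_f"),
        ("ae", "a_e"), ("as", "a_s"), ("af", "a_f"),
        ("Cpe", "c_pe"), ("Cpf", "c_pf"), ("Cps", "c_ps"),
        ("Cep", "c_ep"), ("Cfp", "c_fp"), ("Cfs", "c_fs"),
        ("Csp", "c_sp"), ("Csf", "c_sf"),
        ("m", "noise_mean"), ("var", "noise_var"),
    ]
    for i, aid in enumerate(AREA_IDS):
        for sym, attr in per_area:
            key = f"{sym}{suffix[aid]}"
            yield (key,
                   lambda m, i=i, attr=attr: getattr(m.areas[i], attr),
                   ("area", i, attr))
    for name in ("k21", "k51", "k52", "k12", "k15", "k25", "T"):
        yield (name, lambda m, n=name: getattr(m.conn, n), ("conn", name))


def _apply_overrides(model: Model, overrides: Mapping[str, float]) -> Model:
    setters = {key: target for key, _, target in _flat_fields()}
    areas = [dict(dataclasses.asdict(a)) for a in model.areas]
    conn = dict(dataclasses.asdict(model.conn))
    sigm = dict(dataclasses.asdict(model.sigmoid))
    for key, value in overrides.items():
        if key not in setters:
            raise ConfigError(f"unknown parameter {key!r}")
        target = setters[key]
        value = float(value)
        if not math.isfinite(value):
            raise ConfigError(f"parameter {key!r} must be finite")
        if target[0] == "sigmoid":
            sigm[target[1]] = value
        elif target[0] == "conn":
            conn[target[1]] = value
        else:
            areas[target[1]][target[2]] = value
    return Model(
        areas=tuple(AreaParams(**a) for a in areas),  # type: ignore[arg-type]
        conn=ConnectivityParams(**conn),
        sigmoid=SigmoidParams(**sigm),
    )


# ---------------------------------------------------------------------------
# Config file I/O (flat YAML, symbol-name keys)

def save_config(model: Model, path) -> None:
    """Write the model as a flat YAML mapping keyed by printed symbol names."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_flat(), fh, sort_keys=False)


def load_config(path) -> Model:
    """Load a flat YAML config; missing keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a flat mapping")
    return build_default_model(data)


def packaged_default_config() -> str:
    """Text of the packaged default configuration file."""
    return (resources.files("dorsalstream") / "data" / "default_params.yaml").read_text()
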