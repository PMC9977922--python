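"""One stochastic simulation of the coupled three-area network.

Builds the default model with all long projections at 10 except a
strengthened descending projection from v2 to v1 (k21 = 20), integrates
the delayed stochastic system with the fixed-step Euler scheme, and
prints basic facts about the sampled pyramidal potentials, which stand
in for the EEG-like output of each area.
"""

import numpy as np

from dorsalstream import build_default_model, simulate
from dorsalstream.simulate import CHANNELS, SimulationConfig

model = build_default_model(
    {"k12": 10, "k15": 10, "k25": 10, "k51": 10, "k52": 10, "k21": 20}
)
cfg = SimulationConfig(duration=150.0, transient=30.0, seed=42)
result = simulate(model, cfg)

print(f"Simulated {cfg.duration:.0f} s at dt = {cfg.dt*1e3:.0f} ms "
      f"(first {cfg.transient:.0f} s discarded) -> {len(result)} samples/channel "
      f"at {result.fs:.0f} Hz")
for name in CHANNELS:
    v = result.channel(name)
    print(f"  {name}: mean {v.mean():7.3f} mV, fluctuation std {v.std():6.3f} mV")
print("Identical seeds reproduce this output bit for bit; the parameter")
print("snapshot travels with the result:", f"k21 = {result.params['k21']:g}")
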