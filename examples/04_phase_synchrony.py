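"""Phase-synchrony metrics agree with the coherence read-out.

The phase-locking value (PLV) and the debiased pairwise phase
consistency (PPC) measure whether two band-limited signals keep a fixed
phase relation.  Both drop when the long projection carrying the shared
rhythm is removed, confirming the coherence-based conclusion with
independent metrics.
"""

import numpy as np

from dorsalstream import analysis, build_default_model, simulate_ensemble
from dorsalstream.simulate import SimulationConfig

cfg = SimulationConfig(duration=150.0, transient=30.0)
for k21 in (20.0, 0.0):
    model = build_default_model(
        {"k12": 10, "k15": 10, "k25": 10, "k51": 10, "k52": 10, "k21": k21}
    )
    plvs, ppcs = [], []
    for run in simulate_ensemble(model, cfg, n_runs=5, base_seed=7):
        # restrict both channels to the beta band before extracting phases
        x = analysis.bandpass(run.channel("v_p2"), cfg.fs, 13, 30)
        y = analysis.bandpass(run.channel("v_p1"), cfg.fs, 13, 30)
        plvs.append(analysis.plv(x, y))
        ppcs.append(analysis.ppc(x, y))
    print(f"k21 = {k21:4.0f}:  PLV = {np.mean(plvs):.3f}   PPC = {np.mean(ppcs):.3f}")
print("PLV/PPC near 1: the areas keep a fixed beta-phase relation;")
print("near 0: their phases drift independently once the projection is cut.")
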