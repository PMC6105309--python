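"""Confound-controlled decoding of choice and evidence from population ΔF/F.

The population here encodes evidence only, so choice is decodable through
the evidence-choice correlation — and the independence shuffle, which
permutes choice within strata of matched evidence, removes exactly that
borrowed information.
"""

import numpy as np

from puffcrus import BehaviorParams, CellGroundTruth, TaskConfig
from puffcrus.decoding import decode_variable
from puffcrus.simulate import simulate_session, synthesize_soma_activity

session = simulate_session(TaskConfig(), BehaviorParams(4, 0, 0, 0), 250,
                           rng_seed=7)
cells = [CellGroundTruth(kind="evidence_L" if i % 2 else "evidence_R",
                         noise_sd=0.05) for i in range(24)]
traces = synthesize_soma_activity(cells, session,
                                  rng=np.random.default_rng(1))

rng = np.random.default_rng(2)
results = {}
for target in ("choice", "evidence_side"):
    for condition in ("real", "independent", "shuffle"):
        res = decode_variable(traces, session, target, condition, rng=rng)
        cue = (res.bin_centers > 0) & (res.bin_centers < 3.8)
        results[(target, condition)] = res.accuracy[cue].mean()

print("cue-period decoding accuracy (chance = 0.5):")
for target in ("choice", "evidence_side"):
    row = "  ".join(f"{cond}={results[(target, cond)]:.2f}"
                    for cond in ("real", "independent", "shuffle"))
    print(f"  {target:14s} {row}")
print("evidence decoding survives its controls (the cells encode it"
      " directly); choice decoding collapses to the shuffle level under the"
      " independence condition — there is no choice information beyond"
      " what evidence provides")
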