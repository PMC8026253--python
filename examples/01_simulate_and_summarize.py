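"""Simulate the foraging agent and inspect its revisit statistics.

The agent searches 15 identical objects for a hidden target.  Working
memory holds at most `capacity` inspected objects; when full, one of the
`decay` oldest entries is forgotten; each choice consults memory with
probability `utility` (otherwise it explores at random).  Revisits —
returns to an already-inspected object — are the behavioral signature of
memory failure.
"""

import numpy as np

from oculoforage import ModelParams, simulate_agent, summarize
from oculoforage.summaries import revisit_flags

params = ModelParams(capacity=10, decay=2, utility=0.9)
trials = simulate_agent(params, n_trials=5000, rng=np.random.default_rng(0))

counts = np.array([t.n_saccades for t in trials])
revisits = [f for t in trials for f in revisit_flags(t.choices)]
triplet = summarize(trials)

print(f"agent: capacity={params.capacity} decay={params.decay} utility={params.utility}")
print(f"trials: {len(trials)}, found target: {np.mean([t.found for t in trials]):.1%}")
print(f"mean saccades per trial: {counts.mean():.2f}")
print(f"overall revisit rate: {np.mean(revisits):.3%}")
print("saccade-count distribution (bins 1-15):")
print("  " + " ".join(f"{v:.3f}" for v in triplet.saccade_count_dist[:15]))

# A perfect-memory agent (capacity 15, utility 1) never revisits and finds
# the target by sampling without replacement: count uniform on 1..15, mean 8.
perfect = simulate_agent(ModelParams(15, 1, 1.0), 5000, np.random.default_rng(1))
pc = np.array([t.n_saccades for t in perfect])
print(f"\nperfect memory: mean saccades {pc.mean():.2f} (theory: 8.00), "
      f"revisits {sum(sum(revisit_flags(t.choices)) for t in perfect)}")
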