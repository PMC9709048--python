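"""Compare two model variants with the Test of Practical Equivalence.

Fits the same simulated dataset with and without the distance covariate,
subtracts the posterior draws of each contribution parameter, and asks what
proportion of the 89% highest-density interval of each difference falls
inside the region of practical equivalence (-0.05..0.05).  proportion 1
means the two models practically agree on that parameter; 0 means they
meaningfully disagree; anything else is undecided.
"""

import numpy as np

import mixedstock as ms
from mixedstock.compare import EquivalenceConfig, equivalence_test, posterior_difference
from mixedstock.simulate import SimulationSpec, simulate_dataset

# strongly uneven distances so the covariate has something to say
spec = SimulationSpec(distances=np.array([[500.0, 8000.0, 8000.0, 8000.0],
                                          [8000.0, 500.0, 8000.0, 8000.0]]), seed=9)
dataset, _ = simulate_dataset(spec)

cfg = dict(n_iter=6000, n_burnin=3000)
with_dist, _ = ms.fit(dataset, ms.ModelConfig(mode="distance_weighted", seed=1, **cfg))
without, _ = ms.fit(dataset, ms.ModelConfig(mode="base", seed=2, **cfg))

diffs = posterior_difference(with_dist, without, kind="theta")
res = equivalence_test(diffs, EquivalenceConfig())
print(res.to_dataframe().round(3).to_string(index=False))
print("\n'rejected' rows are contributions the distance covariate genuinely moves;")
print("'accepted' rows are practically unchanged between the two models.")
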