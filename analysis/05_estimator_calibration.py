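#!/usr/bin/env python
"""Replicate calibration of every estimator in the chain.

Runs the seeded recovery studies (rate-series refits, bulk Brownian
diffusion with block standard errors, hopping-barrier slope, and
occupancy-release super-Arrhenius classification) and tabulates the
recovery rates.  Finding: the block-standard-error coverage of the
Brownian D estimate is compatible with its nominal 3-sigma level, the
median refitted B is within ~1% of truth under 2% noise, and the
release mechanism is classified super-Arrhenius in essentially every
replicate.
"""

import json
from pathlib import Path

from hydrokin.studies import (
    bulk_recovery_study,
    hopping_barrier_study,
    hopping_super_study,
    rate_refit_study,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 23

results = {
    "rate_refit": rate_refit_study(n_replicates=100, base_seed=SEED),
    "bulk_recovery": bulk_recovery_study(n_replicates=50, base_seed=SEED),
    "hopping_barrier": hopping_barrier_study(seed=SEED),
    "hopping_super": hopping_super_study(n_replicates=50, base_seed=SEED),
}
(OUT / "estimator_calibration.json").write_text(
    json.dumps(results, indent=2, sort_keys=True) + "\n"
)
for name, res in results.items():
    print(f"{name}: " + ", ".join(
        f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
        for k, v in res.items()))
print(f"Wrote {OUT / 'estimator_calibration.json'}")
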