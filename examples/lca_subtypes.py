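"""Discover misuse subtypes with latent class analysis.

Fits categorical mixture models with 1..8 classes to the ten class-defining
indicators, selects the class count by BIC, and checks how well the matched
class prevalences recover the generating ones (36.5/12.8/39.2/11.5%).
"""

import numpy as np

from opioid_subtypes.config import default_config
from opioid_subtypes.lca import (
    assign_classes,
    class_separation,
    default_indicator_spec,
    match_classes,
    params_from_config,
    posterior_matrix,
    sample_indicators,
    select_model,
)

truth = params_from_config(default_config(n_encounters=0, seed=0))
spec = default_indicator_spec()
data, _ = sample_indicators(truth, 6224, seed=2)

selection = select_model(data, c_range=range(1, 9), n_starts=10, seed=3,
                         item_names=spec.names, n_levels=list(spec.n_levels))
print(" C     loglik    k      BIC     aBIC     cAIC")
for fit in selection.fits:
    print(f" {fit.params.n_classes}  {fit.loglik:9.1f}  {fit.n_params:3d}  "
          f"{fit.bic:8.1f} {fit.abic:8.1f} {fit.caic:8.1f}")
print(f"selected: {selection.selected} classes ({selection.rationale})")

fit4 = selection.fits[selection.c_values.index(4)]
perm = match_classes(fit4.params, truth)
print("matched prevalence estimates (%):", np.round(100 * fit4.params.pi[perm], 2),
      " generating:", np.round(100 * truth.pi, 1))

post = posterior_matrix(data, fit4.params)
sep = class_separation(post, assign_classes(post))
print("mean assigned-class posterior per class:",
      {c + 1: round(m, 2) for c, (m, _s) in sep.items()},
      "(values near 1 mean unambiguous assignment)")
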