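"""Simulate a placebo-controlled within-subject FC study with known truth.

Builds the default desk-scale study — 12 participants x (placebo, drug) x
(first, second half), 40 nodes in 8 networks — with the default drug effect
(within-network coupling reduced, between-network coupling raised, in the
drug-first-half cell only) and checks the injected effect in the raw sample
correlations.
"""

import numpy as np

from sdefc import ConditionEffect, NetworkScheme, StudyDesign, simulate_study

scheme = NetworkScheme.balanced()          # 8 networks x 5 nodes
design = StudyDesign(timepoints_per_half=400, seed=1)
effect = ConditionEffect.default_drug_effect()

scans = simulate_study(design, scheme, effect, seed=1)
print(f"{len(scans)} scans of shape {scans[('sub-01', 'drug', 'first')].data.shape}")

idx = scheme.edge_interaction_index(scheme.node_ids)
iu, ju = np.triu_indices(scheme.n_nodes, k=1)
dm = idx[("within", "DM")]

for cell in (("placebo", "first"), ("drug", "first")):
    vals = []
    for p in design.participants:
        r = np.corrcoef(scans[(p, *cell)].data, rowvar=False)
        vals.append(r[iu[dm], ju[dm]].mean())
    print(f"mean within-DM sample r, {cell[0]:8s}/{cell[1]}: {np.mean(vals):.3f}")

# The drug-first value sits ~0.10 below placebo-first: the injected acute
# reduction of default-mode-network coupling that downstream stages recover.
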