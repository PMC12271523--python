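"""Derive a proximity connectome from an axon population.

Detects axo-dendritic touches between 40 axons and a stratified scene of
stellate neurons, enforces a minimum inter-bouton interval along each axonal
branch, prunes to a dendritic synapse density, and aggregates synapses into
a neuron adjacency and a region projectome.  The final table shows the
linear relation between per-region axon cable and connection count.
"""

import numpy as np
from scipy.stats import pearsonr

from longax.connectome import (aggregate, connections_vs_axon_length,
                               connections_vs_border_distance, detect_touches,
                               filter_interbouton, prune_to_density)
from longax.fixtures import (demo_atlas, demo_population_spec,
                             generate_population, generate_scene)

atlas = demo_atlas()
spec = demo_population_spec()
spec.n_axons = 40
pre, _, _ = generate_population(spec, atlas, seed=3)
post = generate_scene(250, 10_000.0, atlas, seed=4, n_rays=12)

touches = detect_touches(pre, post, touch_distance=30.0)
kept = filter_interbouton(touches, min_interval=25.0)
synapses = prune_to_density(kept, density=0.1, post_morphs=post, rng=0)
print(f"{len(touches)} touches -> {len(kept)} after inter-bouton filter "
      f"-> {len(synapses)} synapses after density pruning")

conn = aggregate(synapses, atlas,
                 pre_region={m.neuron_id: "SRC" for m in pre})
deg = np.array(list(conn.out_degree.values()))
print(f"out-degree (distinct partners): median {np.median(deg):.0f}, "
      f"max {deg.max()}")

table = connections_vs_axon_length(conn, pre, atlas)
table = table[table.axon_length_um > 0].round(0)
r = pearsonr(table.axon_length_um, table.connections)[0]
print(f"\nconnections vs axon length per region (Pearson r = {r:.3f}):")
print(table.to_string(index=False))

dist = connections_vs_border_distance(conn, atlas, "SRC")
print("\nconnections vs border distance to the source region:")
print(dist.round(0).to_string(index=False))
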