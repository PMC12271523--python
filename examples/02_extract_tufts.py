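"""Decompose an axon into its trunk and terminal tufts.

Terminals within 300 um (radially and along the tree) agglomerate into
tufts rooted at their common ancestor; the remaining cable is the trunk.
Each tuft's persistence barcode — (birth, death) path distances of its
branches — is the topological recipe later used to regrow it.
"""

from longax.fixtures import demo_atlas, demo_population_spec, generate_population
from longax.morpho import SectionType
from longax.tufts import extract_tufts

atlas = demo_atlas()
spec = demo_population_spec()
spec.n_axons = 3
morphs, _, _ = generate_population(spec, atlas, seed=2)

for m in morphs:
    trunk, tufts = extract_tufts(m, radial_max=300.0, path_max=300.0,
                                 atlas=atlas)
    print(f"\n{m.neuron_id}: {len(m.nodes)} nodes, "
          f"{len(m.leaves(SectionType.axon))} terminals, "
          f"{m.total_length(SectionType.axon):.0f} um of axon")
    print(f"  trunk: {trunk.total_length(SectionType.axon):.0f} um")
    for t in tufts:
        bars = ", ".join(f"({b:.0f}, {d:.0f})" for b, d in t.barcode)
        print(f"  tuft in {t.region}: {t.n_leaves} terminals, "
              f"{t.total_length:.0f} um, barcode [{bars}]")
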