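"""Build coalescent state-space graphs and inspect their structure.

Constructs the two-population migration-only model and the isolation-with-
migration (IM) model, and prints the structural quantities that govern the
cost of everything downstream: branch types, states, edges, and nodes of
the computational graph used for evaluation.
"""

from coalgf import GfEvaluator
from coalgf.presets import im_model, two_population_migration

for n in (2, 3, 4):
    ev = GfEvaluator(two_population_migration(n))
    s = ev.graph_stats(kmax=2)
    print(
        f"migration-only, {n} samples/deme: "
        f"{s['branch_types']} branch types, {s['state_graph_states']} states, "
        f"{s['computational_graph_nodes']} computational nodes, "
        f"bSFS array {s['bsfs_size']} with {s['bsfs_compatible']} "
        "non-zero entries"
    )

for n in (2, 3):
    ev = GfEvaluator(im_model(n))
    s = ev.graph_stats()
    print(
        f"IM model, {n} samples/deme: {s['state_graph_states']} states, "
        f"{s['computational_graph_nodes']} computational nodes "
        "(collapsing every path prefix that contains the split)"
    )

# The computational-node counts are the quantity that blows up with a
# discrete event: each root-to-split path prefix becomes its own node.
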