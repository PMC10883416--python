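"""Use an externally computed alignment plan (e.g. from PASTE).

Any spot-correspondence matrix saved as delimited text can drive the
bipartite graph; here we save the built-in aligner's plan to TSV and load
it back, which is exactly the route a PASTE plan would take. The
binarization keeps each target spot's five strongest correspondences.
"""

import tempfile

from bigatae import (
    binarize_alignment,
    load_alignment,
    preprocess_pair,
    save_alignment,
    sinkhorn_alignment,
)
from bigatae.synthetic import SynthConfig, generate_slice_pair

target, adjacent = generate_slice_pair(SynthConfig(seed=3))
p_t, p_a = preprocess_pair(target, adjacent)

plan = sinkhorn_alignment(p_t, p_a)
with tempfile.NamedTemporaryFile(suffix=".tsv") as tmp:
    save_alignment(plan, tmp.name)
    reloaded = load_alignment(tmp.name, p_t, p_a)

graph = binarize_alignment(reloaded, top_k=5)
deg = graph.adjacency_mask().sum(axis=1)
print(f"plan: {plan.shape[0]} x {plan.shape[1]}, entries sum to {plan.plan.sum():.6f}")
print(f"graph: {graph.n_edges} edges; target-spot degree min/max = {deg.min()}/{deg.max()}")
# one-to-many correspondences are expected: a spot may borrow from several neighbors
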