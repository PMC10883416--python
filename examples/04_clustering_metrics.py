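"""The seven clustering-evaluation metrics on small worked cases.

With ground-truth labels: ARI, AMI, NMI, homogeneity and completeness
(all reach 1 at perfect agreement, and ARI/AMI are ~0 at chance). Without
labels: silhouette coefficient (SC, in [-1, 1]) and Calinski-Harabasz
index (CHI, unbounded above) on the embedding.
"""

import numpy as np

from bigatae import calinski_harabasz, evaluate_labels, silhouette

truth = [0, 0, 0, 1, 1, 1, 2, 2, 2]
good = [1, 1, 1, 2, 2, 2, 0, 0, 0]   # same partition, renamed
rough = [0, 0, 1, 1, 1, 2, 2, 2, 2]  # two spots misassigned

print("perfect (renamed):", {k: round(v, 3) for k, v in evaluate_labels(truth, good).items()})
print("two errors:       ", {k: round(v, 3) for k, v in evaluate_labels(truth, rough).items()})

pts = np.array([[0.0], [1.0], [10.0], [11.0]])
lab = [0, 0, 1, 1]
print(f"two tight 1-D clusters: SC = {silhouette(pts, lab):.4f}, "
      f"CHI = {calinski_harabasz(pts, lab):.1f}")
# CHI = (B/W) * ((N-K)/(K-1)) = (100/1) * (2/1) = 200 for this configuration
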