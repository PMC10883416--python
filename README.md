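# bigatae

Spatial transcriptomics measures gene expression at thousands of spatially
resolved spots in a tissue section, and a central analysis task is **spatial
domain identification**: partitioning the spots into contiguous regions with
coherent expression signatures (cortical layers, tumor regions, ...).
Many good single-slice clustering methods exist, but modern studies produce
*consecutive* slices — physically adjacent sections of the same tissue —
whose strong mutual similarity those methods cannot exploit.

`bigatae` implements a **bipartite graph attention auto-encoder** that
transfers expression information from an adjacent slice into a target slice,
producing an *enhanced* expression matrix in the original gene space that
any existing single-slice clustering method can consume. It is a shell
around your favorite method, not a replacement for it.

## Model

Spots of the target slice (node set $U$) and the adjacent slice ($V$) are
connected by a bipartite graph $BG(U, V, \varepsilon)$ obtained by
binarizing a probabilistic spot-correspondence plan $\Pi$ (optimal
transport; computed externally, e.g. by PASTE, or by the built-in entropic
aligner). With $E_{u_i}, E_{v_j}$ the preprocessed expression profiles, the
**encoder** is a single attention layer over the bipartite edges:

$$\alpha_{u_i,v_j} = \mathrm{softmax}_{v_j \in N^\varepsilon_{u_i}}
  \big(\mathrm{LeakyReLU}(a_{\mathrm{enc}}^\top [E_{u_i} \| E_{v_j}])\big),
\qquad
z_{u_i} = E_{u_i} + \mathrm{ReLU}\Big(\sum_{v_k} \alpha_{u_i,v_k} E_{v_k}\Big)$$

and the **decoder** removes the borrowed signal again with a second
attention vector $a_{\mathrm{dec}}$ scored on $z$:

$$\bar{E}_{u_i} = z_{u_i} - \mathrm{ReLU}\Big(\sum_{v_k}
  \bar\alpha_{u_i,v_k} E_{v_k}\Big).$$

There is no feature-transforming weight matrix — the two attention vectors
(each of length $2D$) are the only parameters — so $z$ stays in gene space.
Training minimizes the mean squared reconstruction error
$\frac{1}{ND}\sum_i \|E_{u_i} - \bar{E}_{u_i}\|^2$ (Adam, exact analytic
gradients, pure NumPy). The enhanced matrix $z$ is handed to clustering.

The package also ships the seven evaluation metrics used for spatial-domain
benchmarking (ARI, AMI, NMI, homogeneity, completeness, silhouette
coefficient, Calinski–Harabasz index), implemented from their defining
formulas, a Louvain/Leiden clustering adapter with a resolution search for
a fixed domain count, and a synthetic consecutive-slice generator with
layered ground-truth domains so the whole pipeline is testable offline.

## Worked example

```python
from bigatae import RunConfig, run_pipeline
from bigatae.synthetic import SynthConfig, generate_slice_pair

target, adjacent = generate_slice_pair(SynthConfig(seed=0))  # 200 spots, 4 domains
report = run_pipeline(RunConfig(seed=0), target=target, adjacent=adjacent)
print(report.as_table())
```

prints

```
metric	raw	enhanced
ARI	0.5704017368	0.8126211223
AMI	0.5292124839	0.7999360742
NMI	0.5389900502	0.8060736905
Homo	0.5370264064	0.8032566651
Comp	0.5409608741	0.8089005951
```

Each row compares Leiden clustering of the *raw* preprocessed target slice
against the same clustering of the *enhanced* matrix, scored against the
generator's ground-truth domains. On this noisy pair, borrowing expression
from the adjacent slice raises the adjusted Rand index from 0.57 to 0.81 —
the cross-slice information recovers domain structure that per-slice noise
and dropout had obscured. The `examples/` directory has one short script
per capability (enhancement, raw-vs-enhanced comparison, precomputed
alignment import, metrics), and the same workflow is available from the
shell via the `bigatae` CLI (`simulate`, `align`, `enhance`, `cluster`,
`evaluate`, `run`).

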