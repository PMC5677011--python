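# mpdlink — link prediction by matrix perturbation and decomposition

Real network datasets — protein interaction maps, food webs, neural wiring
diagrams, social and communication networks — are both *incomplete* (links
exist that were never observed) and *noisy* (some recorded links are
spurious). `mpdlink` implements a link-prediction method that addresses both
defects at once by manipulating the weighted adjacency matrix as a whole,
for undirected or directed, weighted or unweighted networks. It is intended
for researchers benchmarking link predictors and for practitioners who want
ranked candidate links from a partially observed network.

## The method

Given a network *G(V, E, A)* with weighted adjacency *A* (entry
*a<sub>ij</sub>* > 0 iff link *v<sub>j</sub>* → *v<sub>i</sub>* exists) and an
observed training link set *E<sup>T</sup>*, the **MPD** score matrix is built
in two stages.

**Stage 1 — structural perturbation.** Split the training adjacency into its
symmetric and antisymmetric parts, *A = A<sup>S</sup> + A<sup>AS</sup>* with
*A<sup>S</sup>* = (*A* + *A*ᵀ)/2. Randomly remove a fraction of training
links (the perturbation set); eigendecompose the symmetric part of the
remainder, *R = Σ<sub>k</sub> λ<sub>k</sub> x<sub>k</sub> x<sub>k</sub>ᵀ*,
and estimate the effect of restoring the removed links by first-order
perturbation theory,

&nbsp;&nbsp;&nbsp;&nbsp;Δλ<sub>k</sub> ≈ x<sub>k</sub>ᵀ ΔA<sup>S</sup> x<sub>k</sub> / x<sub>k</sub>ᵀ x<sub>k</sub>,

keeping the eigenvectors fixed:
*Ã<sup>S</sup> = Σ<sub>k</sub> (λ<sub>k</sub> + Δλ<sub>k</sub>) x<sub>k</sub> x<sub>k</sub>ᵀ*.
Averaging over 10 independent perturbation-set draws and re-adding the
antisymmetric part gives the perturbed matrix *Ã = Ã<sup>S</sup> + A<sup>AS</sup>*.

**Stage 2 — noise reduction.** Split *Ã* into a low-rank backbone and sparse
noise by the convex program

&nbsp;&nbsp;&nbsp;&nbsp;min ‖Ã<sub>B</sub>‖<sub>\*</sub> + λ‖Ã<sub>N</sub>‖₁  s.t.  Ã = Ã<sub>B</sub> + Ã<sub>N</sub>,

solved with the inexact augmented-Lagrangian robust-PCA iteration
(alternating singular-value thresholding and soft thresholding). The
backbone entries at unobserved pairs are the link-likelihood scores.

The toolkit also provides the stage-1-only predictor (**SPM**), the
stage-2-only predictor (**LR**, robust PCA of the raw training adjacency),
the local similarity baselines **CN** (common neighbors), **AA**
(Adamic–Adar, 1/ln degree) and **RA** (resource allocation, 1/degree),
precision@L and exact/sampled AUC evaluation with train/probe splitting,
topological descriptors (clustering C, assortativity r, mean degree ⟨k⟩,
mean distance ⟨d⟩, heterogeneity H = ⟨k²⟩/⟨k⟩²), and synthetic generators
(planted low-rank + sparse matrices, stochastic block models).

## Worked example

The package ships the canonical 34-node Zachary karate club network. Its
descriptor row:

```sh
$ mpdlink stats --input karate.tsv --undirected
n_nodes  n_links  clustering  assortativity  mean_degree  mean_distance  heterogeneity
34       78       0.5706      -0.4756        4.5882       2.4082         1.6933
```

(34 members, 78 social ties; strongly clustered, disassortative — hubs
attach to low-degree members — with mean degree 4.59 and typical separation
2.4 steps.)

Benchmarking three predictors under the 90/10 protocol (90% of links kept
for training, precision measured at L = |probe set|, exact AUC, averaged
over 50 random splits):

```python
from mpdlink import karate_club_graph
from mpdlink.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(directed=False, lambda_param=0.22, n_runs=50,
                       master_seed=0, methods=("MPD", "SPM", "RA"))
report = run_experiment(cfg, graph=karate_club_graph())
for m in cfg.methods:
    s = report.summary[m]
    print(f"{m}\t{s['mean_precision']:.3f}\t{s['mean_auc']:.3f}")
```

```
MPD     0.158   0.776
SPM     0.158   0.761
RA      0.160   0.727
```

About 16% of the predicted links are true held-out ties, and a held-out tie
outranks a random non-tie 78% of the time for MPD — the noise-reduction
stage lifts AUC above the perturbation-only SPM, and both beat the local RA
index. `mpdlink sweep` reports the λ grid (default 0.01…0.39, step 0.01) so
the best-performing λ can be read off per network.

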