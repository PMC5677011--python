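# Methods

## Model and procedure

`mpdlink` scores unobserved node pairs of a weighted network
*G(V, E, A)* by a two-stage manipulation of the training adjacency
*A<sup>T</sup>* (the adjacency of the observed link set *E<sup>T</sup>*).

**Symmetric/antisymmetric split.** Any real square matrix decomposes
exactly as *A = A<sup>S</sup> + A<sup>AS</sup>* with
*A<sup>S</sup>* = (*A* + *A*ᵀ)/2 and *A<sup>AS</sup>* = (*A* − *A*ᵀ)/2.
*A<sup>S</sup>* carries the average linking tendency of each pair and is
always diagonalisable with real spectrum; *A<sup>AS</sup>* carries the
directional bias. The perturbation machinery operates on *A<sup>S</sup>*
only, which is what extends the spectral method to directed networks whose
raw adjacency may be non-diagonalisable. In floating point both parts are
exactly (anti)symmetric bitwise; the sum reconstructs the input to machine
precision (a few ulp at the matrix's scale), which is what the test suite
asserts.

**Structural perturbation.** A random subset ΔE of the training links
(default fraction 0.1 of |E<sup>T</sup>|, drawn uniformly without
replacement; for undirected graphs the draw unit is the unordered pair and
removal clears both matrix entries; removed links carry their full weight)
is treated as a perturbation of the remainder *R*. With
*R<sup>S</sup> = Σ λ_k x_k x_kᵀ*, first-order (Rayleigh–Schrödinger)
perturbation theory gives Δλ_k ≈ x_kᵀ ΔA<sup>S</sup> x_k / x_kᵀ x_k, and
the estimate fixes the eigenvectors:
*Ã<sup>S</sup> = Σ (λ_k + Δλ_k) x_k x_kᵀ*. The assumption is that the
network's eigenvectors are the stable, "consistent" part of its structure,
so extrapolating along them generalises the observed topology. The
estimate is averaged over `n_selections` = 10 independent draws, then
*A<sup>AS</sup>* is re-added once (by linearity this equals per-draw
addition). The first-order error is O(‖Δ‖²): the suite verifies a log-log
slope of 2 ± 0.3 for the gap to exact re-diagonalisation over
ε ∈ {1e-1 … 1e-4}.

*Degeneracies.* The shift formula is basis-dependent inside a degenerate
eigenspace. The shifts are applied verbatim to the orthonormal basis LAPACK
`eigh` returns (deterministic for identical input), and a warning is logged
whenever an eigen-gap falls below 1e-8. Sparse real networks hit this
constantly through zero eigenvalues (isolated nodes, duplicated
neighborhoods), so the warning is informational, not an error.

**Robust-PCA noise removal.** The perturbed matrix is split into a low-rank
backbone and sparse noise by the convex program
min ‖·‖<sub>*</sub> + λ‖·‖₁ subject to exact sum. The idealised
rank + l0 program it surrogates is documented but never solved (its balance
parameter γ is intentionally absent from the API). The solver is the
inexact augmented Lagrangian method: alternate singular-value thresholding
(threshold 1/μ) and elementwise soft thresholding (threshold λ/μ), dual
update Y ← Y + μ(residual), μ ← 1.5μ, initialised with
μ₀ = 1.25/‖m‖₂ and Y₀ = m / max(‖m‖₂, ‖m‖<sub>∞</sub>/λ). Convergence is
declared at relative Frobenius constraint violation < 1e-7 (cap 1000
iterations; non-convergence returns the iterate flagged `converged=False`).
These are the standard published defaults for this formulation; the suite
checks exact recovery of planted rank-2 + 1%-corruption instances at
λ = 1/√n (relative error < 1e-4, rank recovered in ≥ 19/20 seeds), that the
converged objective beats both trivial feasible points, and that the
iteration preserves symmetry. The implementation uses a full SVD per
iteration: at the package's intended scale (networks up to a few thousand
nodes) this is simpler than partial-SVD acceleration and exactly
reproducible.

**Scoring and evaluation.** Backbone entries at non-training, non-self
pairs are the candidate scores; for undirected evaluation the unordered
pair {i, j} gets the mean of the two entries, and for directed evaluation
every ordered non-training pair is a candidate. precision@L counts probe
links among the top L candidates (protocol: L = |probe|), with ties broken
by a seeded random shuffle — insertion-order ranking would systematically
favour whichever pairs happen to be enumerated first. AUC is the
probability that a random probe link outscores a random nonexistent link
with half-credit ties; it is computed exactly (Mann–Whitney via midranks)
whenever |probe|·|nonexistent| ≤ 1e8 and otherwise by 672 400 seeded
sampled comparisons, for which the binomial half-width at 99% confidence
is ≈ 0.002. Both metrics are invariant under strictly monotone transforms
of the scores.

**Experiment protocol.** A run draws a train/probe split
(default probe fraction 0.10, probe size rounded half-away-from-zero,
minimum 1), evaluates each requested method, and the experiment averages
over `n_runs` (default 100) independent runs. For the λ-parameterised
methods (MPD, LR) the default λ grid is 0.01–0.39 in steps of 0.01; the
per-λ mean over the same runs is reported with the arg-max λ (ties to the
smallest λ), i.e. the optimum is selected in-sample, mirroring the
bracketed-optimum reporting convention. Held-out λ estimation is possible
by sweeping on a further split of the training set but is deliberately not
automated. Run *i* of master seed *s* uses NumPy's
`SeedSequence([s, i])`, which is documented, splittable and portable
across platforms; all sub-randomness (perturbation draws, tie-breaks, AUC
sampling) derives from the run seed the same way.

## Conventions and edge cases

- Adjacency convention: entry (i, j) is the weight of link
  *v_j* → *v_i* (column = source, row = target). Every stage's algebra is
  transposition-invariant, so the choice only matters at the I/O boundary.
- Self-loops are dropped with a warning on read (several public food webs
  contain cannibalism loops); duplicate edge-list lines keep the last
  weight; weights pass through unnormalised.
- Similarity baselines on directed networks use the undirected neighbor
  view Γ(x) = in ∪ out; an alternative (Γ_out(x) ∩ Γ_in(y)) would change
  baseline numbers but not the MPD method, and is not implemented.
- Network descriptors (C, r, ⟨k⟩, ⟨d⟩, H) are computed on the binary
  undirected view; ⟨d⟩ of a disconnected graph is measured on the largest
  component with a warning. Heterogeneity is H = ⟨k²⟩/⟨k⟩², the
  dimensionless form that equals 1 exactly for regular graphs.

## Synthetic data

The planted generator produces L0 = X·Yᵀ (X, Y n×r standard normal) plus a
sparse ±magnitude corruption at a uniformly random fraction of entries —
the regime with known exact-recovery guarantees for the convex program, so
backbone recovery is checkable against ground truth. The SBM generator
(networkx backend) plants an assortative two-block structure, giving the
full pipeline a known low-rank organisation to exploit; the end-to-end
check (100 nodes, p_in = 0.3, p_out = 0.02, 90/10 splits, 20 runs,
λ = 0.1) asks for mean AUC > 0.6, strictly above the 0.5 random baseline.
These fixtures emulate low-rank-plus-sparse structure and community
organisation only; they have none of the degree heterogeneity, clustering
or weight structure of real networks, so passing tests demonstrate
correctness of the machinery and a detectable signal on planted structure,
not field performance on real data. The shipped 34-node karate-club edge
list is the one real fixture; its descriptor row is the worked example.

Problem sizes in the test suite and acceptance script (n = 50 planted
matrices, 50–100-node SBMs, 20–50 runs) are chosen so the whole suite runs
in seconds on one CPU while keeping every check's statistical margin wide;
the same code runs unchanged at larger n.

## Known limitations

- First-order shifts degrade when the perturbation is not small relative
  to the spectral gaps (large perturbation fractions on tiny graphs).
- In-sample λ selection is optimistically biased by construction; treat
  the reported optimum as a protocol artifact, not a tuned hyperparameter.
- No matrix-completion variant (the decomposition constraint is an exact
  sum), no multigraphs, no temporal streams, no weighted clustering or
  assortativity descriptors, no higher-order or eigenvector perturbation
  corrections.
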