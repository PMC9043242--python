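# Methods

## Problem

Distributed EEG source imaging (ESI) reconstructs a cortical current
distribution `s(t) ∈ R^m` from scalp potentials `x(t) ∈ R^n` related by the
linear forward model

    x(t) = H s(t) + ε(t),

with `n ≪ m` (here 64 electrodes vs 642 candidate sources), so the inverse
problem is ill-posed and needs prior structure. This package targets
*extended* activations — a patch of cortex active together — for which the
useful prior is spatial smoothness over the source mesh.

## Graph-spectral decomposition

The candidate sources form the vertices of a triangulated mesh; connecting
mesh neighbors (order 1, optionally order 2) with unit weights gives an
undirected graph with adjacency `A` and combinatorial Laplacian `L = D − A`.
Its eigendecomposition `L = U Λ Uᵀ` (dense `scipy.linalg.eigh`; fine for
m up to a few thousand) yields an orthonormal basis ordered by eigenvalue.
The graph Fourier transform (GFT) of a source pattern is `s̃ = Uᵀ s`; the
inverse is `s = U s̃`.

Eigenvectors of small eigenvalue vary slowly across edges. This is
quantified by the *graph frequency* of an eigenvector: the number of edges
whose endpoint values have strictly opposite signs (exact zeros contribute
none). Eigenvalue rank and graph-frequency rank agree strongly on icosphere
graphs (Spearman ρ ≥ 0.9 is asserted in the tests; strict monotonicity does
not hold and is not claimed, and within degenerate eigenvalue clusters the
flip counts depend on the eigenvector choice).

Keeping the first `k` columns `U_k` acts as a spatial low-pass filter. A
patch (center + level-1 neighbors) concentrates ≥ 80% of its spectral
energy in the lowest 30% of the spectrum (asserted in tests), so `k =
round(0.3·m)` is the default band — matching the reference configuration's
615 of 2,052 eigenvectors. Selecting by eigenvalue threshold `T_f` is also
supported; no numeric `T_f` is canonical, only the ratio.

Eigenvector signs are fixed deterministically (largest-magnitude entry made
positive, ties broken by lowest index) so serialized bases and trained
models reproduce across runs.

## The BiLSTM inverse solver

The solver learns the mapping from EEG sequences to the low-band GFT
coefficients `s̃′ = U_kᵀ s` rather than to `s` itself, shrinking the output
layer from `m` to `k` units (factor ~3.3 at the default band) and
discarding spatially ragged components by construction. Reconstruction is
`ŝ = U_k ŝ′`, which always lies in the smooth subspace.

The regressor is a single bidirectional LSTM layer: a forward-time and a
backward-time scan with the standard gate equations (forget/input/output
gates, tanh candidate, `[h, x]` concatenation order), whose per-step hidden
states are concatenated and passed through a dense output layer. The output
activation is identity by default: GFT coefficients are signed and
unbounded, so a sigmoid cannot represent them (a sigmoid option is kept for
fidelity experiments). The implementation is pure NumPy — vectorized scans
(the input projection for all time steps is one GEMM; only the `h @ W_h`
recurrence is stepped), full backpropagation through time, float32
arithmetic — with the Nadam optimizer (Adam with Nesterov momentum).
Training minimizes mean squared error on the coefficients, with
mini-batches, seeded shuffling and initialization (Glorot uniform, forget
bias 1), early stopping on validation MSE, and best-epoch weight restore.

Defaults and their reasons:

| parameter        | default | why |
|------------------|---------|-----|
| hidden_size      | 256     | concatenated bidirectional state (128 per direction); the reference 2,560 is read as the concatenated width, per-direction mode selectable |
| k                | 0.3·m   | patch energy concentration (above) |
| epochs / patience| 200 / 20| unreported upstream; early stopping governs |
| batch_size       | 32      | unreported upstream; standard small-batch default |
| learning_rate    | 1e-3    | unreported upstream; benchmark scripts use 2e-3, chosen for convergence speed on the 642-vertex grid |
| target scaling   | global  | see below |

**Target scaling.** Inputs are standardized per channel. Targets are
centered per coefficient but scaled by a single pooled standard deviation
("global"). Per-feature target standardization (also available) reweights
the MSE objective: it up-weights high-frequency coefficients that are
weakly determined by the data, which empirically slows convergence and
degrades the reconstructed spatial pattern. Global scaling keeps the
optimization equivalent to raw-unit MSE on the coefficients.

## Linear benchmarks

MNE, dSPM and sLORETA are implemented from their standard published forms
on the shared Tikhonov kernel `K = Hᵀ(H Hᵀ + λ² I)⁻¹` with identity source
and noise covariances: dSPM divides row `i` by `√((K C Kᵀ)_ii)`, sLORETA by
`√((K H)_ii)` (resolution-matrix diagonal, floored at 1e-12 before the
square root). With identity covariances all three differ only by positive
per-row scaling. λ² defaults to the SNR-matched heuristic
`trace(H Hᵀ)/(n·10^(SNR/10))`. Only fixed (radial) source orientations are
supported, matching the simulator; no depth weighting is applied.

## Simulator

The synthetic protocol mirrors the reference experiments at a scaled size:

* **Source space** — icosphere (subdivision 3: m = 642) of radius 80 mm, a
  stand-in for a 2,052-vertex cortical mesh whose provenance is unpublished.
  All sources sit at one depth with outward radial orientation.
* **Lead field** — closed-form surface potential of a radial dipole in a
  homogeneous conducting sphere (scalp radius 100 mm, conductivity
  0.33 S/m), obtained by summing the Legendre series exactly:
  `V ∝ (2f(x−f)/g³ + 1/g − 1)/f` with `f` the relative source depth,
  `x = cos γ`, `g = √(1−2fx+f²)`. 64 electrodes on a seeded Fibonacci
  lattice over the upper hemisphere; columns average-referenced.
* **Patches** — a center vertex plus its level-1 mesh neighbors, neighbors
  at amplitude 0.5 (the reference says only "lower"; 0.5 is the package
  default, configurable). Single-patch datasets activate every vertex in
  turn; multi-patch datasets draw disjoint random center pairs.
* **Dynamics** — each patch carries one waveform from a stable AR(5)
  process (poles: 0.95·e^(±2πi·0.10), 0.90·e^(±2πi·0.20), 0.60; spectral
  radius 0.95, i.e. oscillatory structure at 10 and 20 Hz at fs = 100 Hz),
  100 samples at 100 Hz, ≥200-sample burn-in discarded, unit-variance
  innovations (amplitudes are arbitrary units; only the neighbor ratio is
  constrained).
* **Noise** — spatially and temporally white Gaussian, rescaled so the
  realized global power ratio `10·log10(P_signal/P_noise)` equals the
  requested SNR exactly (powers pooled over channels and samples).
* **Splits** — 70/15/15 train/val/test with largest-remainder rounding,
  seeded permutation.

What the simulator does *not* emulate: cortical folding and depth/
orientation variability, correlated sensor noise, physiological artifacts,
realistic conductivity layers (BEM/FEM). Consequences for interpretation
are discussed under "Limitations".

## Evaluation

* **AUC** — per-vertex score = max over time of |ŝ_i(t)| (amplitude at the
  energy-peak time is selectable); positives are all patch member vertices;
  AUC is the tie-aware Mann–Whitney probability (computed via
  `sklearn.metrics.roc_auc_score`, cross-checked against a brute-force pair
  count in tests). Per-trial AUCs are averaged over the test split.
* **LE** — at the global energy-peak time (or a given sample), estimated
  peaks are the P strongest local maxima of |ŝ| kept ≥ 2 mesh hops apart
  (P = number of true centers); each true center is matched greedily
  one-to-one by increasing Euclidean distance and the mean distance (mm) is
  reported. The multi-source matching protocol is this package's own
  definition — the reference reports a single number without defining the
  matching. An identically zero estimate is flagged and scored as the mesh
  diameter.

## Benchmark grids and problem sizes

The packaged benchmark (acceptance script and acceptance tests) runs the
scaled grid: m = 642, n = 64, k = 193, hidden 256, single-patch datasets of
642 trials (every vertex once) at 20/30/40 dB, a 1,200-trial two-patch
dataset at 40 dB (random pairs need denser coverage than the enumerated
single centers), learning rate 2e-3, batch 32, 42 epochs per single-patch
training and 100 for the two-patch one (40/60 in the test suite). With
seed 1 the script prints BiLSTM single-patch test AUC ≈ 0.98 at every SNR
with LE ≈ 13–15 mm — close to the reference row (0.9668/0.9821/0.9844, LE
13–16 mm) — and two-patch AUC ≈ 0.92–0.93, which is depressed by the
electrode blind zone discussed under "Limitations".

## Limitations

* On the homogeneous-sphere geometry the linear solvers operate near their
  idealized assumptions (white noise, identity covariance, uniform source
  depth, SNR-matched regularization): sLORETA shows its exact zero-bias
  property (LE < 1 mm, AUC ≈ 0.997 at all tested SNRs). Absolute
  linear-benchmark levels from realistic BEM-cortex studies therefore do
  not carry over to this simulation, and the BiLSTM's *advantage over*
  linear methods seen on realistic geometry does not reproduce here — the
  spherical stand-in favors the linear methods, not the network. The
  BiLSTM's own accuracy band does reproduce.
* **Electrode blind zone.** Electrodes cover only the upper hemisphere
  while sources span the full sphere, so lead-field column norms fall ~35×
  from the north cap to the south cap. Because sensor noise is scaled to
  each trial's total signal power, a trial with two patches of unequal
  visibility leaves the weaker (southern) patch near the noise floor; the
  MSE-optimal regression then predicts ≈ 0 for it, and the per-trial AUC
  distribution becomes bimodal (most trials ≈ 0.99, a southern-patch
  minority ≈ 0.5). This depresses the two-patch mean AUC to ≈ 0.92–0.93 —
  a property of the montage/source-space combination, not of the training
  budget (it persists when trials are scaled 600→2000 and epochs 60→150;
  sLORETA degrades on the same trials, corr(AUC, min patch z) ≈ 0.67).
  Single-patch trials are unaffected since the SNR is then defined against
  that patch's own signal. A full-head montage over a realistic cortex
  (which lies entirely under the cap) has no such blind zone.
* The trained network is specific to one lead field, band and SNR regime;
  there is no transfer across head models.
* Single BiLSTM layer only; no stacked/attention variants.
* Real-data entry is a bare matrix container (channels × samples); no
  EDF/FIF readers, no noise-covariance estimation from baseline segments.
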