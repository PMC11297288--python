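# Methods

## Data model

A profile table is a wells × features matrix of finite real numbers plus
one metadata record per well: `source_id` (laboratory), `batch_id`
(experimental run, namespaced by source), `plate_id` (namespaced by
batch), `well_position`, `compound_id`, `control_type`
(negative | positive | treatment) and optionally `microscope_type`.
Negative controls are DMSO-treated wells with no expected biological
effect; they anchor all normalization. Missing feature values are
rejected at read time rather than imputed, because every downstream
formula assumes complete vectors. Well positions are stored verbatim; no
in-scope metric parses plate geometry. Single-cell tables enter only
through `aggregate_cells_to_wells`, which mean-averages each well's cell
vectors (pseudo-bulk).

## Baseline preprocessing

Four steps, in order; the output is the representation every correction
method receives and is compared against.

1. **Variation filtering.** C_var = |σ̃/X̃| per plate × feature, from
   negative controls only; a feature is dropped if C_var < 10⁻³ on *any*
   plate. Degenerate cases: C_var = 0 when σ̃ = 0 (filtered), and +∞ when
   X̃ = 0 with σ̃ > 0 (kept — the filter targets *low*-variation features
   and the ratio is undefined there).
2. **MAD normalization.** (X − X̃)/σ̃ per plate with control-derived
   statistics. σ̃ is the raw median absolute deviation — no 1.4826
   Gaussian consistency constant. After this step each plate's controls
   have median 0 and MAD 1 per feature exactly.
3. **Inverse normal transform.** Blom scores with c = 3/8, applied per
   feature over all wells of the scenario jointly (not plate-wise: plate
   effects are already handled by step 2, and the transform is defined
   with a single sample count N per feature). Ties receive mid-ranks, so
   tied inputs map to equal scores.
4. **Correlation-based feature selection.** Pearson correlations over all
   wells of the (transformed) scenario, compared in absolute value.
   While any pair exceeds 0.9, the member of the currently worst pair
   with the largest total absolute correlation to all surviving features
   is dropped; exact duplicates therefore lose exactly one copy. The
   procedure is idempotent.

A practical consequence worth knowing: any technical effect that is
*affine per plate* (constant shift, constant rescaling) is removed
exactly by step 2, and any correction that is affine per plate is
likewise cancelled by it. Residual batch structure after preprocessing
therefore comes from effects that interact with the perturbation signal
(see the simulator's multiplicative component) and from the sampling
error of the control median/MAD themselves, which injects small per-plate
offsets of order σ/√n_controls.

## Correction methods

All corrections preserve well count, order and metadata, and declare
whether they return corrected features or a low-dimensional embedding.

- **baseline** — identity; the no-correction reference.
- **sphering** — ZCA whitening fitted on negative controls:
  W = V diag(1/√(λᵢ + ε)) Vᵀ from the eigendecomposition of the control
  covariance, applied to all wells. The regularizer ε (default 0.1) was
  chosen by a held-out-controls sweep on the simulator: with fewer
  controls than features the sample covariance is rank-deficient, and
  ε ≲ 10⁻² amplifies unobserved directions (held-out covariance deviation
  > 0.25 at ε = 10⁻², minimized near ε ≈ 0.1–0.3). Sphering assumes
  control variation is purely technical; it is the only built-in method
  that needs no batch labels.
- **combat** — empirical-Bayes per-batch location/scale adjustment
  (additive + multiplicative batch model on approximately normal
  features), delegated to scanpy's ComBat implementation behind the
  module's contract and precondition checks (≥ 2 batches, ≥ 2 wells per
  batch).
- **mnn** — batches merged onto a reference in descending size order;
  mutual nearest neighbors (k = 5 by default) across the reference and
  the incoming batch define per-pair correction vectors (reference −
  incoming), and each incoming well receives a Gaussian-kernel-weighted
  average of them. The kernel bandwidth defaults to the *median pair
  correction-vector norm*: corrections are smoothed over the spatial
  scale of the displacement they remove. (An earlier candidate — the
  median distance from incoming wells to their nearest paired anchor —
  degenerates to zero whenever most incoming wells are themselves
  anchors, producing noise-chasing per-well corrections.) If the median
  correction norm is numerically zero the batches already coincide on the
  pair set and the global mean correction (zero up to pair symmetry) is
  applied, making identical batches an exact no-op.
- **harmony** (`harmony_lite`) — a compact, faithful-in-spirit variant of
  the iterative mixture-model approach rather than a line-by-line port:
  soft k-means in a PCA embedding (default 20 components) on
  cosine-normalized coordinates, with soft assignments of batches
  over-represented in a cluster down-weighted by ((E+1)/(O+1))^θ
  (expected vs observed batch mass, diversity penalty θ = 1); each
  iteration subtracts Σₖ Rᵢₖ(μ_{k,b(i)} − μₖ) in the raw embedding.
  Convergence when the mean correction step falls below tol × RMS
  (default 10⁻³) or max_iter = 20, else a warning and the last iterate.
  With θ = 0 and coinciding batches the per-cluster batch means equal the
  cluster means, so the output is exactly the PCA embedding. Scored in
  its embedding space, mirroring how embedding-returning tools are
  evaluated in practice.
- **oracle** (simulated data only) — subtracts the generator's true
  additive effects and undoes the multiplicative distortion of the
  biological signal, leaving biology + well noise; the upper reference
  for every comparison.

External methods (e.g. neural or R-ecosystem tools) register through
`register_method(name, func, output_space)` and then participate in the
benchmark like the built-ins.

## Metrics

Four batch-removal and six bio-conservation metrics, each reported raw
and normalized to [0, 1] (1 = best). Feature-space method outputs are
PCA-reduced to 50 components before the neighborhood-based metrics (kNN
graph, LISI, kBET, Leiden) for geometric parity with embedding-space
methods (config flag, default on); silhouette and mAP run on the output
directly. Defaults: kNN k = 15, LISI perplexity 30, kBET neighborhood
≈ min(50, mean batch size / 4), Leiden resolution grid
{0.1, 0.25, 0.5, 1, 2}.

- **Batch ASW** — within each compound group, per-well silhouette s with
  batch as cluster, scored 1 − |s| and averaged within then across
  groups. Labels seen in a single batch are skipped with a warning.
- **Graph connectivity** — per label, the largest connected component of
  the label-induced kNN subgraph divided by label size; mean over labels;
  singletons contribute 1.
- **iLISI / cLISI** — per-well inverse Simpson index over Gaussian-kernel
  neighbor weights calibrated to the perplexity (t-SNE-style entropy
  bisection on squared distances, 3 × perplexity neighbors). iLISI
  normalized (LISI − 1)/(B − 1); cLISI normalized (L − LISI)/(L − 1).
  Note the estimator's finite-kernel bias: with perplexity P the
  effective neighborhood is < 3P, so even perfectly mixed data scores
  slightly below 1 (≈ 0.88 at P = 30, ≈ 0.96 at P = 90 for two equal
  batches); comparisons across methods at a fixed perplexity are
  unaffected.
- **kBET** — per-well chi-square test of neighborhood batch composition
  against the global composition at α = 0.05; score 1 − rejection rate,
  computed within each label group large enough to hold two disjoint
  neighborhoods (else the test is vacuous) and averaged over groups,
  falling back to one global test when no group qualifies. Because
  over-mixed data rejects *less* often than the nominal α, aggressive
  diversity-enforcing corrections can score above a perfectly corrected
  reference on kBET and iLISI — a structural property of batch-removal
  metrics, counterbalanced by the bio-conservation side.
- **Leiden ARI / NMI** — Leiden community detection (leidenalg) on the
  symmetrized kNN graph at each grid resolution; the NMI-maximizing
  resolution is selected and both ARI (clipped at 0) and NMI reported.
- **mAP (nonrep / control)** — every treated well of a compound with
  M ≥ 2 replicates queries a cosine-ranked candidate list of its M − 1
  sibling replicates (anywhere in the dataset) against same-plate
  negatives: treated wells of other compounds (nonrep) or the plate's
  DMSO wells (control). AP = mean precision at the positives' ranks
  (equivalently Σ ΔRₖ Pₖ with nonnegative recall increments), averaged
  per compound then over compounds. Ties in similarity break by stable
  well order. Under random ranking E[AP] ≈ (M−1)/(M−1+N); the exact
  null expectation is ρ + (1−ρ)·H_T/T with T = M−1+N, ρ = (M−2)/(T−1)
  and H_T the T-th harmonic number, which the approximation undershoots
  noticeably when positives are scarce.

## Simulator

`observed = bio ⊙ mult + additive + noise` per well, over a
source → batch → plate → well hierarchy:

- **bio** — one Gaussian effect vector per compound (scale 1.0 by
  default; positive controls 3.0, emulating compounds chosen for strong
  phenotypes); DMSO wells are exactly zero.
- **mult** — per-batch log-normal factors (log-sd
  `batch_multiplicative_scale`) applied to the *biological signal*: they
  model instrument/protocol differences that rescale the measured
  response to perturbation. This is deliberate: a multiplicative factor
  applied to the whole readout would make every injected effect affine
  per plate and hence exactly removable — for baseline and oracle alike —
  by plate-wise MAD normalization, leaving the benchmark without an
  object of study. Applied to the signal only, the distortion is
  invisible in DMSO wells and survives control-based preprocessing,
  which matches why batch effects are hard in practice.
- **additive** — per-batch constant Gaussian vectors plus a
  per-microscope-type shift shared by sources with the same instrument;
  fully visible in raw space, removed by plate normalization.
- **noise** — i.i.d. Gaussian per well (scale 0.3). All draws are
  Gaussian for tractability; post-transform features are near-normal by
  construction and ComBat's model is Gaussian.

Plates carry 16 DMSO wells of 96 (a realistic production-plate fraction;
also chosen because median/MAD estimation from many fewer controls
injects per-plate offsets that would dominate the injected effects at
desk scale), one well per positive control, and treatment wells filled at
the requested replicate counts with leftovers as extra DMSO. The exact
per-well decomposition is stored, so the observed table is bit-exactly
reconstructible and the oracle inversion is exact (with zero well noise
it returns biology exactly).

**Presets.** Desk-scale analogues of five scenarios of increasing
technical heterogeneity, 300 features and ≤ 1,200 wells each so the full
metric suite runs in seconds: s1 one laboratory / 4 runs / 12 heavily
replicated compounds (mild effects: additive 0.15, mult 0.05); s2 three
laboratories, one microscope model (0.6 / 0.25); s3 three laboratories,
150 compounds at 1–3 replicates with 8 positive controls replicated on
every plate (0.8 / 0.3); s4 five laboratories, three microscope types, 12
compounds (0.8 / 0.35, microscope shift 1.0); s5 five laboratories, three
types, 150 compounds (1.0 / 0.4, shift 1.5). The batch variable is the
experimental run for s1 and the laboratory for s2–s5. The scales were
chosen once so the presets bracket an easy→hard range for the baseline
(its raw-space mean batch metric decreases across presets at fixed seed);
they are free parameters of the generator, not calibrated to any real
dataset, and the true magnitude of real-world batch effects is unknown.

**What the simulator does not model** — and what passing tests therefore
do not show about real data: plate-position (edge) effects, single-cell
heterogeneity, non-Gaussian feature distributions (a heavy-tailed stress
variant is not included), batch-specific noise covariance, and batch
effects visible in negative controls after plate normalization. The last
point matters for sphering: under this generator, post-normalization
controls are batch-free by construction, so sphering is statistically
indistinguishable from baseline after preprocessing and is evaluated on
the raw table (where its premise holds) in the dominance regressions.

## Benchmark orchestration

One scenario config (YAML for the CLI) fully determines a run: input
(preset + seed, or a file), batch/label keys, methods with parameters,
metric parameters, and weights w_batch + w_bio = 1 (defaults 0.4/0.6).
The raw table is preprocessed once; each method corrects that
representation; the oracle corrects the raw table and is preprocessed
identically. A failing method is recorded and excluded, not fatal, and
never scored 0. Overall = w_batch · mean(4 batch) + w_bio · mean(6 bio);
ranks per scenario use average ranks on ties; cross-scenario comparison
is by mean rank. Every run writes a manifest (seed, parameters, package
version) beside the tidy metric table. Min–max rescaling of raw metrics
across methods is deliberately not applied — each metric's intrinsic
[0, 1] normalization is used (a config switch could add it, but the
intrinsic scale keeps scores comparable across runs).

UMAP panels (seeded, SVG, one per color key) are qualitative aids only;
extreme dimensionality reduction distorts high-dimensional geometry and
no quantitative claim is based on them.

## Numerical choices and degenerate inputs

- Silhouette on zero-distance data is defined as 0 (normalized 0.5);
  singleton compound labels are excluded from label ASW with a warning.
- ARI can be slightly negative under the null; the normalized value is
  clipped at 0.
- kNN graphs exclude self-neighbors even under exact duplicates.
- Cosine ties break by stable well order (measure-zero on continuous
  data, but determinism matters for reproducibility).
- Sphering with ε = 0 refuses near-singular control covariances and
  suggests ε > 0.
- `mad_normalize` refuses zero-MAD features and points to variation
  filtering; `run_baseline` applies the stages in the only valid order.
- All randomness (simulator, k-means initialization, Leiden, UMAP) is
  seeded through explicit seed arguments; reruns with the same manifest
  are bit-identical.

## Known limitations

- The Harmony-style and MNN implementations are desk-scale reference
  variants; they follow the published ideas but are not numerically
  interchangeable with the original packages.
- kBET uses the asymptotic chi-square null; at small neighborhood sizes
  the test is conservative, which is why undersized label groups fall
  back to a global test.
- Regression margins in the test suite (e.g. "every method within 0.02
  of baseline on s1", "oracle/combat/mnn exceed baseline by ≥ 0.005 on
  s4") are fixed-seed regression guards on the simulator, not claims
  about effect sizes on real data.
- Bio-conservation metrics saturate near 1 on the default presets (the
  compound effect is strong relative to well noise); the simulator's
  scales can be lowered to probe the trade-off regime.
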