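# cpbatch

**Benchmarking batch-correction methods for image-based morphological profiling.**

High-throughput imaging assays such as Cell Painting produce well-level
profiles — one vector of morphological features per well of a multi-well
plate — collected across plates, experimental runs, laboratories and
microscopes. Technical variation between those groupings ("batch effects")
easily dominates the biological signal of the chemical or genetic
perturbations being studied, and is the main obstacle to integrating
profiles across laboratories. `cpbatch` is a framework for *evaluating*
batch-correction methods on such data: it preprocesses profiles, applies a
panel of correction methods, and scores each one with ten complementary
metrics, all exercised end-to-end on a built-in hierarchical profile
simulator with known ground truth.

It is aimed at computational biologists who develop or select
batch-correction methods for morphological profiling and want a
reproducible, quantitative harness for comparing them.

## What it computes

**Preprocessing (the "Baseline")** — four steps applied to raw well-level
profiles:

1. *Variation filtering*: drop feature X if its absolute coefficient of
   variation C_var = |σ̃ / X̃| < 10⁻³ on any plate, where X̃ = median(X) and
   σ̃ = median(|Xᵢ − X̃|) are computed from that plate's DMSO
   negative-control wells only.
2. *MAD normalization*: per plate, X̂ᵢ = (Xᵢ − X̃) / σ̃ with the same
   control-derived statistics.
3. *Rank-based inverse normal transform*: Yᵢ = Φ⁻¹((rᵢ − c)/(N − 2c + 1))
   with Blom offset c = 3/8.
4. *Feature selection*: while any feature pair has |Pearson r| > 0.9, drop
   the member with the largest total absolute correlation.

**Correction methods** — built-in reference implementations of sphering
(ZCA whitening on negative controls), ComBat (empirical-Bayes per-batch
location/scale), MNN (mutual-nearest-neighbor correction vectors with
Gaussian smoothing) and a Harmony-style iterative soft-clustering
correction, plus the identity baseline, a ground-truth oracle for
simulated data, and a plugin registry for external methods.

**Metrics** — four batch-removal metrics (batch ASW, graph connectivity,
iLISI, kBET) and six bio-conservation metrics (label ASW, cLISI, Leiden
ARI, Leiden NMI, and replicate-retrieval mean average precision against
two negative sets), each normalized to [0, 1]. For a query well with M
replicates of its compound and N negatives,

AP = Σₖ (Rₖ − Rₖ₋₁) Pₖ,  Rₖ = TPₖ/(M−1),  Pₖ = TPₖ/k,

averaged over replicates and compounds. The overall score of a method is

overall = 0.4 · mean(batch metrics) + 0.6 · mean(bio metrics),

and methods are compared across scenarios by mean rank.

**Simulator** — profiles are generated as
`observed = bio ⊙ mult + additive + noise` over a source → batch → plate →
well hierarchy, with per-compound biological effect vectors, per-batch
additive shifts and multiplicative response distortions, per-microscope
shifts, and i.i.d. well noise. Five presets (`s1`–`s5`) mirror benchmark
scenarios of increasing technical heterogeneity, from one laboratory with
several runs up to five laboratories with three microscope types.

## Worked example

```python
import cpbatch as cp

config = cp.ScenarioConfig(
    name="demo-s2", preset="s2", seed=7,
    methods={"baseline": {}, "sphering": {}, "combat": {},
             "mnn": {}, "harmony": {}, "oracle": {}},
)
report = cp.run_benchmark(config)
print(report.scores.round(3))
```

prints

```
          batch_score  bio_score  overall  rank
harmony         0.950      0.972    0.963   1.0
oracle          0.946      0.946    0.946   2.0
mnn             0.928      0.952    0.942   3.0
combat          0.922      0.950    0.939   4.0
baseline        0.816      0.950    0.897   5.0
sphering        0.781      0.953    0.884   6.0
```

Reading this: the scenario-2 preset simulates three laboratories sharing
one microscope model. The baseline (preprocessing only) leaves a clear
batch signature (batch score 0.82); every batch-aware method improves on
it, with the Harmony-style correction mixing laboratories most
aggressively. Sphering cannot help here — after plate-wise normalization
the negative controls carry no batch signal, which is exactly the
situation its assumptions exclude — while bio-conservation (~0.95) is
barely affected by any method. The `oracle` row subtracts the simulator's
true injected effects and marks what an ideal correction could achieve.

The same pipeline is available from the shell:

```bash
cpbatch simulate --preset s2 --seed 7 --out profiles.parquet
cpbatch preprocess --input profiles.parquet --output baseline.parquet
cpbatch correct --input baseline.parquet --output corrected.parquet \
    --method combat --batch-key source_id
cpbatch evaluate --input corrected.parquet --output metrics.csv \
    --batch-key source_id
cpbatch run --config scenario.yaml --outdir results/   # full loop + plots
```

`cpbatch run` writes `metrics.csv` (tidy: scenario, method, metric,
category, raw_value, normalized_value), `report.md`, `manifest.json` and
UMAP panels under `embeddings/`.

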