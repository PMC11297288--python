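"""Scenario orchestration: preprocess -> correct -> evaluate -> report.

A :class:`ScenarioConfig` fully determines one benchmark run: the input
(a file or a simulator preset plus seed), the batch and label variables,
the correction methods with their parameters, the metric parameters, and
the category weights of the overall score.  The overall score of a method
is ``w_batch * mean(batch metrics) + w_bio * mean(bio metrics)`` with
default weights 0.4 and 0.6.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import __version__
from .correction import BatchDesign, get_method
from .metrics import (
    BATCH_METRICS,
    BIO_METRICS,
    MetricResult,
    build_knn_graph,
    graph_connectivity,
    kbet_score,
    leiden_cluster_scores,
    lisi_score,
    mean_average_precision,
    silhouette_batch,
    silhouette_label,
)
from .preprocessing import PreprocessParams, run_baseline
from .profile_io import ProfileTable, read_profiles
from .synthetic_data import (
    SCENARIO_BATCH_KEY,
    GroundTruth,
    oracle_correct,
    scenario_preset,
    simulate,
)

__all__ = [
    "MetricParams",
    "ScenarioConfig",
    "BenchmarkReport",
    "evaluate_metrics",
    "run_benchmark",
    "aggregate_scores",
    "rank_methods",
    "compute_embedding",
    "plot_embedding",
    "write_report",
]


@dataclass
class MetricParams:
    """Shared parameters of the metric suite.

    Feature-space method outputs are PCA-reduced to ``pca_dim`` components
    before neighborhood-based metrics (kNN graph, LISI, kBET, Leiden) so
    that feature- and embedding-space methods see comparable geometry;
    silhouette and mAP run on the method's output directly.
    """

    knn_k: int = 15
    lisi_perplexity: float = 30.0
    kbet_size: int | None = None
    leiden_resolutions: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0)
    pca_graph: bool = True
    pca_dim: int = 50
    kbet_per_label: bool = True


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one benchmark run."""

    name: str = "scenario"
    preset: str | None = "s2"          # simulator preset ...
    input_path: str | None = None      # ... or a profile table on disk
    seed: int = 0
    batch_key: str | None = None       # default: the preset's batch variable
    label_key: str = "compound_id"
    methods: dict[str, dict] = field(
        default_factory=lambda: {"baseline": {}, "sphering": {}, "combat": {},
                                 "mnn": {}, "harmony": {}}
    )
    metric_params: MetricParams = field(default_factory=MetricParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    w_batch: float = 0.4
    w_bio: float = 0.6

    def __post_init__(self) -> None:
        if abs(self.w_batch + self.w_bio - 1.0) > 1e-9:
            raise ValueError("w_batch + w_bio must equal 1")
        if self.preset is None and self.input_path is None:
            raise ValueError("either a simulator preset or an input path is required")
        if self.batch_key is None:
            self.batch_key = SCENARIO_BATCH_KEY.get(self.preset or "", "batch_id")


@dataclass
class BenchmarkReport:
    """Metric table, per-method aggregate scores and run manifest."""

    scenario: str
    results: list[MetricResult]
    scores: pd.DataFrame          # index: method; batch_score, bio_score, overall, rank
    failures: dict[str, str]
    manifest: dict

    def tidy(self) -> pd.DataFrame:
        rows = [
            (self.scenario, r.method_name, r.metric_name, r.category,
             r.raw_value, r.normalized_value)
            for r in self.results
        ]
        return pd.DataFrame(
            rows, columns=["scenario", "method", "metric", "category",
                           "raw_value", "normalized_value"],
        )


def _graph_representation(x: np.ndarray, output_space: str,
                          params: MetricParams, seed: int) -> np.ndarray:
    if output_space == "embedding" or not params.pca_graph:
        return x
    from sklearn.decomposition import PCA

    d = min(params.pca_dim, x.shape[1], x.shape[0] - 1)
    if d >= x.shape[1]:
        return x
    return PCA(n_components=d, random_state=seed).fit_transform(x)


def evaluate_metrics(table: ProfileTable, batch_key: str, label_key: str,
                     output_space: str = "feature",
                     params: MetricParams | None = None, seed: int = 0,
                     method_name: str = "") -> list[MetricResult]:
    """Compute all 10 metrics for one corrected representation."""
    params = params or MetricParams()
    if batch_key not in table.meta.columns:
        raise KeyError(f"unknown batch key {batch_key!r}")
    if label_key not in table.meta.columns:
        raise KeyError(f"unknown label key {label_key!r}")
    batches = table.meta[batch_key].astype(str).to_numpy()
    labels = table.meta[label_key].astype(str).to_numpy()
    x = table.matrix()
    g = _graph_representation(x, output_space, params, seed)
    graph = build_knn_graph(g, k=min(params.knn_k, x.shape[0] - 1))

    results = [
        silhouette_batch(x, batches, labels, method_name=method_name),
        graph_connectivity(graph, labels, method_name=method_name),
        lisi_score(g, batches, "batch", params.lisi_perplexity,
                   method_name=method_name),
        kbet_score(g, batches, labels if params.kbet_per_label else None,
                   params.kbet_size, method_name=method_name),
        silhouette_label(x, labels, method_name=method_name),
        lisi_score(g, labels, "label", params.lisi_perplexity,
                   method_name=method_name),
    ]
    ari, nmi = leiden_cluster_scores(
        g, labels, params.leiden_resolutions, k=params.knn_k, seed=seed,
        method_name=method_name,
    )
    results += [ari, nmi]
    results.append(mean_average_precision(x, table.meta, label_key,
                                          "nonrep", method_name=method_name))
    results.append(mean_average_precision(x, table.meta, label_key,
                                          "control", method_name=method_name))
    return results


def aggregate_scores(results: list[MetricResult],
                     w_batch: float = 0.4, w_bio: float = 0.6) -> pd.DataFrame:
    """Per-method batch/bio means and the weighted overall score."""
    if abs(w_batch + w_bio - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    tidy = pd.DataFrame(
        [(r.method_name, r.metric_name, r.category, r.normalized_value)
         for r in results],
        columns=["method", "metric", "category", "normalized_value"],
    )
    rows = {}
    expected = set(BATCH_METRICS) | set(BIO_METRICS)
    for method, grp in tidy.groupby("method", sort=True):
        have = set(grp["metric"])
        if not expected <= have:
            warnings.warn(
                f"method {method!r} missing metric(s) {sorted(expected - have)}; "
                "excluded from aggregation", stacklevel=2,
            )
            continue
        batch = grp.loc[grp["category"] == "batch", "normalized_value"].mean()
        bio = grp.loc[grp["category"] == "bio", "normalized_value"].mean()
        rows[method] = (batch, bio, w_batch * batch + w_bio * bio)
    scores = pd.DataFrame.from_dict(
        rows, orient="index", columns=["batch_score", "bio_score", "overall"]
    )
    scores["rank"] = rankdata(-scores["overall"].to_numpy(), method="average")
    return scores.sort_values("overall", ascending=False)


def _load_input(config: ScenarioConfig) -> tuple[ProfileTable, GroundTruth | None]:
    if config.input_path is not None:
        return read_profiles(config.input_path), None
    cfg = scenario_preset(config.preset, seed=config.seed)
    return simulate(cfg)


def run_benchmark(config: ScenarioConfig) -> BenchmarkReport:
    """Execute one scenario end to end.

    The raw table is preprocessed once (the Baseline representation); each
    method corrects that representation and is scored with all 10 metrics.
    The ``oracle`` method name is special: it inverts the simulator's
    injected effects on the raw table and is then preprocessed identically
    (only available when the input comes from the simulator).  A method
    failing mid-run is recorded and does not abort the others.
    """
    raw, truth = _load_input(config)
    for key in (config.batch_key, config.label_key):
        if key not in raw.meta.columns:
            raise KeyError(f"unknown metadata key {key!r}")
    BatchDesign.from_table(raw, config.batch_key)
    baseline_rep = run_baseline(raw, config.preprocess)

    results: list[MetricResult] = []
    failures: dict[str, str] = {}
    for name, method_params in config.methods.items():
        try:
            if name == "oracle":
                if truth is None:
                    raise ValueError("oracle correction requires simulated input")
                rep = run_baseline(oracle_correct(raw, truth), config.preprocess)
                space = "feature"
            else:
                method = get_method(name)
                rep = method.func(baseline_rep, batch_key=config.batch_key,
                                  seed=config.seed, **method_params)
                space = method.output_space
            results.extend(
                evaluate_metrics(rep, config.batch_key, config.label_key,
                                 output_space=space, params=config.metric_params,
                                 seed=config.seed, method_name=name)
            )
        except Exception as exc:  # isolate per-method failures
            warnings.warn(f"method {name!r} failed: {exc}", stacklevel=2)
            failures[name] = str(exc)
    scores = aggregate_scores(results, config.w_batch, config.w_bio)
    manifest = {
        "scenario": config.name,
        "n_wells": raw.n_wells,
        "preset": config.preset,
        "input_path": config.input_path,
        "seed": config.seed,
        "batch_key": config.batch_key,
        "label_key": config.label_key,
        "methods": {k: dict(v) for k, v in config.methods.items()},
        "metric_params": asdict(config.metric_params),
        "preprocess": asdict(config.preprocess),
        "weights": {"batch": config.w_batch, "bio": config.w_bio},
        "cpbatch_version": __version__,
    }
    return BenchmarkReport(config.name, results, scores, failures, manifest)


def rank_methods(reports: list[BenchmarkReport]) -> pd.DataFrame:
    """Mean rank of each method across scenario reports (1 = best).

    Ties share the average rank.  Methods absent from some scenarios are
    ranked only where present and flagged via ``n_scenarios``.
    """
    if not reports:
        raise ValueError("need >= 1 report")
    ranks: dict[str, list[float]] = {}
    for rep in reports:
        for method, row in rep.scores.iterrows():
            ranks.setdefault(method, []).append(float(row["rank"]))
    table = pd.DataFrame(
        {
            "mean_rank": {m: float(np.mean(v)) for m, v in ranks.items()},
            "n_scenarios": {m: len(v) for m, v in ranks.items()},
        }
    )
    incomplete = table["n_scenarios"] < len(reports)
    if incomplete.any():
        warnings.warn(
            f"method(s) missing from some scenarios: "
            f"{list(table.index[incomplete])}", stacklevel=2,
        )
    return table.sort_values("mean_rank")


def compute_embedding(table: ProfileTable, seed: int = 0,
                      n_neighbors: int = 15) -> np.ndarray:
    """2-D nonlinear (UMAP) embedding of a table; deterministic given seed."""
    import umap

    if table.n_wells < 10:
        raise ValueError("need >= 10 wells for an embedding")
    if table.n_wells <= n_neighbors:
        raise ValueError("fewer wells than embedding neighbors")
    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2,
                        random_state=seed)
    return np.asarray(reducer.fit_transform(table.matrix()))


def plot_embedding(table: ProfileTable, color_keys: list[str], seed: int = 0,
                   outdir: str | Path = ".", n_neighbors: int = 15,
                   prefix: str = "embedding") -> list[Path]:
    """2-D UMAP panels of a table, one per metadata color key (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for key in color_keys:
        if key not in table.meta.columns:
            raise KeyError(f"unknown metadata key {key!r}")
    coords = compute_embedding(table, seed=seed, n_neighbors=n_neighbors)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for key in color_keys:
        fig, ax = plt.subplots(figsize=(5, 4))
        values = table.meta[key].astype(str)
        for val in sorted(values.unique()):
            rows = (values == val).to_numpy()
            ax.scatter(coords[rows, 0], coords[rows, 1], s=8, label=val, alpha=0.7)
        ax.set_title(key)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        if values.nunique() <= 12:
            ax.legend(fontsize=6, markerscale=0.7, frameon=False)
        path = outdir / f"{prefix}_{key}.svg"
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def write_report(report: BenchmarkReport, outdir: str | Path) -> None:
    """Write metrics.csv (tidy), report.md and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.tidy().to_csv(outdir / "metrics.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, default=str)
    lines = [
        f"# Benchmark report: {report.scenario}",
        "",
        "```",
        report.scores.round(4).to_string(),
        "```",
        "",
    ]
    if report.failures:
        lines.append("## Failed methods")
        lines += [f"- {m}: {msg}" for m, msg in report.failures.items()]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
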