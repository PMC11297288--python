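"""Baseline preprocessing pipeline for well-level morphological profiles.

Four steps, applied in order:

1. **Variation filtering** — drop features whose absolute coefficient of
   variation ``C_var = |sigma~ / X~|`` (median and raw median absolute
   deviation, computed plate-wise over negative-control wells only) falls
   below a threshold on *any* plate.
2. **MAD normalization** — robust per-plate standardization
   ``(X - X~) / sigma~`` using each plate's negative-control median and MAD.
3. **Rank-based inverse normal transform (INT)** — per feature, map ranks
   through the standard normal quantile function with the Blom offset
   ``c = 3/8``: ``Y_i = Phi^-1((r_i - c) / (N - 2c + 1))``.
4. **Correlation-based feature selection** — while any feature pair exceeds
   the correlation threshold, drop the pair member with the highest total
   absolute correlation to all remaining features.

The MAD here is the raw median absolute deviation, without the 1.4826
Gaussian consistency constant.  INT is applied per feature over all wells
jointly (plate effects are already handled by step 2).  Correlations are
Pearson on the INT-transformed values, compared in absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profile_io import ProfileTable

__all__ = [
    "PreprocessParams",
    "FeatureStats",
    "compute_feature_stats",
    "filter_low_variance",
    "mad_normalize",
    "inverse_normal_transform",
    "select_features_correlation",
    "run_baseline",
]


@dataclass
class PreprocessParams:
    """Tunable parameters of the baseline pipeline.

    cvar_threshold
        Features with ``C_var`` below this on any plate are discarded.
    int_c
        Blom offset of the inverse normal transform; 3/8 is the classical
        choice giving approximately unbiased normal scores.
    corr_threshold
        Absolute Pearson correlation above which a feature pair is
        considered redundant.
    """

    cvar_threshold: float = 1e-3
    int_c: float = 0.375
    corr_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.corr_threshold < 1):
            raise ValueError("corr_threshold must be in (0, 1)")
        if not (0 <= self.int_c < 0.5):
            raise ValueError("int_c must be in [0, 0.5)")


@dataclass
class FeatureStats:
    """Per (plate, feature) robust location/scale from negative controls.

    Each frame is indexed by plate_id with one column per feature:
    ``median`` (X~), ``mad`` (sigma~, raw MAD) and ``cvar``
    (``|sigma~/X~|``; +inf where the median is 0 with nonzero MAD, and 0
    where the MAD is 0).
    """

    median: pd.DataFrame
    mad: pd.DataFrame
    cvar: pd.DataFrame

    @property
    def plates(self) -> list[str]:
        return list(self.median.index)


def compute_feature_stats(table: ProfileTable) -> FeatureStats:
    """Plate-wise robust statistics from negative-control wells only."""
    meta = table.meta
    plates = meta["plate_id"].unique()
    med_rows, mad_rows = [], []
    for plate in plates:
        on_plate = meta["plate_id"] == plate
        ctrl = on_plate & (meta["control_type"] == "negative")
        n_ctrl = int(ctrl.sum())
        if n_ctrl == 0:
            raise ValueError(f"plate {plate!r} has no negative-control wells")
        if n_ctrl < 2:
            raise ValueError(
                f"plate {plate!r} has only {n_ctrl} negative-control well; >= 2 required"
            )
        x = table.features.loc[ctrl.to_numpy()].to_numpy(dtype=float)
        med = np.median(x, axis=0)
        mad = np.median(np.abs(x - med), axis=0)
        med_rows.append(med)
        mad_rows.append(mad)
    median = pd.DataFrame(med_rows, index=plates, columns=table.feature_names)
    mad = pd.DataFrame(mad_rows, index=plates, columns=table.feature_names)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvar_vals = np.abs(mad.to_numpy() / median.to_numpy())
    cvar_vals[mad.to_numpy() == 0] = 0.0
    cvar_vals[(median.to_numpy() == 0) & (mad.to_numpy() > 0)] = np.inf
    cvar = pd.DataFrame(cvar_vals, index=plates, columns=table.feature_names)
    return FeatureStats(median=median, mad=mad, cvar=cvar)


def filter_low_variance(table: ProfileTable, stats: FeatureStats,
                        params: PreprocessParams | None = None) -> ProfileTable:
    """Drop features with ``C_var`` below threshold on at least one plate."""
    params = params or PreprocessParams()
    missing = set(table.feature_names) - set(stats.cvar.columns)
    if missing:
        raise ValueError(f"stats do not cover feature(s): {sorted(missing)[:5]}")
    missing_plates = set(table.meta["plate_id"].unique()) - set(stats.plates)
    if missing_plates:
        raise ValueError(f"stats do not cover plate(s): {sorted(missing_plates)[:5]}")
    cvar = stats.cvar[table.feature_names]
    keep = (cvar >= params.cvar_threshold).all(axis=0)
    kept = [f for f in table.feature_names if keep[f]]
    if not kept:
        raise ValueError("variation filtering removed every feature")
    return ProfileTable(table.features[kept].copy(), table.meta.copy())


def mad_normalize(table: ProfileTable, stats: FeatureStats) -> ProfileTable:
    """Per-plate robust standardization with control-derived median/MAD."""
    mad = stats.mad[table.feature_names]
    if (mad.to_numpy() == 0).any():
        zero = mad.columns[(mad == 0).any(axis=0)][:5].tolist()
        raise ValueError(
            f"zero MAD for feature(s) {zero}; run variation filtering first"
        )
    med = stats.median[table.feature_names]
    out = np.empty((table.n_wells, table.n_features), dtype=float)
    x = table.features.to_numpy(dtype=float)
    plate_ids = table.meta["plate_id"].to_numpy()
    for plate in np.unique(plate_ids):
        rows = plate_ids == plate
        out[rows] = (x[rows] - med.loc[plate].to_numpy()) / mad.loc[plate].to_numpy()
    return table.with_features(out)


def inverse_normal_transform(values: np.ndarray, c: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse normal transform of a 1-D vector.

    Ties receive mid-ranks, so tied inputs map to equal outputs.  Strictly
    monotone on distinct inputs; a single sample maps to 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D vector")
    n = values.shape[0]
    if n == 0:
        raise ValueError("empty vector")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values")
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf((ranks - c) / (n - 2 * c + 1))


def _int_table(table: ProfileTable, c: float) -> ProfileTable:
    x = table.features.to_numpy(dtype=float)
    out = np.column_stack(
        [inverse_normal_transform(x[:, j], c) for j in range(x.shape[1])]
    )
    return table.with_features(out)


def select_features_correlation(table: ProfileTable,
                                params: PreprocessParams | None = None) -> ProfileTable:
    """Greedy removal of highly correlated (redundant) features.

    While any pair of surviving features has absolute Pearson correlation
    above the threshold, the member of the worst offending pair with the
    largest total absolute correlation to all current features is dropped.
    """
    params = params or PreprocessParams()
    if table.n_features < 2:
        raise ValueError("need >= 2 features for correlation selection")
    x = table.features.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [f for f, s in zip(table.feature_names, sd) if s == 0][:5]
        raise ValueError(f"zero-variance feature(s) at selection stage: {bad}")
    corr = np.abs(np.corrcoef(x, rowvar=False))
    alive = list(range(table.n_features))
    while True:
        sub = corr[np.ix_(alive, alive)]
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= params.corr_threshold:
            break
        total = sub.sum(axis=0)
        drop_local = i if total[i] >= total[j] else j
        del alive[drop_local]
        if len(alive) == 1:
            break
    kept = [table.feature_names[i] for i in alive]
    return ProfileTable(table.features[kept].copy(), table.meta.copy())


def run_baseline(table: ProfileTable,
                 params: PreprocessParams | None = None) -> ProfileTable:
    """Full baseline pipeline: filter -> MAD -> INT -> feature selection.

    The result is the reference representation every batch-correction
    method is applied to and compared against.
    """
    params = params or PreprocessParams()
    stats = compute_feature_stats(table)
    filtered = filter_low_variance(table, stats, params)
    normalized = mad_normalize(filtered, stats)
    transformed = _int_table(normalized, params.int_c)
    return select_features_correlation(transformed, params)
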