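"""Hierarchical simulator for well-level morphological profiles.

Generates profile tables with the nested structure of a multi-site Cell
Painting campaign — source laboratory -> experimental batch -> plate ->
well — together with the exact ground-truth decomposition of every well's
signal, so that metric and correction behavior can be validated against an
oracle that inverts the injected technical effects.

Generative model (all draws Gaussian unless noted), per well ``i`` and
feature ``j``::

    observed[i, j] = bio[i, j] * mult[i, j] + additive[i, j] + noise[i, j]

* ``bio`` — one effect vector per compound, drawn once with scale
  ``compound_effect_scale`` (``positive_effect_scale`` for the heavily
  replicated positive controls, which emulate compounds chosen for strong
  phenotypes); DMSO negative controls have zero biological effect.
* ``additive`` — a per-batch constant vector (scale
  ``batch_additive_scale``) plus a per-microscope-type constant vector
  (scale ``microscope_effect_scale``); sources sharing a microscope model
  share the microscope shift.
* ``mult`` — per-batch, per-feature factors drawn log-normal around 1
  (log-sd ``batch_multiplicative_scale``) that rescale each feature's
  *response to perturbation*.  Applying them to the biological signal
  rather than to the whole readout reflects how instrument and protocol
  differences modulate measured effect sizes, and makes this the
  component of a batch effect that plate-wise normalization on negative
  controls cannot see (DMSO wells carry no signal to rescale).
* ``noise`` — i.i.d. per-well Gaussian measurement noise
  (``well_noise_scale``).

Plate layout: each plate carries ``n_negative_controls_per_plate`` DMSO
wells and one well of every positive control; remaining wells receive
treatment compounds at the requested replicate counts, with any leftover
capacity filled by extra DMSO wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profile_io import ProfileTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "scenario_preset",
    "oracle_correct",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("s1", "s2", "s3", "s4", "s5")

NEGATIVE_COMPOUND = "DMSO"


@dataclass
class SimulationConfig:
    """Knobs of the hierarchical profile simulator.

    ``microscope_types`` has one entry per source; its length defines the
    number of sources.  ``replicates_per_compound`` is either an exact count
    or an inclusive ``(low, high)`` range sampled per compound.  All scales
    are standard deviations in arbitrary feature units (log-sd for the
    multiplicative factors).
    """

    n_features: int = 300
    microscope_types: tuple[str, ...] = ("scope_A",)
    batches_per_source: int = 2
    plates_per_batch: int = 2
    wells_per_plate: int = 60
    n_compounds: int = 12
    replicates_per_compound: int | tuple[int, int] = 8
    n_negative_controls_per_plate: int = 8
    n_positive_controls: int = 4
    compound_effect_scale: float = 1.0
    positive_effect_scale: float = 3.0
    batch_additive_scale: float = 0.5
    batch_multiplicative_scale: float = 0.1
    microscope_effect_scale: float = 0.0
    well_noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_features, len(self.microscope_types), self.batches_per_source,
            self.plates_per_batch, self.wells_per_plate, self.n_compounds,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all structural counts must be >= 1")
        scales = (
            self.compound_effect_scale, self.positive_effect_scale,
            self.batch_additive_scale, self.batch_multiplicative_scale,
            self.microscope_effect_scale, self.well_noise_scale,
        )
        if any(s < 0 for s in scales):
            raise ValueError("scales must be >= 0")
        n_fixed = self.n_negative_controls_per_plate + self.n_positive_controls
        if self.n_negative_controls_per_plate < 2:
            raise ValueError("need >= 2 negative controls per plate")
        if n_fixed >= self.wells_per_plate:
            raise ValueError("control wells exceed plate capacity")

    @property
    def n_sources(self) -> int:
        return len(self.microscope_types)

    @property
    def n_plates(self) -> int:
        return self.n_sources * self.batches_per_source * self.plates_per_batch


@dataclass
class GroundTruth:
    """Exact per-well decomposition of a simulated table.

    ``observed = bio * mult + additive + noise`` holds bit-exactly for
    the table returned alongside this object.
    """

    bio: np.ndarray
    additive: np.ndarray
    mult: np.ndarray
    noise: np.ndarray
    batch_additive: dict[str, np.ndarray]
    batch_mult: dict[str, np.ndarray]
    microscope_shift: dict[str, np.ndarray]
    well_keys: pd.DataFrame

    def reconstruct(self) -> np.ndarray:
        return self.bio * self.mult + self.additive + self.noise


def _well_position(index: int) -> str:
    row, col = divmod(index, 24)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate(config: SimulationConfig) -> tuple[ProfileTable, GroundTruth]:
    """Draw one profile table and its ground-truth decomposition."""
    rng = np.random.default_rng(config.seed)
    f = config.n_features

    # compound effect vectors (drawn once, shared by all replicates)
    compounds = [f"cpd_{i:04d}" for i in range(config.n_compounds)]
    positives = [f"pos_{i}" for i in range(config.n_positive_controls)]
    effects: dict[str, np.ndarray] = {NEGATIVE_COMPOUND: np.zeros(f)}
    for c in compounds:
        effects[c] = rng.normal(0.0, config.compound_effect_scale, f)
    for p in positives:
        effects[p] = rng.normal(0.0, config.positive_effect_scale, f)

    # replicate demand and plate capacity
    n_plates = config.n_plates
    slots_per_plate = (config.wells_per_plate
                       - config.n_negative_controls_per_plate
                       - config.n_positive_controls)
    capacity = n_plates * slots_per_plate
    if isinstance(config.replicates_per_compound, tuple):
        lo, hi = config.replicates_per_compound
        reps = rng.integers(lo, hi + 1, size=config.n_compounds)
    else:
        reps = np.full(config.n_compounds, config.replicates_per_compound)
    assignment = [c for c, r in zip(compounds, reps) for _ in range(int(r))]
    if len(assignment) > capacity:
        raise ValueError(
            f"replicate demand ({len(assignment)} treatment wells) exceeds "
            f"plate capacity ({capacity})"
        )
    # leftover treatment slots become extra DMSO wells
    assignment += [NEGATIVE_COMPOUND] * (capacity - len(assignment))
    order = rng.permutation(len(assignment))
    assignment = [assignment[i] for i in order]

    # technical effects
    micro_types = sorted(set(config.microscope_types))
    microscope_shift = {
        m: rng.normal(0.0, config.microscope_effect_scale, f) for m in micro_types
    }
    batch_additive: dict[str, np.ndarray] = {}
    batch_mult: dict[str, np.ndarray] = {}

    meta_rows = []
    slot = 0
    for s in range(config.n_sources):
        source = f"source_{s + 1}"
        scope = config.microscope_types[s]
        for b in range(config.batches_per_source):
            batch = f"{source}_batch_{b + 1}"
            batch_additive[batch] = rng.normal(0.0, config.batch_additive_scale, f)
            batch_mult[batch] = np.exp(
                rng.normal(0.0, config.batch_multiplicative_scale, f)
            )
            for p in range(config.plates_per_batch):
                plate = f"{batch}_plate_{p + 1}"
                wells = (
                    [(NEGATIVE_COMPOUND, "negative")] * config.n_negative_controls_per_plate
                    + [(pos, "positive") for pos in positives]
                )
                for _ in range(slots_per_plate):
                    cpd = assignment[slot]
                    slot += 1
                    ctype = "negative" if cpd == NEGATIVE_COMPOUND else "treatment"
                    wells.append((cpd, ctype))
                for w, (cpd, ctype) in enumerate(wells):
                    meta_rows.append(
                        (source, batch, plate, _well_position(w), cpd, ctype, scope)
                    )

    meta = pd.DataFrame(
        meta_rows,
        columns=["source_id", "batch_id", "plate_id", "well_position",
                 "compound_id", "control_type", "microscope_type"],
    )
    n = len(meta)
    bio = np.stack([effects[c] for c in meta["compound_id"]])
    additive = np.stack(
        [batch_additive[b] + microscope_shift[m]
         for b, m in zip(meta["batch_id"], meta["microscope_type"])]
    )
    mult = np.stack([batch_mult[b] for b in meta["batch_id"]])
    noise = rng.normal(0.0, config.well_noise_scale, (n, f))
    observed = bio * mult + additive + noise

    feature_names = [f"feat_{j:04d}" for j in range(f)]
    table = ProfileTable(pd.DataFrame(observed, columns=feature_names), meta)
    truth = GroundTruth(
        bio=bio, additive=additive, mult=mult, noise=noise,
        batch_additive=batch_additive, batch_mult=batch_mult,
        microscope_shift={
            f"source_{s + 1}": microscope_shift[config.microscope_types[s]]
            for s in range(config.n_sources)
        },
        well_keys=meta[["source_id", "batch_id", "plate_id", "well_position"]].copy(),
    )
    return table, truth


# -- scenario presets ------------------------------------------------------

# Desk-scale analogues of the five benchmark scenarios, ordered by
# increasing technical heterogeneity:
#   s1  one laboratory, several runs, few compounds, many replicates
#   s2  three laboratories, same microscope model
#   s3  three laboratories, many compounds with 1-3 replicates and heavily
#       replicated positive controls
#   s4  five laboratories, three microscope models, few compounds
#   s5  five laboratories, three microscope models, many compounds
_PRESETS: dict[str, SimulationConfig] = {
    "s1": SimulationConfig(
        microscope_types=("scope_A",),
        batches_per_source=4, plates_per_batch=2, wells_per_plate=96,
        n_compounds=12, replicates_per_compound=30,
        n_negative_controls_per_plate=16,
        batch_additive_scale=0.15, batch_multiplicative_scale=0.05,
        microscope_effect_scale=0.0,
    ),
    "s2": SimulationConfig(
        microscope_types=("scope_A",) * 3,
        batches_per_source=2, plates_per_batch=2, wells_per_plate=96,
        n_compounds=12, replicates_per_compound=45,
        n_negative_controls_per_plate=16,
        batch_additive_scale=0.6, batch_multiplicative_scale=0.25,
        microscope_effect_scale=0.0,
    ),
    "s3": SimulationConfig(
        microscope_types=("scope_A",) * 3,
        batches_per_source=2, plates_per_batch=2, wells_per_plate=96,
        n_compounds=150, replicates_per_compound=(1, 3),
        n_negative_controls_per_plate=16, n_positive_controls=8,
        batch_additive_scale=0.8, batch_multiplicative_scale=0.3,
        microscope_effect_scale=0.0,
    ),
    "s4": SimulationConfig(
        microscope_types=("scope_A", "scope_A", "scope_A", "scope_B", "scope_C"),
        batches_per_source=2, plates_per_batch=1, wells_per_plate=96,
        n_compounds=12, replicates_per_compound=30,
        n_negative_controls_per_plate=16,
        batch_additive_scale=0.8, batch_multiplicative_scale=0.35,
        microscope_effect_scale=1.0,
    ),
    "s5": SimulationConfig(
        microscope_types=("scope_A", "scope_A", "scope_A", "scope_B", "scope_C"),
        batches_per_source=2, plates_per_batch=1, wells_per_plate=96,
        n_compounds=150, replicates_per_compound=(1, 3),
        n_negative_controls_per_plate=16, n_positive_controls=8,
        batch_additive_scale=1.0, batch_multiplicative_scale=0.4,
        microscope_effect_scale=1.5,
    ),
}

#: Batch variable used by each scenario: the experimental run within a
#: single laboratory (s1), the laboratory itself otherwise.
SCENARIO_BATCH_KEY = {
    "s1": "batch_id", "s2": "source_id", "s3": "source_id",
    "s4": "source_id", "s5": "source_id",
}


def scenario_preset(name: str, seed: int | None = None) -> SimulationConfig:
    """Return the desk-scale simulator config for one benchmark scenario."""
    if name not in _PRESETS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    cfg = _PRESETS[name]
    return replace(cfg, seed=cfg.seed if seed is None else seed)


def oracle_correct(table: ProfileTable, truth: GroundTruth) -> ProfileTable:
    """Invert the injected technical effects exactly.

    Subtracts the additive batch/microscope shifts and undoes the
    multiplicative rescaling of the biological signal, leaving
    biology plus well noise.
    """
    if table.n_wells != truth.bio.shape[0]:
        raise ValueError("ground truth does not match table: well count differs")
    keys = table.meta[["source_id", "batch_id", "plate_id", "well_position"]]
    if not keys.reset_index(drop=True).equals(truth.well_keys.reset_index(drop=True)):
        raise ValueError("ground truth does not match table: well addresses differ")
    corrected = table.matrix() - truth.additive - truth.bio * (truth.mult - 1.0)
    return table.with_features(corrected)
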