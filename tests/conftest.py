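import numpy as np
import pandas as pd
import pytest

from cpbatch.profile_io import ProfileTable


def build_table(values, plate_ids, control_types, compounds=None,
                batch_ids=None, source_ids=None, feature_names=None):
    """Assemble a valid ProfileTable from parallel per-well lists."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    plate_ids = list(plate_ids)
    if compounds is None:
        compounds = ["DMSO" if c == "negative" else f"cpd{i}"
                     for i, c in enumerate(control_types)]
    if batch_ids is None:
        batch_ids = ["b1"] * n
    if source_ids is None:
        source_ids = ["s1"] * n
    pos_counter = {}
    positions = []
    for p in plate_ids:
        pos_counter[p] = pos_counter.get(p, 0) + 1
        positions.append(f"A{pos_counter[p]:02d}")
    meta = pd.DataFrame({
        "source_id": source_ids,
        "batch_id": batch_ids,
        "plate_id": plate_ids,
        "well_position": positions,
        "compound_id": list(compounds),
        "control_type": list(control_types),
    })
    names = feature_names or [f"f{j}" for j in range(values.shape[1])]
    return ProfileTable(pd.DataFrame(values, columns=names), meta)


def random_table(rng, n_wells=24, n_features=5, n_plates=2, n_controls=4,
                 n_compounds=4):
    """Random multi-plate table with DMSO controls on every plate."""
    per_plate = n_wells // n_plates
    plate_ids, control_types, compounds, batch_ids = [], [], [], []
    for p in range(n_plates):
        for w in range(per_plate):
            plate_ids.append(f"p{p}")
            batch_ids.append(f"b{p % 2}")
            if w < n_controls:
                control_types.append("negative")
                compounds.append("DMSO")
            else:
                control_types.append("treatment")
                compounds.append(f"c{w % n_compounds}")
    values = rng.normal(size=(len(plate_ids), n_features))
    return build_table(values, plate_ids, control_types, compounds,
                       batch_ids=batch_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """Two plates x 6 wells, 3 features, 2 DMSO controls per plate."""
    rng = np.random.default_rng(0)
    return random_table(rng, n_wells=12, n_features=3, n_plates=2,
                        n_controls=2, n_compounds=2)
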