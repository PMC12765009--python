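import numpy as np
import pandas as pd
import pytest

from hootid import (
    CallRecord,
    CallTable,
    SimConfig,
    pca_scores,
    simulate_population,
    standardize,
    table_to_features,
)


def make_table(n_individuals=2, calls=3, group="G", seed=0):
    """Small hand-buildable call table with distinct per-individual means."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_individuals):
        base = 700.0 + 40.0 * i
        for j in range(calls):
            records.append(CallRecord(
                individual_id=f"m{i + 1}",
                group_label=group,
                call_id=f"m{i + 1}_c{j + 1}",
                duration_s=0.3 + 0.01 * j + 0.005 * i,
                pfc_hz=base + rng.normal(0.0, 5.0, 10),
            ))
    return CallTable(records=records, provenance={"source": "fixture"})


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def sim_scores():
    """PC scores of a moderate simulated population (8 ind x 12 calls)."""
    cfg = SimConfig(n_individuals=8, calls_per_individual=12, seed=42)
    table = simulate_population(cfg).table
    feats = table_to_features(table)
    return pca_scores(standardize(feats))


@pytest.fixture
def flat_file(tmp_path, small_table):
    from hootid import write_call_table

    path = tmp_path / "calls.csv"
    write_call_table(small_table, path)
    return path
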