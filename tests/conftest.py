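import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from hdxdiff import (
    Effect,
    GeneratorConfig,
    MatchedTable,
    PeptideKey,
    compare_states,
    generate_records,
    match_peptides,
)


@pytest.fixture(scope="session")
def small_config():
    """Two states, one injected +1 Da effect, low noise."""
    return GeneratorConfig(
        n_states=2,
        n_timepoints=4,
        n_replicates=3,
        n_peptides=25,
        protein_length=120,
        effects=(Effect(4, "State2", 1.0),),
        noise_sd_da=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    records, truth = generate_records(small_config)
    table = match_peptides(records)
    results, intervals = compare_states(table)
    return dict(
        config=small_config,
        records=records,
        truth=truth,
        table=table,
        results=results,
        intervals=intervals,
    )


def tiny_table(ref_vals, test_vals, percent=None):
    """Hand-built one-peptide, one-timepoint matched table."""
    key = PeptideKey("AKLMNQRSTV", 1, 10)
    uptake = {
        (key, "ref", 60.0): np.asarray(ref_vals, dtype=float),
        (key, "test", 60.0): np.asarray(test_vals, dtype=float),
    }
    pct = {}
    if percent is not None:
        pct = {
            (key, "ref", 60.0): np.asarray(percent[0], dtype=float),
            (key, "test", 60.0): np.asarray(percent[1], dtype=float),
        }
    return MatchedTable(
        peptides=[key],
        states=["ref", "test"],
        timepoints_s=[60.0],
        uptake=uptake,
        percent=pct,
        n_replicates={"ref": len(ref_vals), "test": len(test_vals)},
    )
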