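import numpy as np
import pandas as pd
import pytest

from loocomp import (
    AbundanceTable,
    SampleMetadata,
    SimulationConfig,
    concat_timepoints,
    simulate_cohort,
    to_relative,
)


@pytest.fixture
def tiny_raw_table() -> AbundanceTable:
    """Two samples, two features, nonzero unannotated mass."""
    data = pd.DataFrame(
        {"A": [3.0, 0.0], "B": [1.0, 4.0]}, index=["s1", "s2"]
    )
    return AbundanceTable(data, pd.Series([1.0, 1.0], index=["s1", "s2"]), "raw")


@pytest.fixture
def paired_metadata() -> SampleMetadata:
    """Four subjects sampled at baseline and 3 months."""
    rows = []
    for i in range(1, 5):
        for tp in ("baseline", "3MO"):
            rows.append(
                {
                    "sample_id": f"subj_{i:02d}_{tp}",
                    "subject_id": f"subj_{i:02d}",
                    "timepoint": tp,
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (13/12/8 design, two spiked taxa)."""
    cfg = SimulationConfig(
        seed=7, n_taxa=50, spike_taxa=("taxon_010", "taxon_020"), spike_delta=4.0
    )
    tables, metadata, truth = simulate_cohort(cfg)
    rel = to_relative(concat_timepoints(tables))
    return cfg, rel, metadata, truth


def three_taxon_spike_cohort(delta: float = 10.0, n_subjects: int = 12):
    """Noise-free 3-taxon system: A and B constant, C multiplied by delta
    at 3MO.  Absolute baselines differ per subject so ranks are informative.
    """
    rows, meta = [], []
    ids = []
    for i in range(1, n_subjects + 1):
        # per-subject baselines kept non-proportional so the signed-rank
        # test sees distinct |differences| (no midrank ties)
        a = 1.0 + 0.01 * i
        b = 2.0 + 0.003 * i * i
        c = 1.5 + 0.02 * i + 0.0007 * i * i * i
        for tp, mult in (("baseline", 1.0), ("3MO", delta)):
            sid = f"subj_{i:02d}_{tp}"
            ids.append(sid)
            rows.append([a, b, c * mult])
            meta.append({"sample_id": sid, "subject_id": f"subj_{i:02d}", "timepoint": tp})
    table = AbundanceTable(
        pd.DataFrame(rows, index=ids, columns=["A", "B", "C"]), None, "raw"
    )
    return to_relative(table), SampleMetadata(pd.DataFrame(meta))
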