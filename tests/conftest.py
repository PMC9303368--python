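import numpy as np
import pandas as pd
import pytest

from mcpalm.pipeline import run_pipeline_frames
from mcpalm.simulate import SimulationConfig, simulate_experiment


def make_locs(rows, **common):
    """Build a canonical localization frame from (x, y, frame[, ...]) tuples."""
    defaults = {"photons": 300.0, "width": 300.0, "background": 2.0}
    defaults.update(common)
    recs = []
    for r in rows:
        rec = {"x": r[0], "y": r[1], "frame": r[2], **defaults}
        if len(r) > 3:
            rec.update(r[3])
        recs.append(rec)
    cols = ["x", "y", "frame", *defaults]
    df = pd.DataFrame(recs, columns=cols) if recs else pd.DataFrame({c: [] for c in cols})
    df["frame"] = df["frame"].astype(np.int64)
    return df


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic correlative experiment, shared across tests."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_experiment):
    """Full pipeline run on the default experiment."""
    e = default_experiment
    return run_pipeline_frames(e.sm_locs, e.cluster_locs, e.bead_pairs)
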