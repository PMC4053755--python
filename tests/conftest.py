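"""Shared fixtures: small toy tables and the heavier simulation bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epistat import cli_report, io_sga, synthetic_data


def make_dataset(rows, **log):
    """Build a Dataset from dicts with defaults for unspecified fields."""
    defaults = {
        "query_id": "qX", "array_id": "aX",
        "g01": 1.0, "g10": 1.0, "g11": 1.0,
        "sd01": 0.01, "sd10": 0.01, "sd11": 0.01, "n_reps": 4,
    }
    frame = pd.DataFrame([{**defaults, **r} for r in rows], columns=io_sga.FIELDS)
    return io_sga.Dataset(frame=frame, provenance="toy", filter_log=dict(log))


@pytest.fixture(scope="session")
def small_sim():
    """A 20k-pair synthetic dataset with ground truth (fast unit tests)."""
    cfg = synthetic_data.SyntheticConfig(n_genes=600, n_pairs=20_000, seed=1)
    ds, truth = synthetic_data.generate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def full_pipeline_bundle():
    """The full-scale recovery run: 200k pairs, harmonic surface at the
    reference coefficient 0.079, t-noise, nine mocks, noise-subtracted
    count-weighted fit.  Shared across the acceptance tests."""
    cfg = cli_report.PipelineConfig.from_dict(
        {"simulate": {"n_pairs": 200_000}, "seed": 1}
    )
    return cli_report.run_pipeline(cfg)
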