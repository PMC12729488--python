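"""Shared fixtures: small synthetic deployments reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import koalawalk as kw
from koalawalk import classify


@pytest.fixture(scope="session")
def captive_cfg() -> kw.SimConfig:
    """Captive training protocol, ~1.9 h per animal."""
    return kw.captive_config(days_per_individual=0.08, seed=11)


@pytest.fixture(scope="session")
def captive_features(captive_cfg) -> pd.DataFrame:
    """Feature table over both captive animals (1 s windows, 50% overlap)."""
    tables = [
        kw.extract_feature_table(kw.simulate_stream(captive_cfg, i))
        for i in range(captive_cfg.n_individuals)
    ]
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def trained_bundle(captive_features):
    """Chronological split + tuned forest on the captive feature table."""
    table = classify.training_table(captive_features)
    train, val, test = classify.chronological_split(table)
    best = classify.tune(train, val, search_budget=3, seed=11)
    model = classify.train_forest(train, best)
    return {"train": train, "val": val, "test": test,
            "model": model, "config": best}


@pytest.fixture(scope="session")
def wild_truth_bins():
    """Ground-truth-label path bins for the full 9 x 8-day deployment."""
    from koalawalk.pipeline import ground_truth_bins

    return ground_truth_bins(kw.wild_config(seed=1))


def make_bins(labels, individual="k01", date="2023-05-15", vedba=None,
              hours=None) -> pd.DataFrame:
    """Hand-build a minimal bin table from a label list."""
    n = len(labels)
    start_s = np.arange(n) * 20
    frame = pd.DataFrame(
        {
            "start_s": start_s,
            "label": labels,
            "is_gap": False,
            "vedba_max_mean": vedba if vedba is not None else np.ones(n),
            "vedba_min_mean": 0.0,
            "date": np.datetime64(date),
            "hour": hours if hours is not None else (start_s % 86400) // 3600,
            "individual_id": individual,
            "sex": "M",
            "habitat": "patch",
            "mass_kg": 7.5,
        }
    )
    return frame
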