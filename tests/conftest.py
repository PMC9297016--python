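"""Shared fixtures: synthetic worlds and feature-level tables.

The rendered "study world" (a population with an individual but no clan
signature, recorded at moderate SNR) is expensive, so it is built once per
session and shared by the end-to-end tests. Classifier- and redundancy-level
unit tests use cheap feature tables drawn directly at the feature level, so
they exercise the statistical machinery without audio rendering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from whoopsig import (
    BoutSpec,
    PopulationSpec,
    SplitSpec,
    synthesize_dataset,
    extract_table,
)
from whoopsig.classify import (
    drop_failed,
    filter_adults,
    prepare_individual_dataset,
    run_repeats,
)
from whoopsig.features import FEATURE_NAMES


def make_feature_table(
    rng: np.random.Generator,
    n_clans: int = 2,
    callers_per_clan: int = 4,
    n_bouts: int = 3,
    whoops_per_bout: int = 4,
    caller_effect: float = 1.0,
    clan_effect: float = 0.0,
    bout_effect: float = 0.0,
    noise: float = 1.0,
) -> pd.DataFrame:
    """Feature-level table with a controllable signature structure.

    Caller/clan/bout offsets are added to a subset of feature columns on top
    of unit Gaussian noise; metadata columns follow the package schema.
    """
    signal_cols = ["freq_mean_cf", "freq_max", "dur"]
    rows = []
    wid = 0
    for c in range(n_clans):
        clan = f"clan{c}"
        c_off = rng.normal(0, clan_effect, len(signal_cols))
        for h in range(callers_per_clan):
            caller = f"{clan}_h{h}"
            h_off = rng.normal(0, caller_effect, len(signal_cols))
            for b in range(n_bouts):
                bout = f"{caller}_b{b}"
                b_off = rng.normal(0, bout_effect, len(signal_cols))
                for pos in range(whoops_per_bout):
                    row = {
                        "whoop_id": f"w{wid}", "bout_id": bout, "caller_id": caller,
                        "clan_id": clan, "position_in_bout": pos,
                        "whoop_type": "A" if pos % 2 else "S",
                        "age_months": 60, "sex": "f" if h % 2 else "m",
                        "recording_method": "synthetic",
                    }
                    for name in FEATURE_NAMES:
                        row[name] = rng.normal(0, noise)
                    for j, name in enumerate(signal_cols):
                        row[name] += c_off[j] + h_off[j] + b_off[j]
                    rows.append(row)
                    wid += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_world():
    """Rendered world matching the headline experiment: 4 clans x 5 callers,
    4 bouts x 6 whoops each, individual effect 0.08, no clan effect, 15 dB SNR.
    Returns (feature table, truth table)."""
    pop = PopulationSpec(
        n_clans=4, individuals_per_clan=5,
        clan_effect_scale=0.0, individual_effect_scale=0.08,
        within_individual_cv=0.04, seed=11,
    )
    records, _, truth = synthesize_dataset(
        pop, BoutSpec(length_min=6, length_max=6),
        n_bouts_per_individual=4, snr_db=15.0,
    )
    feats = extract_table(records)
    return feats, truth


@pytest.fixture(scope="session")
def study_tables(study_world):
    """(clan-scheme table, individual-scheme table) after the dataset filters."""
    feats, _ = study_world
    adults = filter_adults(drop_failed(feats))
    indiv = prepare_individual_dataset(adults)
    return adults, indiv


@pytest.fixture(scope="session")
def individual_run(study_tables):
    """100-repeat individual-scheme CV with collected bout votes
    (shared by the signature-detection and redundancy tests)."""
    _, indiv = study_tables
    spec = SplitSpec(scheme="individual", n_repeats=100, n_trees=500, seed=5)
    summary = run_repeats(indiv, spec, target="caller_id", collect_votes=True)
    return indiv, spec, summary


@pytest.fixture(scope="session")
def clan_run(study_tables):
    """100-repeat clan-scheme CV on the same world."""
    adults, _ = study_tables
    spec = SplitSpec(scheme="clan", n_repeats=100, n_trees=500, seed=6)
    summary = run_repeats(adults, spec, target="clan_id")
    return adults, spec, summary
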