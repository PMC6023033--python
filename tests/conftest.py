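"""Shared fixtures: small reference molecules, planted-rule libraries, and a
session-scoped 20-seed train/screen recovery sweep reused by the property and
acceptance tests (one GA sweep, many assertions)."""

from __future__ import annotations

import math

import numpy as np
import pytest

import sigscreen as sg
from sigscreen import CriteriaSet, GaConfig, PlantedRule
from sigscreen.fixtures import planted_marker_signatures

# fixture-scale settings for the GA/SVM search: small population and a coarse
# cost grid keep one training round at a few seconds on one CPU
FAST_GA = dict(population=24, max_iter=15, stall_stop=4)
FAST_GRID = (0.1, 1.0)


@pytest.fixture(scope="session")
def planted_rule() -> PlantedRule:
    return PlantedRule(seed=1)


@pytest.fixture(scope="session")
def planted_library(planted_rule):
    """200 compounds, deterministic planted rule, ~12% carry the pharmacophore."""
    return sg.generate_library(planted_rule, 200, active_fraction=0.118, seed=1)


@pytest.fixture(scope="session")
def marker_signatures(planted_rule):
    markers = planted_marker_signatures(planted_rule)
    assert markers, "fixture grammar must yield pharmacophore-specific signatures"
    return markers


@pytest.fixture(scope="session")
def trained_ensemble(planted_library):
    """One full ensemble (classifiers + QSAR regressor) on the planted library."""
    return sg.train_ensemble(
        planted_library,
        cost_grid=FAST_GRID,
        folds=10,
        ga=GaConfig(seed=1, **FAST_GA),
    )


@pytest.fixture(scope="session")
def recovery_runs(planted_rule, marker_signatures):
    """Twenty seeded train/screen rounds on fresh planted libraries.

    Each run trains classifiers only (no QSAR regressor), screens a held-out
    generated library under relaxed criteria with the IC50 cap disabled, and
    records cross-validation error, marker recovery and screening precision.
    """
    criteria = CriteriaSet(
        min_overlap=0.9, min_svmc_score=0.0, max_pred_ic50_um=math.inf
    )
    runs = []
    for seed in range(1, 21):
        train_lib = sg.generate_library(planted_rule, 200, 0.118, seed=seed)
        ensemble = sg.train_ensemble(
            train_lib,
            cost_grid=FAST_GRID,
            folds=10,
            ga=GaConfig(seed=seed, **FAST_GA),
            regression=False,
        )
        held = sg.generate_library(planted_rule, 120, 0.2, seed=10_000 + seed)
        verdicts, summary = sg.screen_library(held, ensemble, criteria)
        truth = {r.id: r.activity_class is sg.ActivityClass.ACTIVE for r in held}
        tp = sum(1 for v in verdicts if v.passed and truth[v.compound_id])
        fp = sum(1 for v in verdicts if v.passed and not truth[v.compound_id])
        recovered = all(
            set(m.feature_subset) & marker_signatures for m in ensemble.classifiers
        )
        runs.append(
            {
                "seed": seed,
                "cv_error": ensemble.classifiers[0].cv_error,
                "marker_recovered": recovered,
                "tp": tp,
                "fp": fp,
                "passed": summary.passed,
                "n_actives_held": sum(truth.values()),
            }
        )
    return runs


@pytest.fixture()
def benzene():
    return sg.parse_smiles("c1ccccc1", "benzene")


@pytest.fixture()
def ethanol():
    return sg.parse_smiles("CCO", "ethanol")
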