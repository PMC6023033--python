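"""End-to-end orchestration: train an ensemble from a labeled library, and
reproduce the published bioassay bookkeeping from a local record export."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem_io import ActivityClass, Library, read_library
from .filters import clean_training_set, FilterReport
from .signature import DEFAULT_HEIGHTS, build_matrix, signature_tally
from .train import (
    DEFAULT_COST_GRID,
    GaConfig,
    ModelEnsemble,
    ga_svm_search,
    labels_from_library,
    pca_filter,
)


def train_ensemble(
    train_lib: Library,
    heights: Iterable[int] = DEFAULT_HEIGHTS,
    variance_cutoff: float = 0.95,
    importance_rule: str = "mean",
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    nu: float = 0.2,
    folds: int = 10,
    ga: Optional[GaConfig] = None,
    regression: bool = True,
    regression_target: str = "log10",
) -> ModelEnsemble:
    """Full model-building round on a labeled library.

    Classification models are trained on all compounds (active = +1); the
    QSAR regressor on the actives with known IC50 only, using its own
    descriptor matrix and PCA filter.  Returns the tied-classifier ensemble
    with the training set's signature windows attached for overlap screening.
    """
    heights = tuple(sorted(set(heights)))
    matrix = build_matrix(train_lib, heights)
    y = labels_from_library(train_lib)
    pca = pca_filter(matrix, variance_cutoff, importance_rule)
    classifiers = ga_svm_search(
        matrix, y, pca, task="classification",
        cost_grid=cost_grid, nu=nu, folds=folds, ga=ga,
    )

    regressor = None
    if regression:
        actives = [r for r in train_lib if r.activity_class is ActivityClass.ACTIVE
                   and r.ic50_um is not None]
        reg_folds = min(folds, len(actives))
        if reg_folds >= 2:
            reg_lib = Library(records=actives, provenance="actives")
            reg_matrix = build_matrix(reg_lib, heights)
            reg_pca = pca_filter(reg_matrix, variance_cutoff, importance_rule)
            targets = np.array(
                [np.log10(r.ic50_um) if regression_target == "log10" else r.ic50_um
                 for r in actives]
            )
            reg_models = ga_svm_search(
                reg_matrix, targets, reg_pca, task="regression",
                cost_grid=cost_grid, nu=nu, folds=reg_folds, ga=ga,
                target_transform=regression_target,
            )
            regressor = reg_models[0]

    return ModelEnsemble(
        classifiers=classifiers,
        regressor=regressor,
        train_stats=matrix.column_stats,
        heights=heights,
    )


@dataclass
class ReproductionReport:
    """Bookkeeping of a bioassay-record reproduction run."""

    total: int
    actives: int
    inactives: int
    filter_report: FilterReport
    kept: int
    kept_actives: int
    signature_tally_all: dict[int, int]  # per height; -1 = total
    signature_tally_actives: dict[int, int]


def reproduce_aid787(
    path,
    format: Optional[str] = None,
    heights: Iterable[int] = DEFAULT_HEIGHTS,
    patterns=None,
    dedupe_threshold: float = 0.9,
) -> ReproductionReport:
    """Rebuild the training-set bookkeeping from a local bioassay export.

    ``path`` is a CSV (id, smiles, class, ic50_um) or SDF export of the
    public C1s bioassay record (183 compounds, 23 actives with IC50s).
    Applies PAINS + near-duplicate filtering, then tallies unique atomic
    signatures per height over the surviving set and over its actives.
    """
    lib = read_library(path, format)
    report = clean_training_set(lib, patterns=patterns, dedupe_threshold=dedupe_threshold,
                                heights=heights)
    kept = report.kept
    kept_actives = Library(records=kept.actives(), provenance="kept actives")
    tally_all = signature_tally(build_matrix(kept, heights))
    tally_act = signature_tally(build_matrix(kept_actives, heights)) if len(kept_actives) else {}
    return ReproductionReport(
        total=len(lib),
        actives=len(lib.actives()),
        inactives=len(lib.inactives()),
        filter_report=report,
        kept=len(kept),
        kept_actives=len(kept_actives),
        signature_tally_all=tally_all,
        signature_tally_actives=tally_act,
    )
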