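"""Virtual screening: overlap applicability domain, ensemble scoring, criteria.

A candidate passes a screening round when

* its **overlap** with the training set is high enough — the fraction of its
  unique atomic Signatures that occur in the training set with occurrence
  counts inside the training-observed (min, max) window (an extrapolation
  control in the spirit of a set-theoretic Tanimoto coefficient);
* every classifier in the ensemble gives a decision value strictly above the
  score floor (unanimity — no arbitrary representative model is picked); and
* the QSAR regressor predicts an IC50 strictly below the cap.

Round 1 of the study used overlap = 1, score > 2 and IC50 < 50 µM; round 2
relaxed to overlap >= 0.9 and score > 0.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .chem_io import CompoundRecord, Library, ParseError, parse_smiles
from .signature import AtomicSignature, MolecularSignature, molecular_signature
from .train import ModelEnsemble


@dataclass(frozen=True)
class CriteriaSet:
    """Selection thresholds for one screening round.

    Comparisons follow the printed criteria exactly: overlap uses >=, the
    SVM-C score floor and the IC50 cap are strict (> and <).
    """

    min_overlap: float
    min_svmc_score: float
    max_pred_ic50_um: float
    unanimity: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_overlap <= 1.0:
            raise ValueError("min_overlap must be in [0, 1]")
        for v in (self.min_svmc_score, self.max_pred_ic50_um):
            if not math.isfinite(v) and v != math.inf:
                raise ValueError("criteria bounds must be finite (or +inf IC50 cap)")


#: First-round selection: all candidate signatures inside the training
#: windows, every classifier score > 2, predicted IC50 < 50 µM.
ROUND1 = CriteriaSet(min_overlap=1.0, min_svmc_score=2.0, max_pred_ic50_um=50.0)

#: Second-round relaxation: overlap >= 0.9, every classifier score > 0.
ROUND2 = CriteriaSet(min_overlap=0.9, min_svmc_score=0.0, max_pred_ic50_um=50.0)


@dataclass
class ScreeningVerdict:
    compound_id: str
    overlap: float
    svmc_scores: list[float]
    predicted_ic50_um: float
    passed: bool
    failed_criteria: list[str]

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_criteria)


def overlap(
    candidate: MolecularSignature,
    train_stats: dict[AtomicSignature, tuple[int, int]],
) -> float:
    """Fraction of the candidate's unique signatures inside training windows.

    A signature counts toward the numerator when it is in the training
    vocabulary AND its occurrence count in the candidate lies within the
    (min, max) occurrences observed in the training set.
    """
    uniq = candidate.unique()
    if not uniq:
        raise ValueError("candidate has an empty signature set")
    inside = 0
    for sig in uniq:
        window = train_stats.get(sig)
        if window is not None and window[0] <= candidate.counts[sig] <= window[1]:
            inside += 1
    return inside / len(uniq)


def score_candidate(
    candidate: CompoundRecord | MolecularSignature,
    ensemble: ModelEnsemble,
    criteria: CriteriaSet,
) -> ScreeningVerdict:
    """Score one candidate against every ensemble model and the criteria.

    Signatures outside a model's feature subset contribute nothing to its
    decision value; signatures outside the training vocabulary altogether are
    reflected only in the overlap.
    """
    if isinstance(candidate, CompoundRecord):
        molsig = molecular_signature(candidate.structure, ensemble.heights)
    else:
        molsig = candidate
        if any(s.height not in ensemble.heights for s in molsig.counts):
            raise ValueError("candidate featurized at heights the ensemble was not trained on")

    omega = overlap(molsig, ensemble.train_stats)
    scores = [m.decision_values(molsig.counts) for m in ensemble.classifiers]
    pred_ic50 = (
        ensemble.regressor.predict_ic50_um(molsig.counts)
        if ensemble.regressor is not None
        else math.nan
    )

    failed: list[str] = []
    if omega < criteria.min_overlap:
        failed.append("overlap")
    if criteria.unanimity:
        ok = all(s > criteria.min_svmc_score for s in scores)
    else:
        ok = any(s > criteria.min_svmc_score for s in scores)
    if not ok:
        failed.append("svmc_score")
    # an infinite cap disables the IC50 criterion (screening without a QSAR model)
    if math.isfinite(criteria.max_pred_ic50_um) and not (
        pred_ic50 < criteria.max_pred_ic50_um
    ):
        failed.append("predicted_ic50")

    return ScreeningVerdict(
        compound_id=molsig.molecule_id,
        overlap=omega,
        svmc_scores=scores,
        predicted_ic50_um=pred_ic50,
        passed=not failed,
        failed_criteria=failed,
    )


@dataclass
class ScreenSummary:
    screened: int = 0
    passed: int = 0
    unparseable: int = 0


def _iter_smi_chunks(path: Path, chunk_size: int, summary: ScreenSummary) -> Iterator[list[CompoundRecord]]:
    chunk: list[CompoundRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            cid = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                chunk.append(parse_smiles(parts[0], cid))
            except ParseError as exc:
                summary.unparseable += 1
                raise type(exc)(f"{path} line {lineno}: {exc}") from None
            if len(chunk) >= chunk_size:
                yield chunk
                chunk = []
    if chunk:
        yield chunk


def screen_library(
    lib: str | Path | Library,
    ensemble: ModelEnsemble,
    criteria: CriteriaSet,
    chunk_size: int = 1000,
) -> tuple[list[ScreeningVerdict], ScreenSummary]:
    """Screen a library (path to .smi, or an in-memory Library) in chunks.

    Verdicts are pure functions of (candidate, ensemble, criteria), so the
    result is independent of ``chunk_size``; chunking only bounds how many
    parsed molecules are held at once.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    summary = ScreenSummary()
    verdicts: list[ScreeningVerdict] = []

    if isinstance(lib, Library):
        chunks: Iterable[Sequence[CompoundRecord]] = (
            lib.records[i : i + chunk_size] for i in range(0, len(lib), chunk_size)
        )
    else:
        chunks = _iter_smi_chunks(Path(lib), chunk_size, summary)

    for chunk in chunks:
        for rec in chunk:
            v = score_candidate(rec, ensemble, criteria)
            verdicts.append(v)
            summary.screened += 1
            summary.passed += int(v.passed)
    return verdicts, summary


def write_verdicts(verdicts: Sequence[ScreeningVerdict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "overlap", "min_score", "mean_score", "predicted_ic50_um", "passed", "failed_criteria"]
        )
        for v in verdicts:
            writer.writerow(
                [
                    v.compound_id,
                    f"{v.overlap:.6g}",
                    f"{min(v.svmc_scores):.6g}" if v.svmc_scores else "",
                    f"{sum(v.svmc_scores) / len(v.svmc_scores):.6g}" if v.svmc_scores else "",
                    f"{v.predicted_ic50_um:.6g}",
                    int(v.passed),
                    ";".join(v.failed_criteria),
                ]
            )


def hit_rate(tested: Sequence[tuple[bool, bool]]) -> float:
    """Precision over experimentally tested predicted positives: TP/(TP+FP).

    ``tested`` holds (predicted positive, experimentally active) pairs; every
    entry must be a predicted positive (that is what got tested).
    """
    if not tested:
        raise ValueError("no tested compounds")
    if not all(pred for pred, _ in tested):
        raise ValueError("hit_rate is defined over predicted positives only")
    tp = sum(1 for _, active in tested if active)
    return tp / len(tested)
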