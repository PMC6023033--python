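"""Plate-reader data reduction: % inhibition, IC50 interpolation, activity calls.

The fluorogenic protease assay runs on 96-well plates: compound dilution
series occupy columns 1–9 (one compound per column, eight four-fold dilutions
down the rows, 50 µM down to 3.05 nM final), column 10 is a protein check,
column 11 the blank (substrate + buffer) and column 12 the control
(substrate + enzyme, no compound).

Reduction:

* ``%inhibition = 100 x (1 - (signal - blank) / (control - blank))`` with
  blank/control the arithmetic means of their column wells;
* IC50 by interpolation between the closest tested concentrations below and
  above 50% inhibition (linear in concentration by default, matching the
  source protocol; linear in log-concentration available as ``scale="log"``);
  no bracketing pair -> the compound is inactive;
* a compound is called active only when **every** replicate yields an IC50;
  crossing 50% in some but not all replicates is recorded as inactive with a
  weak-activity flag.  The reported IC50 is the mean over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem_io import (
    ActivityClass,
    CompoundRecord,
    Library,
    MoleculeGraph,
)

#: Final-well test concentrations in µM: eight four-fold dilutions, 50 µM -> 3.05 nM.
DEFAULT_CONCENTRATIONS_UM = tuple(50.0 / 4**k for k in range(8))

N_ROWS, N_COLS = 8, 12
PROTEIN_CHECK_COL, BLANK_COL, CONTROL_COL = 9, 10, 11  # 0-based columns 10/11/12


class DegeneratePlateError(ValueError):
    """Blank and control means coincide; % inhibition is undefined."""


@dataclass
class PlateLayout:
    """8x12 grid of raw fluorescence with the fixed column roles."""

    wells: np.ndarray

    def __post_init__(self) -> None:
        self.wells = np.asarray(self.wells, dtype=float)
        if self.wells.shape != (N_ROWS, N_COLS):
            raise ValueError(f"plate must be {N_ROWS}x{N_COLS}, got {self.wells.shape}")

    @property
    def blank_mean(self) -> float:
        return float(self.wells[:, BLANK_COL].mean())

    @property
    def control_mean(self) -> float:
        return float(self.wells[:, CONTROL_COL].mean())

    @property
    def protein_check_ratio(self) -> float:
        """QC only: protein-check column signal relative to the control."""
        denom = self.control_mean - self.blank_mean
        if denom == 0:
            raise DegeneratePlateError("control equals blank")
        return float((self.wells[:, PROTEIN_CHECK_COL].mean() - self.blank_mean) / denom)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls(np.loadtxt(path, delimiter=",", dtype=float))


def percent_inhibition(signal: float, blank_mean: float, control_mean: float) -> float:
    """100 x (1 - (signal - blank) / (control - blank))."""
    denom = control_mean - blank_mean
    if denom == 0:
        raise DegeneratePlateError("control equals blank; plate is degenerate")
    return 100.0 * (1.0 - (signal - blank_mean) / denom)


@dataclass
class DilutionSeries:
    """One replicate's dose–response: descending concentrations + % inhibition."""

    concentrations_um: Sequence[float]
    inhibition_pct: Sequence[float]
    replicate: int = 0

    def __post_init__(self) -> None:
        if len(self.concentrations_um) != len(self.inhibition_pct):
            raise ValueError("concentration and inhibition lengths differ")
        if any(c <= 0 for c in self.concentrations_um):
            raise ValueError("concentrations must be positive")


def plate_to_series(
    plate: PlateLayout,
    compound_columns: dict[str, int],
    concentrations_um: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    replicate: int = 0,
) -> dict[str, DilutionSeries]:
    """Reduce compound columns of a plate to dilution series.

    ``compound_columns`` maps compound id -> 0-based plate column (0–8);
    row i holds the i-th concentration of ``concentrations_um`` (descending).
    """
    blank, control = plate.blank_mean, plate.control_mean
    out = {}
    for cid, col in compound_columns.items():
        if not 0 <= col < PROTEIN_CHECK_COL:
            raise ValueError(f"{cid}: column {col} is not a compound column")
        inhibition = [
            percent_inhibition(plate.wells[row, col], blank, control)
            for row in range(min(N_ROWS, len(concentrations_um)))
        ]
        out[cid] = DilutionSeries(
            concentrations_um=list(concentrations_um[: len(inhibition)]),
            inhibition_pct=inhibition,
            replicate=replicate,
        )
    return out


@dataclass
class InterpolationFlags:
    below_lowest: bool = False  # 50% already exceeded at the lowest tested conc.
    non_monotone: bool = False  # multiple 50% crossings; top-most bracket used


def ic50_interpolate(
    series: DilutionSeries,
    scale: str = "linear",
    flags: Optional[InterpolationFlags] = None,
) -> Optional[float]:
    """IC50 from the bracketing pair around 50% inhibition, or None (inactive).

    The concentration-ordered curve is scanned for adjacent points with
    inhibition on opposite sides of 50%; interpolation is linear in
    concentration (default) or in log10 concentration (``scale="log"``).
    With several crossings the bracket nearest the highest concentration is
    used and flagged.  If no pair brackets 50%, the compound is inactive.
    An exact 50% reading at a tested concentration returns that concentration.
    """
    if len(series.concentrations_um) == 0:
        raise ValueError("empty dilution series")
    order = np.argsort(series.concentrations_um)
    conc = np.asarray(series.concentrations_um, dtype=float)[order]
    inh = np.asarray(series.inhibition_pct, dtype=float)[order]

    if flags is not None and inh[0] >= 50.0:
        flags.below_lowest = True

    exact = np.flatnonzero(inh == 50.0)
    brackets = [
        i for i in range(len(conc) - 1)
        if (inh[i] - 50.0) * (inh[i + 1] - 50.0) < 0
    ]
    if flags is not None and len(brackets) > 1:
        flags.non_monotone = True
    if brackets:
        i = brackets[-1]  # nearest the highest concentration
        lo_c, hi_c = conc[i], conc[i + 1]
        lo_y, hi_y = inh[i], inh[i + 1]
        t = (50.0 - lo_y) / (hi_y - lo_y)
        if scale == "linear":
            return float(lo_c + t * (hi_c - lo_c))
        if scale == "log":
            return float(10 ** (math.log10(lo_c) + t * (math.log10(hi_c) - math.log10(lo_c))))
        raise ValueError(f"unknown interpolation scale {scale!r}")
    if len(exact):
        return float(conc[exact[-1]])
    return None


@dataclass
class ActivityCall:
    """Final experimental call for one compound over its replicates."""

    compound_id: str
    ic50_um: Optional[float]
    active: bool
    replicates: int
    weak_activity: bool = False  # crossed 50% in some but not all replicates

    def __post_init__(self) -> None:
        if self.active != (self.ic50_um is not None):
            raise ValueError("active <=> an IC50 is reported")


def call_activity(
    replicate_series: Sequence[DilutionSeries],
    compound_id: str,
    scale: str = "linear",
) -> ActivityCall:
    """Active only if every replicate yields an IC50; report the mean IC50."""
    if not replicate_series:
        raise ValueError("at least one replicate required")
    ic50s = [ic50_interpolate(s, scale=scale) for s in replicate_series]
    crossed = [v for v in ic50s if v is not None]
    if len(crossed) == len(ic50s):
        return ActivityCall(
            compound_id=compound_id,
            ic50_um=float(np.mean(crossed)),
            active=True,
            replicates=len(ic50s),
        )
    return ActivityCall(
        compound_id=compound_id,
        ic50_um=None,
        active=False,
        replicates=len(ic50s),
        weak_activity=len(crossed) > 0,
    )


def augment_training_set(
    train: Library,
    calls: Sequence[ActivityCall],
    structures: dict[str, MoleculeGraph],
) -> Library:
    """Fold validated screening candidates back into the training set.

    Actives join with their measured IC50, inactives as inactive.  A call id
    already present in the training set is an error (label conflicts must be
    resolved upstream).
    """
    existing = set(train.ids())
    new_records = []
    for call in calls:
        if call.compound_id in existing:
            raise ValueError(f"{call.compound_id} already in the training set")
        if call.compound_id not in structures:
            raise KeyError(f"no structure provided for {call.compound_id}")
        new_records.append(
            CompoundRecord(
                id=call.compound_id,
                structure=structures[call.compound_id],
                activity_class=ActivityClass.ACTIVE if call.active else ActivityClass.INACTIVE,
                ic50_um=call.ic50_um,
            )
        )
    return Library(
        records=list(train.records) + new_records,
        provenance=f"{train.provenance}+{len(new_records)} validated",
    )
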