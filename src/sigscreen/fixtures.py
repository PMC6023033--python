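"""Synthetic libraries and plates with planted ground truth.

Real screening data (a protease bioassay record and 96-well fluorescence
plates) cannot ship with the package, so every pipeline stage is exercised on
generated data with a known structure–activity rule: molecules are built from
aromatic scaffolds with substituents at ortho/meta/para positions, actives
carry a planted pharmacophore substituent (a sulfonamide by default), and
active IC50s are drawn log-normally.  Plates are simulated from a saturating
1:1 binding inhibition curve plus Gaussian noise.

The generator's defaults mirror the study conditions: an active fraction of
0.118 and a 50 µM top test concentration with eight four-fold dilutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import ActivityClass, CompoundRecord, Library, parse_smiles
from .assay import (
    BLANK_COL,
    CONTROL_COL,
    DEFAULT_CONCENTRATIONS_UM,
    N_COLS,
    N_ROWS,
    PROTEIN_CHECK_COL,
    PlateLayout,
)

#: default planted pharmacophore: primary sulfonamide
DEFAULT_PHARMACOPHORE_SMARTS = "S(=O)(=O)N"
DEFAULT_PHARMACOPHORE_FRAGMENT = "S(=O)(=O)N"

# scaffold templates: '{a}'/'{b}' are substituent slots (branch attachment)
_DISUB_TEMPLATES = (
    "c1ccc({a})c({b})c1",   # benzene, ortho
    "c1cc({a})cc({b})c1",   # benzene, meta
    "c1c({a})ccc({b})c1",   # benzene, para
    "c1cc({a})nc({b})c1",   # pyridine
)
_MONOSUB_TEMPLATES = (
    "c1ccc({a})cc1",        # benzene
    "c1cc({a})cnc1",        # pyridine
    "c1cc({a})cs1",         # thiophene
)

#: decoy substituents; none contains (or can combine into) the sulfonamide
_DECOY_SUBSTITUENTS = (
    "C", "CC", "CCC", "O", "OC", "OCC", "N", "NC", "F", "Cl", "Br",
    "C(=O)OC", "C(=O)OCC", "C(=O)N", "C(=O)C", "C#N", "[N+](=O)[O-]",
    "C=C", "CO", "CCl",
)


@dataclass
class PlantedRule:
    """Ground-truth structure–activity rule for generated libraries."""

    pharmacophore_smarts: str = DEFAULT_PHARMACOPHORE_SMARTS
    pharmacophore_fragment: str = DEFAULT_PHARMACOPHORE_FRAGMENT
    p_active_given_match: float = 1.0
    p_active_given_no_match: float = 0.0
    ic50_log10_mu: float = math.log10(5.0)  # median 5 µM, inside the assay window
    ic50_log10_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_active_given_match, self.p_active_given_no_match):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.ic50_log10_sigma <= 0:
            raise ValueError("sigma must be > 0")

    def matcher(self):
        patt = Chem.MolFromSmarts(self.pharmacophore_smarts)
        if patt is None:
            raise ValueError(f"invalid pharmacophore SMARTS {self.pharmacophore_smarts!r}")
        return patt


def _build_smiles(rng: np.random.Generator, with_pharmacophore: bool) -> str:
    if with_pharmacophore:
        tpl = _DISUB_TEMPLATES[rng.integers(len(_DISUB_TEMPLATES))]
        decoy = _DECOY_SUBSTITUENTS[rng.integers(len(_DECOY_SUBSTITUENTS))]
        a, b = (DEFAULT_PHARMACOPHORE_FRAGMENT, decoy)
        if rng.random() < 0.5:
            a, b = b, a
        return tpl.format(a=a, b=b)
    if rng.random() < 0.4:
        tpl = _MONOSUB_TEMPLATES[rng.integers(len(_MONOSUB_TEMPLATES))]
        return tpl.format(a=_DECOY_SUBSTITUENTS[rng.integers(len(_DECOY_SUBSTITUENTS))])
    tpl = _DISUB_TEMPLATES[rng.integers(len(_DISUB_TEMPLATES))]
    a = _DECOY_SUBSTITUENTS[rng.integers(len(_DECOY_SUBSTITUENTS))]
    b = _DECOY_SUBSTITUENTS[rng.integers(len(_DECOY_SUBSTITUENTS))]
    return tpl.format(a=a, b=b)


def generate_library(
    rule: PlantedRule,
    n: int,
    active_fraction: float = 0.118,
    seed: Optional[int] = None,
) -> Library:
    """Generate ``n`` labeled compounds with the planted rule.

    Each compound carries the pharmacophore with probability
    ``active_fraction`` (so the realized active count is a seeded binomial
    draw); labels follow the rule's conditional activity probabilities and
    IC50s are drawn log-normally for actives only.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(rule.seed if seed is None else seed)
    patt = rule.matcher()
    records = []
    width = len(str(n))
    for i in range(n):
        has_pharm = bool(rng.random() < active_fraction)
        smiles = _build_smiles(rng, has_pharm)
        rec = parse_smiles(smiles, f"syn{i:0{width}d}")
        # guard against a decoy accidentally matching the planted pattern
        matches = rec.structure.to_rdkit().HasSubstructMatch(patt)
        if matches != has_pharm:  # pragma: no cover - grammar excludes this
            raise RuntimeError(f"fixture grammar produced an inconsistent molecule: {smiles}")
        p_active = rule.p_active_given_match if has_pharm else rule.p_active_given_no_match
        active = bool(rng.random() < p_active)
        ic50 = None
        if active:
            ic50 = float(10 ** rng.normal(rule.ic50_log10_mu, rule.ic50_log10_sigma))
        records.append(
            CompoundRecord(
                id=rec.id,
                structure=rec.structure,
                activity_class=ActivityClass.ACTIVE if active else ActivityClass.INACTIVE,
                ic50_um=ic50,
            )
        )
    return Library(records=records, provenance=f"planted-rule n={n} seed={seed}")


def planted_marker_signatures(rule: PlantedRule, heights=(0, 1, 2)):
    """Signatures diagnostic of the planted pharmacophore.

    A trained model has "recovered the planted rule" when its feature subset
    intersects this set.  In the default grammar these are exactly the
    signatures whose rendered
    subtree reaches the non-aromatic sulfonamide sulfur ``[S]`` (decoy
    substituents are sulfur-free and thiophene sulfur renders aromatic
    ``[s]``), sampled over pharmacophore-bearing grammar products.
    """
    from .signature import molecular_signature

    rng = np.random.default_rng(12345)
    markers = set()
    for _ in range(200):
        rec = parse_smiles(_build_smiles(rng, True), "m")
        markers |= {
            s
            for s in molecular_signature(rec.structure, heights).unique()
            if "[S]" in s.canon
        }
    return markers


def inhibition_fraction(conc_um: float, ic50_um: Optional[float]) -> float:
    """Saturating 1:1 binding inhibition curve; 0 for a truly inactive compound."""
    if ic50_um is None:
        return 0.0
    return conc_um / (conc_um + ic50_um)


def generate_plate(
    true_ic50s_um: Sequence[Optional[float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    concentrations_um: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    control_level: float = 1000.0,
    blank_level: float = 100.0,
) -> PlateLayout:
    """Simulate one 96-well plate for up to nine compounds.

    Compound j's dilution series runs down column j (row i at the i-th
    concentration, descending).  Fluorescence interpolates between the blank
    (full inhibition) and control (no inhibition) levels according to the
    binding curve, plus Gaussian noise of sd ``noise_sd`` (fluorescence units)
    on every well.  Columns 10/11/12 are protein check, blank and control.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(true_ic50s_um) > PROTEIN_CHECK_COL:
        raise ValueError(f"at most {PROTEIN_CHECK_COL} compounds per plate")
    rng = np.random.default_rng(seed)
    wells = np.empty((N_ROWS, N_COLS))
    span = control_level - blank_level
    for col in range(N_COLS):
        for row in range(N_ROWS):
            if col < len(true_ic50s_um):
                f = inhibition_fraction(concentrations_um[row], true_ic50s_um[col])
                level = control_level - f * span
            elif col < PROTEIN_CHECK_COL:  # unused compound column: no compound
                level = control_level
            elif col == PROTEIN_CHECK_COL:  # enzyme + buffer, no substrate
                level = blank_level
            elif col == BLANK_COL:
                level = blank_level
            else:  # CONTROL_COL
                level = control_level
            wells[row, col] = level + rng.normal(0.0, noise_sd)
    return PlateLayout(wells=wells)


def generate_triplicate_plates(
    true_ic50s_um: Sequence[Optional[float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> list[PlateLayout]:
    """Three independent replicate plates of the same compounds."""
    return [
        generate_plate(true_ic50s_um, noise_sd=noise_sd, seed=seed * 3 + r, **kwargs)
        for r in range(3)
    ]
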