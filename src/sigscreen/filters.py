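"""Library hygiene: PAINS removal and near-duplicate structure removal.

Pan-assay interference compounds (PAINS) are promiscuous or artifact-prone
structures (quinone methides, azo dyes, catechols, ...) that confound
activity models; they are removed by substructure match against the published
PAINS SMARTS families (RDKit's built-in FilterCatalog by default, or a
user-supplied SMARTS list).  Structural near-duplicates of flagged or
reference compounds are removed with a signature-set Tanimoto criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import FilterCatalog

from .chem_io import Library, CompoundRecord
from .signature import DEFAULT_HEIGHTS, molecular_signature


class ConfigurationError(ValueError):
    """Invalid filter configuration (bad SMARTS, empty pattern list)."""


@dataclass
class FilterReport:
    kept: Library
    removed: list[tuple[str, str]]  # (compound id, reason)

    def removed_ids(self) -> set[str]:
        return {cid for cid, _ in self.removed}


def _default_catalog() -> FilterCatalog.FilterCatalog:
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
    return FilterCatalog.FilterCatalog(params)


def load_smarts_patterns(path) -> list[tuple[str, str]]:
    """Read a pattern file: one "SMARTS<whitespace>family" per line."""
    patterns = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        patterns.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
    return patterns


def pains_filter(
    lib: Library, patterns: Optional[Sequence[tuple[str, str]]] = None
) -> FilterReport:
    """Remove compounds matching any PAINS pattern.

    ``patterns`` is a list of (SMARTS, family name); ``None`` selects the
    published PAINS families shipped with RDKit.  An explicitly empty list is
    a configuration error.  Matches record the family as ``pains:<family>``.
    """
    if patterns is not None and len(patterns) == 0:
        raise ConfigurationError("PAINS pattern list is empty")

    if patterns is None:
        catalog = _default_catalog()

        def match(mol: Chem.Mol) -> Optional[str]:
            entry = catalog.GetFirstMatch(mol)
            return entry.GetDescription() if entry is not None else None

    else:
        compiled = []
        for smarts, family in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ConfigurationError(f"invalid SMARTS {smarts!r} ({family})")
            compiled.append((patt, family))

        def match(mol: Chem.Mol) -> Optional[str]:
            for patt, family in compiled:
                if mol.HasSubstructMatch(patt):
                    return family
            return None

    kept, removed = [], []
    for rec in lib:
        family = match(rec.structure.to_rdkit())
        if family is None:
            kept.append(rec)
        else:
            removed.append((rec.id, f"pains:{family}"))
    return FilterReport(
        kept=Library(records=kept, provenance=f"{lib.provenance}|pains_filtered"),
        removed=removed,
    )


def signature_tanimoto(
    a: CompoundRecord, b: CompoundRecord, heights: Iterable[int] = DEFAULT_HEIGHTS
) -> float:
    """Tanimoto coefficient on the two compounds' unique signature sets."""
    sa = molecular_signature(a.structure, heights).unique()
    sb = molecular_signature(b.structure, heights).unique()
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def near_duplicate_filter(
    lib: Library,
    reference: Library,
    threshold: float = 0.9,
    heights: Iterable[int] = DEFAULT_HEIGHTS,
) -> FilterReport:
    """Remove library compounds whose signature-set Tanimoto to any reference
    compound is >= threshold (default 0.9)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    heights = tuple(sorted(set(heights)))
    ref_sets = [
        (r.id, molecular_signature(r.structure, heights).unique()) for r in reference
    ]
    kept, removed = [], []
    for rec in lib:
        mine = molecular_signature(rec.structure, heights).unique()
        hit = None
        for rid, rset in ref_sets:
            union = mine | rset
            if union and len(mine & rset) / len(union) >= threshold:
                hit = rid
                break
        if hit is None:
            kept.append(rec)
        else:
            removed.append((rec.id, f"near_duplicate_of:{hit}"))
    return FilterReport(
        kept=Library(records=kept, provenance=f"{lib.provenance}|dedupe"),
        removed=removed,
    )


def clean_training_set(
    lib: Library,
    patterns: Optional[Sequence[tuple[str, str]]] = None,
    dedupe_threshold: float = 0.9,
    heights: Iterable[int] = DEFAULT_HEIGHTS,
) -> FilterReport:
    """PAINS removal followed by removal of near-duplicates of the PAINS hits.

    Mirrors the pre-modeling hygiene step of the screening pipeline: flagged
    interference compounds leave the set, and so do compounds structurally
    similar to them.
    """
    pains = pains_filter(lib, patterns)
    flagged = Library(
        records=[lib.get(cid) for cid in sorted(pains.removed_ids())],
        provenance="pains_hits",
    )
    if len(flagged) == 0:
        return pains
    dedupe = near_duplicate_filter(pains.kept, flagged, dedupe_threshold, heights)
    return FilterReport(kept=dedupe.kept, removed=pains.removed + dedupe.removed)
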