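"""Signature fragment descriptors.

An *atomic Signature* is a canonical string encoding of the bond-labeled
subtree grown from one root atom out to a fixed graph distance (the height),
expanding breadth-first and never stepping back along the edge just used.
The multiset of atomic Signatures over all atoms and requested heights is the
*molecular Signature*; stacking molecular Signatures over a library gives the
occurrence-count descriptor matrix used by PCA/GA/SVM model building.

String dialect (a canonical injection; only signature-to-signature identity
matters downstream):

* each atom renders as ``[X]`` with aromatic atoms lower-cased and formal
  charge appended (``[n+]``, ``[O-]``);
* each child is prefixed by its bond symbol — '' single, ``=`` double,
  ``#`` triple, ``:`` aromatic;
* at every branching point children are ordered by lexicographic comparison
  of their fully rendered subtree strings;
* an atom whose neighborhood is exhausted before the requested height renders
  as its lower-height form but is still recorded under the requested height
  (keeps the per-height total equal to the heavy-atom count).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_io import Library, MoleculeGraph

DEFAULT_HEIGHTS = (0, 1, 2)

_BOND_SYMBOL = {1: "", 2: "=", 3: "#", "ar": ":"}


@dataclass(frozen=True, order=True)
class AtomicSignature:
    """One root atom's canonical subtree string at one height."""

    height: int
    canon: str

    def __str__(self) -> str:  # "h2:[C]([C][O])" style, used in serialization
        return f"h{self.height}:{self.canon}"

    @classmethod
    def parse(cls, text: str) -> "AtomicSignature":
        h, canon = text.split(":", 1)
        return cls(height=int(h.lstrip("h")), canon=canon)


def _atom_label(atom: tuple[str, bool, int]) -> str:
    symbol, aromatic, charge = atom
    if aromatic:
        symbol = symbol.lower()
    if charge > 0:
        symbol += "+" if charge == 1 else f"+{charge}"
    elif charge < 0:
        symbol += "-" if charge == -1 else f"{charge}"
    return f"[{symbol}]"


def atomic_signature(mol: MoleculeGraph, root: int, height: int) -> AtomicSignature:
    """Canonical Signature of ``root`` at the given height.

    Expansion never traverses back along the edge just used (per-path
    no-backtracking); ring atoms may re-appear on distinct paths.
    """
    if not (0 <= root < mol.n_atoms):
        raise IndexError(f"root index {root} out of range for {mol.n_atoms} atoms")
    if height < 0:
        raise ValueError("height must be >= 0")
    adj = mol.neighbors()

    def render(atom: int, parent: Optional[int], depth: int) -> str:
        label = _atom_label(mol.atoms[atom])
        if depth == height:
            return label
        children = sorted(
            _BOND_SYMBOL[order] + render(nbr, atom, depth + 1)
            for nbr, order in adj[atom]
            if nbr != parent
        )
        return label + "(" + "".join(children) + ")" if children else label

    return AtomicSignature(height=height, canon=render(root, None, 0))


@dataclass
class MolecularSignature:
    """Occurrence counts of atomic Signatures over all roots and heights."""

    counts: Counter  # AtomicSignature -> positive int
    molecule_id: str = ""

    def unique(self) -> set[AtomicSignature]:
        return set(self.counts)

    def total(self, height: Optional[int] = None) -> int:
        return sum(
            c for s, c in self.counts.items() if height is None or s.height == height
        )


def molecular_signature(
    mol: MoleculeGraph, heights: Iterable[int] = DEFAULT_HEIGHTS
) -> MolecularSignature:
    heights = sorted(set(heights))
    if not heights:
        raise ValueError("heights must be non-empty")
    counts: Counter = Counter()
    for h in heights:
        for root in range(mol.n_atoms):
            counts[atomic_signature(mol, root, h)] += 1
    return MolecularSignature(counts=counts, molecule_id=mol.id)


@dataclass
class DescriptorMatrix:
    """Compounds × unique atomic Signatures, with per-column (min, max) windows.

    ``column_stats[j]`` is the (min, max) occurrence of signature j over the
    compounds that actually contain it (min >= 1 by construction); the windows
    are the applicability-domain fingerprint used by the overlap metric.
    """

    ids: list[str]
    signatures: list[AtomicSignature]
    X: np.ndarray  # (n_compounds, n_signatures) non-negative ints
    heights: tuple[int, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        occupied = (self.X > 0).any(axis=0)
        if not occupied.all():
            raise ValueError("descriptor matrix contains an all-zero column")

    @property
    def column_stats(self) -> dict[AtomicSignature, tuple[int, int]]:
        stats = {}
        for j, sig in enumerate(self.signatures):
            col = self.X[:, j]
            present = col[col > 0]
            stats[sig] = (int(present.min()), int(present.max()))
        return stats

    def row(self, cid: str) -> np.ndarray:
        return self.X[self.ids.index(cid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.ids,
                            columns=[str(s) for s in self.signatures])

    def to_csv(self, path, sidecar=None) -> None:
        """CSV of counts plus optional JSON sidecar of signatures and windows."""
        self.to_frame().to_csv(path, index_label="id")
        if sidecar is not None:
            import json

            payload = {
                str(s): {"height": s.height, "min": lo, "max": hi}
                for s, (lo, hi) in self.column_stats.items()
            }
            with open(sidecar, "w") as fh:
                json.dump(payload, fh, indent=1)


def build_matrix(
    lib: Library,
    heights: Iterable[int] = DEFAULT_HEIGHTS,
    dedupe_degenerate_heights: bool = False,
) -> DescriptorMatrix:
    """Assemble the descriptor matrix for a library.

    Columns are the union of unique signatures over the library in
    deterministic (height, canon) order.  With ``dedupe_degenerate_heights``
    a signature whose rendered string equals its lower-height form is merged
    into the lowest height at which that string appears (alternate column
    accounting for small molecules exhausted before the requested height).
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    heights = tuple(sorted(set(heights)))
    molsigs = [molecular_signature(r.structure, heights) for r in lib]
    if dedupe_degenerate_heights:
        remapped = []
        for ms in molsigs:
            merged: Counter = Counter()
            by_canon: dict[str, int] = {}
            for sig in sorted(ms.counts):
                by_canon.setdefault(sig.canon, sig.height)
            for sig, c in ms.counts.items():
                merged[AtomicSignature(by_canon[sig.canon], sig.canon)] += c
            remapped.append(MolecularSignature(merged, ms.molecule_id))
        molsigs = remapped
    vocab = sorted({s for ms in molsigs for s in ms.counts})
    index = {s: j for j, s in enumerate(vocab)}
    X = np.zeros((len(lib), len(vocab)), dtype=np.int64)
    for i, ms in enumerate(molsigs):
        for s, c in ms.counts.items():
            X[i, index[s]] = c
    return DescriptorMatrix(ids=lib.ids(), signatures=vocab, X=X, heights=heights)


def vectorize(
    molsig: MolecularSignature, signatures: Sequence[AtomicSignature]
) -> np.ndarray:
    """Counts of ``molsig`` over a fixed signature vocabulary (0 if absent)."""
    return np.array([molsig.counts.get(s, 0) for s in signatures], dtype=np.int64)


def signature_tally(matrix: DescriptorMatrix) -> dict[int, int]:
    """Unique-signature counts per height (plus total under key -1)."""
    tally: dict[int, int] = {}
    for s in matrix.signatures:
        tally[s.height] = tally.get(s.height, 0) + 1
    tally[-1] = len(matrix.signatures)
    return tally
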