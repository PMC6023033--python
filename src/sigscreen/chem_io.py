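"""Molecule and activity-record I/O.

Molecules are held as light heavy-atom colored graphs (:class:`MoleculeGraph`)
built from RDKit-parsed structures: aromaticity perceived, salts/solvents
stripped to the largest covalent fragment, hydrogens implicit, stereochemistry
ignored.  Activity data ride along in :class:`CompoundRecord` (class label and
optional IC50 in µM) and libraries of records in :class:`Library`.

Supported formats: ``.smi`` ("SMILES<whitespace>id" per line), SDF V2000, and
CSV with columns ``id, smiles[, class][, ic50_um]``.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

log = logging.getLogger("sigscreen")

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise is re-reported via our own warnings


class ParseError(ValueError):
    """A structure could not be parsed into a molecule graph."""


class EmptyStructureError(ParseError):
    """Nothing left after salt/solvent stripping."""


class ActivityClass(enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom colored graph: the substrate of Signature fragmentation.

    ``atoms`` is a list of (element symbol, aromatic flag, formal charge);
    ``bonds`` a list of (i, j, order) with order in {1, 2, 3, "ar"}.  Atom
    indices are 0-based and stable within a parsed record.
    """

    atoms: tuple[tuple[str, bool, int], ...]
    bonds: tuple[tuple[int, int, object], ...]
    id: str = ""
    smiles: str = ""  # canonical SMILES of the parsed (largest) fragment

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> dict[int, list[tuple[int, object]]]:
        """Adjacency: atom index -> list of (neighbor index, bond order)."""
        adj: dict[int, list[tuple[int, object]]] = {i: [] for i in range(self.n_atoms)}
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles was produced by rdkit
            raise ParseError(f"stored SMILES no longer parses: {self.smiles!r}")
        return mol


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


def _graph_from_rdkit(mol: Chem.Mol, mol_id: str) -> MoleculeGraph:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise EmptyStructureError(f"{mol_id}: empty after fragment stripping")
    # largest covalent fragment; ties broken by canonical SMILES for determinism
    frag = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    frag = Chem.RemoveHs(frag)
    if frag.GetNumHeavyAtoms() == 0:
        raise EmptyStructureError(f"{mol_id}: no heavy atoms after stripping")
    atoms = tuple(
        (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge()) for a in frag.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER[b.GetBondType()])
        for b in frag.GetBonds()
    )
    return MoleculeGraph(atoms=atoms, bonds=bonds, id=mol_id, smiles=Chem.MolToSmiles(frag))


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    structure: MoleculeGraph
    activity_class: ActivityClass = ActivityClass.UNKNOWN
    ic50_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ic50_um is not None:
            if self.ic50_um <= 0:
                raise ValueError(f"{self.id}: IC50 must be positive, got {self.ic50_um}")
            if self.activity_class is not ActivityClass.ACTIVE:
                raise ValueError(
                    f"{self.id}: an IC50 implies the active class "
                    f"(got {self.activity_class.value})"
                )


@dataclass
class Library:
    """Ordered collection of compound records with unique ids."""

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""
    skipped: list[str] = field(default_factory=list)  # unparseable inputs, logged not dropped

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids in library: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, key: int) -> CompoundRecord:
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, cid: str) -> CompoundRecord:
        for r in self.records:
            if r.id == cid:
                return r
        raise KeyError(cid)

    def actives(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.activity_class is ActivityClass.ACTIVE]

    def inactives(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.activity_class is ActivityClass.INACTIVE]


def parse_smiles(smiles: str, id: str = "") -> CompoundRecord:
    """Parse one SMILES into a compound record.

    Aromaticity is perceived, counter-ions/solvents are stripped to the largest
    covalent fragment and hydrogens are left implicit.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"malformed SMILES: {smiles!r} (id={id!r})")
    return CompoundRecord(id=id or smiles, structure=_graph_from_rdkit(mol, id or smiles))


_CLASS_MAP = {
    "1": ActivityClass.ACTIVE,
    "0": ActivityClass.INACTIVE,
    "active": ActivityClass.ACTIVE,
    "inactive": ActivityClass.INACTIVE,
    "": ActivityClass.UNKNOWN,
    "unknown": ActivityClass.UNKNOWN,
}


def _with_activity(
    rec: CompoundRecord, klass: ActivityClass, ic50_um: Optional[float]
) -> CompoundRecord:
    if ic50_um is not None:
        klass = ActivityClass.ACTIVE
    return CompoundRecord(rec.id, rec.structure, klass, ic50_um)


def read_library(path: str | Path, format: Optional[str] = None) -> Library:
    """Read a compound library from .smi, .sdf or .csv.

    Unparseable records are counted in ``Library.skipped`` and logged, never
    silently dropped.  Raises if the format is unknown or nothing parses.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"smi", "sdf", "csv"}:
        raise ValueError(f"unknown library format: {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[CompoundRecord] = []
    skipped: list[str] = []

    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                records.append(parse_smiles(smi, cid))
            except ParseError as exc:
                skipped.append(f"line {lineno}: {exc}")
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped.append(f"record {i}: unparseable SDF record")
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            try:
                records.append(CompoundRecord(id=cid, structure=_graph_from_rdkit(mol, cid)))
            except ParseError as exc:
                skipped.append(f"record {i}: {exc}")
    else:  # csv
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            cols = {c.lower(): c for c in reader.fieldnames or []}
            if "id" not in cols or "smiles" not in cols:
                raise ValueError(f"{path}: csv needs 'id' and 'smiles' columns")
            for rowno, row in enumerate(reader, 2):
                cid = row[cols["id"]].strip()
                try:
                    rec = parse_smiles(row[cols["smiles"]].strip(), cid)
                    klass = ActivityClass.UNKNOWN
                    if "class" in cols:
                        raw = (row[cols["class"]] or "").strip().lower()
                        if raw not in _CLASS_MAP:
                            raise ParseError(f"unrecognized class value {raw!r}")
                        klass = _CLASS_MAP[raw]
                    ic50 = None
                    if "ic50_um" in cols and (row[cols["ic50_um"]] or "").strip():
                        ic50 = float(row[cols["ic50_um"]])
                    records.append(_with_activity(rec, klass, ic50))
                except (ParseError, ValueError) as exc:
                    skipped.append(f"row {rowno}: {exc}")

    for msg in skipped:
        log.warning("read_library(%s): skipped %s", path.name, msg)
    if not records:
        raise ValueError(f"{path}: zero parseable records")
    return Library(records=records, provenance=str(path), skipped=skipped)


def write_library(lib: Library, path: str | Path, format: Optional[str] = None) -> None:
    """Write a library (.smi or .csv with class/IC50 columns)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "smi":
        lines = [f"{r.structure.smiles}\t{r.id}" for r in lib]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "class", "ic50_um"])
            for r in lib:
                klass = {"active": "1", "inactive": "0", "unknown": ""}[r.activity_class.value]
                writer.writerow([r.id, r.structure.smiles, klass,
                                 "" if r.ic50_um is None else r.ic50_um])
    else:
        raise ValueError(f"unknown output format: {fmt!r}")


def library_from_records(
    records: Iterable[CompoundRecord], provenance: str = ""
) -> Library:
    return Library(records=list(records), provenance=provenance)
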