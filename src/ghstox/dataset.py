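"""Chemicals table handling and GHS acute-oral-toxicity discretization.

A chemicals table pairs substance identifiers with rat oral LD50 values
(mg/kg) and, optionally, SMILES structure strings.  LD50 is discretized
into the three GHS-derived toxicity classes used throughout the pipeline:

* class I   (highly toxic):          LD50 <= 300 mg/kg
* class II  (intermediate):    300 < LD50 <= 2000 mg/kg
* class III (low to non-toxic):      LD50 >  2000 mg/kg

Class labels are carried internally as the integers 1, 2, 3 and rendered
as roman numerals in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GHS_CLASS_I_MAX = 300.0  # mg/kg
GHS_CLASS_II_MAX = 2000.0  # mg/kg

ROMAN = {1: "I", 2: "II", 3: "III"}
ROMAN_TO_INT = {v: k for k, v in ROMAN.items()}

#: SMARTS patterns for the optional structure-curation rule (diazo and
#: guanidine moieties, whose resonance forms make 2D descriptors ambiguous).
#: Applied only on request and only when structures are present.
CURATION_SMARTS: tuple[tuple[str, str], ...] = (
    ("diazo", "[N-]=[N+]=[C,N]"),
    ("diazo", "N=[N+]=[N-]"),
    ("guanidine", "NC(=N)N"),
)


class DatasetError(ValueError):
    """Raised for malformed chemicals or descriptor tables."""


def assign_ghs_class(ld50: float) -> int:
    """Map a rat oral LD50 (mg/kg) to its GHS toxicity class.

    Boundaries are inclusive on the lower (more toxic) class:
    300 -> I, 2000 -> II, 2000.1 -> III.

    Raises
    ------
    DatasetError
        If ``ld50`` is missing, non-positive or not finite.
    """
    if ld50 is None or (isinstance(ld50, float) and math.isnan(ld50)):
        raise DatasetError("LD50 is missing; cannot assign a GHS class")
    value = float(ld50)
    if not math.isfinite(value) or value <= 0:
        raise DatasetError(f"LD50 must be a positive finite dose in mg/kg, got {ld50!r}")
    if value <= GHS_CLASS_I_MAX:
        return 1
    if value <= GHS_CLASS_II_MAX:
        return 2
    return 3


@dataclass
class ChemicalRecord:
    """One substance: identifier, optional SMILES, LD50 and derived class."""

    id: str
    ld50: float
    smiles: Optional[str] = None
    ghs_class: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ld50 is not None:
            self.ld50 = float(self.ld50)
            if self.ghs_class is None:
                self.ghs_class = assign_ghs_class(self.ld50)
            elif self.ghs_class != assign_ghs_class(self.ld50):
                raise DatasetError(
                    f"record {self.id!r}: stored class {self.ghs_class} inconsistent "
                    f"with LD50 {self.ld50} mg/kg"
                )

    @property
    def ghs_roman(self) -> str:
        return ROMAN[self.ghs_class]


@dataclass
class DescriptorMatrix:
    """Numeric descriptor matrix (chemicals x descriptors) with provenance.

    ``values`` is an ``(n, p)`` float array; missing cells hold NaN and are
    additionally tracked in ``missing_mask``.  Every filter applied to the
    matrix appends ``(filter_name, removed_columns)`` to ``filter_log``.
    """

    row_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    filter_log: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.row_ids) != n:
            raise DatasetError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.column_names) != p:
            raise DatasetError(f"{len(self.column_names)} column names for {p} columns")
        if len(set(self.row_ids)) != n:
            raise DatasetError("duplicate row ids in descriptor matrix")
        if len(set(self.column_names)) != p:
            raise DatasetError("duplicate column names in descriptor matrix")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise DatasetError("missing_mask shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {c: j for j, c in enumerate(self.column_names)}
        return np.array([pos[c] for c in names], dtype=int)

    def select_columns(self, keep: Sequence[str]) -> "DescriptorMatrix":
        idx = self.column_index(keep)
        return DescriptorMatrix(
            row_ids=list(self.row_ids),
            column_names=list(keep),
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            filter_log=list(self.filter_log),
        )

    def select_rows(self, keep_ids: Sequence[str]) -> "DescriptorMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = np.array([pos[r] for r in keep_ids], dtype=int)
        return DescriptorMatrix(
            row_ids=list(keep_ids),
            column_names=list(self.column_names),
            values=self.values[idx, :].copy(),
            missing_mask=self.missing_mask[idx, :].copy(),
            filter_log=list(self.filter_log),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)
        return df.mask(self.missing_mask)


def _parse_ld50(raw: object, row_label: str) -> float:
    """Strict numeric parse; thousands separators and units are rejected."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise DatasetError(f"row {row_label}: LD50 is missing")
    text = str(raw).strip()
    try:
        value = float(text)
    except ValueError:
        raise DatasetError(
            f"row {row_label}: LD50 value {text!r} is not a plain decimal number"
        ) from None
    if not math.isfinite(value) or value <= 0:
        raise DatasetError(f"row {row_label}: LD50 must be positive, got {text!r}")
    return value


def read_chemicals_table(path: str | Path) -> list[ChemicalRecord]:
    """Read a chemicals CSV (columns ``id``, optional ``smiles``, ``ld50_mg_kg``).

    Comma-separated, UTF-8, header mandatory; empty cell or ``NA`` = missing.
    Records are returned in file order; duplicate ids and unparseable LD50
    values are rejected with an error naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "ld50_mg_kg"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise DatasetError(f"{path}: missing required column(s) {sorted(missing_cols)}")
    records: list[ChemicalRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        cid = str(row["id"]).strip()
        if not cid or cid == "NA":
            raise DatasetError(f"{path}: row {i + 2}: empty id")
        if cid in seen:
            raise DatasetError(f"{path}: duplicate id {cid!r} at row {i + 2}")
        seen.add(cid)
        ld50 = _parse_ld50(row["ld50_mg_kg"], f"{i + 2} (id {cid!r})")
        smiles = None
        if "smiles" in df.columns:
            s = str(row["smiles"]).strip()
            smiles = s if s and s != "NA" else None
        records.append(ChemicalRecord(id=cid, ld50=ld50, smiles=smiles))
    return records


def write_chemicals_table(records: Sequence[ChemicalRecord], path: str | Path) -> None:
    """Write records in the same CSV dialect ``read_chemicals_table`` accepts."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles if r.smiles is not None else "" for r in records],
            "ld50_mg_kg": [repr(r.ld50) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_descriptor_matrix(path: str | Path) -> DescriptorMatrix:
    """Read a descriptor CSV: first column ``id``, remaining columns numeric.

    Empty cells and ``NA`` become missing values (NaN + mask).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "id":
        raise DatasetError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    row_ids = [str(v).strip() for v in df["id"]]
    body = df.drop(columns=["id"]).replace({"": np.nan, "NA": np.nan})
    values = body.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return DescriptorMatrix(row_ids=row_ids, column_names=list(body.columns), values=values)


def write_descriptor_matrix(matrix: DescriptorMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "id", matrix.row_ids)
    df.to_csv(path, index=False, na_rep="NA")


def align_tables(
    records: Sequence[ChemicalRecord], matrix: DescriptorMatrix
) -> tuple[list[ChemicalRecord], DescriptorMatrix]:
    """Check the 1:1 id correspondence between the two input tables."""
    rec_ids = [r.id for r in records]
    if rec_ids != matrix.row_ids:
        if set(rec_ids) != set(matrix.row_ids):
            raise DatasetError("chemicals and descriptor tables carry different id sets")
        matrix = matrix.select_rows(rec_ids)
    return list(records), matrix


def _fragment_count(smiles: str) -> int:
    return smiles.count(".") + 1


def _canonical_smiles(smiles: str) -> str:
    """Canonicalize through RDKit when available; fall back to the raw string."""
    try:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            return Chem.MolToSmiles(mol)
    except ImportError:
        pass
    return smiles


def _matches_curation_pattern(smiles: str) -> Optional[str]:
    try:
        from rdkit import Chem
        from rdkit import RDLogger
    except ImportError:
        return None
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    for name, smarts in CURATION_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.HasSubstructMatch(patt):
            return name
    return None


def curate_structures(
    records: Sequence[ChemicalRecord],
    remove_patterns: bool = False,
) -> tuple[list[ChemicalRecord], list[dict]]:
    """Remove salts/mixtures and flag duplicate structures.

    Records without a SMILES string pass through untouched.  A record whose
    SMILES contains a disconnection (more than one fragment) is removed as a
    salt or mixture.  Exact duplicates (by canonical SMILES) keep the first
    occurrence; later ones are removed and reported.  With
    ``remove_patterns=True`` (off by default), structures matching the
    documented diazo/guanidine SMARTS list are also removed.

    Returns ``(kept_records, removal_report)`` where each report entry is a
    dict with ``id`` and ``reason``.
    """
    kept: list[ChemicalRecord] = []
    report: list[dict] = []
    seen_canonical: dict[str, str] = {}
    for rec in records:
        if rec.smiles is None:
            kept.append(rec)
            continue
        if _fragment_count(rec.smiles) > 1:
            report.append({"id": rec.id, "reason": "salt_or_mixture"})
            continue
        canonical = _canonical_smiles(rec.smiles)
        if canonical in seen_canonical:
            report.append(
                {
                    "id": rec.id,
                    "reason": "duplicate_structure",
                    "duplicate_of": seen_canonical[canonical],
                }
            )
            continue
        if remove_patterns:
            hit = _matches_curation_pattern(rec.smiles)
            if hit is not None:
                report.append({"id": rec.id, "reason": f"pattern:{hit}"})
                continue
        seen_canonical[canonical] = rec.id
        kept.append(rec)
    return kept, report
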