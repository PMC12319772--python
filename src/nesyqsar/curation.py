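"""Bioactivity-table curation: units, pIC50, labels, dedup, split, scaling.

Raw exports from compound databases (ChEMBL, BindingDB, PubChem, GTP style)
arrive as CSV tables of (id, SMILES, IC50, unit, source).  Curation
harmonises every IC50 to nanomolar (nM = μM × 1000), converts to
pIC50 = −log10(IC50 · 10⁻⁹), assigns active/inactive labels at a potency
threshold (default pIC50 ≥ 6, i.e. IC50 ≤ 1 μM), canonicalises SMILES with
RDKit and deduplicates on the canonical form, then stratified-splits
train/val/test and standard-scales features on training statistics only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # raw tables legitimately contain junk SMILES

__all__ = [
    "BioactivityRecord",
    "CurationLog",
    "harmonize_units",
    "compute_pic50",
    "assign_label",
    "canonicalize_smiles",
    "merge_and_dedupe",
    "stratified_split",
    "standard_scale",
    "read_raw_csv",
    "curate",
    "DEFAULT_SOURCE_ORDER",
    "ACTIVE",
    "INACTIVE",
]

ACTIVE = "active"
INACTIVE = "inactive"

#: duplicate resolution merges sources in this priority order, first-seen wins
DEFAULT_SOURCE_ORDER: tuple[str, ...] = ("ChEMBL", "BindingDB", "PubChem", "GTP")

_UNIT_ALIASES = {
    "nm": "nM",
    "um": "uM",
    "μm": "uM",
    "µm": "uM",
}


@dataclass(frozen=True)
class BioactivityRecord:
    """One compound measurement from a source database.

    ``qualifier`` carries a censoring mark (">" / "<") when the export
    reported a bound rather than a point value; such records are dropped
    during curation with a logged count.
    """

    compound_id: str | None
    smiles: str | None
    ic50_value: float | None
    ic50_unit: str | None
    source: str = ""
    qualifier: str | None = None


@dataclass
class CurationLog:
    """Per-filter drop counts for one curation run."""

    n_input: int = 0
    n_missing: int = 0
    n_censored: int = 0
    n_bad_unit: int = 0
    n_invalid_smiles: int = 0
    n_duplicates: int = 0
    n_excluded_band: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _normalize_unit(unit: str) -> str:
    key = str(unit).strip().lower()
    if key not in _UNIT_ALIASES:
        raise ValueError(f"unknown IC50 unit {unit!r}: expected nM or μM")
    return _UNIT_ALIASES[key]


def harmonize_units(value: float, unit: str) -> float:
    """Convert an IC50 measurement to nM (nM pass through; μM × 1000)."""
    value = float(value)
    if not (value > 0.0) or not math.isfinite(value):
        raise ValueError(f"IC50 must be a positive finite number, got {value!r}")
    return value if _normalize_unit(unit) == "nM" else value * 1000.0


def compute_pic50(ic50_nM: float) -> float:
    """pIC50 = −log10(IC50 · 10⁻⁹) for IC50 in nM."""
    ic50_nM = float(ic50_nM)
    if not (ic50_nM > 0.0) or not math.isfinite(ic50_nM):
        raise ValueError(f"IC50 (nM) must be positive and finite, got {ic50_nM!r}")
    return -math.log10(ic50_nM * 1e-9)


def assign_label(pic50: float, threshold: float = 6.0) -> str:
    """Active iff pIC50 ≥ threshold (the boundary counts as active)."""
    return ACTIVE if float(pic50) >= float(threshold) else INACTIVE


def canonicalize_smiles(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None when the string does not parse."""
    if smiles is None:
        return None
    mol = Chem.MolFromSmiles(str(smiles))
    return None if mol is None else Chem.MolToSmiles(mol)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def merge_and_dedupe(
    records: Iterable[BioactivityRecord],
    threshold: float = 6.0,
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
    exclusion_band: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, CurationLog]:
    """Merge multi-source records into one labeled, deduplicated table.

    Records with missing ID/SMILES/IC50 are discarded, censored measurements
    dropped, SMILES canonicalised internally, and duplicates collapsed on the
    canonical SMILES keeping the first-seen record after stable source-priority
    ordering.  ``exclusion_band`` optionally removes a pIC50 gray zone
    (off by default — the labeling is binary).
    """
    records = list(records)
    log = CurationLog(n_input=len(records))
    rank = {s: i for i, s in enumerate(source_order)}
    ordered = sorted(records, key=lambda r: rank.get(r.source, len(source_order)))

    rows = []
    seen: set[str] = set()
    for rec in ordered:
        if _is_missing(rec.compound_id) or _is_missing(rec.smiles) or rec.ic50_value is None:
            log.n_missing += 1
            continue
        if rec.qualifier in (">", "<"):
            log.n_censored += 1
            continue
        try:
            ic50_nm = harmonize_units(rec.ic50_value, rec.ic50_unit)
        except ValueError:
            log.n_bad_unit += 1
            continue
        canonical = canonicalize_smiles(rec.smiles)
        if canonical is None:
            log.n_invalid_smiles += 1
            continue
        if canonical in seen:
            log.n_duplicates += 1
            continue
        seen.add(canonical)
        pic50 = compute_pic50(ic50_nm)
        if exclusion_band is not None and exclusion_band[0] <= pic50 < exclusion_band[1]:
            log.n_excluded_band += 1
            continue
        rows.append(
            {
                "compound_id": rec.compound_id,
                "canonical_smiles": canonical,
                "ic50_nM": ic50_nm,
                "pic50": pic50,
                "label": assign_label(pic50, threshold),
                "source": rec.source,
            }
        )
    if not rows:
        raise ValueError(f"no valid records survived curation; log: {log.to_dict()}")
    log.n_output = len(rows)
    return pd.DataFrame(rows), log


def stratified_split(
    dataset: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 42,
) -> pd.DataFrame:
    """Assign train/val/test splits stratified on the label column.

    Split sizes follow the ratios within rounding; per-split label
    proportions track the global proportion; deterministic under the seed.
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    labels = dataset["label"]
    if labels.nunique() < 2 or labels.value_counts().min() < 2:
        raise ValueError("stratified split needs both labels with >= 2 members each")
    train_frac, val_frac, test_frac = ratios
    idx = dataset.index.to_numpy()
    # integer sizes avoid float-ratio rounding drift in the second split
    n_test = int(round(test_frac * len(idx)))
    n_val = int(round(val_frac * len(idx)))
    idx_rest, idx_test = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=labels.loc[idx]
    )
    idx_train, idx_val = train_test_split(
        idx_rest, test_size=n_val, random_state=seed, stratify=labels.loc[idx_rest]
    )
    out = dataset.copy()
    out["split"] = ""
    out.loc[idx_train, "split"] = "train"
    out.loc[idx_val, "split"] = "val"
    out.loc[idx_test, "split"] = "test"
    return out


def standard_scale(
    features: np.ndarray, split: Sequence[str]
) -> tuple[np.ndarray, StandardScaler]:
    """Z-score all rows using mean/variance of the training split only.

    Zero-variance columns pass through centered (scale 1).  Returns the
    scaled matrix (row order unchanged) and the fitted scaler.
    """
    features = np.asarray(features, dtype=np.float64)
    split = np.asarray(split)
    train_mask = split == "train"
    if not train_mask.any():
        raise ValueError("empty training split: nothing to fit the scaler on")
    scaler = StandardScaler().fit(features[train_mask])
    return scaler.transform(features), scaler


_DEFAULT_COLUMNS = {"id": "id", "smiles": "smiles", "ic50": "ic50", "unit": "unit", "source": "source"}


def read_raw_csv(path, column_map: dict[str, str] | None = None) -> list[BioactivityRecord]:
    """Read a raw bioactivity CSV into records.

    ``column_map`` maps the logical names (id, smiles, ic50, unit, source) to
    the file's column names.  IC50 cells may carry ">"/"<" censoring
    qualifiers, which are preserved on the record for curation to drop.
    """
    cols = dict(_DEFAULT_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"raw CSV missing columns {missing_cols}; found {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        raw_value = str(row[cols["ic50"]]).strip()
        qualifier = None
        if raw_value[:1] in (">", "<"):
            qualifier, raw_value = raw_value[0], raw_value[1:].strip()
        try:
            value = float(raw_value) if raw_value else None
        except ValueError:
            value = None
        records.append(
            BioactivityRecord(
                compound_id=row[cols["id"]] or None,
                smiles=row[cols["smiles"]] or None,
                ic50_value=value,
                ic50_unit=row[cols["unit"]] or None,
                source=row[cols["source"]],
                qualifier=qualifier,
            )
        )
    return records


def curate(
    records: Iterable[BioactivityRecord],
    threshold: float = 6.0,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 42,
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
    exclusion_band: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, CurationLog]:
    """Full curation: merge + dedupe + label, then stratified split."""
    table, log = merge_and_dedupe(
        records, threshold=threshold, source_order=source_order, exclusion_band=exclusion_band
    )
    return stratified_split(table, ratios=ratios, seed=seed), log
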