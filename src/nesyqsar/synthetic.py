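"""Synthetic fixtures: raw bioactivity tables with realistic pathologies, and
separable Gaussian feature sets with a known Bayes error.

``simulate_bioactivity_table`` emulates a multi-source IC50 export: valid
drug-like SMILES (drawn without replacement from the bundled pool), log-normal
IC50 values around class-dependent centres (actives ~50 nM, inactives ~20 μM,
giving a few percent of label noise at the pIC50 = 6 cutoff), a fraction of
rows reported in μM, exact duplicates re-spelled as alternative SMILES of the
same molecule, and rows with missing mandatory fields.  Alongside the table it
emits a ground-truth ledger stating exactly what curation must reproduce.

``simulate_separable_features`` draws two spherical Gaussian classes at a
configurable mean separation (in within-class σ units); the Bayes error is
the closed-form normal tail Φ(−separation/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import norm

from .curation import DEFAULT_SOURCE_ORDER, assign_label
from .smiles_pool import get_pool

__all__ = [
    "SimulationSpec",
    "GroundTruthLedger",
    "simulate_bioactivity_table",
    "simulate_separable_features",
]

_SOURCES = DEFAULT_SOURCE_ORDER
# log10(IC50/nM) class centres: actives 50 nM, inactives 20 μM, sd 0.7 —
# ~3% of each class crosses the pIC50=6 threshold, so labels are noisy but
# strongly class-correlated
_LOG10_NM_ACTIVE = (1.7, 0.7)
_LOG10_NM_INACTIVE = (4.3, 0.7)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated raw table."""

    n_records: int = 500
    active_fraction: float = 0.5
    unit_mix: float = 0.3        # fraction of rows reported in μM
    duplicate_rate: float = 0.1
    missing_rate: float = 0.05
    threshold: float = 6.0       # pIC50 activity cutoff used for the ledger labels
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")
        if not (0.0 < self.active_fraction < 1.0):
            raise ValueError("active_fraction must lie in (0, 1)")
        for name in ("unit_mix", "duplicate_rate", "missing_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.duplicate_rate + self.missing_rate >= 1.0:
            raise ValueError("duplicate_rate + missing_rate must be < 1")


@dataclass
class GroundTruthLedger:
    """What curation of the simulated table must produce, exactly."""

    n_records: int
    n_clean: int
    n_duplicates: int
    n_missing: int
    expected_survivors: int
    expected_label_counts: dict[str, int]
    survivor_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _respell(canonical: str, seed: int) -> str:
    """An alternative, equivalent SMILES spelling of the same molecule."""
    mol = Chem.MolFromSmiles(canonical)
    variants = Chem.MolToRandomSmilesVect(mol, 5, randomSeed=int(seed))
    for v in variants:
        if v != canonical:
            return v
    return canonical


def simulate_bioactivity_table(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Raw multi-source table plus the ledger curation must reproduce.

    The emitted table has columns (id, smiles, ic50, unit, source) matching
    the curation reader's defaults.  The ledger is computed by independent
    bookkeeping over the emitted rows (stable source-priority ordering,
    first-seen canonical-SMILES dedup), not by calling the curation code.
    """
    rng = np.random.default_rng(spec.seed)
    pool = get_pool()
    n_dup = int(round(spec.duplicate_rate * spec.n_records))
    n_missing = int(round(spec.missing_rate * spec.n_records))
    n_clean = spec.n_records - n_dup - n_missing
    if n_clean > len(pool):
        raise ValueError(
            f"n_records too large: needs {n_clean} unique molecules, pool has {len(pool)}"
        )

    pool_idx = rng.choice(len(pool), size=n_clean, replace=False)
    # activity is tied to structure (molecular weight above the active-fraction
    # quantile) so fingerprints carry a learnable signal end to end; the IC50
    # spread around the class centres still crosses the threshold occasionally
    from rdkit.Chem import Descriptors

    mw = np.array([Descriptors.MolWt(Chem.MolFromSmiles(pool[pi])) for pi in pool_idx])
    cutoff = np.quantile(mw, 1.0 - spec.active_fraction)
    rows: list[dict] = []
    true_nm: list[float | None] = []
    for i, pi in enumerate(pool_idx):
        is_active = bool(mw[i] >= cutoff)
        mu, sd = _LOG10_NM_ACTIVE if is_active else _LOG10_NM_INACTIVE
        nm = 10.0 ** rng.normal(mu, sd)
        if rng.random() < spec.unit_mix:
            value_um = nm / 1000.0
            nm = value_um * 1000.0  # ground truth defined via the conversion, exact round-trip
            value, unit = value_um, "uM"
        else:
            value, unit = nm, "nM"
        rows.append(
            {
                "id": f"CPD{i:05d}",
                "smiles": pool[pi],
                "ic50": repr(float(value)),
                "unit": unit,
                "source": _SOURCES[rng.integers(len(_SOURCES))],
            }
        )
        true_nm.append(nm)

    # exact duplicates: re-emit earlier clean rows under an equivalent spelling
    # and a fresh (conflicting) measurement — curation must drop them
    for j in range(n_dup):
        k = int(rng.integers(n_clean))
        base = rows[k]
        mu, sd = _LOG10_NM_ACTIVE if rng.random() < spec.active_fraction else _LOG10_NM_INACTIVE
        nm = 10.0 ** rng.normal(mu, sd)
        rows.append(
            {
                "id": f"DUP{j:05d}",
                "smiles": _respell(base["smiles"], seed=int(rng.integers(2**31 - 1))),
                "ic50": repr(float(nm)),
                "unit": "nM",
                "source": base["source"],  # same rank: the earlier row stays first-seen
                "_dup_of": k,
            }
        )
        true_nm.append(nm)

    # rows with one mandatory field blanked — curation must drop them
    for j in range(n_missing):
        pi = int(rng.integers(len(pool)))
        which = ("id", "smiles", "ic50")[int(rng.integers(3))]
        row = {
            "id": f"MIS{j:05d}",
            "smiles": pool[pi],
            "ic50": repr(float(10.0 ** rng.normal(3.0, 1.0))),
            "unit": "nM",
            "source": _SOURCES[rng.integers(len(_SOURCES))],
        }
        row[which] = ""
        rows.append(row)
        true_nm.append(None)

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    true_nm = [true_nm[i] for i in order]

    table = pd.DataFrame(
        [{k: v for k, v in r.items() if not k.startswith("_")} for r in rows]
    )
    ledger = _ledger(spec, rows, true_nm)
    return table, ledger


def _ledger(spec: SimulationSpec, rows: list[dict], true_nm: list[float | None]) -> GroundTruthLedger:
    """Independent survivor/label bookkeeping over the emitted rows."""
    rank = {s: i for i, s in enumerate(_SOURCES)}
    ordered = sorted(range(len(rows)), key=lambda i: rank[rows[i]["source"]])
    seen: set[str] = set()
    survivor_ids: list[str] = []
    label_counts = {"active": 0, "inactive": 0}
    n_dup_drop = n_missing_drop = 0
    for i in ordered:
        row = rows[i]
        if "" in (row["id"], row["smiles"], row["ic50"]):
            n_missing_drop += 1
            continue
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(row["smiles"]))
        if canonical in seen:
            n_dup_drop += 1
            continue
        seen.add(canonical)
        survivor_ids.append(row["id"])
        pic50 = 9.0 - np.log10(true_nm[i])
        label_counts[assign_label(pic50, spec.threshold)] += 1
    return GroundTruthLedger(
        n_records=len(rows),
        n_clean=len(survivor_ids),
        n_duplicates=n_dup_drop,
        n_missing=n_missing_drop,
        expected_survivors=len(survivor_ids),
        expected_label_counts=label_counts,
        survivor_ids=sorted(survivor_ids),
    )


def simulate_separable_features(
    n: int, dim: int, separation: float, seed: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two spherical Gaussian classes with mean distance = separation · σ.

    Returns (features, labels, bayes_error); the Bayes error is the normal
    tail Φ(−separation/2).
    """
    if n < 2 or dim < 1:
        raise ValueError("need n >= 2 samples and dim >= 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)
    offset = (separation / 2.0) * direction
    labels = np.zeros(n, dtype=np.int64)
    labels[n // 2 :] = 1
    x = rng.normal(size=(n, dim))
    x[labels == 0] -= offset
    x[labels == 1] += offset
    perm = rng.permutation(n)
    bayes_error = float(norm.sf(separation / 2.0))
    return x[perm], labels[perm], bayes_error
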