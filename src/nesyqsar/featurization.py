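"""Molecular featurization: Morgan fingerprints, physicochemical properties,
optional CDK-extended descriptors, and block concatenation.

All featurizers are pure functions of the canonical SMILES: canonicalising
first never changes the output.  The combined feature used by the strongest
classifier configuration concatenates a 1024-bit CDK-extended fingerprint
with Morgan fingerprints at 512, 1024 and 2048 bits (total 4608 columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "FeatureBackendUnavailable",
    "morgan_fingerprint",
    "physchem_properties",
    "cdk_extended",
    "precomputed_embeddings",
    "concat_features",
    "featurize",
    "PHYSCHEM_NAMES",
    "ALLOWED_MORGAN_BITS",
]

ALLOWED_MORGAN_BITS = (512, 1024, 2048)
PHYSCHEM_NAMES = ("MW", "LogP", "TPSA", "HBD", "HBA", "RotB")


class FeatureBackendUnavailable(RuntimeError):
    """An optional descriptor backend is not installed."""


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks to compute, in order.

    ``morgan_bits`` may list several widths; each becomes an independent
    hashed fingerprint block and they are concatenated (512+1024+2048 = 3584
    columns when all three are requested).  Radius 2 corresponds to ECFP4.
    """

    schemes: tuple[str, ...] = ("morgan",)
    morgan_bits: tuple[int, ...] = (1024,)
    morgan_radius: int = 2

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one feature scheme is required")
        for scheme in self.schemes:
            if scheme not in ("morgan", "physchem", "cdk_extended") and not scheme.startswith(
                "precomputed:"
            ):
                raise ValueError(f"unknown feature scheme {scheme!r}")
        for bits in self.morgan_bits:
            if bits not in ALLOWED_MORGAN_BITS:
                raise ValueError(f"morgan_bits must be in {ALLOWED_MORGAN_BITS}, got {bits}")
        if self.morgan_radius < 1:
            raise ValueError("morgan radius must be >= 1")


@dataclass
class FeatureMatrix:
    """Compounds × dimensions block with scheme-prefixed column labels."""

    values: np.ndarray
    column_labels: list[str]
    scheme_dims: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column label count does not match matrix width")
        if sum(self.scheme_dims.values()) != self.values.shape[1]:
            raise ValueError("scheme dimensions do not sum to the matrix width")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_labels)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Hashed circular-substructure (ECFP-style) bit vector of length n_bits."""
    if n_bits not in ALLOWED_MORGAN_BITS:
        raise ValueError(f"n_bits must be one of {ALLOWED_MORGAN_BITS}, got {n_bits}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(_mol(smiles)).astype(np.float64)


def physchem_properties(smiles: str) -> np.ndarray:
    """Six interpretable properties in fixed order: MW, LogP, TPSA, HBD, HBA, RotB."""
    mol = _mol(smiles)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
        ],
        dtype=np.float64,
    )


def cdk_extended(smiles_list: Sequence[str]) -> np.ndarray:
    """1024-bit CDK-extended fingerprints via the PaDEL descriptor engine.

    Requires the optional ``padelpy`` backend (a Java descriptor engine); the
    rest of the pipeline is fully usable without it.
    """
    try:
        from padelpy import from_smiles  # type: ignore
    except ImportError as exc:
        raise FeatureBackendUnavailable(
            "CDK-extended fingerprints need the optional 'padelpy' package "
            "(PaDEL descriptor engine); install it or drop the 'cdk_extended' "
            "scheme — morgan/physchem remain available"
        ) from exc
    rows = []
    for smiles in smiles_list:
        desc = from_smiles(smiles, fingerprints=True, descriptors=False)
        bits = [v for k, v in sorted(desc.items()) if k.startswith("ExtFP")]
        if len(bits) != 1024:
            raise RuntimeError(f"expected 1024 ExtFP bits, got {len(bits)}")
        rows.append([float(b) for b in bits])
    return np.asarray(rows, dtype=np.float64)


def precomputed_embeddings(path, smiles_list: Sequence[str]) -> np.ndarray:
    """Load externally computed embeddings (e.g. chemical language models).

    The CSV must carry a ``smiles`` column plus numeric embedding columns;
    rows are aligned to ``smiles_list`` by canonical SMILES.
    """
    table = pd.read_csv(path)
    if "smiles" not in table.columns:
        raise ValueError("precomputed embedding CSV needs a 'smiles' column")
    canon = lambda s: Chem.MolToSmiles(_mol(s))  # noqa: E731
    table = table.set_index(table["smiles"].map(canon)).drop(columns=["smiles"])
    keys = [canon(s) for s in smiles_list]
    missing = [k for k in keys if k not in table.index]
    if missing:
        raise ValueError(f"{len(missing)} compounds missing from embedding CSV, e.g. {missing[0]!r}")
    return table.loc[keys].to_numpy(dtype=np.float64)


def concat_features(blocks: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature blocks sharing row order."""
    if not blocks:
        raise ValueError("no feature blocks to concatenate")
    n_rows = {b.n_compounds for b in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"blocks disagree on compound count: {sorted(n_rows)}")
    scheme_dims: dict[str, int] = {}
    for b in blocks:
        for name, dim in b.scheme_dims.items():
            if name in scheme_dims:
                raise ValueError(f"duplicate scheme {name!r} in concatenation")
            scheme_dims[name] = dim
    return FeatureMatrix(
        values=np.hstack([b.values for b in blocks]),
        column_labels=[c for b in blocks for c in b.column_labels],
        scheme_dims=scheme_dims,
    )


def featurize(smiles_list: Sequence[str], config: FeatureConfig = FeatureConfig()) -> FeatureMatrix:
    """Compute the configured feature blocks for a compound list, in order."""
    smiles_list = list(smiles_list)
    blocks: list[FeatureMatrix] = []
    for scheme in config.schemes:
        if scheme == "morgan":
            for bits in config.morgan_bits:
                values = np.vstack(
                    [morgan_fingerprint(s, bits, config.morgan_radius) for s in smiles_list]
                )
                name = f"morgan{bits}"
                blocks.append(
                    FeatureMatrix(values, [f"{name}_{i}" for i in range(bits)], {name: bits})
                )
        elif scheme == "physchem":
            values = np.vstack([physchem_properties(s) for s in smiles_list])
            blocks.append(
                FeatureMatrix(values, [f"physchem_{n}" for n in PHYSCHEM_NAMES], {"physchem": 6})
            )
        elif scheme == "cdk_extended":
            values = cdk_extended(smiles_list)
            blocks.append(
                FeatureMatrix(values, [f"cdk_{i}" for i in range(1024)], {"cdk_extended": 1024})
            )
        elif scheme.startswith("precomputed:"):
            path = scheme.split(":", 1)[1]
            values = precomputed_embeddings(path, smiles_list)
            name = "precomputed"
            blocks.append(
                FeatureMatrix(
                    values, [f"{name}_{i}" for i in range(values.shape[1])], {name: values.shape[1]}
                )
            )
    return concat_features(blocks)
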