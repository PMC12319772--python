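"""Bundled pool of valid drug-like SMILES for synthetic bioactivity tables.

A hand-curated list of marketed drugs — headed by the approved DPP-4
inhibitors (the gliptins) — is extended with a scaffold × substituent grid of
simple drug-like molecules.  Every entry is parsed with RDKit at first use;
anything unparseable is discarded and the pool is deduplicated on canonical
SMILES, so consumers always see unique, valid structures.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

__all__ = ["get_pool", "pool_size"]

# approved DPP-4 inhibitors first, then a spread of common small-molecule drugs
_NAMED_DRUGS: tuple[str, ...] = (
    # gliptins
    "Fc1cc(c(F)cc1F)C[C@@H](N)CC(=O)N1CCn2c(nnc2C(F)(F)F)C1",          # sitagliptin
    "N#C[C@@H]1C[C@@H]2CC[C@H]1N2C(=O)[C@@H](N)C12CC3CC(CC(O)(C3)C1)C2",  # saxagliptin
    "OC12CC3CC(CC(C3)C1)(C2)NCC(=O)N1CCC[C@H]1C#N",                     # vildagliptin
    "Cn1c(=O)cc(N2CCC[C@@H](N)C2)n(Cc2ccccc2C#N)c1=O",                  # alogliptin
    "CC#CCn1c(N2CCC[C@@H](N)C2)nc2c1c(=O)n(C)c(=O)n2Cc1nc2ccccc2c(C)n1",  # linagliptin
    # other common drugs
    "CC(=O)Oc1ccccc1C(=O)O",              # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",         # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                 # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",         # caffeine
    "CN(C)C(=N)NC(=N)N",                  # metformin
    "CN1C2CCC1CC(OC(=O)c1ccccc1)C2",      # tropane ester
    "Clc1ccccc1-c1nc2ccccc2[nH]1",        # benzimidazole
    "O=C(O)c1ccccc1O",                    # salicylic acid
    "Nc1ccc(S(=O)(=O)Nc2ccccn2)cc1",      # sulfapyridine
    "CC(N)Cc1ccccc1",                     # amphetamine
    "OCC(O)c1ccc(O)c(O)c1",               # catechol diol
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",       # naproxen
    "NC(=O)c1ccc[nH]1",                   # pyrrole amide
    "Oc1ccc(CCN)cc1",                     # tyramine
    "CN1CCC[C@H]1c1cccnc1",               # nicotine
    "Clc1ccc(C(c2ccccc2)N2CCN(CCO)CC2)cc1",  # hydroxyzine-like
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",      # melatonin
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",        # tryptophan
    "NC(Cc1ccc(O)cc1)C(=O)O",             # tyrosine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",         # citric acid
    "Nc1ncnc2[nH]cnc12",                  # adenine
    "Cc1ncc([N+](=O)[O-])n1CCO",          # metronidazole
    "OC(c1ccccc1)c1ccccc1",               # benzhydrol
    "O=C1NC(=O)NC(=O)C1(CC)CC",           # barbital
    "CCN(CC)C(=O)c1ccccc1",               # benzamide
    "COc1cc2c(cc1OC)CC(N)C2",             # aminotetralin ether
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",     # atenolol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",      # salbutamol
    "O=c1[nH]cnc2[nH]ncc12",              # allopurinol
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",     # estradiol
    "CC(CS)C(=O)N1CCCC1C(=O)O",           # captopril
    "Clc1ccc2c(c1)C(=O)N(C)CC2",          # chloro lactam
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",  # perphenazine-like
    "CC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3C(O)CC21C",  # corticoid-like
    "Nc1nc(N)c2nc(-c3ccccc3)c(N)nc2n1",   # triamterene
    "CCOC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1cccc([N+](=O)[O-])c1",  # nitrendipine-like
)

# scaffold × substituent grid; substituents attach as a single branch and use
# ring-closure digit 3 to avoid clashing with scaffold ring numbering
_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc({})cc1",
    "Cc1ccc({})cc1",
    "CCOC(=O)c1ccc({})cc1",
    "CC(=O)Nc1ccc({})cc1",
    "O=C(O)c1ccc({})cc1",
    "O=S(=O)(N)c1ccc({})cc1",
    "c1ccc(-c2ccc({})cc2)cc1",
    "CN1CCN(c2ccc({})cc2)CC1",
    "O=C(Nc1ccccc1)c1ccc({})cc1",
    "c1ccc2cc({})ccc2c1",
    "Cc1cc({})ccc1O",
    "COc1ccc({})cc1",
)

_SUBSTITUENTS: tuple[str, ...] = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C",
    "OC", "OCC", "OCCC", "N", "NC", "N(C)C", "NCC", "C#N", "[N+](=O)[O-]",
    "C(F)(F)F", "O", "S", "SC", "C(=O)C", "C(=O)OC", "C(=O)N", "C(=O)O",
    "CO", "CCO", "C=C", "CCl", "CF", "OC(C)C", "NC(C)=O", "S(C)(=O)=O",
    "CCOC", "CC#N", "CC(C)O", "CN", "CCN", "CCCl", "OCC(C)C", "C3CC3",
    "N3CCCC3", "N3CCOCC3", "N3CCN(C)CC3", "OC(F)F", "C(=O)NC", "CC(N)=O",
    "OCC3CC3",
)


@lru_cache(maxsize=1)
def get_pool() -> tuple[str, ...]:
    """Unique canonical SMILES pool (named drugs first, then the grid)."""
    candidates = list(_NAMED_DRUGS)
    candidates += [s.format(sub) for s in _SCAFFOLDS for sub in _SUBSTITUENTS]
    seen: set[str] = set()
    pool: list[str] = []
    for smiles in candidates:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            pool.append(canonical)
    return tuple(pool)


def pool_size() -> int:
    return len(get_pool())
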