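"""MACCS structural keys and molecular descriptor vectors.

Fingerprints use the public 166-key MACCS dictionary as implemented in RDKit;
bit indices follow the original MACCS numbering (key 134 = any halogen,
103 = chlorine, 46 = bromine, 165 = any ring, 162 = aromatic).

The descriptor set is the open RDKit 2D descriptor collection plus three
named descriptors the screening analysis keys on explicitly:

* ``logP_estimate`` — Crippen atom-contribution octanol/water log P, the open
  proxy for a consensus log P descriptor;
* ``carbon_fraction`` — carbon atoms over all atoms including hydrogens
  (the C% convention of constitutional descriptor families);
* ``halogen_count`` — number of F/Cl/Br/I atoms, a persistence-relevant
  constitutional count.

Uncomputable descriptors become explicit NaN, never a silent zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys
from rdkit.Chem.MACCSkeys import smartsPatts

from .io import CompoundRecord

logger = logging.getLogger(__name__)

N_MACCS_KEYS = 166

KEY_HALOGEN = 134
KEY_CHLORINE = 103
KEY_BROMINE = 46
KEY_FLUORINE = 42
KEY_RING = 165
KEY_AROMATIC = 162

#: plain-language descriptions for keys that recur in screening reports;
#: other keys fall back to their SMARTS pattern.
MACCS_DESCRIPTIONS: dict[int, str] = {
    42: "Fluorine atom",
    46: "Bromine atoms",
    87: "Halogen atom not bonded to an atom participating in a ring bond",
    103: "Chlorine atom",
    106: "One atom connected to three nonmethine groups",
    107: "Halogen atom connected to one atom which is connected to two atoms",
    112: "One central atom connected to four atoms",
    134: "Halogens",
    139: "Hydroxyl group",
    143: "Ring heteroatom-methylene pattern",
    144: "Non-ring atom bridging two ring atoms",
    150: "Atom bridging two nonaromatic ring systems",
    152: "Carbon-oxygen pattern with methyl branch",
    153: "Heteroatom connected to a methylene group bonded to another atom",
    154: "Carbonyl group",
    155: "Methylene connected to other atoms with more than one chain bond",
    157: "Carbon-oxygen single bond",
    159: "More than one oxygen atom",
    160: "Methyl group",
    162: "Aromatic structure",
    163: "Six-membered ring",
    164: "Oxygen atom",
    165: "Any cyclic structure",
}


def maccs_key_name(key: int) -> str:
    """SMARTS pattern string for a MACCS key (its short 'name')."""
    patt = smartsPatts.get(key)
    return patt[0] if patt else "?"


def maccs_key_description(key: int) -> str:
    return MACCS_DESCRIPTIONS.get(key, maccs_key_name(key))


@dataclass
class FingerprintVector:
    """166-bit MACCS fingerprint, ``bits[k-1]`` = original key number k."""

    compound_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (N_MACCS_KEYS,):
            raise ValueError(f"expected {N_MACCS_KEYS} bits, got {self.bits.shape}")

    def key_set(self, key: int) -> bool:
        """Whether original MACCS key number ``key`` (1-166) is set."""
        return bool(self.bits[key - 1])


def _mol(record: CompoundRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"{record.compound_id}: unparseable SMILES {record.smiles!r}")
    # re-parse from the canonical SMILES so atom ordering (and with it every
    # eigenvalue-based descriptor) is identical for any spelling of a molecule
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def maccs_fingerprint(record: CompoundRecord) -> FingerprintVector:
    """MACCS fingerprint by substructure matching of the public key SMARTS."""
    fp = MACCSkeys.GenMACCSKeys(_mol(record))  # 167 bits, bit index = key number
    arr = np.zeros(N_MACCS_KEYS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        if 1 <= bit <= N_MACCS_KEYS:
            arr[bit - 1] = 1
    return FingerprintVector(compound_id=record.compound_id, bits=arr)


_HALOGENS = {9, 17, 35, 53}


def _carbon_fraction(mol: Chem.Mol) -> float:
    molh = Chem.AddHs(mol)
    n_atoms = molh.GetNumAtoms()
    n_carbon = sum(1 for a in molh.GetAtoms() if a.GetAtomicNum() == 6)
    return n_carbon / n_atoms if n_atoms else float("nan")


def _halogen_count(mol: Chem.Mol) -> float:
    return float(sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in _HALOGENS))


# Ipc grows exponentially with molecule size and overflows for larger
# structures, which also wrecks any distance computed on z-scored features.
# MolLogP is already exposed (by name) as logP_estimate; keeping both would
# duplicate the feature and split its attribution.
_EXCLUDED_DESCRIPTORS = {"Ipc", "MolLogP"}


def descriptor_names() -> list[str]:
    """The fixed, ordered descriptor name list shared across a run."""
    rd = sorted(
        name for name, _ in Descriptors.descList if name not in _EXCLUDED_DESCRIPTORS
    )
    return ["logP_estimate", "carbon_fraction", "halogen_count"] + rd


def descriptor_vector(record: CompoundRecord) -> dict[str, float]:
    """Named descriptor values for one compound (NaN where uncomputable)."""
    mol = _mol(record)
    values: dict[str, float] = {
        "logP_estimate": float(Descriptors.MolLogP(mol)),
        "carbon_fraction": _carbon_fraction(mol),
        "halogen_count": _halogen_count(mol),
    }
    funcs = dict(Descriptors.descList)
    for name in descriptor_names()[3:]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = float(funcs[name](mol))
            if not np.isfinite(val):
                val = float("nan")
        except Exception:  # descriptor-specific failures -> explicit NaN
            logger.warning("%s: descriptor %s uncomputable", record.compound_id, name)
            val = float("nan")
        values[name] = val
    return values


def is_noncyclic(record: CompoundRecord) -> bool:
    """True iff the molecular graph contains no ring."""
    mol = _mol(record)  # keep the Mol alive while its RingInfo is read
    return mol.GetRingInfo().NumRings() == 0


def fingerprint_matrix(records: list[CompoundRecord]) -> pd.DataFrame:
    """Compound x MACCS-key binary matrix, columns = original key numbers."""
    rows = [maccs_fingerprint(r).bits for r in records]
    return pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, N_MACCS_KEYS), dtype=np.uint8),
        index=[r.compound_id for r in records],
        columns=list(range(1, N_MACCS_KEYS + 1)),
    )


def descriptor_matrix(records: list[CompoundRecord]) -> pd.DataFrame:
    """Compound x descriptor matrix with the fixed column order."""
    names = descriptor_names()
    rows = [descriptor_vector(r) for r in records]
    df = pd.DataFrame(rows, index=[r.compound_id for r in records])
    return df.reindex(columns=names)


#: a feature matrix with more constant columns than this is considered
#: degenerate (many RDKit fragment counters are legitimately all-zero on any
#: given roster, so the guard is generous)
MAX_ZERO_VARIANCE_FRACTION = 0.5


def zero_variance_fraction(desc: pd.DataFrame) -> float:
    """Fraction of descriptor columns that are constant (degenerate)."""
    if desc.shape[1] == 0:
        return 0.0
    variances = desc.var(axis=0, skipna=True).fillna(0.0)
    return float((variances == 0).mean())
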