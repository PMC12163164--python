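"""Circular-substructure fingerprints: Morgan counts and SMILES-ECFP bits.

``morgan_counts`` wraps RDKit's Morgan generator (hashed count vector,
chirality information on).  ``secfp_binary`` is this package's
implementation of the SMILES extended-connectivity idea: the circular
atom environment of every atom at radii 1..r is written out as a rooted
SMILES shingle, hashed (SHA-1) and folded into a fixed-length binary
vector.  Both are deterministic functions of the input molecule.
"""

from __future__ import annotations

import hashlib

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .ngram import FeaturizationError

__all__ = ["morgan_counts", "secfp_binary"]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"cannot parse SMILES {smiles!r}")
    return mol


def morgan_counts(smiles: str, radius: int = 2, hash_len: int = 1024) -> np.ndarray:
    """Hashed Morgan count fingerprint with chirality, as an int vector."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=hash_len, includeChirality=True
    )
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(hash_len, dtype=np.int64)
    for pos, count in fp.GetNonzeroElements().items():
        vec[pos] = count
    return vec


def _shingles(mol: Chem.Mol, radius: int) -> set[str]:
    shingles: set[str] = set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        for r in range(1, radius + 1):
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
            if not env:
                continue
            amap: dict[int, int] = {}
            submol = Chem.PathToSubmol(mol, env, atomMap=amap)
            if idx not in amap:
                continue
            smi = Chem.MolToSmiles(submol, rootedAtAtom=amap[idx], canonical=True)
            if smi:
                shingles.add(smi)
    return shingles


def secfp_binary(smiles: str, radius: int = 2, hash_len: int = 1024) -> np.ndarray:
    """Binary folded fingerprint over circular-environment SMILES shingles."""
    mol = _mol_from_smiles(smiles)
    vec = np.zeros(hash_len, dtype=np.int64)
    for shingle in _shingles(mol, radius):
        digest = hashlib.sha1(shingle.encode("utf-8")).digest()
        vec[int.from_bytes(digest[:8], "big") % hash_len] = 1
    return vec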