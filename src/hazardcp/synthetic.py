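"""Synthetic labelled SMILES datasets with the structure of hazard data.

Real hazard-statement datasets cannot be redistributed, so the test beds
for this package are generated: molecules are assembled from a small
fragment grammar (aromatic and aliphatic scaffolds with substitution
slots), the binary label is driven by planted *toxicophore motifs*
(nitro, acyl halide, nitrile, epoxide substructures) optionally flipped
by label noise, a configurable fraction of records carries an appended
counter-ion fragment ('.'-separated SMILES), and the class imbalance can
mirror the hazard-statement groups (from a ~3% active rate for acute
oral toxicity up to ~49% for long-lasting aquatic toxicity).

Labels are a function of structure (XOR noise), so featurizers genuinely
carry signal: a noise-free dataset is learnable to high balanced
accuracy, which is what makes conformal efficiency meaningful here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import MoleculeRecord, standardize_smiles

__all__ = [
    "SyntheticConfig",
    "SyntheticError",
    "generate_dataset",
    "imbalance_profiles",
    "TOXICOPHORE_MOTIFS",
]


class SyntheticError(ValueError):
    pass


#: SMARTS patterns whose presence drives the active label
TOXICOPHORE_MOTIFS: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "acyl_chloride": "[CX3](=O)Cl",
    "nitrile": "[CX2]#[NX1]",
    "epoxide": "C1OC1",
}

#: substituents that realize each motif in the fragment grammar
_MOTIF_SUBSTITUENTS: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "acyl_chloride": "C(=O)Cl",
    "nitrile": "C#N",
    "epoxide": "C2OC2",
}

#: motif-free substituents
_BENIGN_SUBSTITUENTS: tuple[str, ...] = (
    "O", "N", "Cl", "F", "Br", "S", "C", "CC", "CCC", "OC", "CO",
    "C(C)C", "C(=O)O", "C(=O)OC", "NC", "OCC", "C2CC2", "[C@@H](C)O",
    "[C@H](N)C", "CCO",
)

#: scaffolds with substitution slots (ring closure digit 1 reserved)
_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc({0})cc1",
    "c1ccc({0})c({1})c1",
    "c1cc({0})cc({1})c1",
    "c1ccnc({0})c1",
    "c1csc({0})c1",
    "C1CCC({0})CC1",
    "C1CCN({0})CC1",
    "CC({0})C{1}",
    "CCC({0})CC{1}",
    "C({0})CC{1}",
)

#: '.'-separated counter-ion fragments for the salt/metal records
_SALT_FRAGMENTS: tuple[str, ...] = ("[Na+]", "[K+]", "[Cl-]", "[Br-]", "[Li+]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic dataset.

    ``active_fraction`` is the target rate of motif-bearing (pre-noise
    active) compounds; ``label_noise`` flips each label independently
    with this probability; ``salt_fraction`` of records get an appended
    counter-ion fragment.

    The default 20% label noise emulates the annotation ambiguity of
    regulatory hazard data (conflicting dossier entries), which puts
    models in the informative-but-imperfect regime hazard classifiers
    actually operate in; set ``label_noise=0`` for a dataset whose
    labels are a pure function of structure.
    """

    n_compounds: int = 2000
    active_fraction: float = 0.3
    motifs: tuple[str, ...] = tuple(TOXICOPHORE_MOTIFS)
    label_noise: float = 0.2
    salt_fraction: float = 0.1
    scaffolds: tuple[str, ...] = _SCAFFOLDS
    benign_substituents: tuple[str, ...] = _BENIGN_SUBSTITUENTS
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 < self.active_fraction < 1.0:
            raise SyntheticError("active_fraction must be in (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise SyntheticError("label_noise must be in [0, 0.5)")
        if not 0.0 <= self.salt_fraction <= 1.0:
            raise SyntheticError("salt_fraction must be in [0, 1]")
        if not self.motifs:
            raise SyntheticError("motif list must be nonempty")
        unknown = [m for m in self.motifs if m not in TOXICOPHORE_MOTIFS]
        if unknown:
            raise SyntheticError(
                f"unknown motifs {unknown}; available: {sorted(TOXICOPHORE_MOTIFS)}"
            )


def _motif_queries(motifs: Sequence[str]) -> list[Chem.Mol]:
    return [Chem.MolFromSmarts(TOXICOPHORE_MOTIFS[m]) for m in motifs]


def _contains_motif(smiles: str, queries: Sequence[Chem.Mol]) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(q) for q in queries)


def _build_molecule(
    rng: np.random.Generator, config: SyntheticConfig, active: bool,
    queries: Sequence[Chem.Mol],
) -> str:
    """Assemble one molecule; rejection-sample until motif status matches."""
    for _ in range(200):
        scaffold = config.scaffolds[rng.integers(len(config.scaffolds))]
        n_slots = scaffold.count("{")
        subs = [
            config.benign_substituents[rng.integers(len(config.benign_substituents))]
            for _ in range(n_slots)
        ]
        if active:
            motif = config.motifs[rng.integers(len(config.motifs))]
            subs[rng.integers(n_slots)] = _MOTIF_SUBSTITUENTS[motif]
        smiles = scaffold.format(*subs)
        std = standardize_smiles(smiles)
        if std is None:
            continue
        if _contains_motif(std, queries) == active:
            return std
    raise SyntheticError(
        f"could not build a {'motif' if active else 'motif-free'} molecule "
        f"from the grammar after 200 attempts"
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Generate a labelled dataset plus its ground-truth annotations.

    Returns standardized records (every SMILES parses) and a frame with
    one row per record: ``id``, ``has_motif`` (the structural ground
    truth), ``label`` (= has_motif XOR noise flip), ``flipped`` and
    ``has_salt``.  Deterministic per ``config.seed``; the pre-noise
    active count is exactly ``round(n_compounds * active_fraction)``.
    """
    rng = np.random.default_rng(config.seed)
    queries = _motif_queries(config.motifs)

    n_active = int(round(config.n_compounds * config.active_fraction))
    if not 0 < n_active < config.n_compounds:
        raise SyntheticError("active_fraction leaves a class empty at this n")
    motif_flags = np.zeros(config.n_compounds, dtype=bool)
    motif_flags[:n_active] = True
    rng.shuffle(motif_flags)

    records: list[MoleculeRecord] = []
    truth_rows = []
    for i, has_motif in enumerate(motif_flags):
        smiles = _build_molecule(rng, config, bool(has_motif), queries)
        has_salt = bool(rng.uniform() < config.salt_fraction)
        if has_salt:
            salt = _SALT_FRAGMENTS[rng.integers(len(_SALT_FRAGMENTS))]
            smiles = standardize_smiles(f"{smiles}.{salt}")
        flipped = bool(rng.uniform() < config.label_noise)
        label = int(bool(has_motif) != flipped)
        rec_id = f"{config.name}-{i:05d}"
        records.append(
            MoleculeRecord(
                id=rec_id, smiles_raw=smiles, label=label,
                smiles_std=smiles, valid=True,
            )
        )
        truth_rows.append(
            {"id": rec_id, "has_motif": bool(has_motif), "label": label,
             "flipped": flipped, "has_salt": has_salt}
        )
    return records, pd.DataFrame(truth_rows)


def imbalance_profiles(n_compounds: int = 2000) -> dict[str, SyntheticConfig]:
    """Named configurations mirroring the class balance of the ten
    hazard-statement groups (active / total compound counts)."""
    ratios = {
        "H30x-like": 448 / (448 + 13108),
        "H31x0123-like": 1067 / (1067 + 5942),
        "H31x57-like": 4931 / (4931 + 5342),
        "H33x0123-like": 393 / (393 + 8433),
        "H33x45-like": 1708 / (1708 + 1994),
        "H34x-like": 393 / (393 + 8433),
        "H35x-like": 510 / (510 + 2769),
        "H36x01-like": 903 / (903 + 4905),
        "H40x-like": 1754 / (1754 + 7615),
        "H41x-like": 4847 / (4847 + 5040),
    }
    return {
        name: SyntheticConfig(
            n_compounds=n_compounds, active_fraction=frac, name=name
        )
        for name, frac in ratios.items()
    }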