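"""Featurizers: SMILES strings -> fixed-length numeric vectors.

Ten named descriptor configurations are registered (see
:data:`REGISTERED_SPECS`): hashed character N-grams of the raw SMILES at
lengths 4 and 6 and hash sizes 64/256/1024, token-level N-grams after
pair-encoding tokenization, character N-grams of the DeepSMILES-style and
SELFIES-style re-encodings, Morgan count fingerprints at radii 2 and 4,
and binary SMILES extended-connectivity fingerprints at radii 2 and 4.
Core-substituent fingerprints are exposed as an adapter slot only: an
external provider callable may be registered, but nothing in the core
pipeline depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ngram import (
    NGRAM_DICTIONARY,
    FeaturizationError,
    TokenDictionary,
    encode_ngram_counts,
    encode_token_ngrams,
    encode_window,
)
from .pe import learn_pe_merges, tokenize_pe, tokenize_smiles
from .deepsmiles import transform_deepsmiles, decode_deepsmiles
from .selfies import transform_selfies, decode_selfies
from .circular import morgan_counts, secfp_binary

__all__ = [
    "FeaturizerSpec",
    "Featurizer",
    "FeaturizationError",
    "REGISTERED_SPECS",
    "get_featurizer",
    "featurize_dataset",
    "register_adapter",
    "NGRAM_DICTIONARY",
    "TokenDictionary",
    "encode_ngram_counts",
    "encode_token_ngrams",
    "encode_window",
    "tokenize_pe",
    "tokenize_smiles",
    "learn_pe_merges",
    "transform_deepsmiles",
    "decode_deepsmiles",
    "transform_selfies",
    "decode_selfies",
    "morgan_counts",
    "secfp_binary",
]

_FAMILIES = {
    "ngram", "ngram_pe", "deepsmiles_ngram", "selfies_ngram",
    "morgan", "secfp", "core_substituent",
}


@dataclass(frozen=True)
class FeaturizerSpec:
    """Configuration of one descriptor: family, gram length, hash length, radius."""

    name: str
    family: str
    n: int | None = None
    hash_len: int = 1024
    radius: int | None = None
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise FeaturizationError(f"unknown featurizer family {self.family!r}")
        if self.family == "ngram":
            if self.n not in (4, 6) or self.hash_len not in (64, 256, 1024):
                raise FeaturizationError(
                    f"{self.name}: ngram family needs n in {{4,6}} and "
                    f"hash_len in {{64,256,1024}}"
                )
            if self.value_kind != "counts":
                raise FeaturizationError(f"{self.name}: ngram vectors are counts")
        if self.family == "morgan" and (self.hash_len != 1024 or self.value_kind != "counts"):
            raise FeaturizationError(f"{self.name}: morgan uses 1024 counts")
        if self.family == "secfp" and (self.hash_len != 1024 or self.value_kind != "binary"):
            raise FeaturizationError(f"{self.name}: secfp uses 1024 binary")
        if self.family == "core_substituent" and (
            self.hash_len != 1000 or self.value_kind != "binary"
        ):
            raise FeaturizationError(f"{self.name}: core_substituent uses 1000 binary")

    def to_dict(self) -> dict:
        return {
            "name": self.name, "family": self.family, "n": self.n,
            "hash_len": self.hash_len, "radius": self.radius,
            "value_kind": self.value_kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturizerSpec":
        return cls(**d)


#: the descriptor configurations used throughout the experiments
REGISTERED_SPECS: dict[str, FeaturizerSpec] = {
    spec.name: spec
    for spec in [
        *[
            FeaturizerSpec(f"ngram_{n}_hashed_{h}", "ngram", n=n, hash_len=h)
            for n in (4, 6)
            for h in (64, 256, 1024)
        ],
        FeaturizerSpec("ngramsPE", "ngram_pe", n=4, hash_len=1024),
        FeaturizerSpec("deepsmiles", "deepsmiles_ngram", n=4, hash_len=1024),
        FeaturizerSpec("selfies", "selfies_ngram", n=4, hash_len=1024),
        FeaturizerSpec("morgan2", "morgan", radius=2, hash_len=1024),
        FeaturizerSpec("morgan4", "morgan", radius=4, hash_len=1024),
        FeaturizerSpec("SMILES_extnd_connect_fps_2", "secfp", radius=2,
                       hash_len=1024, value_kind="binary"),
        FeaturizerSpec("SMILES_extnd_connect_fps_4", "secfp", radius=4,
                       hash_len=1024, value_kind="binary"),
        FeaturizerSpec("Core-Substituent_fps", "core_substituent",
                       hash_len=1000, value_kind="binary"),
    ]
}

#: adapter providers for externally computed fingerprints
_ADAPTERS: dict[str, Callable[[str], np.ndarray]] = {}


def register_adapter(family: str, provider: Callable[[str], np.ndarray]) -> None:
    """Register an external fingerprint provider for an adapter family.

    The provider receives a SMILES string and must return a deterministic
    vector of the spec's length; for binary families the values must be
    in {0, 1}.
    """
    _ADAPTERS[family] = provider


class Featurizer:
    """A configured descriptor with any per-dataset state (token dictionary)."""

    def __init__(
        self,
        spec: FeaturizerSpec,
        token_dict: TokenDictionary | None = None,
        pe_merges: Sequence[tuple[str, str]] | None = None,
    ):
        self.spec = spec
        self.token_dict = token_dict or TokenDictionary()
        self.pe_merges = list(pe_merges) if pe_merges else []

    def __call__(self, smiles: str) -> np.ndarray:
        spec = self.spec
        if spec.family == "ngram":
            return encode_ngram_counts(smiles, n=spec.n, hash_len=spec.hash_len)
        if spec.family == "ngram_pe":
            tokens = tokenize_pe(smiles, self.pe_merges)
            return encode_token_ngrams(tokens, n=spec.n, hash_len=spec.hash_len,
                                       token_dict=self.token_dict)
        if spec.family == "deepsmiles_ngram":
            return encode_ngram_counts(transform_deepsmiles(smiles),
                                       n=spec.n, hash_len=spec.hash_len)
        if spec.family == "selfies_ngram":
            return encode_ngram_counts(transform_selfies(smiles),
                                       n=spec.n, hash_len=spec.hash_len)
        if spec.family == "morgan":
            return morgan_counts(smiles, radius=spec.radius, hash_len=spec.hash_len)
        if spec.family == "secfp":
            return secfp_binary(smiles, radius=spec.radius, hash_len=spec.hash_len)
        if spec.family == "core_substituent":
            provider = _ADAPTERS.get(spec.family)
            if provider is None:
                raise FeaturizationError(
                    "no core_substituent provider registered; register one with "
                    "hazardcp.features.register_adapter('core_substituent', fn)"
                )
            vec = np.asarray(provider(smiles))
            if vec.shape != (spec.hash_len,):
                raise FeaturizationError(
                    f"adapter returned shape {vec.shape}, expected ({spec.hash_len},)"
                )
            if not np.isin(vec, (0, 1)).all():
                raise FeaturizationError("adapter vector is not binary")
            return vec.astype(np.int64)
        raise FeaturizationError(f"unhandled family {spec.family!r}")


def get_featurizer(spec, **kwargs) -> Featurizer:
    """Resolve a spec name or :class:`FeaturizerSpec` to a ready featurizer."""
    if isinstance(spec, str):
        if spec not in REGISTERED_SPECS:
            raise FeaturizationError(
                f"unknown featurizer {spec!r}; registered: {sorted(REGISTERED_SPECS)}"
            )
        spec = REGISTERED_SPECS[spec]
    return Featurizer(spec, **kwargs)


def featurize_dataset(records, spec, **kwargs):
    """Featurize the valid records of a dataset.

    Returns ``(X, row_index, failures)`` where ``X`` has one row per
    successfully featurized record, ``row_index`` maps matrix rows to
    positions in ``records``, and ``failures`` lists ``(position, error)``
    pairs for records that could not be featurized (invalid structures or
    per-record featurization errors).  Raises if every record fails.
    """
    featurizer = spec if isinstance(spec, Featurizer) else get_featurizer(spec, **kwargs)
    rows, row_index, failures = [], [], []
    for pos, rec in enumerate(records):
        if not rec.valid:
            failures.append((pos, "invalid structure"))
            continue
        try:
            rows.append(featurizer(rec.smiles_std))
            row_index.append(pos)
        except FeaturizationError as exc:
            failures.append((pos, str(exc)))
    if not rows:
        raise FeaturizationError("no record could be featurized")
    return np.vstack(rows), np.asarray(row_index), failures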