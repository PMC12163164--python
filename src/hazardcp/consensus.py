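"""Consensus predictors over several per-descriptor conformal models.

Two combination rules are provided:

* ``consensus_pvals`` — the per-compound, per-class **median** p-value
  across models (even model counts use the mean of the two central
  values); prediction sets are derived from the median pair.
* ``consensus_cls`` — a **majority vote** over the models' prediction
  sets at the shared significance level, ties resolved by the fixed
  priority single-active > single-inactive > both > empty.

Two named descriptor subsets mirror the study's selections, alongside
the full set: ``set1`` mixes fingerprints and string N-grams, ``set2``
is the pure N-gram set (the recommended default, since it never fails on
salts or metal-containing compounds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .conformal import Outcome, prediction_sets

__all__ = [
    "MODEL_SETS",
    "ConsensusConfig",
    "ConsensusError",
    "consensus_pvals",
    "consensus_cls",
    "resolve_model_set",
    "TIE_ORDER",
]


class ConsensusError(ValueError):
    pass


#: named descriptor subsets for consensus modelling
MODEL_SETS: dict[str, tuple[str, ...] | None] = {
    "all": None,  # every available model
    "set1": (
        "Core-Substituent_fps",
        "deepsmiles",
        "morgan2",
        "ngramsPE",
        "SMILES_extnd_connect_fps_2",
        "selfies",
        "ngram_4_hashed_1024",
    ),
    "set2": (
        "ngram_4_hashed_64",
        "ngram_4_hashed_256",
        "ngram_4_hashed_1024",
        "ngram_6_hashed_64",
        "ngram_6_hashed_256",
        "ngram_6_hashed_1024",
        "ngramsPE",
    ),
}

#: fixed priority for equal maximum vote counts
TIE_ORDER: tuple[Outcome, ...] = (
    Outcome.SINGLE_ACTIVE,
    Outcome.SINGLE_INACTIVE,
    Outcome.BOTH,
    Outcome.EMPTY,
)


@dataclass(frozen=True)
class ConsensusConfig:
    """Which combination rule, which descriptor subset, which significance."""

    mode: str = "cls"          # "pvals" | "cls"
    model_set: str = "set2"    # "all" | "set1" | "set2"
    significance: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("pvals", "cls"):
            raise ConsensusError(f"mode must be 'pvals' or 'cls', got {self.mode!r}")
        if self.model_set not in MODEL_SETS:
            raise ConsensusError(
                f"model_set must be one of {sorted(MODEL_SETS)}, got {self.model_set!r}"
            )
        if not 0.0 < self.significance < 1.0:
            raise ConsensusError(f"significance must be in (0, 1)")

    @property
    def name(self) -> str:
        return f"consensus_{self.mode}_{self.model_set}"


def resolve_model_set(model_set: str, available: Sequence[str]) -> list[str]:
    """Resolve a named subset against the available fitted models.

    A member missing from ``available`` is a configuration error, never a
    silent skip; a resolved set must contain at least two models.
    """
    if model_set not in MODEL_SETS:
        raise ConsensusError(f"unknown model set {model_set!r}")
    members = MODEL_SETS[model_set]
    names = list(available) if members is None else list(members)
    missing = [m for m in names if m not in available]
    if missing:
        raise ConsensusError(
            f"model set {model_set!r} requires models not available: {missing}"
        )
    if len(names) < 2:
        raise ConsensusError(
            f"model set {model_set!r} resolves to {len(names)} model(s); need >= 2"
        )
    return names


def _check_aligned(lengths: Sequence[int], what: str) -> int:
    if len(set(lengths)) != 1:
        raise ConsensusError(f"ragged {what}: lengths {sorted(set(lengths))}")
    return lengths[0]


def consensus_pvals(
    per_model_pvals: Sequence[np.ndarray], epsilon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Median-p-value consensus.

    ``per_model_pvals`` holds one (n, 2) p-value array (columns
    p_inactive, p_active) per model, all for the same compounds in the
    same order.  Returns ``(outcomes, median_pvals)``.
    """
    arrays = [np.asarray(p, dtype=float) for p in per_model_pvals]
    if not arrays:
        raise ConsensusError("no models supplied")
    _check_aligned([a.shape[0] for a in arrays], "p-value lists")
    stacked = np.stack(arrays)                 # (models, n, 2)
    median = np.median(stacked, axis=0)        # even count -> mean of central pair
    return prediction_sets(median, epsilon), median


def consensus_cls(
    per_model_outcomes: Sequence[Sequence[Outcome]],
    epsilon: float | None = None,
    missing: Mapping[int, Sequence[int]] | None = None,
) -> np.ndarray:
    """Majority-vote consensus over prediction sets computed at one shared
    significance level.

    ``missing`` optionally maps a model index to compound indices where
    that model could not featurize the compound; those votes are excluded
    for those compounds only.  Ties go to the first outcome of
    :data:`TIE_ORDER`.
    """
    if not per_model_outcomes:
        raise ConsensusError("no models supplied")
    n = _check_aligned([len(o) for o in per_model_outcomes], "outcome lists")
    missing = {int(k): set(v) for k, v in (missing or {}).items()}
    result = np.empty(n, dtype=object)
    for i in range(n):
        votes = {o: 0 for o in TIE_ORDER}
        n_votes = 0
        for m, outcomes in enumerate(per_model_outcomes):
            if i in missing.get(m, ()):
                continue
            votes[Outcome(outcomes[i])] += 1
            n_votes += 1
        if n_votes == 0:
            raise ConsensusError(f"no model voted for compound {i}")
        best = max(votes.values())
        result[i] = next(o for o in TIE_ORDER if votes[o] == best)
    return result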