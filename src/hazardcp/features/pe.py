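"""Pair-encoding tokenization of SMILES for token-level N-grams.

SMILES strings are first split into chemically atomic tokens (bracket
atoms such as ``[Na+]`` and ``[C@@H]`` stay whole, as do two-letter
organic-subset halogens and ``%NN`` ring closures); an optional set of
byte-pair merges learned from a corpus then greedily fuses the most
frequent adjacent token pairs into multi-character tokens.  Concatenating
the tokens always reproduces the input string exactly.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Sequence

__all__ = ["tokenize_smiles", "learn_pe_merges", "tokenize_pe"]

# bracket atoms atomic; Cl/Br before single letters; %NN ring closures whole
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|%\d{2}|Cl|Br|.)", re.DOTALL
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into atomic tokens (lossless)."""
    return _SMILES_TOKEN_RE.findall(smiles)


def learn_pe_merges(corpus: Iterable[str], n_merges: int = 100) -> list[tuple[str, str]]:
    """Learn byte-pair merges over atom-level tokenizations of a corpus.

    Repeatedly records the most frequent adjacent token pair (ties broken
    lexicographically for determinism) and fuses it throughout the corpus,
    ``n_merges`` times or until no pair repeats.
    """
    seqs = [tokenize_smiles(s) for s in corpus]
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        counts: Counter[tuple[str, str]] = Counter()
        for seq in seqs:
            counts.update(zip(seq, seq[1:]))
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        best = min(p for p, c in counts.items() if c == best_count)
        merges.append(best)
        seqs = [_apply_merge(seq, best) for seq in seqs]
    return merges


def _apply_merge(tokens: Sequence[str], pair: tuple[str, str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(tokens):
        if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) == pair:
            out.append(tokens[i] + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def tokenize_pe(smiles: str, merges: Sequence[tuple[str, str]] | None = None) -> list[str]:
    """Pair-encoding tokenization of a SMILES string.

    Without merges this is the deterministic atom-level split (the
    fallback pattern set); with merges, each learned pair is applied in
    order.  The concatenation of the returned tokens equals the input.
    """
    tokens = tokenize_smiles(smiles)
    for pair in merges or ():
        tokens = _apply_merge(tokens, pair)
    return tokens
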