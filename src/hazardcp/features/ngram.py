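"""Dictionary-based N-gram hashing of SMILES and related string encodings.

Every character of the input string is mapped to a fixed 3-digit code from
a printed dictionary; each sliding window of ``n`` consecutive characters
is turned into one decimal integer by concatenating its codes left to
right ('abcd' -> 101102103104), reduced modulo the hash length, and the
resulting position's count incremented.  Windows advance one character at
a time, so a length-L string emits ``max(0, L - n + 1)`` grams.

The token-level variant does the same over multi-character tokens using a
persisted token dictionary with fixed-width codes, which keeps the decimal
concatenation injective.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NGRAM_DICTIONARY",
    "FeaturizationError",
    "encode_window",
    "encode_ngram_counts",
    "TokenDictionary",
    "encode_token_ngrams",
]


def _build_dictionary() -> dict[str, int]:
    d: dict[str, int] = {}
    for i, c in enumerate("abcdefghijklmnopqrstuvwxyz"):
        d[c] = 101 + i
    for i, c in enumerate("ABCDEFGHIJKLMNOPQRSTUVWXYZ"):
        d[c] = 127 + i
    for i, c in enumerate([" ", "\\", "/", ".", "[", "]", "(", ")", "=", "#", "@"]):
        d[c] = 153 + i
    for i, c in enumerate("0123456789"):
        d[c] = 164 + i
    for i, c in enumerate("+-%|"):
        d[c] = 174 + i
    return d


#: character -> 3-digit code; covers every character the canonical SMILES
#: writer can emit (lower/upper-case letters, digits, ring/branch/bond
#: punctuation, charge signs, '%' multi-digit ring closures).
NGRAM_DICTIONARY: dict[str, int] = _build_dictionary()


class FeaturizationError(ValueError):
    """Raised when a string or molecule cannot be featurized."""


def encode_window(chars: str, dictionary: Mapping[str, int] | None = None) -> int:
    """Decimal concatenation code of one window of characters.

    Codes are concatenated left to right into a single arbitrary-precision
    integer, e.g. 'abcd' -> 101102103104.
    """
    d = NGRAM_DICTIONARY if dictionary is None else dictionary
    parts = []
    for pos, c in enumerate(chars):
        if c not in d:
            raise FeaturizationError(
                f"character {c!r} at position {pos} is not in the N-gram dictionary"
            )
        parts.append(str(d[c]))
    return int("".join(parts))


def encode_ngram_counts(
    s: str,
    n: int = 4,
    hash_len: int = 1024,
    dictionary: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Hashed N-gram count vector of a string.

    Slides a window of ``n`` characters one position at a time from the
    start to the end of ``s``; each window's concatenation code modulo
    ``hash_len`` gives the vector position to increment.  Strings shorter
    than ``n`` yield the zero vector (no complete window exists).

    Raises :class:`FeaturizationError` naming the character and position
    if ``s`` contains a character outside the dictionary.
    """
    d = NGRAM_DICTIONARY if dictionary is None else dictionary
    for pos, c in enumerate(s):
        if c not in d:
            raise FeaturizationError(
                f"character {c!r} at position {pos} is not in the N-gram dictionary"
            )
    vec = np.zeros(hash_len, dtype=np.int64)
    for i in range(len(s) - n + 1):
        vec[encode_window(s[i : i + n], d) % hash_len] += 1
    return vec


class TokenDictionary:
    """Stable token -> fixed-width integer code mapping for token N-grams.

    Codes are assigned in first-seen order starting at ``10**(width-1) + 1``
    (4-digit codes 1001, 1002, ... by default), so every code has exactly
    ``width`` digits and no leading zero — the property that makes decimal
    concatenation of token codes injective.  The mapping is persisted with
    a fitted model via :meth:`to_dict` / :meth:`from_dict`.
    """

    def __init__(self, width: int = 4, mapping: Mapping[str, int] | None = None):
        self.width = width
        self._codes: dict[str, int] = dict(mapping) if mapping else {}
        for tok, code in self._codes.items():
            if len(str(code)) != width:
                raise FeaturizationError(
                    f"token {tok!r} has code {code} not of width {width}"
                )

    @property
    def _next_code(self) -> int:
        return 10 ** (self.width - 1) + 1 + len(self._codes)

    def code(self, token: str) -> int:
        """Code for a token, assigning the next free code on first sight."""
        if token not in self._codes:
            nxt = self._next_code
            if nxt >= 10**self.width:
                raise FeaturizationError(
                    f"token dictionary overflow: width {self.width} exhausted"
                )
            self._codes[token] = nxt
        return self._codes[token]

    def __len__(self) -> int:
        return len(self._codes)

    def __contains__(self, token: str) -> bool:
        return token in self._codes

    def to_dict(self) -> dict[str, int]:
        return dict(self._codes)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, int], width: int = 4) -> "TokenDictionary":
        return cls(width=width, mapping=mapping)


def encode_token_ngrams(
    tokens: Sequence[str],
    n: int = 4,
    hash_len: int = 1024,
    token_dict: TokenDictionary | Mapping[str, int] | None = None,
) -> np.ndarray:
    """Hashed N-gram counts over a token sequence.

    Mirrors :func:`encode_ngram_counts` with tokens in place of characters:
    windows of ``n`` consecutive token codes are concatenated decimally and
    reduced modulo ``hash_len``.  Fewer than ``n`` tokens yield the zero
    vector.  Passing a plain character mapping (e.g. the N-gram dictionary
    itself) as ``token_dict`` with single-character tokens reproduces the
    character-level encoder exactly.
    """
    if token_dict is None:
        token_dict = TokenDictionary()
    vec = np.zeros(hash_len, dtype=np.int64)
    if isinstance(token_dict, TokenDictionary):
        codes = [token_dict.code(t) for t in tokens]
    else:
        try:
            codes = [token_dict[t] for t in tokens]
        except KeyError as exc:
            raise FeaturizationError(f"token {exc.args[0]!r} not in token dictionary")
    for i in range(len(codes) - n + 1):
        window = int("".join(str(c) for c in codes[i : i + n]))
        vec[window % hash_len] += 1
    return vec
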