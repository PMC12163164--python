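"""Self-referencing bracket-token encoding of molecules (SELFIES-style).

Every symbol of the encoding is one bracketed token, and branch and ring
information is carried *inside* tokens rather than by matched delimiters,
which is what makes the format robust to local edits:

* ``[C]``, ``[=O]``, ``[c]``, ``[Cl]`` — an atom with its preceding bond
  symbol; bracket atoms of the source SMILES keep their content, e.g.
  ``[Na+1]`` stays ``[Na+1]`` and ``[C@@H]`` becomes ``[C@@H]``.
* ``[BranchK]`` — the next ``K`` tokens form a branch; after the branch
  the attachment point returns to the current atom.  Nested branches are
  counted inside ``K``.
* ``[RingN]`` (or ``[=RingN]`` etc.) — a ring bond from the current atom
  to the atom ``N`` steps back along the traversal path.

The emitted text uses only characters of the SMILES N-gram dictionary, so
encoded molecules feed the same character-level k-merizer.  The decoder
reconstructs a SMILES string; encode -> decode -> encode is a fixed point.
"""

from __future__ import annotations

import re

from ._moltree import AtomNode, parse_smiles, tree_to_smiles
from .ngram import FeaturizationError

__all__ = ["transform_selfies", "decode_selfies", "selfies_tokens"]

_TOKEN_RE = re.compile(r"\[([^\[\]]*)\]")
_BRANCH_RE = re.compile(r"^Branch(\d+)$")
_RING_RE = re.compile(r"^([-=#:/\\~]?)Ring(\d+)$")


def _atom_token(node: AtomNode) -> str:
    inner = node.token[1:-1] if node.token.startswith("[") else node.token
    return f"[{node.bond}{inner}]"


def transform_selfies(smiles: str) -> str:
    """Encode a SMILES string as a bracket-token string."""
    roots = parse_smiles(smiles)
    out: list[str] = []

    def emit(node: AtomNode, path: list[AtomNode]) -> list[str]:
        path = path + [node]
        tokens = [_atom_token(node)]
        for opener, bond in node.rings:
            for i in range(len(path) - 1, -1, -1):
                if path[i] is opener:
                    tokens.append(f"[{bond}Ring{len(path) - 1 - i}]")
                    break
            else:
                raise FeaturizationError("ring bond crosses a fragment boundary")
        for child in node.children[:-1]:
            branch = emit(child, path)
            tokens.append(f"[Branch{len(branch)}]")
            tokens.extend(branch)
        if node.children:
            tokens.extend(emit(node.children[-1], path))
        return tokens

    for i, root in enumerate(roots):
        if i:
            out.append(".")
        out.extend(emit(root, []))
    return "".join(out)


def selfies_tokens(s: str) -> list[str]:
    """Split an encoded string into its bracket tokens ('.' separates fragments)."""
    tokens = []
    pos = 0
    while pos < len(s):
        if s[pos] == ".":
            tokens.append(".")
            pos += 1
            continue
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise FeaturizationError(f"malformed token stream at position {pos} in {s!r}")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def decode_selfies(s: str) -> str:
    """Decode a bracket-token string back to SMILES."""
    tokens = selfies_tokens(s)
    roots: list[AtomNode] = []

    def read(tokens: list[str], start: int, stop: int,
             stack: list[AtomNode], attach_root: bool) -> None:
        pos = start
        while pos < stop:
            tok = tokens[pos]
            if tok == ".":
                stack.clear()
                pos += 1
                continue
            inner = tok[1:-1]
            m = _BRANCH_RE.match(inner)
            if m:
                k = int(m.group(1))
                if pos + 1 + k > stop:
                    raise FeaturizationError(f"branch of {k} tokens overruns the string")
                read(tokens, pos + 1, pos + 1 + k, list(stack), False)
                pos += 1 + k
                continue
            m = _RING_RE.match(inner)
            if m:
                bond, n = m.group(1), int(m.group(2))
                if not stack or n < 1 or n >= len(stack):
                    raise FeaturizationError(f"ring reference {n} impossible here")
                stack[-1].rings.append((stack[-1 - n], bond))
                pos += 1
                continue
            bond = inner[0] if inner and inner[0] in "-=#:/\\~" else ""
            body = inner[len(bond):]
            # multi-character organic-subset atoms and bracket atoms
            if re.fullmatch(r"[A-Za-z*]|Cl|Br", body):
                token = body
            else:
                token = f"[{body}]"
            node = AtomNode(token=token, bond=bond)
            if stack:
                stack[-1].children.append(node)
            elif attach_root:
                roots.append(node)
            else:
                raise FeaturizationError("branch may not start a new fragment")
            stack.append(node)
            pos += 1

    read(tokens, 0, len(tokens), [], True)
    return tree_to_smiles(roots)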