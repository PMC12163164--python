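"""Parenthesis-free rewriting of SMILES (DeepSMILES-style), own codec.

The encoding removes the two redundancies of SMILES syntax:

* **Branches** — open parentheses are dropped; each branch is terminated
  by as many ``)`` symbols as atoms remain on the traversal path inside
  it, so a single ``)`` steps the attachment point back one atom
  (``CC(=O)O`` -> ``CC=O)O``; ``C(C(C)C)C`` -> ``CCC)C))C``).
* **Rings** — the paired ring-closure digits are replaced by a single
  number at the closing atom giving the ring size, i.e. how many atoms
  back along the current path the partner sits plus one
  (``c1ccccc1`` -> ``cccccc6``).  Sizes above 9 use ``%NN``.

Both rewrites are enabled, matching the variant used for N-gram
featurization.  The output alphabet is a subset of the SMILES N-gram
dictionary, so encoded strings feed the same character-level k-merizer.
"""

from __future__ import annotations

from ._moltree import AtomNode, parse_smiles, tree_to_smiles
from .ngram import FeaturizationError
from .pe import tokenize_smiles
from ._moltree import BOND_CHARS

__all__ = ["transform_deepsmiles", "decode_deepsmiles"]


def _fmt_size(size: int) -> str:
    if size <= 9:
        return str(size)
    if size <= 99:
        return f"%{size:02d}"
    raise FeaturizationError(f"ring size {size} not representable")


def transform_deepsmiles(smiles: str) -> str:
    """Encode a SMILES string into its parenthesis-free form."""
    roots = parse_smiles(smiles)
    out: list[str] = []

    def depth_of(node: AtomNode, path: list[AtomNode]) -> int:
        # index of node in the current path (it is always an ancestor)
        for i in range(len(path) - 1, -1, -1):
            if path[i] is node:
                return i
        raise FeaturizationError("ring bond crosses a fragment boundary")

    def emit(node: AtomNode, path: list[AtomNode]) -> int:
        """Serialize node's subtree; return atoms left on the path."""
        path = path + [node]
        out.append(node.bond + node.token)
        for opener, bond in node.rings:
            size = len(path) - 1 - depth_of(opener, path)
            out.append(bond + _fmt_size(size + 1))
        for child in node.children[:-1]:
            out.append(")" * emit(child, path))
        if node.children:
            return 1 + emit(node.children[-1], path)
        return 1

    for i, root in enumerate(roots):
        if i:
            out.append(".")
        emit(root, [])
    return "".join(out)


def decode_deepsmiles(s: str) -> str:
    """Decode the parenthesis-free form back to a SMILES string.

    Round-trips through :func:`transform_deepsmiles` to a SMILES of the
    same molecule (modulo canonical rewriting).
    """
    roots: list[AtomNode] = []
    stack: list[AtomNode] = []
    pending = ""
    for tok in tokenize_smiles(s):
        if tok == ")":
            if not stack:
                raise FeaturizationError(f"')' with empty path in {s!r}")
            stack.pop()
        elif tok in BOND_CHARS:
            pending = tok
        elif tok == ".":
            stack = []
            pending = ""
        elif tok.isdigit() or tok.startswith("%"):
            size = int(tok.lstrip("%"))
            if size < 3 or size > len(stack):
                raise FeaturizationError(f"ring size {size} impossible at this point in {s!r}")
            stack[-1].rings.append((stack[-size], pending))
            pending = ""
        elif tok == "(":
            raise FeaturizationError(f"'(' is not part of the encoding: {s!r}")
        else:
            node = AtomNode(token=tok, bond=pending)
            pending = ""
            if stack:
                stack[-1].children.append(node)
            else:
                roots.append(node)
            stack.append(node)
    return tree_to_smiles(roots)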