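"""Internal SMILES <-> spanning-tree machinery for the string codecs.

A SMILES string is a depth-first traversal of a molecular graph: atoms in
pre-order, parentheses marking branch excursions, and matched ring-closure
digits marking the back edges.  Both alternative string encodings in this
package (the parenthesis-free ring/branch rewriting and the bracket-token
encoding) are different serializations of that same spanning tree, so they
share this parser and the tree -> SMILES writer.

Only the syntax the RDKit canonical writer emits is supported; ring bonds
crossing a '.' fragment separator are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ngram import FeaturizationError
from .pe import tokenize_smiles

BOND_CHARS = frozenset("-=#:/\\~")


@dataclass
class AtomNode:
    """One atom of the traversal tree.

    ``bond`` is the bond symbol written before this atom ('' for a default
    single/aromatic bond); ``rings`` holds back edges closing at this atom
    as (opening_node, bond_symbol) pairs.
    """

    token: str
    bond: str = ""
    children: list["AtomNode"] = field(default_factory=list)
    rings: list[tuple["AtomNode", str]] = field(default_factory=list)


def parse_smiles(smiles: str) -> list[AtomNode]:
    """Parse a SMILES string into one traversal tree per fragment."""
    roots: list[AtomNode] = []
    stack: list[AtomNode] = []
    marks: list[int] = []
    ring_open: dict[str, tuple[AtomNode, str]] = {}
    pending = ""

    for tok in tokenize_smiles(smiles):
        if tok == "(":
            marks.append(len(stack))
        elif tok == ")":
            if not marks:
                raise FeaturizationError(f"unmatched ')' in {smiles!r}")
            del stack[marks.pop() :]
        elif tok in BOND_CHARS:
            pending = tok
        elif tok == ".":
            if marks:
                raise FeaturizationError(f"'.' inside a branch in {smiles!r}")
            stack = []
            pending = ""
        elif tok.isdigit() or tok.startswith("%"):
            label = tok.lstrip("%")
            if not stack:
                raise FeaturizationError(f"ring closure before any atom in {smiles!r}")
            if label in ring_open:
                opener, obond = ring_open.pop(label)
                stack[-1].rings.append((opener, pending or obond))
            else:
                ring_open[label] = (stack[-1], pending)
            pending = ""
        else:
            node = AtomNode(token=tok, bond=pending)
            pending = ""
            if stack:
                stack[-1].children.append(node)
            else:
                roots.append(node)
            stack.append(node)
    if ring_open:
        raise FeaturizationError(f"unclosed ring bond(s) in {smiles!r}")
    return roots


def tree_to_smiles(roots: list[AtomNode]) -> str:
    """Serialize traversal trees back to a SMILES string.

    Ring-closure numbers are allocated by sweeping atoms in DFS pre-order:
    a number is in use from its opening atom to its closing atom and may be
    reused afterwards (but not at the closing atom itself, which would be
    ambiguous).
    """
    dfs_order: list[AtomNode] = []

    def collect(node: AtomNode) -> None:
        dfs_order.append(node)
        for child in node.children:
            collect(child)

    for root in roots:
        collect(root)

    def fmt(num: int) -> str:
        if num <= 9:
            return str(num)
        if num <= 99:
            return f"%{num:02d}"
        raise FeaturizationError("more than 99 concurrently open ring bonds")

    open_digits: dict[int, list[str]] = {}
    close_digits: dict[int, list[str]] = {}
    opens_at: dict[int, list[tuple[AtomNode, str]]] = {}
    for node in dfs_order:
        for opener, bond in node.rings:
            opens_at.setdefault(id(opener), []).append((node, bond))

    free_numbers: list[int] = []
    next_number = 1
    active: dict[tuple[int, int], int] = {}  # (opener id, closer id) -> number
    for node in dfs_order:
        freed: list[int] = []
        for key, num in [(k, v) for k, v in active.items() if k[1] == id(node)]:
            freed.append(num)
            del active[key]
        for closer, bond in opens_at.get(id(node), []):
            if free_numbers:
                num = free_numbers.pop()
            else:
                num = next_number
                next_number += 1
            active[(id(node), id(closer))] = num
            open_digits.setdefault(id(node), []).append(fmt(num))
            close_digits.setdefault(id(closer), []).append(bond + fmt(num))
        free_numbers.extend(freed)  # reusable from the next atom on

    def serialize(node: AtomNode) -> str:
        out = node.bond + node.token
        out += "".join(open_digits.get(id(node), []))
        out += "".join(close_digits.get(id(node), []))
        for child in node.children[:-1]:
            out += "(" + serialize(child) + ")"
        if node.children:
            out += serialize(node.children[-1])
        return out

    return ".".join(serialize(root) for root in roots)
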