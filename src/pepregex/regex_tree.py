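"""Evolvable regular expressions as array-backed binary trees.

A pattern is a binary tree over seven operators — concatenation,
alternation ``|``, the ``+`` quantifier, a fixed repetition count ``{n}``,
character class ``[...]``, negated character class ``[^...]`` and grouping
``(...)`` — with leaves holding short runs of amino-acid letters.  The
tree is stored in the implicit-array layout where the children of node
``i`` sit at ``2i + 1`` and ``2i + 2``; unexpressed slots are ``None``.
Maximal depth is 6, which bounds rendered patterns to a size that is
cheap to match against 10-13-residue peptides.

The module provides random generation (full / grow, and the ramped
half-and-half initialisation), rendering to a compilable pattern string,
structural validation, leftmost-longest non-overlapping match extraction,
and the four tree-level mutation operators (branch replacement, node
inversion, subtree deletion, leaf extension).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .peptide_data import AMINO_ACIDS

MAX_DEPTH = 6
ARRAY_SIZE = 2 ** MAX_DEPTH - 1
REPEAT_RANGE = (2, 6)  # repetition counts for {n}, mirrors the MDB window sizes
LEAF_MAX_LEN = 6


class NodeKind(str, Enum):
    CONCAT = "CONCAT"
    ALT = "ALT"
    PLUS = "PLUS"
    REPEAT = "REPEAT"
    CLASS = "CLASS"
    NCLASS = "NCLASS"
    GROUP = "GROUP"
    LEAF = "LEAF"


ARITY = {
    NodeKind.CONCAT: 2,
    NodeKind.ALT: 2,
    NodeKind.PLUS: 1,
    NodeKind.REPEAT: 1,
    NodeKind.CLASS: 1,
    NodeKind.NCLASS: 1,
    NodeKind.GROUP: 1,
    NodeKind.LEAF: 0,
}

_INTERNAL_KINDS = [k for k in NodeKind if k is not NodeKind.LEAF]


@dataclass(frozen=True)
class RegexNode:
    """One tree node: an operator, or a leaf holding 1-6 AA letters.

    ``payload`` is the letter run for LEAF nodes, the repetition count for
    REPEAT nodes, and None otherwise.
    """

    kind: NodeKind
    payload: str | int | None = None


@dataclass
class RegexTree:
    """Implicit-array binary tree; index i parents (2i+1, 2i+2)."""

    nodes: list[RegexNode | None]

    @classmethod
    def empty(cls) -> "RegexTree":
        return cls(nodes=[None] * ARRAY_SIZE)

    @classmethod
    def leaf(cls, payload: str) -> "RegexTree":
        t = cls.empty()
        t.nodes[0] = RegexNode(NodeKind.LEAF, payload)
        return t

    def copy(self) -> "RegexTree":
        return RegexTree(nodes=list(self.nodes))

    def expressed_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n is not None]

    def depth(self) -> int:
        d = 0
        for i in self.expressed_indices():
            d = max(d, _level(i))
        return d

    def subtree_indices(self, root: int) -> list[int]:
        """Indices of the expressed nodes in the subtree rooted at ``root``."""
        out = []
        stack = [root]
        while stack:
            i = stack.pop()
            if i < ARRAY_SIZE and self.nodes[i] is not None:
                out.append(i)
                stack.extend((2 * i + 1, 2 * i + 2))
        return out

    @property
    def pattern(self) -> str:
        return render(self)

    def serialize(self) -> str:
        """Compact text form: ``index:kind:payload`` triples joined by ';'."""
        parts = []
        for i in self.expressed_indices():
            node = self.nodes[i]
            payload = "" if node.payload is None else str(node.payload)
            parts.append(f"{i}:{node.kind.value}:{payload}")
        return ";".join(parts)

    @classmethod
    def deserialize(cls, text: str) -> "RegexTree":
        t = cls.empty()
        for part in text.split(";"):
            idx_s, kind_s, payload_s = part.split(":")
            kind = NodeKind(kind_s)
            payload: str | int | None
            if kind is NodeKind.LEAF:
                payload = payload_s
            elif kind is NodeKind.REPEAT:
                payload = int(payload_s)
            else:
                payload = None
            t.nodes[int(idx_s)] = RegexNode(kind, payload)
        return t


def _level(index: int) -> int:
    """1-based depth level of an array index (root is level 1)."""
    return (index + 1).bit_length()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_letters(rng, k: int, distinct: bool = False) -> str:
    if distinct:
        idx = rng.choice(len(AMINO_ACIDS), size=k, replace=False)
        return "".join(AMINO_ACIDS[i] for i in idx)
    return "".join(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(k))


def _random_leaf(rng, charset: bool = False) -> RegexNode:
    if charset:
        # character-set leaf: 1-5 distinct letters
        k = int(rng.integers(1, 6))
        return RegexNode(NodeKind.LEAF, _random_letters(rng, k, distinct=True))
    k = int(rng.integers(1, 4))  # literal runs kept short
    return RegexNode(NodeKind.LEAF, _random_letters(rng, k))


def _fill(tree: RegexTree, index: int, budget: int, mode: str, rng) -> None:
    if budget == 1:
        tree.nodes[index] = _random_leaf(rng)
        return
    if mode == "grow":
        # uniform over {leaf} + the 7 operators, standard grow initialisation
        pick = int(rng.integers(len(NodeKind)))
        kind = list(NodeKind)[pick]
        if kind is NodeKind.LEAF:
            tree.nodes[index] = _random_leaf(rng)
            return
    else:
        # full mode drives every path to the depth limit; class nodes
        # terminate one level down, so they are only eligible at budget 2
        pool = (
            _INTERNAL_KINDS
            if budget == 2
            else [
                k
                for k in _INTERNAL_KINDS
                if k not in (NodeKind.CLASS, NodeKind.NCLASS)
            ]
        )
        kind = pool[int(rng.integers(len(pool)))]
    left, right = 2 * index + 1, 2 * index + 2
    if kind in (NodeKind.CONCAT, NodeKind.ALT):
        tree.nodes[index] = RegexNode(kind)
        _fill(tree, left, budget - 1, mode, rng)
        _fill(tree, right, budget - 1, mode, rng)
    elif kind in (NodeKind.CLASS, NodeKind.NCLASS):
        # the child of a (negated) class is a character-set leaf
        tree.nodes[index] = RegexNode(kind)
        tree.nodes[left] = _random_leaf(rng, charset=True)
    elif kind is NodeKind.REPEAT:
        count = int(rng.integers(REPEAT_RANGE[0], REPEAT_RANGE[1] + 1))
        tree.nodes[index] = RegexNode(kind, count)
        _fill(tree, left, budget - 1, mode, rng)
    else:  # PLUS, GROUP
        tree.nodes[index] = RegexNode(kind)
        _fill(tree, left, budget - 1, mode, rng)


def generate_tree(max_depth: int, mode: str, rng) -> RegexTree:
    """Random valid tree of depth <= ``max_depth``.

    ``mode='full'`` places leaves only at the depth limit; ``mode='grow'``
    may stop early at any node.
    """
    if not 1 <= max_depth <= MAX_DEPTH:
        raise ValueError(f"max_depth must be in [1, {MAX_DEPTH}], got {max_depth}")
    if mode not in ("full", "grow"):
        raise ValueError(f"mode must be 'full' or 'grow', got {mode!r}")
    tree = RegexTree.empty()
    _fill(tree, 0, max_depth, mode, rng)
    return tree


def ramped_half_and_half(
    n: int, depth_range: tuple[int, int] = (2, MAX_DEPTH), rng=None
) -> list[RegexTree]:
    """``n`` trees with depths cycling over ``depth_range``, alternating
    grow and full generation — the classic heterogeneous initialisation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d_min, d_max = depth_range
    n_depths = d_max - d_min + 1
    trees = []
    for i in range(n):
        depth = d_min + (i // 2) % n_depths
        mode = "grow" if i % 2 == 0 else "full"
        trees.append(generate_tree(depth, mode, rng))
    return trees


# ---------------------------------------------------------------------------
# rendering / validation
# ---------------------------------------------------------------------------

def _collect_leaf_letters(tree: RegexTree, index: int) -> str:
    """In-order concatenation of leaf payloads in a subtree (for classes)."""
    node = tree.nodes[index]
    if node is None:
        return ""
    if node.kind is NodeKind.LEAF:
        return str(node.payload)
    return _collect_leaf_letters(tree, 2 * index + 1) + _collect_leaf_letters(
        tree, 2 * index + 2
    )


def _emit(tree: RegexTree, index: int) -> str:
    node = tree.nodes[index]
    if node is None:
        raise ValueError(f"missing node at index {index}")
    left, right = 2 * index + 1, 2 * index + 2
    kind = node.kind
    if kind is NodeKind.LEAF:
        return str(node.payload)
    if kind is NodeKind.CONCAT:
        return _emit(tree, left) + _emit(tree, right)
    if kind is NodeKind.ALT:
        return f"({_emit(tree, left)}|{_emit(tree, right)})"
    if kind is NodeKind.PLUS:
        return _quantifiable(_emit(tree, left)) + "+"
    if kind is NodeKind.REPEAT:
        return _quantifiable(_emit(tree, left)) + "{%d}" % node.payload
    if kind is NodeKind.CLASS:
        return f"[{_collect_leaf_letters(tree, left)}]"
    if kind is NodeKind.NCLASS:
        return f"[^{_collect_leaf_letters(tree, left)}]"
    if kind is NodeKind.GROUP:
        return f"({_emit(tree, left)})"
    raise AssertionError(kind)


def _quantifiable(sub: str) -> str:
    # stacked quantifiers ("K+{2}", "K{2}{3}") are not valid patterns;
    # parenthesise the operand when it already ends in a quantifier
    if sub.endswith("+") or sub.endswith("}"):
        return f"({sub})"
    return sub


def render(tree: RegexTree) -> str:
    """Deterministic in-order emission of the pattern string."""
    if tree.nodes[0] is None:
        raise ValueError("cannot render a tree without a root")
    return _emit(tree, 0)


_compiled_cache: dict[str, re.Pattern] = {}


def compile_pattern(pattern: str) -> re.Pattern:
    """Compile with an unbounded cache (the stdlib cache is too small for
    an evolving population of patterns)."""
    cre = _compiled_cache.get(pattern)
    if cre is None:
        cre = re.compile(pattern)
        _compiled_cache[pattern] = cre
    return cre


def validate(tree: RegexTree) -> list[str]:
    """Structural and semantic checks; returns a list of violations
    (empty when the tree is valid)."""
    violations: list[str] = []
    if len(tree.nodes) != ARRAY_SIZE:
        violations.append(f"array size {len(tree.nodes)} != {ARRAY_SIZE}")
        return violations
    if tree.nodes[0] is None:
        violations.append("root absent")
        return violations
    for i in tree.expressed_indices():
        node = tree.nodes[i]
        if _level(i) > MAX_DEPTH:
            violations.append(f"node {i} exceeds max depth {MAX_DEPTH}")
        if i != 0:
            parent = tree.nodes[(i - 1) // 2]
            if parent is None:
                violations.append(f"node {i} has no expressed parent")
                continue
        left = 2 * i + 1
        right = 2 * i + 2
        has_left = left < ARRAY_SIZE and tree.nodes[left] is not None
        has_right = right < ARRAY_SIZE and tree.nodes[right] is not None
        arity = ARITY[node.kind]
        if arity == 2 and not (has_left and has_right):
            violations.append(f"arity: {node.kind.value} node {i} needs 2 children")
        if arity == 1 and not has_left:
            violations.append(f"arity: {node.kind.value} node {i} needs a child")
        if arity == 1 and has_right:
            violations.append(
                f"arity: {node.kind.value} node {i} must not have a right child"
            )
        if arity == 0 and (has_left or has_right):
            violations.append(f"arity: LEAF node {i} must not have children")
        if node.kind is NodeKind.LEAF:
            payload = node.payload
            if (
                not isinstance(payload, str)
                or not 1 <= len(payload) <= LEAF_MAX_LEN
                or any(c not in AMINO_ACIDS for c in payload)
            ):
                violations.append(f"leaf payload: node {i} has {payload!r}")
        elif node.kind is NodeKind.REPEAT:
            if (
                not isinstance(node.payload, int)
                or not REPEAT_RANGE[0] <= node.payload <= REPEAT_RANGE[1]
            ):
                violations.append(f"repeat range: node {i} has {node.payload!r}")
        elif node.payload is not None:
            violations.append(f"payload: {node.kind.value} node {i} must be empty")
    if violations:
        return violations
    try:
        cre = compile_pattern(render(tree))
    except re.error as exc:
        violations.append(f"pattern does not compile: {exc}")
        return violations
    if cre.search("") is not None:
        violations.append("pattern matches the empty string")
    return violations


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def extract_matches(tree: RegexTree, sequence: str) -> list[str]:
    """All leftmost-longest non-overlapping matches, scanning left to
    right; empty list when the pattern never matches."""
    return extract_matches_pattern(render(tree), sequence)


def extract_matches_pattern(pattern: str, sequence: str) -> list[str]:
    cre = compile_pattern(pattern)
    out: list[str] = []
    i = 0
    n = len(sequence)
    while i < n:
        m = cre.search(sequence, i)
        if m is None:
            break
        start = m.start()
        # longest match anchored at the leftmost feasible start
        end = n
        while end > start:
            if cre.fullmatch(sequence, start, end):
                break
            end -= 1
        if end == start:  # cannot happen for non-empty-matching patterns
            end = m.end()
        out.append(sequence[start:end])
        i = end
    return out


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

MUTATION_KINDS = ("replace_branch", "invert_node", "delete_subtree", "add_leaf_aa")


def _clear_subtree(tree: RegexTree, root: int) -> None:
    for i in tree.subtree_indices(root):
        tree.nodes[i] = None


def _graft(tree: RegexTree, root: int, sub: RegexTree) -> None:
    """Write ``sub`` (rooted at 0) into ``tree`` at array position ``root``."""
    mapping = [(0, root)]
    while mapping:
        src, dst = mapping.pop()
        node = sub.nodes[src] if src < ARRAY_SIZE else None
        if node is None:
            continue
        tree.nodes[dst] = node
        mapping.append((2 * src + 1, 2 * dst + 1))
        mapping.append((2 * src + 2, 2 * dst + 2))


def mutate_tree(tree: RegexTree, kind: str, rng) -> tuple[RegexTree, bool]:
    """Apply one tree-level mutation; returns (tree, applied).

    ``replace_branch`` swaps a uniformly chosen subtree for a freshly
    grown one within the remaining depth budget; ``invert_node`` flips
    CONCAT<->ALT or CLASS<->NCLASS, resamples a LEAF letter, or resamples
    a REPEAT count; ``delete_subtree`` replaces a subtree by a fresh
    random leaf; ``add_leaf_aa`` appends 1-4 random letters to a leaf
    (payload capped at 6).  When the requested kind is inapplicable the
    input is returned unchanged with ``applied=False``.
    """
    if kind not in MUTATION_KINDS:
        raise ValueError(f"unknown mutation kind {kind!r}")
    out = tree.copy()
    expressed = out.expressed_indices()

    if kind == "replace_branch":
        target = expressed[int(rng.integers(len(expressed)))]
        budget = MAX_DEPTH - _level(target) + 1
        depth = int(rng.integers(1, budget + 1))
        sub = generate_tree(depth, "grow", rng)
        _clear_subtree(out, target)
        _graft(out, target, sub)
        return out, True

    if kind == "invert_node":
        invertible = [
            i
            for i in expressed
            if out.nodes[i].kind
            in (
                NodeKind.CONCAT,
                NodeKind.ALT,
                NodeKind.CLASS,
                NodeKind.NCLASS,
                NodeKind.REPEAT,
                NodeKind.LEAF,
            )
        ]
        target = invertible[int(rng.integers(len(invertible)))]
        node = out.nodes[target]
        swap = {
            NodeKind.CONCAT: NodeKind.ALT,
            NodeKind.ALT: NodeKind.CONCAT,
            NodeKind.CLASS: NodeKind.NCLASS,
            NodeKind.NCLASS: NodeKind.CLASS,
        }
        if node.kind in swap:
            out.nodes[target] = RegexNode(swap[node.kind], node.payload)
        elif node.kind is NodeKind.REPEAT:
            choices = [
                c
                for c in range(REPEAT_RANGE[0], REPEAT_RANGE[1] + 1)
                if c != node.payload
            ]
            out.nodes[target] = RegexNode(
                NodeKind.REPEAT, choices[int(rng.integers(len(choices)))]
            )
        else:  # LEAF: resample one letter to a different amino acid
            payload = str(node.payload)
            pos = int(rng.integers(len(payload)))
            alternatives = [c for c in AMINO_ACIDS if c != payload[pos]]
            new_letter = alternatives[int(rng.integers(len(alternatives)))]
            out.nodes[target] = RegexNode(
                NodeKind.LEAF, payload[:pos] + new_letter + payload[pos + 1:]
            )
        return out, True

    if kind == "delete_subtree":
        target = expressed[int(rng.integers(len(expressed)))]
        _clear_subtree(out, target)
        out.nodes[target] = _random_leaf(rng)
        return out, True

    # add_leaf_aa
    leaves = [
        i
        for i in expressed
        if out.nodes[i].kind is NodeKind.LEAF
        and len(str(out.nodes[i].payload)) < LEAF_MAX_LEN
    ]
    if not leaves:
        return tree, False
    target = leaves[int(rng.integers(len(leaves)))]
    payload = str(out.nodes[target].payload)
    k = int(rng.integers(1, 5))
    k = min(k, LEAF_MAX_LEN - len(payload))
    out.nodes[target] = RegexNode(
        NodeKind.LEAF, payload + _random_letters(rng, k)
    )
    return out, True
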