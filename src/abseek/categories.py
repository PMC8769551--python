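"""Hierarchical amino-acid ambiguity categories and per-position scoring.

A category is a named subset of the 20 standard residues; categories are
organized in a tree whose root covers the whole alphabet and whose leaves are
single residues.  A position assigned category ``c`` matches residue ``r`` iff
``r`` is a member of ``c``; a match contributes ``1 / |members(c)|`` to the
alignment score, so fully confident (singleton) assignments contribute 1.0 and
the uninformative root contributes 1/20 = 0.05.  Mismatches contribute 0.

The default tree shipped here groups residues by coarse structural class
(side-chain presence, size, branching, rings, hydrophobicity of medium side
chains) — a documented stand-in for any lab-specific assignment scheme; the
scoring machinery depends only on member-set sizes, and
:func:`load_category_tree` accepts a user tree in a simple tabular format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "AminoAcidCategory",
    "CategoryTree",
    "TreeFormatError",
    "TreeValidationError",
    "UnknownCodeError",
    "default_tree",
    "load_category_tree",
]

#: The 20 standard one-letter amino-acid symbols.
STANDARD_AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")


class TreeFormatError(ValueError):
    """A tree-definition file could not be parsed."""


class TreeValidationError(ValueError):
    """A parsed tree violates a structural invariant."""


class UnknownCodeError(KeyError):
    """A category code is not present in the tree."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class AminoAcidCategory:
    """One node of the ambiguity tree.

    Parameters
    ----------
    code:
        Opaque identifier; numeric labels and letter abbreviations are both
        legal.
    members:
        Non-empty subset of the 20 standard residues the category stands for.
    parent_code:
        Code of the parent node, or ``None`` for the root.
    label:
        Optional human-readable name (e.g. ``"medium side chain, hydrophilic"``).
    """

    code: str
    members: frozenset[str]
    parent_code: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise TreeValidationError(f"category {self.code!r} has an empty member set")
        bad = set(self.members) - STANDARD_AMINO_ACIDS
        if bad:
            raise TreeValidationError(
                f"category {self.code!r} contains non-standard residues: {sorted(bad)}"
            )

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CategoryTree:
    """A validated hierarchy of :class:`AminoAcidCategory` nodes.

    Exactly one root whose member set is the full alphabet; every other node's
    parent exists, member sets never widen down an edge, and codes are unique.
    """

    nodes: dict[str, AminoAcidCategory]
    root_code: str
    name: str = "custom"
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {code: [] for code in self.nodes}
        roots = [c for c, n in self.nodes.items() if n.parent_code is None]
        if len(roots) != 1:
            raise TreeValidationError(
                f"tree must have exactly one root, found {len(roots)}: {sorted(roots)}"
            )
        if roots[0] != self.root_code:
            raise TreeValidationError(
                f"declared root {self.root_code!r} does not match parentless node {roots[0]!r}"
            )
        root = self.nodes[self.root_code]
        if root.members != STANDARD_AMINO_ACIDS:
            raise TreeValidationError(
                "root member set must be the full 20-residue alphabet, "
                f"got {len(root.members)} residues"
            )
        for code, node in self.nodes.items():
            if node.parent_code is None:
                continue
            parent = self.nodes.get(node.parent_code)
            if parent is None:
                raise TreeValidationError(
                    f"category {code!r} references missing parent {node.parent_code!r}"
                )
            if not node.members <= parent.members:
                raise TreeValidationError(
                    f"category {code!r} members are not a subset of parent "
                    f"{node.parent_code!r}"
                )
            self._children[node.parent_code].append(code)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # subset validation already forbids most cycles; walk parents to be sure
        for code in self.nodes:
            seen = set()
            cur: str | None = code
            while cur is not None:
                if cur in seen:
                    raise TreeValidationError(f"cycle detected at category {code!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent_code

    # -- queries ------------------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, code: str) -> AminoAcidCategory:
        try:
            return self.nodes[code]
        except KeyError:
            raise UnknownCodeError(f"unknown category code {code!r}") from None

    def children(self, code: str) -> list[str]:
        self.node(code)
        return list(self._children[code])

    def depth(self, code: str) -> int:
        """Edge distance from the root (root has depth 0)."""
        node = self.node(code)
        d = 0
        while node.parent_code is not None:
            node = self.nodes[node.parent_code]
            d += 1
        return d

    def codes_at_depth(self, depth: int) -> list[str]:
        return sorted(c for c in self.nodes if self.depth(c) == depth)

    def max_depth(self) -> int:
        return max(self.depth(c) for c in self.nodes)

    def expand_code(self, code: str) -> frozenset[str]:
        """Full member set of ``code`` (all downstream amino-acid possibilities)."""
        return self.node(code).members

    def position_score(self, code: str) -> float:
        """Per-position match score ``1 / |members|``; in [1/20, 1]."""
        return 1.0 / self.node(code).size

    def contains(self, code: str, residue: str) -> bool:
        """True iff ``residue`` is a member of ``code``.

        Residues outside the 20-letter alphabet (e.g. ``X``) never match.
        Comparison is case-insensitive.
        """
        return residue.upper() in self.node(code).members

    def leaves_for(self, residue: str) -> list[str]:
        """Codes of singleton categories naming ``residue``."""
        r = residue.upper()
        return sorted(
            c for c, n in self.nodes.items() if n.size == 1 and r in n.members
        )


# -- module-level functional API (thin wrappers used throughout) -------------


def expand_code(tree: CategoryTree, code: str) -> frozenset[str]:
    return tree.expand_code(code)


def position_score(tree: CategoryTree, code: str) -> float:
    return tree.position_score(code)


def contains(tree: CategoryTree, code: str, residue: str) -> bool:
    return tree.contains(code, residue)


# -- default tree -------------------------------------------------------------

# Coarse structural classes: glycine alone (no side chain), small side chains,
# beta-branched, medium side chains split by hydrophobicity, long flexible side
# chains (split into basic and amide/acid), and ring-containing side chains
# (split into aromatic and small-ring).  Every residue also gets a singleton
# leaf for fully confident assignments.
_DEFAULT_CLASSES: list[tuple[str, str | None, str, str]] = [
    ("ANY", None, "ACDEFGHIKLMNPQRSTVWY", "any residue (root)"),
    ("NSC", "ANY", "G", "no side chain"),
    ("SML", "ANY", "ACS", "small side chain"),
    ("BRC", "ANY", "ITV", "beta-branched side chain"),
    ("MHB", "ANY", "LM", "medium side chain, hydrophobic"),
    ("MHL", "ANY", "DN", "medium side chain, hydrophilic"),
    ("LNG", "ANY", "EKQR", "long flexible side chain"),
    ("RNG", "ANY", "FHPWY", "ring-containing side chain"),
    ("LNB", "LNG", "KR", "long side chain, basic"),
    ("LNA", "LNG", "EQ", "long side chain, amide/acid"),
    ("ARO", "RNG", "FWY", "aromatic ring"),
    ("SRG", "RNG", "HP", "small ring"),
]

_LEAF_PARENT: dict[str, str] = {
    "G": "NSC",
    "A": "SML", "C": "SML", "S": "SML",
    "I": "BRC", "T": "BRC", "V": "BRC",
    "L": "MHB", "M": "MHB",
    "D": "MHL", "N": "MHL",
    "K": "LNB", "R": "LNB",
    "E": "LNA", "Q": "LNA",
    "F": "ARO", "W": "ARO", "Y": "ARO",
    "H": "SRG", "P": "SRG",
}


def default_tree() -> CategoryTree:
    """The built-in structural-class tree (root, 11 group nodes, 20 leaves)."""
    nodes: dict[str, AminoAcidCategory] = {}
    for code, parent, members, label in _DEFAULT_CLASSES:
        nodes[code] = AminoAcidCategory(code, frozenset(members), parent, label)
    for residue, parent in _LEAF_PARENT.items():
        nodes[residue] = AminoAcidCategory(
            residue, frozenset(residue), parent, f"residue {residue}"
        )
    return CategoryTree(nodes=nodes, root_code="ANY", name="default")


# -- tree-definition file ------------------------------------------------------
#
# Plain text, one node per line, tab- or comma-separated fields:
#
#     code <sep> parent <sep> members <sep> label
#
# ``parent`` is empty for the root; ``members`` is a string of one-letter
# residues; ``label`` is optional.  Lines starting with '#' and blank lines are
# ignored.


def _split_fields(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(sep)]


def load_category_tree(path: str | Path | None = None) -> CategoryTree:
    """Load a tree definition file, or return the built-in default tree.

    Raises
    ------
    TreeFormatError
        On a malformed line (names the line number).
    TreeValidationError
        On structural violations (duplicate code, missing parent, empty or
        non-subset member set, cycle, bad root).
    """
    if path is None:
        return default_tree()
    path = Path(path)
    nodes: dict[str, AminoAcidCategory] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise TreeFormatError(
                    f"{path}:{lineno}: expected at least 3 fields "
                    f"(code, parent, members), got {len(fields)}"
                )
            code, parent, members = fields[0], fields[1], fields[2].upper()
            label = fields[3] if len(fields) > 3 else ""
            if not code:
                raise TreeFormatError(f"{path}:{lineno}: empty category code")
            if code in nodes:
                raise TreeValidationError(
                    f"{path}:{lineno}: duplicate category code {code!r}"
                )
            try:
                nodes[code] = AminoAcidCategory(
                    code, frozenset(members), parent or None, label
                )
            except TreeValidationError as exc:
                raise TreeValidationError(f"{path}:{lineno}: {exc}") from None
    if not nodes:
        raise TreeFormatError(f"{path}: no category records found")
    roots = [c for c, n in nodes.items() if n.parent_code is None]
    if len(roots) != 1:
        raise TreeValidationError(
            f"{path}: expected exactly one root record, found {len(roots)}"
        )
    return CategoryTree(nodes=nodes, root_code=roots[0], name=path.stem)


def write_category_tree(tree: CategoryTree, path: str | Path) -> None:
    """Serialize ``tree`` in the tabular format :func:`load_category_tree` reads."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# code\tparent\tmembers\tlabel\n")
        order = _breadth_first(tree)
        for code in order:
            node = tree.nodes[code]
            fh.write(
                f"{code}\t{node.parent_code or ''}\t"
                f"{''.join(sorted(node.members))}\t{node.label}\n"
            )


def _breadth_first(tree: CategoryTree) -> Iterable[str]:
    queue = [tree.root_code]
    while queue:
        code = queue.pop(0)
        yield code
        queue.extend(sorted(tree.children(code)))
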