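"""Ultrametric time trees: parsing, validation, pruning, and clade-age queries.

Trees are consumed with divergence times already estimated (e.g. from a
relaxed-clock analysis); node ages are expressed in Ma before present, with
the deepest tip defining the present (age 0).  Newick I/O is delegated to
dendropy; this module adds the age bookkeeping the downstream range
reconstruction needs and enforces the invariants it relies on.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy

__all__ = [
    "TimeTree",
    "CladeAges",
    "UltrametricReport",
    "NewickParseError",
    "parse_newick",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be turned into a valid TimeTree."""


@dataclass(frozen=True)
class CladeAges:
    """Stem and crown ages (Ma) of a clade.

    ``stem`` is the age of the clade MRCA's parent node (None for the root,
    whose stem is undefined); ``crown`` is the age of the MRCA itself.
    """

    clade: frozenset
    stem: Optional[float]
    crown: float

    def __post_init__(self):
        if self.stem is not None and self.stem < self.crown - 1e-12:
            raise ValueError(
                f"stem age {self.stem} < crown age {self.crown} for {sorted(self.clade)}"
            )


@dataclass(frozen=True)
class UltrametricReport:
    max_deviation: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_deviation <= self.tolerance


class TimeTree:
    """A rooted time-scaled tree with node ages in Ma before present.

    Wraps a :class:`dendropy.Tree`.  On construction, node ages are computed
    by cumulative branch lengths from the root and rebased so the deepest tip
    sits at age 0.  Each dendropy node gains an ``age`` attribute; internal
    node labels (posterior supports etc.) are kept but never required.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._compute_ages()
        self._check_invariants()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"cannot parse Newick: {exc}") from exc
        tree.is_rooted = True
        labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                node = edge.head_node
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(f"missing branch length on edge to {name!r}")
        return cls(tree)

    def _compute_ages(self):
        root = self._tree.seed_node
        root.depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            node.depth = node.parent_node.depth + (node.edge.length or 0.0)
        max_depth = max(lf.depth for lf in self._tree.leaf_node_iter())
        for node in self._tree.preorder_node_iter():
            node.age = max_depth - node.depth

    def _check_invariants(self):
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                if child.age > node.age + 1e-9 * max(1.0, self.root_age):
                    raise ValueError(
                        "negative branch length: child older than parent "
                        f"({child.age} > {node.age})"
                    )

    # -- basic queries -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self):
        return self._tree.seed_node

    @property
    def root_age(self) -> float:
        return self._tree.seed_node.age

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def is_bifurcating(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def postorder_nodes(self):
        return self._tree.postorder_node_iter()

    def leaf_nodes(self):
        return self._tree.leaf_nodes()

    # -- operations --------------------------------------------------------

    def check_ultrametric(self, tol: Optional[float] = None) -> UltrametricReport:
        """Report the largest tip-age deviation from 0.

        The default tolerance is 1e-6 x root age; the check never raises.
        """
        if tol is None:
            tol = 1e-6 * max(self.root_age, 1.0)
        max_dev = max(abs(lf.age) for lf in self._tree.leaf_node_iter())
        return UltrametricReport(max_deviation=max_dev, tolerance=tol)

    def prune_to_taxa(self, keep: Iterable[str]) -> "TimeTree":
        """Induced subtree on ``keep``, with unary nodes suppressed.

        Retained nodes keep their ages because suppressed-node branch lengths
        are summed along the path.
        """
        keep = list(keep)
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to keep")
        known = set(self.tip_labels)
        unknown = [k for k in keep if k not in known]
        if unknown:
            raise KeyError(f"unknown tip name(s): {unknown}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        clone.purge_taxon_namespace()
        return TimeTree(clone)

    def mrca(self, clade: Iterable[str]):
        labels = set(clade)
        if len(labels) == 1:
            (label,) = labels
            for lf in self._tree.leaf_node_iter():
                if lf.taxon.label == label:
                    return lf
            raise KeyError(f"unknown tip {label!r}")
        return self._tree.mrca(taxon_labels=labels)

    def clade_ages(self, clade: Iterable[str]) -> CladeAges:
        """Stem and crown ages of a monophyletic tip set.

        Raises ``ValueError`` naming intruding tips if the set is not
        monophyletic.  A single-tip clade has crown age 0 and stem age equal
        to its parent's age; the full tip set has an undefined (None) stem.
        """
        labels = frozenset(clade)
        node = self.mrca(labels)
        subtended = {lf.taxon.label for lf in node.leaf_iter()}
        intruders = subtended - labels
        if intruders:
            raise ValueError(
                f"tip set is not monophyletic; MRCA also contains {sorted(intruders)}"
            )
        crown = node.age
        stem = node.parent_node.age if node.parent_node is not None else None
        return CladeAges(clade=labels, stem=stem, crown=crown)

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self._tree.phylogenetic_distance_matrix()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with branch lengths to 9 significant digits."""
        out = io.StringIO()
        self._tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
            unquoted_underscores=True,
        )
        return out.getvalue().strip()

    def __repr__(self):
        return f"<TimeTree {self.n_tips} tips, root age {self.root_age:.4g} Ma>"


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree` (ages rebased to tips)."""
    return TimeTree.from_newick(text)
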