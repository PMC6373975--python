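"""Rooted, dated host phylogeny (chronogram) with taxonomic annotations.

The tree is the scaffold of the whole analysis: species pairs are compared
at their most recent common ancestor (MRCA), reference dS distributions are
attached to internal nodes, and transfer events are counted on induced
subtrees.  Node ages are expressed in million years (My); tips sit at age 0
and the root carries the maximal age.  Internal nodes have stable string
identifiers so that panels, event tables and truth tables can refer to them
across files and runs.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy

__all__ = ["HostTree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed trees or queries on unknown nodes."""


class HostTree:
    """Immutable rooted tree with node ages, order labels and reference flags.

    Parameters
    ----------
    children:
        Mapping from internal node id to the tuple of its child node ids.
        Tips are the ids that never appear as keys.
    ages:
        Node id -> age in My.  Tips must have age 0 (enforced to within
        ``ULTRAMETRIC_RTOL`` relative to the root age).
    orders:
        Optional mapping tip id -> taxonomic order label.
    references:
        Tips flagged as full-genome reference species.
    """

    ULTRAMETRIC_RTOL = 1e-9

    def __init__(
        self,
        children: Mapping[str, tuple[str, ...]],
        ages: Mapping[str, float],
        orders: Mapping[str, str] | None = None,
        references: Iterable[str] = (),
    ) -> None:
        self.children: dict[str, tuple[str, ...]] = {
            k: tuple(v) for k, v in children.items()
        }
        self.parent: dict[str, str | None] = {}
        for node, kids in self.children.items():
            if len(kids) < 2:
                raise TreeError(f"internal node {node!r} has fewer than 2 children")
            for c in kids:
                if c in self.parent:
                    raise TreeError(f"node {c!r} has two parents")
                self.parent[c] = node
        all_nodes = set(self.children) | set(self.parent)
        roots = [n for n in all_nodes if n not in self.parent]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {sorted(roots)}")
        self.root: str = roots[0]
        self.parent[self.root] = None
        self.ages: dict[str, float] = {n: float(ages[n]) for n in all_nodes}
        self._tips: tuple[str, ...] = tuple(
            sorted(n for n in all_nodes if n not in self.children)
        )
        tol = self.ULTRAMETRIC_RTOL * max(self.ages[self.root], 1.0)
        for t in self._tips:
            if abs(self.ages[t]) > tol:
                raise TreeError(f"tip {t!r} has nonzero age {self.ages[t]}")
            self.ages[t] = 0.0
        self.orders: dict[str, str] = dict(orders or {})
        self.references: frozenset[str] = frozenset(references)
        unknown = self.references - set(self._tips)
        if unknown:
            raise TreeError(f"reference flags on unknown tips: {sorted(unknown)}")
        # depth (edge count from root) for fast MRCA walks
        self._depth: dict[str, int] = {self.root: 0}
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in self.children.get(n, ()):
                self._depth[c] = self._depth[n] + 1
                stack.append(c)
        self._subtree_tips: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def tips(self) -> tuple[str, ...]:
        return self._tips

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.children))

    def is_tip(self, node: str) -> bool:
        return node not in self.children

    def age(self, node: str) -> float:
        try:
            return self.ages[node]
        except KeyError:
            raise TreeError(f"unknown node {node!r}") from None

    def subtree_tips(self, node: str) -> frozenset[str]:
        """All tips descending from ``node`` (a tip descends from itself)."""
        if node not in self.ages:
            raise TreeError(f"unknown node {node!r}")
        cached = self._subtree_tips.get(node)
        if cached is None:
            if self.is_tip(node):
                cached = frozenset((node,))
            else:
                acc: set[str] = set()
                for c in self.children[node]:
                    acc |= self.subtree_tips(c)
                cached = frozenset(acc)
            self._subtree_tips[node] = cached
        return cached

    def ancestors(self, node: str) -> list[str]:
        """Path from ``node`` (inclusive) up to the root (inclusive)."""
        if node not in self.ages:
            raise TreeError(f"unknown node {node!r}")
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return path

    def mrca(self, a: str, b: str) -> str:
        if a not in self.ages or b not in self.ages:
            missing = a if a not in self.ages else b
            raise TreeError(f"unknown node {missing!r}")
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.parent[a]  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = self.parent[b]  # type: ignore[assignment]
            db -= 1
        while a != b:
            a = self.parent[a]  # type: ignore[assignment]
            b = self.parent[b]  # type: ignore[assignment]
        return a

    def path_nodes(self, a: str, b: str) -> frozenset[str]:
        """All nodes on the path between tips/nodes ``a`` and ``b``."""
        m = self.mrca(a, b)
        nodes: set[str] = set()
        for start in (a, b):
            n = start
            while n != m:
                nodes.add(n)
                n = self.parent[n]  # type: ignore[assignment]
        nodes.add(m)
        return frozenset(nodes)

    def order_of(self, tip: str) -> str:
        return self.orders.get(tip, "unassigned")

    @property
    def order_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.orders.values())))

    # ------------------------------------------------------------------
    # subtree extraction
    # ------------------------------------------------------------------
    def extract_subtree(self, keep: Iterable[str]) -> "HostTree":
        """Minimal spanning subtree induced by the given tips.

        Degree-2 internal nodes are suppressed; surviving nodes keep their
        original identifiers and ages, so event nodes found on the subtree
        are directly comparable with nodes of the full tree.
        """
        keep_set = set(keep)
        missing = keep_set - set(self._tips)
        if missing:
            raise TreeError(f"species absent from tree: {sorted(missing)}")
        if len(keep_set) < 2:
            raise TreeError("need at least 2 tips to induce a subtree")

        def reduce(node: str) -> str | None:
            """Return the induced-subtree node replacing ``node``, or None."""
            if self.is_tip(node):
                return node if node in keep_set else None
            live = [r for r in (reduce(c) for c in self.children[node]) if r]
            if not live:
                return None
            if len(live) == 1:
                return live[0]
            new_children[node] = tuple(live)
            return node

        new_children: dict[str, tuple[str, ...]] = {}
        new_root = reduce(self.root)
        assert new_root is not None
        nodes = set(new_children) | keep_set
        return HostTree(
            new_children,
            {n: self.ages[n] for n in nodes},
            {t: self.orders[t] for t in keep_set if t in self.orders},
            self.references & keep_set,
        )

    # ------------------------------------------------------------------
    # Newick I/O
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        text: str,
        orders: Mapping[str, str] | None = None,
        references: Iterable[str] = (),
    ) -> "HostTree":
        """Parse a Newick chronogram (branch lengths in My).

        Internal node labels are honoured when present; unlabeled internal
        nodes receive deterministic ids ``N0001, N0002, ...`` in postorder.
        """
        dtree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(dtree, orders=orders, references=references)

    @classmethod
    def from_dendropy(
        cls,
        dtree: "dendropy.Tree",
        orders: Mapping[str, str] | None = None,
        references: Iterable[str] = (),
    ) -> "HostTree":
        # root distance -> age, after measuring tree height on tips
        depths: dict[int, float] = {}
        for nd in dtree.preorder_node_iter():
            base = depths[id(nd.parent_node)] if nd.parent_node is not None else 0.0
            depths[id(nd)] = base + (nd.edge.length or 0.0)
        tip_depths = [depths[id(nd)] for nd in dtree.leaf_node_iter()]
        height = max(tip_depths)
        if height > 0 and (height - min(tip_depths)) > 1e-6 * height:
            raise TreeError("input tree is not ultrametric")
        names: dict[int, str] = {}
        counter = 0
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                names[id(nd)] = nd.taxon.label.replace(" ", "_")
            else:
                label = nd.label
                if not label:
                    counter += 1
                    label = f"N{counter:04d}"
                names[id(nd)] = label
        children = {
            names[id(nd)]: tuple(names[id(c)] for c in nd.child_nodes())
            for nd in dtree.preorder_node_iter()
            if not nd.is_leaf()
        }
        ages = {
            names[id(nd)]: (0.0 if nd.is_leaf() else height - depths[id(nd)])
            for nd in dtree.preorder_node_iter()
        }
        return cls(children, ages, orders=orders, references=references)

    def to_newick(self) -> str:
        """Serialize with internal labels and branch lengths in My."""

        def render(node: str) -> str:
            if self.is_tip(node):
                body = node
            else:
                inner = ",".join(render(c) for c in self.children[node])
                body = f"({inner}){node}"
            parent = self.parent[node]
            if parent is None:
                return body
            return f"{body}:{self.ages[parent] - self.ages[node]:.10g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HostTree({len(self._tips)} tips, root age "
            f"{self.ages[self.root]:.3g} My, {len(self.order_labels)} orders)"
        )
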