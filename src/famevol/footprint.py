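"""Dating gene-family member origins against annotated polyploidy events.

Given a rooted species tree whose branches are annotated with named
whole-genome duplication/triplication events (e.g. the core-eudicot
hexaploidy "gamma", the Brassicaceae duplications "alpha"/"beta", the
poplar-lineage "salicoid" duplication, the Brassica triplication), and a
member x species copy-number matrix, each member is assigned a gain branch
by Dollo parsimony: a single gain on the branch subtending the most recent
common ancestor of all species carrying the member, with losses free.  The
gain branch is then translated into an interval label relative to the
annotated events on the root-to-gain path ("after X, before Y").

Events annotated on the gain branch itself are treated as preceding the
gain — a member whose copies were created by a polyploidy necessarily
postdates it — and are additionally reported in
:attr:`GainAssignment.coincident_events` so coincidence is not lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "SpeciesTree",
    "GainAssignment",
    "dollo_gain_branch",
    "footprint_table",
]


@dataclass(frozen=True)
class GainAssignment:
    """Dollo gain branch and event-interval label for one family member."""

    member: str
    gain_branch: str
    interval_label: str
    coincident_events: tuple[str, ...] = ()
    gain_depth: int = 0


class SpeciesTree:
    """Rooted species tree with per-branch polyploidy-event annotations.

    A branch is identified with the node below it; branch identifiers are
    node labels (leaf taxon labels for terminal branches) when present,
    otherwise the sorted "|"-joined leaf set of the clade.
    """

    def __init__(self, tree: dendropy.Tree, events: Mapping[str, Sequence[str]] | None = None):
        tree.is_rooted = True
        self._tree = tree
        self._branch_of: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            self._branch_of[self._branch_id(node)] = node
        self._events: dict[str, tuple[str, ...]] = {}
        for node in tree.preorder_node_iter():
            parsed = self._node_events(node)
            if parsed:
                self._events[self._branch_id(node)] = parsed
        if events:
            for branch, evs in events.items():
                if branch not in self._branch_of:
                    raise KeyError(f"unknown branch {branch!r}")
                self._events[branch] = tuple(evs)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTree":
        """Load from a Newick file or string with [&events=a+b] comments."""
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=True,
        )
        return cls(tree)

    def apply_events_tsv(self, path: str | Path) -> None:
        """Fallback annotation: TSV with columns clade (comma-joined leaf
        names) and events (comma- or +-separated)."""
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "clade\t")):
                continue
            clade, evs = line.split("\t")[:2]
            leaves = frozenset(s.strip() for s in clade.split(","))
            node = self._tree.mrca(taxon_labels=sorted(leaves))
            if node is None or self.leaves_under_node(node) != leaves:
                raise KeyError(f"no branch subtends exactly {sorted(leaves)}")
            self._events[self._branch_id(node)] = tuple(
                e.strip() for e in evs.replace("+", ",").split(",") if e.strip()
            )

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _branch_id(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))

    @staticmethod
    def _node_events(node: dendropy.Node) -> tuple[str, ...]:
        value = node.annotations.get_value("events")
        if not value:
            return ()
        return tuple(e for e in str(value).replace(",", "+").split("+") if e)

    def leaves_under_node(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    # -- public API -------------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(t.label for t in self._tree.taxon_namespace)

    @property
    def branch_ids(self) -> tuple[str, ...]:
        return tuple(self._branch_of)

    @property
    def events(self) -> dict[str, tuple[str, ...]]:
        return dict(self._events)

    def events_on(self, branch: str) -> tuple[str, ...]:
        if branch not in self._branch_of:
            raise KeyError(f"unknown branch {branch!r}")
        return self._events.get(branch, ())

    def leaves_under(self, branch: str) -> frozenset[str]:
        if branch not in self._branch_of:
            raise KeyError(f"unknown branch {branch!r}")
        return self.leaves_under_node(self._branch_of[branch])

    def node_for(self, branch: str) -> dendropy.Node:
        return self._branch_of[branch]

    def mrca_node(self, species: Iterable[str]) -> dendropy.Node:
        species = sorted(set(species))
        unknown = set(species) - self.leaf_labels
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(species) == 1:
            (leaf,) = [
                l for l in self._tree.leaf_node_iter()
                if l.taxon.label == species[0]
            ]
            return leaf
        return self._tree.mrca(taxon_labels=species)

    def depth(self, node: dendropy.Node) -> int:
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        return d


def _frontier_events(tree: SpeciesTree, node: dendropy.Node) -> list[str]:
    """Events on the shallowest event-bearing branches below ``node``."""
    found: list[str] = []
    stack = list(node.child_nodes())
    while stack:
        child = stack.pop()
        evs = tree.events_on(SpeciesTree._branch_id(child))
        if evs:
            found.extend(evs)
        else:
            stack.extend(child.child_nodes())
    return found


def dollo_gain_branch(
    member_presence: Mapping[str, int],
    tree: SpeciesTree,
    member: str = "",
) -> GainAssignment:
    """Single-gain (Dollo) origin of a member from its presence pattern.

    The gain branch subtends the MRCA of all species where the member has
    copy count >= 1.  The interval label reports the most recent polyploidy
    event at or above the gain ("after ...") and the events on the
    shallowest event-bearing branches below it ("before ...").
    """
    present = [s for s, c in member_presence.items() if c >= 1]
    if not present:
        raise ValueError(f"member {member!r} present in no species")
    gain_node = tree.mrca_node(present)
    gain_branch = SpeciesTree._branch_id(gain_node)

    # walk root -> gain collecting events; the deepest event-bearing branch
    # at or above the gain defines the "after" clause
    path = []
    node = gain_node
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()
    after: tuple[str, ...] = ()
    for nd in path:
        evs = tree.events_on(SpeciesTree._branch_id(nd))
        if evs:
            after = evs
    before = _frontier_events(tree, gain_node)

    parts = []
    if after:
        parts.append("after " + "/".join(after))
    if before:
        parts.append("before " + "/".join(before))
    label = ", ".join(parts) if parts else "no flanking events"
    return GainAssignment(
        member=member,
        gain_branch=gain_branch,
        interval_label=label,
        coincident_events=tree.events_on(gain_branch),
        gain_depth=tree.depth(gain_node),
    )


def footprint_table(
    matrix: pd.DataFrame, tree: SpeciesTree
) -> tuple[list[GainAssignment], pd.Series]:
    """Gain assignments for every member plus per-species copy totals.

    ``matrix`` is member x species with nonnegative integer copy counts;
    its column set must equal the tree's leaf set.
    """
    if (matrix.values < 0).any():
        raise ValueError("copy counts must be nonnegative")
    species = frozenset(matrix.columns)
    if species != tree.leaf_labels:
        raise ValueError(
            f"species mismatch: matrix has {sorted(species)}, "
            f"tree has {sorted(tree.leaf_labels)}"
        )
    assignments = [
        dollo_gain_branch(row.to_dict(), tree, member=str(member))
        for member, row in matrix.iterrows()
    ]
    totals = matrix.sum(axis=0)
    totals.name = "total_copies"
    return assignments, totals
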