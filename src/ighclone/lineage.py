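"""Intraclonal diversification: shared/private mutation counts and topology.

A clone expanded from one founder B cell can diversify in two extreme ways:
a star ("bush-like") genealogy in which each member accumulates its own
private mutations independently, and a stepwise ladder in which members
inherit an increasing set of shared mutations. The star index — the
fraction of the clone's distinct mutations seen in exactly one member —
separates the two: near 1 for a star, near 1/k for a k-member ladder.

Mutations are keyed by (region, position, observed base), so independent
recurrent changes to different bases at one site count separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .annotate import Mutation
from .clonality import Clone

MutKey = tuple[str, int, str]

# star-index cuts calibrated on the packaged simulator (see docs/methods.md):
# a k-member ladder floors at 1/k, so the stepwise cut must sit above 1/3
# for the smallest informative clone size (k = 3)
BUSH_CUT = 0.7
STEPWISE_CUT = 0.4


def _as_key(m) -> MutKey:
    if isinstance(m, Mutation):
        return m.key
    region, position, obs = m
    return (str(region), int(position), str(obs))


@dataclass
class LineageReport:
    clone_id: str
    n_members: int
    n_mut_union: int
    n_shared: int
    n_private: int
    star_index: float | None
    topology_call: str  # bush | stepwise | indeterminate

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def lineage_report(
    clone: Clone,
    mutations_by_member: dict[str, Iterable],
    v_calls: dict[str, str] | None = None,
    bush_cut: float = BUSH_CUT,
    stepwise_cut: float = STEPWISE_CUT,
) -> LineageReport:
    """Shared/private mutation bookkeeping and topology call for one clone.

    ``mutations_by_member`` maps member id to its mutation list (``Mutation``
    objects or (region, position, obs_base) keys) against the clone's common
    germline. The call is ``indeterminate`` for clones with fewer than three
    members or no mutations at all.
    """
    if v_calls is not None:
        used = {v_calls[m] for m in clone.member_ids if m in v_calls}
        if len(used) > 1:
            raise ValueError(f"{clone.clone_id}: members annotated against different V genes {sorted(used)}")
    carriers: dict[MutKey, int] = {}
    for member in clone.member_ids:
        for key in {_as_key(m) for m in mutations_by_member.get(member, [])}:
            carriers[key] = carriers.get(key, 0) + 1
    n_union = len(carriers)
    n_shared = sum(1 for c in carriers.values() if c >= 2)
    n_private = n_union - n_shared
    star = n_private / n_union if n_union else None
    if clone.size < 3 or n_union == 0:
        call = "indeterminate"
    elif star > bush_cut:
        call = "bush"
    elif star < stepwise_cut:
        call = "stepwise"
    else:
        call = "indeterminate"
    return LineageReport(
        clone_id=clone.clone_id,
        n_members=clone.size,
        n_mut_union=n_union,
        n_shared=n_shared,
        n_private=n_private,
        star_index=star,
        topology_call=call,
    )


@dataclass
class TreeNode:
    label: str
    edge_mutations: list[MutKey] = field(default_factory=list)
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.label}:{len(self.edge_mutations)}"
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner}){self.label}:{len(self.edge_mutations)}"

    def total_edge_mutations(self) -> int:
        return len(self.edge_mutations) + sum(c.total_edge_mutations() for c in self.children)


@dataclass
class Genealogy:
    clone_id: str
    root: TreeNode
    homoplasies: list[MutKey]

    def newick(self) -> str:
        return self.root.newick()


def parsimony_genealogy(clone: Clone, mutations_by_member: dict[str, Iterable]) -> Genealogy:
    """Greedy perfect-phylogeny genealogy of one clone, rooted at germline.

    Mutations sharing a carrier set define candidate clades; clades are
    accepted greedily by decreasing size when compatible (nested or
    disjoint) with all previously accepted ones. Mutation pairs violating
    the four-gamete condition are reported as homoplasies and placed on
    every carrier's terminal edge, so the tree explains every mutation at
    least once (exactly once when the matrix is compatible).
    """
    members = sorted(clone.member_ids)
    member_keys: dict[str, set[MutKey]] = {
        m: {_as_key(x) for x in mutations_by_member.get(m, [])} for m in members
    }
    carrier_sets: dict[MutKey, frozenset[str]] = {}
    for m, keys in member_keys.items():
        for key in keys:
            carrier_sets[key] = carrier_sets.get(key, frozenset()) | {m}
    by_set: dict[frozenset[str], list[MutKey]] = {}
    for key, cset in carrier_sets.items():
        by_set.setdefault(cset, []).append(key)
    for keys in by_set.values():
        keys.sort()

    ordered = sorted(by_set, key=lambda s: (-len(s), sorted(s)))
    accepted: list[frozenset[str]] = []
    homoplasies: list[MutKey] = []
    for cset in ordered:
        if all(cset <= a or a <= cset or not (cset & a) for a in accepted):
            accepted.append(cset)
        else:
            homoplasies.extend(by_set[cset])

    root = TreeNode(label="germline")
    node_of: dict[frozenset[str], TreeNode] = {}
    # internal nodes for accepted multi-member clades, nested by containment
    internal = [s for s in accepted if len(s) > 1]
    for cset in sorted(internal, key=len, reverse=True):
        node_of[cset] = TreeNode(label="", edge_mutations=list(by_set[cset]))
    for cset in sorted(internal, key=len):
        supers = [s for s in internal if cset < s]
        parent = node_of[min(supers, key=len)] if supers else root
        parent.children.append(node_of[cset])
    for m in members:
        leaf_muts = sorted(
            k for k in member_keys[m] if carrier_sets[k] == frozenset({m}) and frozenset({m}) in accepted
        )
        leaf_muts += sorted(k for k in homoplasies if m in carrier_sets[k])
        leaf = TreeNode(label=m, edge_mutations=leaf_muts)
        containing = [s for s in internal if m in s]
        parent = node_of[min(containing, key=len)] if containing else root
        parent.children.append(leaf)
    _sort_children(root)
    return Genealogy(clone_id=clone.clone_id, root=root, homoplasies=sorted(set(homoplasies)))


def _sort_children(node: TreeNode) -> None:
    for child in node.children:
        _sort_children(child)
    node.children.sort(key=lambda c: (not c.is_leaf, c.label, c._newick()))
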