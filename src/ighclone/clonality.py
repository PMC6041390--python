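"""Clonal grouping of annotated heavy chains.

Two sequences from the same mouse belong to the same clone when they use
the same V and J gene (and the same D gene when both carry a D call),
their CDR3s have identical nucleotide length, and CDR3 nucleotide identity
exceeds the threshold (default >95%, computed as 1 - hamming/length on the
equal-length CDR3s). Clones are the connected components of this relation
(single linkage), so a chain of near-identical members stays together even
if its extremes diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class ClonalRecord:
    """Minimal view of an annotated record needed for grouping."""

    record_id: str
    mouse_id: str
    v_call: str
    j_call: str
    cdr3_nt: str | None
    d_call: str | None = None


@dataclass
class Clone:
    clone_id: str
    member_ids: list[str]
    v_call: str
    j_call: str
    cdr3_length_nt: int
    mouse_id: str
    flags: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def cdr3_identity(a: str, b: str) -> float:
    """Fraction identity between two equal-length CDR3 nucleotide strings."""
    if len(a) != len(b):
        raise ValueError("CDR3 identity is defined for equal lengths only")
    if not a:
        return 1.0
    mismatches = sum(1 for x, y in zip(a, b) if x != y)
    return 1.0 - mismatches / len(a)


def _linked(a: ClonalRecord, b: ClonalRecord, threshold: float) -> bool:
    if a.v_call != b.v_call or a.j_call != b.j_call:
        return False
    if a.d_call and b.d_call and a.d_call != b.d_call:
        return False
    if a.cdr3_nt is None or b.cdr3_nt is None:
        return False
    if len(a.cdr3_nt) != len(b.cdr3_nt):
        return False
    return cdr3_identity(a.cdr3_nt, b.cdr3_nt) > threshold


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_clones(records: list[ClonalRecord], identity_threshold: float = 0.95) -> list[Clone]:
    """Partition records into clones (single-linkage, per mouse).

    Records without a CDR3 become flagged singleton clones. Clone ids are
    deterministic: per mouse, components are numbered in order of their
    smallest member id.
    """
    clones: list[Clone] = []
    by_mouse: dict[str, list[ClonalRecord]] = {}
    for rec in records:
        by_mouse.setdefault(rec.mouse_id, []).append(rec)
    for mouse_id in sorted(by_mouse):
        mrecs = sorted(by_mouse[mouse_id], key=lambda r: r.record_id)
        uf = _UnionFind(len(mrecs))
        for i in range(len(mrecs)):
            for j in range(i + 1, len(mrecs)):
                if _linked(mrecs[i], mrecs[j], identity_threshold):
                    uf.union(i, j)
        components: dict[int, list[ClonalRecord]] = {}
        for i, rec in enumerate(mrecs):
            components.setdefault(uf.find(i), []).append(rec)
        ordered = sorted(components.values(), key=lambda ms: min(m.record_id for m in ms))
        for k, members in enumerate(ordered, start=1):
            head = members[0]
            flags = [] if head.cdr3_nt is not None else ["missing_cdr3"]
            clones.append(
                Clone(
                    clone_id=f"{mouse_id}_c{k}",
                    member_ids=[m.record_id for m in members],
                    v_call=head.v_call,
                    j_call=head.j_call,
                    cdr3_length_nt=len(head.cdr3_nt) if head.cdr3_nt else 0,
                    mouse_id=mouse_id,
                    flags=flags,
                )
            )
    return clones


def clone_summary(clones: list[Clone]) -> pd.DataFrame:
    """Per-mouse clone counts: total, expanded (size >= 2) and largest size."""
    rows = []
    by_mouse: dict[str, list[Clone]] = {}
    for clone in clones:
        by_mouse.setdefault(clone.mouse_id, []).append(clone)
    for mouse_id in sorted(by_mouse):
        sizes = [c.size for c in by_mouse[mouse_id]]
        rows.append(
            {
                "mouse_id": mouse_id,
                "n_clones": len(sizes),
                "n_expanded_clones": sum(1 for s in sizes if s >= 2),
                "largest_clone_size": max(sizes),
            }
        )
    return pd.DataFrame(rows, columns=["mouse_id", "n_clones", "n_expanded_clones", "largest_clone_size"])


def clones_from_labels(records) -> list[Clone]:
    """Build the clone partition from printed clone labels.

    For the amino-acid-only hybridoma table the grouping criterion is
    nucleotide-level and cannot be re-derived; the published labels are the
    ground-truth partition.
    """
    groups: dict[tuple[str, str], list] = {}
    for rec in records:
        groups.setdefault((rec.mouse_id, rec.clone_label), []).append(rec)
    clones = []
    for mouse_id in sorted({m for m, _ in groups}):
        labelled = sorted((lbl, ms) for (m, lbl), ms in groups.items() if m == mouse_id)
        for k, (_, members) in enumerate(labelled, start=1):
            head = members[0]
            clones.append(
                Clone(
                    clone_id=f"{mouse_id}_c{k}",
                    member_ids=[m.record_id for m in members],
                    v_call=head.v_call,
                    j_call=head.j_call,
                    cdr3_length_nt=3 * len(head.cdr3_aa_imgt) if head.cdr3_aa_imgt else 0,
                    mouse_id=mouse_id,
                )
            )
    return clones
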