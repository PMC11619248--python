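"""Clonotype sharing between sorted T-cell populations.

Overlap is presence/absence at the chosen clonotype resolution: a
clonotype counts toward a Venn region irrespective of its abundance,
matching how clonotype-sharing diagrams report numbers of clonotypes
rather than read mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .io import KeyMode, Repertoire, clonotype_key


@dataclass(frozen=True)
class OverlapResult:
    """Exclusive Venn region counts for 2 or 3 populations.

    ``region_counts`` maps each non-empty subset of ``set_labels``
    (as a sorted tuple) to the number of clonotypes present in exactly
    that subset. Regions are disjoint and sum to ``union_size``.
    """

    set_labels: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    union_size: int


def _key_set(rep: Repertoire, mode: KeyMode) -> set:
    return {k for k in (clonotype_key(r, mode) for r in rep.records) if k not in ("", ("", ""))}


def venn_counts(reps: Sequence[Repertoire], mode: KeyMode = "nt") -> OverlapResult:
    """Exclusive-region clonotype counts for 2 or 3 repertoires."""
    if not 2 <= len(reps) <= 3:
        raise ValueError(f"venn_counts requires 2 or 3 repertoires, got {len(reps)}")
    labels = tuple(r.sample_id for r in reps)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")
    sets = {lab: _key_set(rep, mode) for lab, rep in zip(labels, reps)}
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for subset in combinations(labels, r):
            regions[subset] = 0
    for key in union:
        member = tuple(lab for lab in labels if key in sets[lab])
        regions[member] += 1
    return OverlapResult(set_labels=labels, region_counts=regions, union_size=len(union))


def shared_clonotypes(
    rep_a: Repertoire, rep_b: Repertoire, mode: KeyMode = "nt"
) -> list[tuple[object, int, int]]:
    """Clonotype keys present in both samples, with each sample's count.

    Sorted by combined count descending (ties broken by key) so the most
    abundant shared clones come first.
    """
    counts_a = {clonotype_key(r, mode): r.count for r in rep_a.records}
    counts_b = {clonotype_key(r, mode): r.count for r in rep_b.records}
    shared = [
        (k, counts_a[k], counts_b[k])
        for k in counts_a.keys() & counts_b.keys()
        if k not in ("", ("", ""))
    ]
    shared.sort(key=lambda t: (-(t[1] + t[2]), str(t[0])))
    return shared
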