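"""Cross-experiment set analysis of classified binder peptides.

Venn-region counts between dilutions of one antivenom or between
antivenoms, the non-shared fraction quantifying dilution disagreement,
and the set of toxins recognised through at least one binder peptide.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .classify import BinderSet

OccurrenceMap = dict[str, tuple[tuple[str, int], ...]]


@dataclass
class OverlapReport:
    """Exclusive Venn-region counts for two or three binder sets.

    ``regions`` maps a frozenset of member labels to the count of
    peptides belonging to exactly those sets; region counts sum to the
    union size.
    """

    labels: list[str]
    regions: dict[frozenset, int]
    union_size: int
    intersection_size: int
    non_shared: dict[frozenset, float]

    def region(self, *labels: str) -> int:
        return self.regions[frozenset(labels)]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "regions": {
                "&".join(sorted(k)): v for k, v in self.regions.items()
            },
            "union_size": self.union_size,
            "intersection_size": self.intersection_size,
            "non_shared_fraction": {
                "&".join(sorted(k)): v for k, v in self.non_shared.items()
            },
        }


def overlap_counts(sets: dict[str, BinderSet | frozenset | set]) -> OverlapReport:
    """Exclusive region counts for a 2- or 3-set Venn diagram.

    Each peptide in the union is assigned to exactly one region — the
    combination of sets that contain it — so the inclusion–exclusion
    identity holds by construction.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_counts handles 2 or 3 sets")
    plain = {
        label: (s.peptides if isinstance(s, BinderSet) else frozenset(s))
        for label, s in sets.items()
    }
    labels = list(plain)
    union = frozenset().union(*plain.values())
    inter = union
    for s in plain.values():
        inter &= s
    regions = {
        frozenset(combo): 0
        for r in range(1, len(labels) + 1)
        for combo in combinations(labels, r)
    }
    for peptide in union:
        members = frozenset(l for l in labels if peptide in plain[l])
        regions[members] += 1
    non_shared = {
        frozenset((a, b)): non_shared_fraction(plain[a], plain[b])
        for a, b in combinations(labels, 2)
    }
    return OverlapReport(
        labels=labels,
        regions=regions,
        union_size=len(union),
        intersection_size=len(inter),
        non_shared=non_shared,
    )


def non_shared_fraction(a, b, denominator: str = "union") -> float:
    """Fraction of peptides found in one experiment but not the other.

    Default is the symmetric difference over the union; 0 when both sets
    are empty (convention). ``denominator="sum"`` divides by |A|+|B|
    instead.
    """
    a = a.peptides if isinstance(a, BinderSet) else set(a)
    b = b.peptides if isinstance(b, BinderSet) else set(b)
    union = a | b
    if not union:
        return 0.0
    diff = len(union) - len(a & b)
    if denominator == "union":
        return diff / len(union)
    if denominator == "sum":
        return diff / (len(a) + len(b))
    raise ValueError(f"unknown denominator {denominator!r}")


def toxins_with_binders(binders: BinderSet, occurrences: OccurrenceMap) -> set[str]:
    """Accessions of toxins contributing at least one binder peptide."""
    hits: set[str] = set()
    for peptide in binders.peptides:
        if peptide not in occurrences:
            raise KeyError(f"binder peptide {peptide} has no occurrence record")
        hits.update(acc for acc, _ in occurrences[peptide])
    return hits
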