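"""Anchor-gene thresholding of bulk expression profiles.

A gene panel is called expressed in a bulk profile when each gene's value
is at or above that of a chosen anchor gene (here, classically *Ntf3*):
the anchor's expression defines the threshold, and the anchor's
percentile rank documents how permissive the cutoff is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from .io import BulkProfileSet, GeneSet, canonical_symbol


@dataclass
class ExpressedSetResult:
    condition: str
    anchor: str
    threshold_value: float
    anchor_percentile: float  # % of profiled genes at or below the anchor
    expressed: GeneSet
    missing: list[str] = field(default_factory=list)  # panel genes absent


def anchor_threshold(profile: BulkProfileSet, condition: str, anchor: str,
                     convention: str = "at-or-below") -> tuple[float, float]:
    """Anchor gene's expression value and percentile rank in a condition.

    ``convention`` selects whether ties at the anchor's value are counted
    with the anchor (``"at-or-below"``, default) or not (``"below"``);
    "expressed in the top X%" phrasing in the literature is ambiguous
    about ties, so both are exposed.
    """
    anchor = canonical_symbol(anchor)
    col = profile.condition(condition)
    if anchor not in col.index:
        raise KeyError(f"anchor gene {anchor!r} absent from profile")
    value = float(col[anchor])
    if convention == "at-or-below":
        frac = (col <= value).mean()
    elif convention == "below":
        frac = (col < value).mean()
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return value, 100.0 * float(frac)


def call_expressed_ligands(profile: BulkProfileSet, condition: str,
                           ligand_panel: GeneSet, anchor: str,
                           ) -> ExpressedSetResult:
    """Call panel genes expressed when their value is >= the anchor's
    (inclusive: the anchor calls itself expressed).  Panel genes absent
    from the profile are reported in ``missing``, not silently dropped."""
    if len(ligand_panel) == 0:
        raise ValueError("empty ligand panel")
    threshold, pct = anchor_threshold(profile, condition, anchor)
    col = profile.condition(condition)
    expressed, missing = [], []
    for g in ligand_panel.sorted():
        if g not in col.index:
            missing.append(g)
        elif col[g] >= threshold:
            expressed.append(g)
    return ExpressedSetResult(
        condition=condition, anchor=canonical_symbol(anchor),
        threshold_value=threshold, anchor_percentile=pct,
        expressed=GeneSet(f"{condition}_expressed", frozenset(expressed)),
        missing=missing)


def venn_counts(sets: Mapping[str, Iterable[str]],
                ) -> dict[tuple[str, ...], int]:
    """Disjoint-region counts for 2 or 3 named sets.

    Keys are sorted tuples of the set names whose exclusive region the
    count belongs to; counts sum to the size of the union.
    """
    named = {name: set(s.members if isinstance(s, GeneSet) else s)
             for name, s in sets.items()}
    if not 2 <= len(named) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    names = sorted(named)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(len(names), 0, -1):
        for combo in combinations(names, k):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set.union(set(), *(named[n] for n in names
                                         if n not in combo))
            regions[combo] = len(inside - outside)
    return regions
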