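"""Outlet categorization: franchise detection, weighted descriptor scoring,
rarity tie-breaking, franchise subtyping, and category transfer across
matched outlets.

An outlet is first split into franchise vs non-franchise: a *franchise* is a
brand (identical normalized name) with strictly more than 10 distinct physical
locations across both datasets, matched pairs counted once. Franchise outlets
take the ``takeaway_franchise`` main category plus a subtype; non-franchise
outlets are scored from their category descriptors: each descriptor maps to
one or more main categories with an integer weight (base weight 2, with
prominence adjustments such as "fast food" at 4 and niche descriptors at 1),
weights accumulate per category, and the highest cumulative score wins. Score
ties go to the category that is globally *rarer*, to counter the
over-representation of the dominant category. Matched local outlets inherit
their online twin's category instead of being re-scored.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    AssignmentSource,
    CategoryAssignment,
    FranchiseSubtype,
    MainCategory,
    MatchResult,
    NormalizedOutlet,
)

logger = logging.getLogger(__name__)

_C = MainCategory

#: descriptor -> [(main category, weight)]; base weight 2, prominence-adjusted
#: entries carry 4 (broad, e.g. "fast food") or 1 (niche, e.g. "japanese set
#: item"); multi-category descriptors contribute to every mapped category.
DEFAULT_LEXICON_ENTRIES: dict[str, list[tuple[MainCategory, int]]] = {
    # restaurants / cafes
    "asian": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "italian": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "thai": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "vietnamese": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "indian": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "cafe": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "coffee": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "sushi": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "noodles": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "dumplings": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "seafood": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "japanese set item": [(_C.INDEPENDENT_RESTAURANT_CAFE, 1)],
    # takeaway
    "chicken": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "fast food": [(_C.INDEPENDENT_TAKEAWAY, 4)],
    "comfort food": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "burger": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "kebab": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "pizza": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "fried chicken": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "fish and chips": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "wings": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "family meals": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    "american": [(_C.INDEPENDENT_TAKEAWAY, 2)],
    # supermarkets / grocers
    "supermarket": [(_C.SUPERMARKET_GROCER, 2)],
    "grocery": [(_C.SUPERMARKET_GROCER, 2)],
    # fresh produce
    "greengrocer": [(_C.FRESH_PRODUCE, 2)],
    "fruit and vegetables": [(_C.FRESH_PRODUCE, 2)],
    "farmers market": [(_C.FRESH_PRODUCE, 2)],
    "butcher": [(_C.FRESH_PRODUCE, 2)],
    # sandwich / salad
    "salad": [(_C.SANDWICH_SALAD, 2)],
    "sandwich": [(_C.SANDWICH_SALAD, 2)],
    "salad bar": [(_C.SANDWICH_SALAD, 2)],
    "wraps": [(_C.SANDWICH_SALAD, 2)],
    "poke": [(_C.SANDWICH_SALAD, 2)],
    # sweets / extra foods
    "desserts": [(_C.SWEETS_EXTRA, 2)],
    "ice cream": [(_C.SWEETS_EXTRA, 2)],
    "bubble tea": [(_C.SWEETS_EXTRA, 2)],
    "candy": [(_C.SWEETS_EXTRA, 2)],
    "frozen yoghurt": [(_C.SWEETS_EXTRA, 2)],
    "juice": [(_C.SWEETS_EXTRA, 2)],
    "smoothies": [(_C.SWEETS_EXTRA, 2)],
    # bakeries
    "bakery": [(_C.BAKERY, 2)],
    "bread": [(_C.BAKERY, 2)],
    "pastries": [(_C.BAKERY, 2)],
    "patisserie": [(_C.BAKERY, 2)],
    # convenience / petrol
    "convenience store": [(_C.CONVENIENCE_PETROL, 2)],
    "petrol station": [(_C.CONVENIENCE_PETROL, 2)],
    "service station": [(_C.CONVENIENCE_PETROL, 2)],
    "corner store": [(_C.CONVENIENCE_PETROL, 2)],
    # alcohol retail
    "bottle shop": [(_C.ALCOHOL_RETAILER, 2)],
    "liquor store": [(_C.ALCOHOL_RETAILER, 2)],
    "wine merchant": [(_C.ALCOHOL_RETAILER, 2)],
    # multi-category descriptors
    "grocer": [(_C.SUPERMARKET_GROCER, 2), (_C.FRESH_PRODUCE, 2)],
    "hotel": [(_C.ALCOHOL_RETAILER, 2), (_C.INDEPENDENT_RESTAURANT_CAFE, 2)],
    "restaurant": [(_C.INDEPENDENT_RESTAURANT_CAFE, 2), (_C.INDEPENDENT_TAKEAWAY, 2)],
}

#: fixed order used when both scores and global frequencies tie
CATEGORY_TIE_ORDER: tuple[MainCategory, ...] = tuple(
    c for c in MainCategory if c is not MainCategory.NA
)


@dataclass
class CategoryLexicon:
    """Descriptor-to-category weight table."""

    entries: dict[str, list[tuple[MainCategory, int]]] = field(
        default_factory=lambda: dict(DEFAULT_LEXICON_ENTRIES)
    )
    default_weight: int = 2

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, list]) -> "CategoryLexicon":
        """Build from a plain config mapping: descriptor -> list of
        ``[category, weight]`` pairs or bare category names (base weight)."""
        entries: dict[str, list[tuple[MainCategory, int]]] = {}
        for desc, targets in mapping.items():
            pairs = []
            for t in targets:
                if isinstance(t, str):
                    pairs.append((MainCategory(t), cls.default_weight))
                else:
                    cat, w = t
                    pairs.append((MainCategory(cat), int(w)))
            entries[desc.lower()] = pairs
        return cls(entries=entries)

    def lookup(self, descriptor: str) -> Optional[list[tuple[MainCategory, int]]]:
        return self.entries.get(descriptor.lower())


def score_categories(descriptors: Sequence[str],
                     lexicon: CategoryLexicon) -> dict[MainCategory, int]:
    """Cumulative category scores for one outlet's descriptor list.

    Unknown descriptors contribute nothing (logged at debug level); an empty
    descriptor list yields all-zero scores (an empty map).
    """
    scores: Counter = Counter()
    for desc in descriptors:
        pairs = lexicon.lookup(desc)
        if pairs is None:
            logger.debug("descriptor without lexicon entry: %r", desc)
            continue
        for cat, weight in pairs:
            scores[cat] += weight
    return dict(scores)


def assign_main_category(
    scores: Mapping[MainCategory, int],
    global_category_frequencies: Mapping[MainCategory, int],
) -> tuple[MainCategory, bool]:
    """Pick the main category from cumulative scores.

    Unique maximum wins outright. A tie among maxima goes to the tied category
    with the lowest global frequency (rarity priority); a residual tie falls
    back to the fixed category order. All-zero scores give the NA sentinel.
    """
    positive = {c: s for c, s in scores.items() if s > 0}
    if not positive:
        return MainCategory.NA, False
    best = max(positive.values())
    tied = [c for c, s in positive.items() if s == best]
    if len(tied) == 1:
        return tied[0], False
    winner = min(
        tied,
        key=lambda c: (global_category_frequencies.get(c, 0),
                       CATEGORY_TIE_ORDER.index(c)),
    )
    return winner, True


def compute_global_frequencies(
    score_maps: Iterable[Mapping[MainCategory, int]],
) -> Counter:
    """Provisional category frequencies over the whole dataset.

    Only outlets with a *unique* maximum contribute, so the table is defined
    before any tie needs breaking; it is then frozen and reused for every
    tie-break.
    """
    freq: Counter = Counter()
    for scores in score_maps:
        positive = {c: s for c, s in scores.items() if s > 0}
        if not positive:
            continue
        best = max(positive.values())
        tied = [c for c, s in positive.items() if s == best]
        if len(tied) == 1:
            freq[tied[0]] += 1
    return freq


@dataclass
class FranchiseRegistry:
    """Brands with more than the threshold number of distinct locations."""

    brands: dict[str, tuple[int, FranchiseSubtype]] = field(default_factory=dict)

    def __contains__(self, brand_norm: str) -> bool:
        return brand_norm in self.brands

    def location_count(self, brand_norm: str) -> int:
        return self.brands[brand_norm][0]

    def subtype(self, brand_norm: str) -> FranchiseSubtype:
        return self.brands[brand_norm][1]


def detect_franchises(
    all_outlets: Sequence[NormalizedOutlet],
    matches: Optional[Sequence[MatchResult]] = None,
    min_locations: int = 11,
) -> FranchiseRegistry:
    """Register every brand with at least ``min_locations`` distinct physical
    locations (default 11, i.e. strictly more than 10).

    A location is a distinct ``(street_number, street_name, suburb)`` triple
    for an identical normalized name, counted across both datasets with
    matched pairs counted once (the local twin of each match is skipped).
    """
    matched_local = {m.local_id for m in matches} if matches else set()
    locations: dict[str, set[tuple[str, str, str]]] = {}
    for o in all_outlets:
        if o.source_id in matched_local:
            continue
        key = (o.street_number, o.street_name, o.suburb_norm)
        locations.setdefault(o.name_norm, set()).add(key)
    brands = {
        name: (len(locs), FranchiseSubtype.UNASSIGNED)
        for name, locs in locations.items()
        if len(locs) >= min_locations
    }
    return FranchiseRegistry(brands=brands)


_DESSERT_KEYWORDS = {"desserts", "dessert", "ice cream", "bubble tea",
                     "frozen yoghurt", "candy", "sweets", "cake", "cakes"}
_BAKERY_KEYWORDS = {"bakery", "bread", "pastries", "patisserie"}
_JUICE_KEYWORDS = {"juice", "smoothies", "juice bar"}
_HEALTHY_KEYWORDS = {"salad", "salad bar", "sushi", "sandwich", "wraps", "poke"}


def subtype_franchise(
    brand_norm: str,
    subtype_lexicon: Mapping[str, FranchiseSubtype | str],
    descriptors: Sequence[str] = (),
) -> FranchiseSubtype:
    """Subtype a franchise brand.

    Known brands come straight from the subtype lexicon. Unknown brands are
    decided from their descriptors with keyword precedence sweets -> bakery ->
    juice -> healthy, defaulting to unhealthy (renowned fast-food offerings).
    """
    if brand_norm in subtype_lexicon:
        return FranchiseSubtype(subtype_lexicon[brand_norm])
    descs = {d.lower() for d in descriptors}
    if descs & _DESSERT_KEYWORDS:
        sub = FranchiseSubtype.DESSERT
    elif descs & _BAKERY_KEYWORDS:
        sub = FranchiseSubtype.BAKERY
    elif descs & _JUICE_KEYWORDS:
        sub = FranchiseSubtype.JUICE
    elif descs & _HEALTHY_KEYWORDS:
        sub = FranchiseSubtype.HEALTHY
    else:
        sub = FranchiseSubtype.UNHEALTHY
    logger.info("brand %r not in subtype lexicon; decided %s from descriptors",
                brand_norm, sub.value)
    return sub


def transfer_categories(
    assignments_online: Mapping[str, CategoryAssignment],
    matches: Sequence[MatchResult],
) -> dict[str, CategoryAssignment]:
    """Carry each matched online outlet's main category onto its local twin.

    Returns assignments keyed by *local* id with source ``transferred``.
    Unmatched local outlets are not produced here; they are scored from the
    local-source lexicon by :func:`categorize_all`.
    """
    out: dict[str, CategoryAssignment] = {}
    for m in matches:
        twin = assignments_online.get(m.online_id)
        if twin is None:
            continue
        out[m.local_id] = CategoryAssignment(
            outlet_id=m.local_id,
            scores=dict(twin.scores),
            main_category=twin.main_category,
            tie_broken=twin.tie_broken,
            assignment_source=AssignmentSource.TRANSFERRED,
            franchise_subtype=twin.franchise_subtype,
        )
    return out


def categorize_all(
    online: Sequence[NormalizedOutlet],
    local: Sequence[NormalizedOutlet],
    matches: Sequence[MatchResult],
    online_lexicon: CategoryLexicon,
    local_lexicon: CategoryLexicon,
    subtype_lexicon: Optional[Mapping[str, FranchiseSubtype | str]] = None,
    franchise_min_locations: int = 11,
) -> tuple[dict[str, CategoryAssignment], FranchiseRegistry]:
    """Full categorization pass over both datasets.

    Order of operations: franchise split, online scoring, transfer to matched
    locals, then local scoring for the remainder — with the tie-break
    frequency table computed once, up front, from unique-maximum score
    assignments over all non-franchise outlets in both datasets.
    """
    subtype_lexicon = dict(subtype_lexicon or {})
    registry = detect_franchises(list(online) + list(local), matches,
                                 franchise_min_locations)
    # resolve subtypes once per brand, from pooled descriptors
    brand_descs: dict[str, list[str]] = {}
    for o in list(online) + list(local):
        if o.name_norm in registry:
            brand_descs.setdefault(o.name_norm, []).extend(o.descriptors)
    for brand in registry.brands:
        count, _ = registry.brands[brand]
        sub = subtype_franchise(brand, subtype_lexicon, brand_descs.get(brand, ()))
        registry.brands[brand] = (count, sub)

    def franchise_assignment(o: NormalizedOutlet) -> CategoryAssignment:
        return CategoryAssignment(
            outlet_id=o.source_id,
            scores={},
            main_category=MainCategory.TAKEAWAY_FRANCHISE,
            assignment_source=AssignmentSource.FRANCHISE,
            franchise_subtype=registry.subtype(o.name_norm),
        )

    online_scores = {
        o.source_id: score_categories(o.descriptors, online_lexicon)
        for o in online if o.name_norm not in registry
    }
    local_scores = {
        o.source_id: score_categories(o.descriptors, local_lexicon)
        for o in local if o.name_norm not in registry
    }
    global_freq = compute_global_frequencies(
        list(online_scores.values()) + list(local_scores.values())
    )

    assignments: dict[str, CategoryAssignment] = {}
    for o in online:
        if o.name_norm in registry:
            assignments[o.source_id] = franchise_assignment(o)
        else:
            scores = online_scores[o.source_id]
            cat, tie = assign_main_category(scores, global_freq)
            assignments[o.source_id] = CategoryAssignment(
                outlet_id=o.source_id, scores=scores, main_category=cat,
                tie_broken=tie, assignment_source=AssignmentSource.SCORED,
            )

    online_assignments = {
        oid: a for oid, a in assignments.items()
    }
    transferred = transfer_categories(online_assignments, matches)
    for o in local:
        if o.name_norm in registry:
            assignments[o.source_id] = franchise_assignment(o)
        elif o.source_id in transferred:
            assignments[o.source_id] = transferred[o.source_id]
        else:
            scores = local_scores[o.source_id]
            cat, tie = assign_main_category(scores, global_freq)
            assignments[o.source_id] = CategoryAssignment(
                outlet_id=o.source_id, scores=scores, main_category=cat,
                tie_broken=tie, assignment_source=AssignmentSource.SCORED,
            )
    return assignments, registry
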