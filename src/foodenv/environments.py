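"""Assembly of local, online and hybrid food environments per geography, and
the summary statistics reported on them.

For a geographic unit (postcode, or region aggregating postcodes):

* the *local* environment is the set of food outlets physically located there;
* the *online* environment is the set of unique platform outlets able to
  deliver there (from the delivery rows, not physical location);
* the *hybrid* environment is their union with cross-listed outlets counted
  once — matched online outlets collapse onto their local twin.

The headline expansion statistic is the percent change: hybrid outlets divided
by local outlets, times 100, rounded half-up to an integer. Category shares
are one-decimal percentages; online accessibility per category is the online
count over the local count (it may exceed 100 when a category is better
represented on the platform than in the directory).
"""

from __future__ import annotations

from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .types import (
    CategoryAssignment,
    EnvironmentView,
    MainCategory,
    MatchResult,
    NormalizedOutlet,
    RegionSummary,
)

UNKNOWN_UNIT = "unknown"


def pct_change(n_local: int, n_hybrid: int) -> Optional[int]:
    """Integer percent: round-half-up of 100 * hybrid / local; None if no local."""
    if n_local <= 0:
        return None
    return int((Decimal(100 * n_hybrid) / Decimal(n_local))
               .quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def category_share(by_category: Mapping[MainCategory, int],
                   total: int) -> dict[MainCategory, float]:
    """Percent share per category at one-decimal precision (half-up)."""
    if total <= 0:
        return {c: 0.0 for c in by_category}
    return {c: _round1(100.0 * n / total) for c, n in by_category.items()}


def online_accessibility(n_online: int, n_local: int) -> Optional[float]:
    """Exact percent of local outlets of a category that are accessible online.

    Values above 100 are legitimate (more online than local listings of the
    category). Returns the unrounded value; render with
    :func:`format_accessibility` at either printed precision. None when the
    category has no local outlets.
    """
    if n_local <= 0:
        return 0.0 if n_online == 0 else None
    return 100.0 * n_online / n_local


def format_accessibility(value: Optional[float], decimals: int = 1) -> str:
    if value is None:
        return ""
    if decimals == 0:
        return str(int(Decimal(repr(value)).quantize(Decimal("1"),
                                                     rounding=ROUND_HALF_UP)))
    return str(_round1(value))


def cuisine_frequencies(
    outlets: Sequence[NormalizedOutlet],
) -> list[tuple[str, int]]:
    """Descriptor frequency table (the word-cloud payload), descending count,
    ties lexicographic."""
    counts = Counter(d for o in outlets for d in o.descriptors)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def density_by_postcode(counts: Mapping[str, int]) -> dict[str, float]:
    """Min-max scaled relative density per postcode on [0, 1].

    Degenerate case (all counts equal) maps every postcode to 1.0.
    """
    if not counts:
        return {}
    lo, hi = min(counts.values()), max(counts.values())
    if hi == lo:
        return {pc: 1.0 for pc in counts}
    return {pc: (n - lo) / (hi - lo) for pc, n in counts.items()}


def _category_counts(ids: frozenset[str],
                     assignments: Mapping[str, CategoryAssignment]) -> dict[MainCategory, int]:
    counts: Counter = Counter()
    for oid in ids:
        a = assignments.get(oid)
        counts[a.main_category if a else MainCategory.NA] += 1
    return dict(counts)


class EnvironmentAssembler:
    """Builds per-postcode and per-region local/online/hybrid views.

    Parameters
    ----------
    local_outlets : cleaned, filtered local outlets (physical locations).
    online_outlets : deduplicated online outlets (one per platform ID).
    delivery_rows : (platform_id, delivery_suburb_norm) pairs — one per suburb
        an outlet delivers to.
    matches : one-to-one online/local match results.
    geography : table with suburb/postcode/region columns (suburbs compared in
        normalized lowercase form).
    assignments : category assignments keyed by outlet id.
    """

    def __init__(
        self,
        local_outlets: Sequence[NormalizedOutlet],
        online_outlets: Sequence[NormalizedOutlet],
        delivery_rows: Sequence[tuple[str, str]],
        matches: Sequence[MatchResult],
        geography: pd.DataFrame,
        assignments: Optional[Mapping[str, CategoryAssignment]] = None,
    ) -> None:
        self.local_outlets = list(local_outlets)
        self.online_outlets = list(online_outlets)
        self.assignments = dict(assignments or {})
        self.online_to_local = {m.online_id: m.local_id for m in matches}
        self._outlet_by_id = {o.source_id: o for o in
                              self.local_outlets + self.online_outlets}

        geo = geography.copy()
        geo["suburb_norm"] = geo["suburb"].str.lower().str.strip()
        geo["postcode"] = geo["postcode"].astype(str)
        self.geography = geo
        self.suburb_to_postcode = dict(zip(geo["suburb_norm"], geo["postcode"]))
        self.postcode_to_region = dict(zip(geo["postcode"], geo["region"]))

        # local membership: physical postcode
        self.local_by_unit: dict[str, set[str]] = {}
        for o in self.local_outlets:
            unit = o.postcode_norm if o.postcode_norm in self.postcode_to_region \
                else UNKNOWN_UNIT
            self.local_by_unit.setdefault(unit, set()).add(o.source_id)
        # online membership: deliverable-to postcode from delivery rows
        self.online_by_unit: dict[str, set[str]] = {}
        for pid, suburb in delivery_rows:
            unit = self.suburb_to_postcode.get(str(suburb).lower().strip(),
                                               UNKNOWN_UNIT)
            self.online_by_unit.setdefault(unit, set()).add(pid)

    # -- view construction ---------------------------------------------------

    def _canon(self, online_id: str) -> str:
        """Collapse a matched online outlet onto its local twin's identity."""
        return self.online_to_local.get(online_id, online_id)

    def _make_view(self, scope: str, unit: str, ids: frozenset[str]) -> EnvironmentView:
        outlets = [self._outlet_by_id[i] for i in ids if i in self._outlet_by_id]
        return EnvironmentView(
            scope=scope,
            geography_unit=unit,
            outlet_ids=ids,
            by_category=_category_counts(ids, self.assignments),
            cuisine_frequencies=cuisine_frequencies(outlets),
        )

    def unit_views(self, unit: str) -> dict[str, EnvironmentView]:
        """The (local, online, hybrid) triple for one postcode unit."""
        local_ids = frozenset(self.local_by_unit.get(unit, set()))
        online_ids = frozenset(self.online_by_unit.get(unit, set()))
        hybrid_ids = frozenset(local_ids | {self._canon(i) for i in online_ids})
        return {
            "local": self._make_view("local", unit, local_ids),
            "online": self._make_view("online", unit, online_ids),
            "hybrid": self._make_view("hybrid", unit, hybrid_ids),
        }

    def all_units(self) -> list[str]:
        units = set(self.local_by_unit) | set(self.online_by_unit)
        return sorted(units)

    def build_views(self) -> dict[str, dict[str, EnvironmentView]]:
        """Per-postcode view triples for every unit with any outlet."""
        return {u: self.unit_views(u) for u in self.all_units()}

    # -- region and total summaries -------------------------------------------

    def region_views(self, region: str) -> dict[str, EnvironmentView]:
        postcodes = [pc for pc, r in self.postcode_to_region.items() if r == region]
        local_ids = frozenset().union(
            *[frozenset(self.local_by_unit.get(pc, set())) for pc in postcodes]
        ) if postcodes else frozenset()
        online_ids = frozenset().union(
            *[frozenset(self.online_by_unit.get(pc, set())) for pc in postcodes]
        ) if postcodes else frozenset()
        hybrid_ids = frozenset(local_ids | {self._canon(i) for i in online_ids})
        return {
            "local": self._make_view("local", region, local_ids),
            "online": self._make_view("online", region, online_ids),
            "hybrid": self._make_view("hybrid", region, hybrid_ids),
        }

    def region_summaries(self) -> list[RegionSummary]:
        out = []
        for region, g in self.geography.groupby("region", sort=True):
            views = self.region_views(region)
            n_local = views["local"].n_outlets
            n_hybrid = views["hybrid"].n_outlets
            out.append(RegionSummary(
                region=region,
                n_postcodes=g["postcode"].nunique(),
                population=int(g["region_population"].iloc[0]),
                n_local=n_local,
                n_online=views["online"].n_outlets,
                n_hybrid=n_hybrid,
                pct_change=pct_change(n_local, n_hybrid),
            ))
        return out

    def unique_totals(self) -> dict[str, int]:
        """State-wide unique outlet totals (each outlet counted once, however
        many units it appears in)."""
        local_ids = {o.source_id for o in self.local_outlets}
        online_ids = {o.source_id for o in self.online_outlets}
        hybrid_ids = local_ids | {self._canon(i) for i in online_ids}
        return {
            "local": len(local_ids),
            "online": len(online_ids),
            "hybrid": len(hybrid_ids),
        }

    def category_table(self) -> pd.DataFrame:
        """State-wide category composition: counts and shares per scope, plus
        per-category online accessibility."""
        local_ids = frozenset(o.source_id for o in self.local_outlets)
        online_ids = frozenset(o.source_id for o in self.online_outlets)
        hybrid_ids = frozenset(local_ids | {self._canon(i) for i in online_ids})
        local_cat = _category_counts(local_ids, self.assignments)
        online_cat = _category_counts(online_ids, self.assignments)
        hybrid_cat = _category_counts(hybrid_ids, self.assignments)
        local_share = category_share(local_cat, len(local_ids))
        online_share = category_share(online_cat, len(online_ids))
        hybrid_share = category_share(hybrid_cat, len(hybrid_ids))
        rows = []
        cats = sorted(set(local_cat) | set(online_cat) | set(hybrid_cat),
                      key=lambda c: c.value)
        for c in cats:
            acc = online_accessibility(online_cat.get(c, 0), local_cat.get(c, 0))
            rows.append({
                "category": c.value,
                "n_local": local_cat.get(c, 0),
                "pct_local": local_share.get(c, 0.0),
                "n_online": online_cat.get(c, 0),
                "pct_online": online_share.get(c, 0.0),
                "n_hybrid": hybrid_cat.get(c, 0),
                "pct_hybrid": hybrid_share.get(c, 0.0),
                "accessibility_pct": acc,
                "accessibility_1dp": format_accessibility(acc, 1),
                "accessibility_int": format_accessibility(acc, 0),
            })
        return pd.DataFrame(rows)

    def densities(self, scope: str = "hybrid") -> dict[str, float]:
        """Per-postcode relative density of the chosen scope's outlet counts."""
        views = self.build_views()
        counts = {u: v[scope].n_outlets for u, v in views.items()
                  if u != UNKNOWN_UNIT}
        return density_by_postcode(counts)
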