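"""The deterministic matching cascade linking online to local outlets.

Matching proceeds through 15 ordered steps, each placing fewer restrictions
than the last; matched records leave both pools before the next step, and the
result is one-to-one. Steps 1-9 require exact equality of the normalized name
plus a shrinking set of address fields. Steps 10-11 drop the exact-name
requirement but demand a name similarity of at least 83 on the 0-100 ratio
scale. Steps 12-15 nominally require only one shared field; taken literally
they would match almost anything, so they are additionally constrained to the
dual similarity thresholds. After step 15, a final similarity pass matches
remaining pairs whose name AND address similarities clear the thresholds on
BOTH scales (Jaro >= 0.90 and edit ratio >= 90).

Within a step, online outlets are processed in stable sorted-ID order and each
takes its best remaining candidate (highest name ratio, then lexicographically
smallest local ID), so permuting the input row order never changes the match
set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .config import SimilarityThresholds
from .similarity import name_similarity
from .types import MatchResult, NormalizedOutlet

#: field-equality sets of the 15 cascade steps
_STEP_FIELDS: dict[int, tuple[str, ...]] = {
    1: ("name", "street_name", "suburb", "postcode"),
    2: ("name", "street_name", "suburb"),
    3: ("name", "street_name", "postcode"),
    4: ("name", "postcode"),
    5: ("name", "suburb"),
    6: ("name", "street_name", "street_type"),
    7: ("name", "suburb", "postcode"),
    8: ("name", "street_number", "street_name"),
    9: ("name", "street_number", "suburb", "postcode"),
    10: ("street_number", "street_name", "suburb", "postcode"),
    11: ("street_name", "suburb", "postcode"),
    12: ("postcode",),
    13: ("suburb",),
    14: ("street_name",),
    15: ("street_type",),
}

_FIELD_ATTRS = {
    "name": "name_norm",
    "street_number": "street_number",
    "street_name": "street_name",
    "street_type": "street_type",
    "suburb": "suburb_norm",
    "postcode": "postcode_norm",
}


@dataclass(frozen=True)
class MatchStepSpec:
    """One cascade step: required equal fields plus optional fuzzy constraints."""

    step: int
    required_equal_fields: tuple[str, ...]
    name_similarity_min: Optional[float] = None  # on the 0-100 ratio scale
    require_dual_similarity: bool = False

    def __post_init__(self) -> None:
        bad = set(self.required_equal_fields) - set(_FIELD_ATTRS)
        if bad:
            raise ValueError(f"unknown match fields: {sorted(bad)}")


def default_match_steps(
    thresholds: Optional[SimilarityThresholds] = None,
) -> list[MatchStepSpec]:
    """The 15-step sequence: exact-name steps 1-9, the 83%-name steps 10-11,
    and the similarity-constrained single-field steps 12-15."""
    thresholds = thresholds or SimilarityThresholds()
    steps = []
    for n, fields in _STEP_FIELDS.items():
        if n in (10, 11):
            steps.append(MatchStepSpec(n, fields,
                                       name_similarity_min=thresholds.step10_11_name_min))
        elif n >= 12:
            steps.append(MatchStepSpec(n, fields, require_dual_similarity=True))
        else:
            steps.append(MatchStepSpec(n, fields))
    return steps


def _passes_dual(o: NormalizedOutlet, l: NormalizedOutlet,
                 thresholds: SimilarityThresholds) -> bool:
    nj, nr = name_similarity(o.name_norm, l.name_norm)
    if nj < thresholds.jaro_min or nr < thresholds.levenshtein_ratio_min:
        return False
    aj, ar = name_similarity(o.address_string(), l.address_string())
    return aj >= thresholds.jaro_min and ar >= thresholds.levenshtein_ratio_min


def _result(o: NormalizedOutlet, l: NormalizedOutlet,
            step: Union[int, str]) -> MatchResult:
    nj, nr = name_similarity(o.name_norm, l.name_norm)
    _, ar = name_similarity(o.address_string(), l.address_string())
    return MatchResult(online_id=o.source_id, local_id=l.source_id, step=step,
                       name_similarity_jaro=nj, name_similarity_ratio=nr,
                       address_similarity_ratio=ar)


def run_cascade(
    online: Sequence[NormalizedOutlet],
    local: Sequence[NormalizedOutlet],
    steps: Optional[Sequence[MatchStepSpec]] = None,
    thresholds: Optional[SimilarityThresholds] = None,
) -> tuple[list[MatchResult], list[NormalizedOutlet], list[NormalizedOutlet]]:
    """Run the full cascade plus the final dual-similarity pass.

    Inputs must be deduplicated (unique source ids) — duplicates raise. Returns
    ``(matches, unmatched_online, unmatched_local)``; the step recorded on each
    match is the first step whose criteria the pair satisfied.
    """
    thresholds = thresholds or SimilarityThresholds()
    steps = list(steps) if steps is not None else default_match_steps(thresholds)
    for pool, label in ((online, "online"), (local, "local")):
        ids = [o.source_id for o in pool]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in {label} input; dedupe upstream")

    online_pool = sorted(online, key=lambda o: o.source_id)
    local_pool = sorted(local, key=lambda o: o.source_id)
    matches: list[MatchResult] = []

    for spec in steps:
        attrs = [_FIELD_ATTRS[f] for f in spec.required_equal_fields]
        index: dict[tuple, list[NormalizedOutlet]] = {}
        for l in local_pool:
            index.setdefault(tuple(getattr(l, a) for a in attrs), []).append(l)
        taken_local: set[str] = set()
        taken_online: set[str] = set()
        for o in online_pool:
            key = tuple(getattr(o, a) for a in attrs)
            cands = [l for l in index.get(key, []) if l.source_id not in taken_local]
            if spec.name_similarity_min is not None:
                cands = [l for l in cands
                         if name_similarity(o.name_norm, l.name_norm)[1]
                         >= spec.name_similarity_min]
            if spec.require_dual_similarity:
                cands = [l for l in cands if _passes_dual(o, l, thresholds)]
            if not cands:
                continue
            best = min(cands, key=lambda l: (
                -name_similarity(o.name_norm, l.name_norm)[1], l.source_id))
            matches.append(_result(o, best, spec.step))
            taken_local.add(best.source_id)
            taken_online.add(o.source_id)
        if taken_online:
            online_pool = [o for o in online_pool if o.source_id not in taken_online]
            local_pool = [l for l in local_pool if l.source_id not in taken_local]

    # final pass: dual name+address similarity with no field-equality blocking
    taken_local = set()
    taken_online = set()
    for o in online_pool:
        cands = [l for l in local_pool
                 if l.source_id not in taken_local and _passes_dual(o, l, thresholds)]
        if not cands:
            continue
        best = min(cands, key=lambda l: (
            -name_similarity(o.name_norm, l.name_norm)[1], l.source_id))
        matches.append(_result(o, best, "similarity_pass"))
        taken_local.add(best.source_id)
        taken_online.add(o.source_id)
    online_pool = [o for o in online_pool if o.source_id not in taken_online]
    local_pool = [l for l in local_pool if l.source_id not in taken_local]
    return matches, online_pool, local_pool


# ---------------------------------------------------------------------------
# unmatched audit

AUDIT_REASONS = (
    "malformed_field",
    "centre_address_residue",
    "suburb_inconsistency",
    "name_near_miss",
    "no_candidate",
)

_POSTCODE_RE = re.compile(r"^\d{4}$")


@dataclass
class AuditEntry:
    online_id: str
    reason: str
    detail: str = ""


def audit_unmatched(
    unmatched_online: Sequence[NormalizedOutlet],
    local: Sequence[NormalizedOutlet],
    centre_list: Sequence[str] = (),
    raw_fields: Optional[dict[str, dict[str, Optional[str]]]] = None,
    near_miss_ratio: float = 75.0,
) -> list[AuditEntry]:
    """Classify unmatched online outlets into the observed error taxonomy.

    Advisory only — it explains why a record probably failed to match, in
    priority order: malformed raw fields (e.g. a postcode sitting in the state
    column), shopping-centre residue left in the address, suburb naming
    inconsistencies (same name, suburbs equal once spaces are removed), a
    near-miss name in the same suburb/postcode, else no plausible candidate.

    ``raw_fields`` optionally maps online ids to their raw ``state``/
    ``postcode`` column values for the malformed-field check.
    """
    raw_fields = raw_fields or {}
    centre_tokens = [c.lower() for c in centre_list]
    by_name: dict[str, list[NormalizedOutlet]] = {}
    for l in local:
        by_name.setdefault(l.name_norm, []).append(l)

    entries: list[AuditEntry] = []
    for o in unmatched_online:
        raw = raw_fields.get(o.source_id, {})
        state_val = (raw.get("state") or "").strip()
        postcode_val = (raw.get("postcode") or "").strip()
        if (_POSTCODE_RE.match(state_val)
                or (postcode_val and not _POSTCODE_RE.match(postcode_val))):
            entries.append(AuditEntry(o.source_id, "malformed_field",
                                      f"state={state_val!r} postcode={postcode_val!r}"))
            continue
        addr = f"{o.street_name} {o.street_type}"
        if any(tok in addr or tok in o.name_norm for tok in centre_tokens):
            entries.append(AuditEntry(o.source_id, "centre_address_residue", addr))
            continue
        twins = by_name.get(o.name_norm, [])
        squeezed = o.suburb_norm.replace(" ", "")
        inconsistent = [
            l for l in twins
            if l.suburb_norm != o.suburb_norm
            and l.suburb_norm.replace(" ", "") == squeezed
        ]
        if inconsistent:
            entries.append(AuditEntry(o.source_id, "suburb_inconsistency",
                                      inconsistent[0].suburb_norm))
            continue
        near = [
            l for l in local
            if (l.suburb_norm == o.suburb_norm or l.postcode_norm == o.postcode_norm)
            and near_miss_ratio <= name_similarity(o.name_norm, l.name_norm)[1] < 100.0
        ]
        if near:
            entries.append(AuditEntry(o.source_id, "name_near_miss",
                                      near[0].name_norm))
            continue
        entries.append(AuditEntry(o.source_id, "no_candidate"))
    return entries
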