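"""Cleaning, parsing, deduplication and imputation of scraped outlet rows.

The rules make two differently-noisy sources comparable:

* suburbs: lowercase, dashes/quotes stripped, spaces kept (so "Brighton Le
  Sands" and "Brightonlesands" deliberately remain unequal — a documented
  failure mode of the source data, surfaced later by the unmatched audit);
  rows from outside the target state are rejected;
* names: lowercase alphanumerics, with shopping-centre, petrol-station,
  suburb, city and state tokens removed whole-word;
* street addresses: embedded suburb/state/postcode stripped, centre/building
  prefixes and unit designators removed, then split into (number, name, type)
  with a closed street-type vocabulary;
* missing fields: suburb imputed as the modal suburb of its postcode over the
  combined dataset; the sentinels are suburb "empty", postcode "0000" and
  street number "12345".

Every operation is idempotent and never touches ``source``/``source_id``.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import Counter, defaultdict
from dataclasses import replace
from typing import Iterable, Optional, Sequence, Union

from .config import NormalizationConfig
from .types import NormalizedOutlet, RawOutletListing, Source, Status

logger = logging.getLogger(__name__)


class _Reject:
    """Sentinel for rows excluded by the state filter."""

    def __repr__(self) -> str:  # pragma: no cover
        return "REJECT"


REJECT = _Reject()

_WS = re.compile(r"\s+")
_NON_ALNUM_SPACE = re.compile(r"[^a-z0-9 ]+")
_UNIT_PREFIX = re.compile(r"^(?:shop|unit|level|suite|kiosk|stall|shed)\s+\w+\s+")


def _strip_diacritics(s: str) -> str:
    # so accented names can match their plain-ASCII twins ("café" -> "cafe")
    return "".join(
        c for c in unicodedata.normalize("NFKD", s) if not unicodedata.combining(c)
    )


def _basic_clean(s: str) -> str:
    """Lowercase, de-accent, '&' -> 'and', drop non-alphanumerics, collapse spaces."""
    s = _strip_diacritics(s).lower().replace("&", " and ")
    s = _NON_ALNUM_SPACE.sub("", s)
    return _WS.sub(" ", s).strip()


def _remove_phrases(text: str, phrases: Iterable[str]) -> str:
    """Remove whole-word occurrences of each (cleaned) phrase."""
    for phrase in phrases:
        p = _basic_clean(phrase)
        if not p:
            continue
        text = re.sub(rf"(?:(?<=^)|(?<= )){re.escape(p)}(?=$| )", "", text)
        text = _WS.sub(" ", text).strip()
    return text


def normalize_suburb(
    raw_suburb: Optional[str],
    state: Optional[str],
    config: NormalizationConfig,
) -> Union[str, None, _Reject]:
    """Clean a suburb string; REJECT rows from outside the target state.

    Only dashes/quotes (and other specials) are removed — no spaces are
    inserted, so differently-spaced variants of one suburb stay distinct.
    Missing input returns None for downstream imputation.
    """
    if state is not None:
        state_clean = _basic_clean(state)
        if state_clean and state_clean not in {_basic_clean(t) for t in config.target_states}:
            return REJECT
    if raw_suburb is None or not str(raw_suburb).strip():
        return None
    cleaned = _basic_clean(str(raw_suburb))
    return cleaned or None  # all-punctuation input is as good as missing


def normalize_name(
    raw_name: str,
    centre_list: Sequence[str],
    suburb_list: Sequence[str],
    city_state_tokens: Sequence[str],
    petrol_list: Sequence[str] = (),
) -> str:
    """Canonical outlet-name form.

    Removal order (fixed and documented): centre names, petrol-station names,
    suburb names, then city/state tokens. Longer phrases are removed before
    shorter ones within each group so multi-word names win. An empty result is
    returned as "" and flagged by the caller for manual review.
    """
    text = _basic_clean(raw_name)
    for group in (centre_list, petrol_list, suburb_list, city_state_tokens):
        ordered = sorted(group, key=lambda p: -len(p))
        text = _remove_phrases(text, ordered)
    if not text:
        logger.warning("outlet name empty after normalization: %r", raw_name)
    return text


MISSING_STREET_NUMBER = "12345"
MISSING_SUBURB = "empty"
MISSING_POSTCODE = "0000"

_LEADING_NUMBER = re.compile(r"^(\d+[a-z]?)(?:\s+|$)")
_TRAILING_POSTCODE = re.compile(r"\s\d{4}$")


def parse_street_address(
    raw_address: Optional[str],
    suburb: Optional[str],
    postcode: Optional[str],
    state: Optional[str],
    centre_list: Sequence[str],
    street_types: dict[str, str],
    state_tokens: Sequence[str] = (),
) -> tuple[str, str, str]:
    """Split a raw street address into (street_number, street_name, street_type).

    Embedded suburb/postcode/state copies and centre/building prefixes are
    removed first; unit designators ("shop 12", "level 3") are stripped from
    the front. A missing leading number becomes the "12345" sentinel. A
    trailing token outside the street-type vocabulary leaves street_type
    "unknown" with the full remainder as the street name.
    """
    text = _basic_clean(raw_address or "")
    tokens = list(state_tokens) + ([state] if state else [])
    text = _remove_phrases(text, sorted({t for t in tokens if t}, key=lambda p: -len(p)))
    if suburb:
        text = _remove_phrases(text, [suburb])
    if postcode:
        text = _remove_phrases(text, [str(postcode)])
    text = _TRAILING_POSTCODE.sub("", text).strip()
    text = _remove_phrases(text, sorted(centre_list, key=lambda p: -len(p)))
    while True:
        stripped = _UNIT_PREFIX.sub("", text)
        if stripped == text:
            break
        text = stripped

    m = _LEADING_NUMBER.match(text)
    if m:
        number = m.group(1)
        rest = text[m.end():].strip()
    else:
        number = MISSING_STREET_NUMBER
        rest = text
    parts = rest.split()
    if parts and parts[-1] in street_types:
        stype = street_types[parts[-1]]
        name = " ".join(parts[:-1])
    else:
        stype = "unknown"
        name = rest
    return number, name, stype


def normalize_listing(
    raw: RawOutletListing,
    config: NormalizationConfig,
) -> Union[NormalizedOutlet, _Reject]:
    """Apply all field-level rules to one raw row (imputation comes later)."""
    suburb = normalize_suburb(raw.suburb, raw.state, config)
    if suburb is REJECT:
        return REJECT
    name = normalize_name(
        raw.name, config.centre_list, config.suburb_list,
        config.city_tokens + config.state_tokens, config.petrol_list,
    )
    number, street_name, street_type = parse_street_address(
        raw.street_address, suburb, raw.postcode, raw.state,
        config.centre_list, config.street_types, config.state_tokens,
    )
    postcode = None
    if raw.postcode is not None and re.fullmatch(r"\d{4}", str(raw.postcode).strip()):
        postcode = str(raw.postcode).strip()
    return NormalizedOutlet(
        source=raw.source,
        source_id=raw.source_id,
        name_norm=name,
        street_number=number,
        street_name=street_name,
        street_type=street_type,
        suburb_norm=suburb if suburb is not None else "",
        postcode_norm=postcode if postcode is not None else "",
        imputed_street_number=(number == MISSING_STREET_NUMBER),
        descriptors=[_basic_clean(d) for d in raw.category_descriptors],
        latitude=raw.latitude,
        longitude=raw.longitude,
    )


def compute_postcode_suburb_stats(
    records: Iterable[NormalizedOutlet],
) -> dict[str, str]:
    """Modal suburb per postcode over the combined dataset, ties lexicographic."""
    counts: dict[str, Counter] = defaultdict(Counter)
    for r in records:
        if r.postcode_norm and r.suburb_norm and not r.imputed_suburb:
            counts[r.postcode_norm][r.suburb_norm] += 1
    return {
        pc: min((s for s, n in c.items() if n == max(c.values())))
        for pc, c in counts.items()
    }


def compute_suburb_postcode_stats(
    records: Iterable[NormalizedOutlet],
) -> dict[str, str]:
    """Modal postcode per suburb (the symmetric table), ties lexicographic."""
    counts: dict[str, Counter] = defaultdict(Counter)
    for r in records:
        if r.postcode_norm and r.suburb_norm and not r.imputed_postcode:
            counts[r.suburb_norm][r.postcode_norm] += 1
    return {
        sb: min((p for p, n in c.items() if n == max(c.values())))
        for sb, c in counts.items()
    }


def impute_missing(
    record: NormalizedOutlet,
    postcode_suburb_stats: dict[str, str],
    suburb_postcode_stats: Optional[dict[str, str]] = None,
) -> NormalizedOutlet:
    """Fill missing suburb/postcode using the combined-dataset modal tables.

    Missing suburb with a known postcode takes that postcode's modal suburb; a
    postcode unseen in the stats leaves suburb "empty" (postcode kept). Both
    missing become ("empty", "0000"). A missing postcode with a known suburb
    takes the suburb's modal postcode where one exists, else "0000".
    """
    suburb = record.suburb_norm
    postcode = record.postcode_norm
    imputed_suburb = record.imputed_suburb
    imputed_postcode = record.imputed_postcode
    if not suburb and not postcode:
        suburb, postcode = MISSING_SUBURB, MISSING_POSTCODE
        imputed_suburb = imputed_postcode = True
    elif not suburb:
        modal = postcode_suburb_stats.get(postcode)
        suburb = modal if modal is not None else MISSING_SUBURB
        imputed_suburb = True
    elif not postcode:
        modal = (suburb_postcode_stats or {}).get(suburb)
        postcode = modal if modal is not None else MISSING_POSTCODE
        imputed_postcode = True
    if (suburb, postcode, imputed_suburb, imputed_postcode) == (
        record.suburb_norm, record.postcode_norm,
        record.imputed_suburb, record.imputed_postcode,
    ):
        return record
    return replace(
        record,
        suburb_norm=suburb,
        postcode_norm=postcode,
        imputed_suburb=imputed_suburb,
        imputed_postcode=imputed_postcode,
    )


def dedupe_online(rows: Sequence[RawOutletListing]) -> list[RawOutletListing]:
    """One representative row per platform outlet ID.

    The representative is the row whose delivery suburb equals the outlet's
    physical suburb when such a row exists, else the first row in stable input
    order. Conflicting physical addresses under one ID keep the modal address
    (a warning is logged).
    """
    by_id: dict[str, list[RawOutletListing]] = {}
    order: list[str] = []
    for row in rows:
        if row.source_id not in by_id:
            order.append(row.source_id)
        by_id.setdefault(row.source_id, []).append(row)
    out = []
    n_conflicts = 0
    for pid in order:
        group = by_id[pid]
        addresses = Counter(r.street_address for r in group)
        if len(addresses) > 1:
            n_conflicts += 1
            logger.debug("platform id %s lists %d distinct addresses; keeping modal",
                         pid, len(addresses))
            modal_addr = min(
                (a for a, n in addresses.items() if n == max(addresses.values()))
            )
            group = [r for r in group if r.street_address == modal_addr]
        rep = next(
            (r for r in group
             if r.suburb and r.extra.get("delivery_suburb")
             and str(r.extra["delivery_suburb"]).strip().lower()
             == str(r.suburb).strip().lower()),
            group[0],
        )
        out.append(rep)
    if n_conflicts:
        logger.warning("%d platform ids listed conflicting physical addresses; "
                       "kept the modal address for each", n_conflicts)
    return out


def filter_local(
    rows: Sequence[RawOutletListing],
    nonfood_categories: Sequence[str],
) -> list[RawOutletListing]:
    """Drop permanently-closed rows, rows whose tags are all non-food, and
    repeated directory IDs (first occurrence kept)."""
    nonfood = {_basic_clean(c) for c in nonfood_categories}
    seen: set[str] = set()
    out = []
    for row in rows:
        if row.source_id in seen:
            continue
        seen.add(row.source_id)
        if row.status is Status.PERMANENTLY_CLOSED:
            continue
        tags = [_basic_clean(d) for d in row.category_descriptors]
        if tags and all(t in nonfood for t in tags):
            continue
        out.append(row)
    return out


def normalize_dataset(
    online_rows: Sequence[RawOutletListing],
    local_rows: Sequence[RawOutletListing],
    config: NormalizationConfig,
) -> tuple[list[NormalizedOutlet], list[NormalizedOutlet]]:
    """Full cleaning pass: dedupe/filter, normalize, then impute with modal
    tables computed over the combined dataset."""
    online_unique = dedupe_online(online_rows)
    local_kept = filter_local(local_rows, config.nonfood_categories)
    online_norm = [
        n for n in (normalize_listing(r, config) for r in online_unique)
        if n is not REJECT
    ]
    local_norm = [
        n for n in (normalize_listing(r, config) for r in local_kept)
        if n is not REJECT
    ]
    ps_stats = compute_postcode_suburb_stats(online_norm + local_norm)
    sp_stats = compute_suburb_postcode_stats(online_norm + local_norm)
    online_out = [impute_missing(r, ps_stats, sp_stats) for r in online_norm]
    local_out = [impute_missing(r, ps_stats, sp_stats) for r in local_norm]
    return online_out, local_out
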