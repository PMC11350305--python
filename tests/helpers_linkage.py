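"""Brute-force reference implementation of the matching cascade.

Written independently of ``foodenv.linkage``: no blocking indexes, no pooled
data structures — every remaining (online, local) pair is tested against every
step in order, straight from a literal transcription of the step table. Used
as the oracle for cascade-equivalence tests.
"""

from __future__ import annotations

from foodenv.similarity import jaro, levenshtein_ratio

# (step, fields, name_ratio_min, dual_similarity_required)
STEP_TABLE = [
    (1, ("name", "street_name", "suburb", "postcode"), None, False),
    (2, ("name", "street_name", "suburb"), None, False),
    (3, ("name", "street_name", "postcode"), None, False),
    (4, ("name", "postcode"), None, False),
    (5, ("name", "suburb"), None, False),
    (6, ("name", "street_name", "street_type"), None, False),
    (7, ("name", "suburb", "postcode"), None, False),
    (8, ("name", "street_number", "street_name"), None, False),
    (9, ("name", "street_number", "suburb", "postcode"), None, False),
    (10, ("street_number", "street_name", "suburb", "postcode"), 83.0, False),
    (11, ("street_name", "suburb", "postcode"), 83.0, False),
    (12, ("postcode",), None, True),
    (13, ("suburb",), None, True),
    (14, ("street_name",), None, True),
    (15, ("street_type",), None, True),
]

_ATTR = {
    "name": "name_norm",
    "street_number": "street_number",
    "street_name": "street_name",
    "street_type": "street_type",
    "suburb": "suburb_norm",
    "postcode": "postcode_norm",
}


def _addr(o):
    return " ".join(p for p in (o.street_number, o.street_name, o.street_type) if p)


def _dual_ok(o, l, jaro_min=0.90, ratio_min=90.0):
    if jaro(o.name_norm, l.name_norm) < jaro_min:
        return False
    if levenshtein_ratio(o.name_norm, l.name_norm) < ratio_min:
        return False
    if jaro(_addr(o), _addr(l)) < jaro_min:
        return False
    return levenshtein_ratio(_addr(o), _addr(l)) >= ratio_min


def oracle_cascade(online, local, jaro_min=0.90, ratio_min=90.0,
                   step10_11_min=83.0):
    """Returns {(online_id, local_id): step} for the full cascade plus the
    final dual-similarity pass."""
    online = sorted(online, key=lambda o: o.source_id)
    local = sorted(local, key=lambda l: l.source_id)
    matched_online: set[str] = set()
    matched_local: set[str] = set()
    result: dict[tuple[str, str], object] = {}

    def try_round(criterion, step_label):
        for o in online:
            if o.source_id in matched_online:
                continue
            best = None
            best_key = None
            for l in local:
                if l.source_id in matched_local:
                    continue
                if not criterion(o, l):
                    continue
                key = (-levenshtein_ratio(o.name_norm, l.name_norm), l.source_id)
                if best is None or key < best_key:
                    best, best_key = l, key
            if best is not None:
                result[(o.source_id, best.source_id)] = step_label
                matched_online.add(o.source_id)
                matched_local.add(best.source_id)

    for step, fields, name_min, dual in STEP_TABLE:
        def crit(o, l, fields=fields, name_min=name_min, dual=dual):
            for f in fields:
                if getattr(o, _ATTR[f]) != getattr(l, _ATTR[f]):
                    return False
            if name_min is not None and \
                    levenshtein_ratio(o.name_norm, l.name_norm) < name_min:
                return False
            if dual and not _dual_ok(o, l, jaro_min, ratio_min):
                return False
            return True
        try_round(crit, step)

    try_round(lambda o, l: _dual_ok(o, l, jaro_min, ratio_min), "similarity_pass")
    return result
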