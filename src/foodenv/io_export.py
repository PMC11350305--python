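"""CSV/JSON/GeoJSON readers and writers for every pipeline stage.

Dialect is fixed: UTF-8, comma-delimited, quoted strings, header row.
Descriptor lists are serialised pipe-separated (descriptors never contain a
pipe). GeoJSON uses WGS84 lon-lat coordinate order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .linkage import AuditEntry
from .types import (
    CategoryAssignment,
    MatchResult,
    NormalizedOutlet,
    RawOutletListing,
    RegionSummary,
    Source,
    Status,
)

_SEP = "|"
_CSV_KW = dict(index=False, encoding="utf-8")


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, quoting=1, **_CSV_KW)  # QUOTE_ALL for strings is overkill; 1=QUOTE_ALL


def write_raw_listings(rows: Sequence[RawOutletListing], path: str | Path) -> None:
    records = []
    for r in rows:
        records.append({
            "source": r.source.value,
            "source_id": r.source_id,
            "name": r.name,
            "street_address": r.street_address,
            "suburb": r.suburb or "",
            "state": r.state or "",
            "postcode": r.postcode or "",
            "latitude": "" if r.latitude is None else r.latitude,
            "longitude": "" if r.longitude is None else r.longitude,
            "category_descriptors": _SEP.join(r.category_descriptors),
            "status": r.status.value,
            "delivery_suburb": r.extra.get("delivery_suburb", ""),
            "row_id": r.extra.get("row_id", ""),
        })
    _df_to_csv(pd.DataFrame(records), Path(path))


def read_raw_listings(path: str | Path) -> list[RawOutletListing]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = []
    for rec in df.to_dict("records"):
        extra = {}
        if rec.get("delivery_suburb"):
            extra["delivery_suburb"] = rec["delivery_suburb"]
        if rec.get("row_id"):
            extra["row_id"] = rec["row_id"]
        rows.append(RawOutletListing(
            source=Source(rec["source"]),
            source_id=rec["source_id"],
            name=rec["name"],
            street_address=rec["street_address"],
            suburb=rec["suburb"] or None,
            state=rec["state"] or None,
            postcode=rec["postcode"] or None,
            latitude=float(rec["latitude"]) if rec["latitude"] else None,
            longitude=float(rec["longitude"]) if rec["longitude"] else None,
            category_descriptors=(rec["category_descriptors"].split(_SEP)
                                  if rec["category_descriptors"] else []),
            status=Status(rec["status"]),
            extra=extra,
        ))
    return rows


def write_truth_map(truth_map: Sequence[tuple[str, str, str]],
                    path: str | Path) -> None:
    df = pd.DataFrame(truth_map, columns=["row_id", "truth_id", "contaminant_flag"])
    _df_to_csv(df, Path(path))


def read_truth_map(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [tuple(r) for r in df[["row_id", "truth_id", "contaminant_flag"]].values]


def write_geography(geography: pd.DataFrame, path: str | Path) -> None:
    _df_to_csv(geography, Path(path))


def read_geography(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"postcode": str})
    df["urban"] = df["urban"].astype(bool)
    return df


def write_normalized(outlets: Sequence[NormalizedOutlet], path: str | Path) -> None:
    records = []
    for o in outlets:
        records.append({
            "source": o.source.value,
            "source_id": o.source_id,
            "name_norm": o.name_norm,
            "street_number": o.street_number,
            "street_name": o.street_name,
            "street_type": o.street_type,
            "suburb_norm": o.suburb_norm,
            "postcode_norm": o.postcode_norm,
            "imputed_suburb": o.imputed_suburb,
            "imputed_postcode": o.imputed_postcode,
            "imputed_street_number": o.imputed_street_number,
            "descriptors": _SEP.join(o.descriptors),
            "latitude": "" if o.latitude is None else o.latitude,
            "longitude": "" if o.longitude is None else o.longitude,
        })
    _df_to_csv(pd.DataFrame(records), Path(path))


def read_normalized(path: str | Path) -> list[NormalizedOutlet]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        out.append(NormalizedOutlet(
            source=Source(rec["source"]),
            source_id=rec["source_id"],
            name_norm=rec["name_norm"],
            street_number=rec["street_number"],
            street_name=rec["street_name"],
            street_type=rec["street_type"],
            suburb_norm=rec["suburb_norm"],
            postcode_norm=rec["postcode_norm"],
            imputed_suburb=rec["imputed_suburb"] == "True",
            imputed_postcode=rec["imputed_postcode"] == "True",
            imputed_street_number=rec["imputed_street_number"] == "True",
            descriptors=rec["descriptors"].split(_SEP) if rec["descriptors"] else [],
            latitude=float(rec["latitude"]) if rec["latitude"] else None,
            longitude=float(rec["longitude"]) if rec["longitude"] else None,
        ))
    return out


def write_matches(matches: Sequence[MatchResult], path: str | Path) -> None:
    df = pd.DataFrame([{
        "online_id": m.online_id,
        "local_id": m.local_id,
        "step": m.step,
        "name_similarity_jaro": m.name_similarity_jaro,
        "name_similarity_ratio": m.name_similarity_ratio,
        "address_similarity_ratio": m.address_similarity_ratio,
    } for m in matches])
    _df_to_csv(df, Path(path))


def read_matches(path: str | Path) -> list[MatchResult]:
    df = pd.read_csv(path, dtype={"online_id": str, "local_id": str, "step": str},
                     float_precision="round_trip")
    out = []
    for rec in df.to_dict("records"):
        step = rec["step"]
        out.append(MatchResult(
            online_id=rec["online_id"],
            local_id=rec["local_id"],
            step=int(step) if str(step).isdigit() else str(step),
            name_similarity_jaro=float(rec["name_similarity_jaro"]),
            name_similarity_ratio=float(rec["name_similarity_ratio"]),
            address_similarity_ratio=float(rec["address_similarity_ratio"]),
        ))
    return out


def write_audit(entries: Sequence[AuditEntry], path: str | Path) -> None:
    df = pd.DataFrame([{"online_id": e.online_id, "reason": e.reason,
                        "detail": e.detail} for e in entries])
    _df_to_csv(df, Path(path))


def write_assignments(assignments: Mapping[str, CategoryAssignment],
                      path: str | Path) -> None:
    df = pd.DataFrame([{
        "outlet_id": a.outlet_id,
        "main_category": a.main_category.value,
        "franchise_subtype": a.franchise_subtype.value if a.franchise_subtype else "",
        "assignment_source": a.assignment_source.value,
        "tie_broken": a.tie_broken,
        "scores": json.dumps({c.value: s for c, s in sorted(a.scores.items(),
                                                            key=lambda kv: kv[0].value)}),
    } for a in assignments.values()])
    _df_to_csv(df, Path(path))


def write_region_summaries(summaries: Sequence[RegionSummary],
                           path: str | Path) -> None:
    df = pd.DataFrame([{
        "region": s.region,
        "n_postcodes": s.n_postcodes,
        "population": s.population,
        "n_local": s.n_local,
        "n_online": s.n_online,
        "n_hybrid": s.n_hybrid,
        "pct_change": "" if s.pct_change is None else s.pct_change,
    } for s in summaries])
    _df_to_csv(df, Path(path))


def write_wordcloud_json(frequencies: Sequence[tuple[str, int]],
                         path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = [{"descriptor": d, "count": n} for d, n in frequencies]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def write_density_geojson(
    densities: Mapping[str, float],
    counts: Mapping[str, int],
    geography: pd.DataFrame,
    path: str | Path,
    pct_change_by_postcode: Optional[Mapping[str, Optional[int]]] = None,
) -> None:
    """Point FeatureCollection per postcode (centroid of its suburb midpoints),
    with count/density/pct_change properties; lon-lat order."""
    geo = geography.copy()
    geo["postcode"] = geo["postcode"].astype(str)
    centroids = geo.groupby("postcode")[["lon", "lat"]].mean()
    features = []
    for pc in sorted(densities):
        if pc not in centroids.index:
            continue
        lon, lat = centroids.loc[pc, "lon"], centroids.loc[pc, "lat"]
        props = {"postcode": pc, "count": counts.get(pc, 0),
                 "density": round(densities[pc], 6)}
        if pct_change_by_postcode is not None:
            props["pct_change"] = pct_change_by_postcode.get(pc)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(float(lon), 6), round(float(lat), 6)]},
            "properties": props,
        })
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(fc, indent=1), encoding="utf-8")
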