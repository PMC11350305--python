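"""Synthetic outlet universe and noisy "scraped" views.

No deposited data exist for this kind of analysis — the scraped sources are
ephemeral — so the package generates its own ground truth: a universe of
outlets placed in a synthetic geography, rendered into the two views the
pipeline consumes, with a truth map linking every rendered row back to its
universe outlet (or marking it as an injected contaminant). That makes
linkage, filtering and categorization testable end to end.

The two views emulate the structural quirks of real scraped listings:

* the *local* (directory) view lists every outlet once, plus non-food and
  permanently-closed contaminant rows at configurable rates;
* the *online* (delivery-platform) view lists each participating outlet once
  **per suburb it delivers to**, so unique outlets appear many times under one
  platform ID; participation is higher in urban than rural regions;
* both views suffer field noise: missing suburbs/postcodes/street numbers,
  shopping-centre prefixes, suburb/city/state tokens embedded in names and
  addresses, case shuffles and stray punctuation.

Determinism: one global seed drives per-row substreams keyed by row index
(via ``numpy`` SeedSequence spawn keys), so outputs are byte-identical for a
fixed seed and insertion order cannot change noise outcomes.

Distances are equirectangular: ``d = R * sqrt(dphi^2 + (cos(phi_m) dlambda)^2)``
with R = 6371.0088 km — exact enough at suburb scale for deriving delivery
suburb lists.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import GeographySpec, NoiseConfig, SimulationConfig
from .types import GroundTruthOutlet, MainCategory, RawOutletListing, Source, Status

EARTH_RADIUS_KM = 6371.0088

# ---------------------------------------------------------------------------
# word pools (kept disjoint from each other so normalization token-removal
# cannot eat outlet-name words)

_SUBURB_FIRST = ("oak", "fern", "wattle", "marra", "bella", "stone", "clear",
                 "glen", "wara", "kirra", "tall", "yarra")
_SUBURB_SECOND = ("vale", "ville", "wood", "creek", "heights", "point",
                  "ridge", "brook", "field", "bay", "downs", "gully")

_STREET_NAMES = ("king", "queen", "maple", "church", "station", "harbour",
                 "anchor", "miller", "bourke", "elm", "cedar", "pine",
                 "acacia", "banksia", "victoria", "albert", "short", "long",
                 "north", "south", "railway", "ocean", "river", "hill")
_STREET_TYPES = ("street", "road", "avenue", "drive", "lane", "parade",
                 "place", "crescent")

_NAME_ADJ = ("golden", "silver", "happy", "lucky", "royal", "rustic", "cosy",
             "urban", "little", "grand", "blue", "red", "green", "velvet",
             "smoky", "crispy", "spicy", "sweet", "wild", "humble")
_NAME_NOUN = ("dragon", "lotus", "kitchen", "bistro", "grill", "pantry",
              "spoon", "fork", "table", "garden", "corner", "hearth", "wok",
              "oven", "plate", "bowl", "cup", "bean", "olive", "basil")

_NONFOOD_NAMES = ("sparkle jewellers", "brightlight appliances",
                  "ironmonger supplies", "apex corporate office",
                  "shear bliss hair salon", "wellfit gym",
                  "crystal car wash", "petal florist")
_NONFOOD_TAGS = ("jewelry store", "appliance store", "hardware store",
                 "corporate office", "hair salon", "gym", "car wash", "florist")

#: per-category descriptor pools for independents (single-category lexicon
#: entries only, so the true category always has the unique maximum score)
_CATEGORY_DESCRIPTORS: dict[MainCategory, tuple[str, ...]] = {
    MainCategory.INDEPENDENT_RESTAURANT_CAFE: (
        "asian", "italian", "thai", "vietnamese", "indian", "cafe", "coffee",
        "sushi", "noodles", "dumplings", "seafood"),
    MainCategory.INDEPENDENT_TAKEAWAY: (
        "chicken", "comfort food", "burger", "kebab", "pizza",
        "fried chicken", "fish and chips", "wings", "family meals"),
    MainCategory.SUPERMARKET_GROCER: ("supermarket", "grocery"),
    MainCategory.FRESH_PRODUCE: (
        "greengrocer", "fruit and vegetables", "farmers market", "butcher"),
    MainCategory.SANDWICH_SALAD: ("salad", "sandwich", "salad bar", "wraps"),
    MainCategory.SWEETS_EXTRA: (
        "desserts", "ice cream", "bubble tea", "frozen yoghurt", "juice"),
    MainCategory.BAKERY: ("bakery", "bread", "pastries", "patisserie"),
    MainCategory.CONVENIENCE_PETROL: (
        "convenience store", "petrol station", "service station", "corner store"),
    MainCategory.ALCOHOL_RETAILER: ("bottle shop", "liquor store", "wine merchant"),
}

_URBAN_REGION_NAMES = ("metro east", "metro west", "metro north", "metro south",
                       "harbour city", "inner ring")
_RURAL_REGION_NAMES = ("riverlands", "far plains", "high country",
                       "western downs", "coastal strip", "tablelands")


def equirectangular_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Equirectangular approximation of great-circle distance in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    x = dlam * math.cos((phi1 + phi2) / 2.0)
    return EARTH_RADIUS_KM * math.hypot(dphi, x)


def make_geography(spec: Optional[GeographySpec] = None) -> pd.DataFrame:
    """Deterministic synthetic geography: suburbs on a planar grid per region.

    Columns: suburb, postcode, region, region_population, urban, lat, lon.
    Regions are placed ~110 km apart so delivery radii never straddle regions;
    urban suburbs sit on a tighter grid than rural ones.
    """
    spec = spec or GeographySpec()
    rows = []
    suburb_names = [f"{a}{b}" for a in _SUBURB_FIRST for b in _SUBURB_SECOND]
    name_idx = 0
    postcode_urban = 2000
    postcode_rural = 2800
    region_idx = 0
    plans = [(True, spec.n_urban_regions, spec.suburbs_per_urban_region,
              spec.urban_spacing_km),
             (False, spec.n_rural_regions, spec.suburbs_per_rural_region,
              spec.rural_spacing_km)]
    for urban, n_regions, n_suburbs, spacing in plans:
        pool = _URBAN_REGION_NAMES if urban else _RURAL_REGION_NAMES
        for r in range(n_regions):
            region = pool[r] if r < len(pool) else f"{'urban' if urban else 'rural'} region {r + 1}"
            base_lat = -33.0 - region_idx * 1.0
            base_lon = 150.5
            population = (420_000 + 30_000 * r) if urban else (115_000 + 18_000 * r)
            dlat = spacing / 111.32
            dlon = spacing / (111.32 * math.cos(math.radians(base_lat)))
            cols = 4
            for s in range(n_suburbs):
                lat = base_lat + (s // cols) * dlat
                lon = base_lon + (s % cols) * dlon
                suburb = suburb_names[name_idx % len(suburb_names)]
                if name_idx >= len(suburb_names):  # keep names unique
                    suburb = f"{suburb}{name_idx // len(suburb_names) + 1}"
                name_idx += 1
                if urban:
                    postcode = f"{postcode_urban}"
                    postcode_urban += 1
                else:
                    postcode = f"{postcode_rural}"
                    postcode_rural += 1
                rows.append({"suburb": suburb, "postcode": postcode,
                             "region": region, "region_population": population,
                             "urban": urban, "lat": round(lat, 6),
                             "lon": round(lon, 6)})
            region_idx += 1
    return pd.DataFrame(rows)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Substream generator: deterministic in (seed, key), order-independent."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_universe(
    config: SimulationConfig,
    geography: pd.DataFrame,
    seed: int,
) -> list[GroundTruthOutlet]:
    """Draw the ground-truth outlet universe.

    Franchise brand locations are planted first (each brand exactly at its
    configured location count, spread over regions proportionally to region
    size); remaining slots become independents with the configured category
    mix. A configured fraction of food outlets is permanently closed and a
    fraction of rows are non-food businesses. Delivery-platform participation
    is Bernoulli per outlet with an urban or rural rate by region.
    """
    if geography.empty:
        raise ValueError("geography must be non-empty")
    counts = config.outlets_per_region
    if any(n < 0 for n in counts.values()):
        raise ValueError("negative outlet counts")
    unknown = set(counts) - set(geography["region"])
    if unknown:
        raise ValueError(f"regions not in geography: {sorted(unknown)}")

    region_urban = dict(zip(geography["region"], geography["urban"]))
    suburbs_by_region = {
        r: g[["suburb", "postcode", "lat", "lon"]].to_dict("records")
        for r, g in geography.groupby("region", sort=False)
    }

    # region slot list in deterministic order, then shuffled once
    slots: list[str] = []
    for region in counts:
        slots.extend([region] * counts[region])
    n_total = len(slots)
    n_franchise = sum(b.n_locations for b in config.franchise_brands)
    if n_franchise > n_total:
        raise ValueError("franchise locations exceed total outlet count")
    rng0 = _rng(seed, 0)
    slots = [slots[i] for i in rng0.permutation(n_total)]

    # category sampler for independents
    mix_items = [(MainCategory(k), v) for k, v in config.category_mix.items()]
    weights = np.array([v for _, v in mix_items], dtype=float)
    weights = weights / weights.sum()

    outlets: list[GroundTruthOutlet] = []
    brand_plan: list[tuple[str, int]] = []  # (brand name, index in config)
    for bi, b in enumerate(config.franchise_brands):
        brand_plan.extend([(b.name, bi)] * b.n_locations)

    used_keys: set[tuple[str, str, str]] = set()  # (name, suburb, street)
    for i, region in enumerate(slots):
        rng = _rng(seed, 1, i)
        region_suburbs = suburbs_by_region[region]

        def draw_place():
            sub = region_suburbs[int(rng.integers(len(region_suburbs)))]
            street = _STREET_NAMES[int(rng.integers(len(_STREET_NAMES)))]
            return sub, street

        def draw_indep_name():
            adj = _NAME_ADJ[int(rng.integers(len(_NAME_ADJ)))]
            noun = _NAME_NOUN[int(rng.integers(len(_NAME_NOUN)))]
            name = f"{adj} {noun}"
            if rng.random() < 0.3:
                name = f"{name} {_NAME_NOUN[int(rng.integers(len(_NAME_NOUN)))]}"
            return name

        sub, street_name = draw_place()
        street_type = _STREET_TYPES[int(rng.integers(len(_STREET_TYPES)))]
        street_number = int(rng.integers(1, 300))

        if i < len(brand_plan):
            brand_name, bi = brand_plan[i]
            brand_spec = config.franchise_brands[bi]
            name = brand_name
            category = MainCategory.TAKEAWAY_FRANCHISE
            descriptors = tuple(brand_spec.descriptors)
            is_food = True
            brand: Optional[str] = brand_name
            # one branch per street per suburb: keeps distinct physical
            # locations distinguishable by address
            for _ in range(50):
                if (name, sub["suburb"], street_name) not in used_keys:
                    break
                sub, street_name = draw_place()
        else:
            brand = None
            if rng.random() < config.nonfood_fraction:
                is_food = False
                category = MainCategory.NA
                name = _NONFOOD_NAMES[int(rng.integers(len(_NONFOOD_NAMES)))]
                descriptors = (_NONFOOD_TAGS[int(rng.integers(len(_NONFOOD_TAGS)))],)
            else:
                is_food = True
                category = mix_items[int(rng.choice(len(mix_items), p=weights))][0]
                pool = _CATEGORY_DESCRIPTORS[category]
                k = int(rng.integers(1, min(3, len(pool)) + 1))
                idx = rng.choice(len(pool), size=k, replace=False)
                descriptors = tuple(pool[j] for j in sorted(int(x) for x in idx))
                name = draw_indep_name()
                for _ in range(50):
                    if (name, sub["suburb"], street_name) not in used_keys:
                        break
                    name = draw_indep_name()
                    sub, street_name = draw_place()
        if is_food:
            used_keys.add((name, sub["suburb"], street_name))
        jitter_km = rng.uniform(-0.8, 0.8, size=2)
        lat = sub["lat"] + jitter_km[0] / 111.32
        lon = sub["lon"] + jitter_km[1] / (111.32 * math.cos(math.radians(sub["lat"])))
        is_open = bool(rng.random() >= config.closed_fraction)
        participation = (config.urban_participation if region_urban[region]
                         else config.rural_participation)
        on_platform = bool(is_food and is_open and rng.random() < participation)
        outlets.append(GroundTruthOutlet(
            truth_id=f"t{i:06d}",
            brand=brand,
            canonical_name=name,
            street_number=street_number,
            street_name=street_name,
            street_type=street_type,
            suburb=sub["suburb"],
            postcode=sub["postcode"],
            region=region,
            latitude=lat,
            longitude=lon,
            true_category=category,
            descriptors=descriptors,
            is_food_business=is_food,
            is_open=is_open,
            on_delivery_platform=on_platform,
            delivery_radius_km=config.delivery_radius_km,
        ))
    return outlets


# ---------------------------------------------------------------------------
# noise operators


def _noisy_name(name: str, suburb: str, rng: np.random.Generator,
                noise: NoiseConfig) -> str:
    if rng.random() < noise.p_name_decoration:
        extra = [suburb.title(), "Sydney", "NSW", f"{suburb.title()} NSW"]
        name = f"{name} {extra[int(rng.integers(len(extra)))]}"
    if rng.random() < noise.p_punctuation:
        words = name.split()
        mode = int(rng.integers(3))
        if mode == 0 and words and words[0].endswith("s"):
            words[0] = words[0][:-1] + "'s"
        elif mode == 1 and len(words) >= 2:
            words[0] = words[0] + "-" + words[1]
            del words[1]
        else:
            words[-1] = words[-1] + "!"
        name = " ".join(words)
    if rng.random() < noise.p_case_shuffle:
        mode = int(rng.integers(3))
        name = name.upper() if mode == 0 else name.title() if mode == 1 else name
    return name


def _noisy_address(
    outlet: GroundTruthOutlet, rng: np.random.Generator, noise: NoiseConfig,
    centre_list: Sequence[str],
) -> tuple[str, Optional[str], Optional[str]]:
    """Returns (street_address, suburb_or_none, postcode_or_none)."""
    addr = f"{outlet.street_number} {outlet.street_name} {outlet.street_type}"
    if rng.random() < noise.p_missing_street_number:
        addr = f"{outlet.street_name} {outlet.street_type}"
    if rng.random() < noise.p_centre_prefix and centre_list:
        centre = centre_list[int(rng.integers(len(centre_list)))]
        addr = f"Shop {int(rng.integers(1, 40))}, {centre.title()}, {addr}"
    if rng.random() < noise.p_address_embed:
        addr = f"{addr} {outlet.suburb.title()} NSW {outlet.postcode}"
    suburb: Optional[str] = outlet.suburb
    postcode: Optional[str] = outlet.postcode
    if rng.random() < noise.p_missing_both:
        suburb = postcode = None
    else:
        if rng.random() < noise.p_missing_suburb:
            suburb = None
        if rng.random() < noise.p_missing_postcode:
            postcode = None
    return addr, suburb, postcode


def render_local_view(
    universe: Sequence[GroundTruthOutlet],
    noise: NoiseConfig,
    centre_list: Sequence[str] = (),
) -> tuple[list[RawOutletListing], list[tuple[str, str, str]]]:
    """Render the directory ("local") view of the universe.

    One row per universe outlet plus injected contaminant rows (non-food and
    permanently-closed) at the configured rates. Returns ``(rows, truth_map)``
    where truth_map rows are ``(row_id, truth_id, contaminant_flag)`` with an
    empty truth_id and a flag of ``"nonfood"``/``"closed"`` for contaminants.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    rows: list[RawOutletListing] = []
    truth_map: list[tuple[str, str, str]] = []
    for i, u in enumerate(universe):
        rng = _rng(noise.seed, 10, i)
        addr, suburb, postcode = _noisy_address(u, rng, noise, centre_list)
        name = _noisy_name(u.canonical_name, u.suburb, rng, noise)
        row_id = f"g{i:06d}"
        rows.append(RawOutletListing(
            source=Source.LOCAL,
            source_id=row_id,
            name=name,
            street_address=addr,
            suburb=suburb.title() if suburb else None,
            state="NSW",
            postcode=postcode,
            latitude=u.latitude,
            longitude=u.longitude,
            category_descriptors=list(u.descriptors),
            status=Status.OPEN if u.is_open else Status.PERMANENTLY_CLOSED,
        ))
        truth_map.append((row_id, u.truth_id, ""))
        # injected contaminants, each on its own substream
        crng = _rng(noise.seed, 11, i)
        if crng.random() < noise.p_nonfood_rows:
            rid = f"gn{i:06d}"
            nf = int(crng.integers(len(_NONFOOD_NAMES)))
            rows.append(RawOutletListing(
                source=Source.LOCAL, source_id=rid,
                name=_NONFOOD_NAMES[nf].title(),
                street_address=f"{int(crng.integers(1, 300))} "
                               f"{_STREET_NAMES[int(crng.integers(len(_STREET_NAMES)))]} street",
                suburb=u.suburb.title(), state="NSW", postcode=u.postcode,
                latitude=u.latitude, longitude=u.longitude,
                category_descriptors=[_NONFOOD_TAGS[nf % len(_NONFOOD_TAGS)]],
                status=Status.OPEN,
            ))
            truth_map.append((rid, "", "nonfood"))
        if crng.random() < noise.p_closed_rows:
            rid = f"gc{i:06d}"
            adj = _NAME_ADJ[int(crng.integers(len(_NAME_ADJ)))]
            noun = _NAME_NOUN[int(crng.integers(len(_NAME_NOUN)))]
            rows.append(RawOutletListing(
                source=Source.LOCAL, source_id=rid,
                name=f"{adj} {noun}".title(),
                street_address=f"{int(crng.integers(1, 300))} "
                               f"{_STREET_NAMES[int(crng.integers(len(_STREET_NAMES)))]} road",
                suburb=u.suburb.title(), state="NSW", postcode=u.postcode,
                latitude=u.latitude, longitude=u.longitude,
                category_descriptors=["cafe"],
                status=Status.PERMANENTLY_CLOSED,
            ))
            truth_map.append((rid, "", "closed"))
    return rows, truth_map


def delivery_suburbs(
    outlet: GroundTruthOutlet, geography: pd.DataFrame,
) -> list[dict]:
    """Suburb rows within the outlet's delivery radius (sorted by name);
    falls back to the outlet's home suburb when the radius covers none."""
    hits = [
        rec for rec in geography.to_dict("records")
        if equirectangular_km(outlet.latitude, outlet.longitude,
                              rec["lat"], rec["lon"]) <= outlet.delivery_radius_km
    ]
    if not hits:
        hits = [rec for rec in geography.to_dict("records")
                if rec["suburb"] == outlet.suburb]
    return sorted(hits, key=lambda r: r["suburb"])


def render_online_view(
    universe: Sequence[GroundTruthOutlet],
    geography: pd.DataFrame,
    noise: NoiseConfig,
    centre_list: Sequence[str] = (),
) -> tuple[list[RawOutletListing], list[tuple[str, str, str]]]:
    """Render the delivery-platform ("online") view.

    Each participating outlet yields one row per delivery suburb within its
    radius; all rows of an outlet share one platform outlet ID. Noise applies
    independently per row. Truth-map rows are keyed by the per-row id
    ``<platform_id>:<k>`` (the platform id itself prefixes every row of the
    outlet).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    rows: list[RawOutletListing] = []
    truth_map: list[tuple[str, str, str]] = []
    for i, u in enumerate(universe):
        if not u.on_delivery_platform:
            continue
        pid = f"u{i:06d}"
        for k, sub in enumerate(delivery_suburbs(u, geography)):
            rng = _rng(noise.seed, 20, i, k)
            addr, suburb, postcode = _noisy_address(u, rng, noise, centre_list)
            name = _noisy_name(u.canonical_name, u.suburb, rng, noise)
            rows.append(RawOutletListing(
                source=Source.ONLINE,
                source_id=pid,
                name=name,
                street_address=addr,
                suburb=suburb.title() if suburb else None,
                state="NSW",
                postcode=postcode,
                latitude=u.latitude,
                longitude=u.longitude,
                category_descriptors=list(u.descriptors),
                status=Status.OPEN,
                extra={"delivery_suburb": sub["suburb"], "row_id": f"{pid}:{k}"},
            ))
            truth_map.append((f"{pid}:{k}", u.truth_id, ""))
    return rows, truth_map


def truth_by_source_id(truth_map: Sequence[tuple[str, str, str]]) -> dict[str, str]:
    """Map source ids to truth ids (platform row ids collapse to their ID)."""
    out: dict[str, str] = {}
    for row_id, truth_id, flag in truth_map:
        if flag:
            continue
        out[row_id.split(":")[0]] = truth_id
    return out
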